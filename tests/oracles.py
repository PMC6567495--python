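"""Independent brute-force oracles used by the test suite.

Deliberately naive (pure-Python loops, no shared code with the package) so
agreement with the optimized implementations is meaningful.
"""

from __future__ import annotations

import math


def brute_recurrence_matrix(symbols):
    n = len(symbols)
    return [[1 if symbols[i] == symbols[j] else 0 for j in range(n)] for i in range(n)]


def brute_recurrence_rate(symbols, theiler=1):
    """Percent of off-band cells that are recurrent, by exhaustive pair count."""
    n = len(symbols)
    mat = brute_recurrence_matrix(symbols)
    num = den = 0
    for i in range(n):
        for j in range(n):
            if abs(i - j) < theiler:
                continue
            den += 1
            num += mat[i][j]
    return 100.0 * num / den


def brute_diagonal_histogram(symbols, theiler=1):
    """Maximal diagonal runs on the upper triangle, enumerated cell by cell."""
    n = len(symbols)
    mat = brute_recurrence_matrix(symbols)
    hist: dict[int, int] = {}
    for offset in range(theiler, n):
        run = 0
        for i in range(n - offset):
            if mat[i][i + offset]:
                run += 1
            else:
                if run:
                    hist[run] = hist.get(run, 0) + 1
                run = 0
        if run:
            hist[run] = hist.get(run, 0) + 1
    return hist


def brute_determinism(symbols, lmin=2, theiler=1):
    hist = brute_diagonal_histogram(symbols, theiler)
    total = sum(l * c for l, c in hist.items())
    if total == 0:
        return None
    return 100.0 * sum(l * c for l, c in hist.items() if l >= lmin) / total


def brute_entropy(symbols, lmin=2, theiler=1):
    hist = brute_diagonal_histogram(symbols, theiler)
    counts = [c for l, c in hist.items() if l >= lmin]
    if not counts:
        return None
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts)


def ols_fit(x_rows, y):
    """Closed-form least squares (normal equations via Gaussian elimination)."""
    n = len(x_rows)
    p = len(x_rows[0])
    xtx = [[sum(x_rows[i][a] * x_rows[i][b] for i in range(n)) for b in range(p)] for a in range(p)]
    xty = [sum(x_rows[i][a] * y[i] for i in range(n)) for a in range(p)]
    # Gaussian elimination with partial pivoting
    aug = [row[:] + [xty[a]] for a, row in enumerate(xtx)]
    for col in range(p):
        pivot = max(range(col, p), key=lambda r: abs(aug[r][col]))
        aug[col], aug[pivot] = aug[pivot], aug[col]
        for r in range(p):
            if r != col and aug[r][col] != 0:
                f = aug[r][col] / aug[col][col]
                aug[r] = [aug[r][c] - f * aug[col][c] for c in range(p + 1)]
    return [aug[a][p] / aug[a][a] for a in range(p)]
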
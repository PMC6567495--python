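"""Categorical recurrence quantification analysis (RQA).

A coded interaction sequence is treated as a categorical time series: the
recurrence plot marks every pair of time points at which the group revisits
the same interaction state (exact symbol equality — the categorical limit of
the usual closeness threshold).  Three summary measures quantify the plot:

* recurrence rate (RR, %) — how often any state recurs: the "stability" of
  the interaction pattern;
* determinism (DET, %) — the share of recurrent points lying on diagonal
  lines of at least ``lmin`` cells: the predictability of the sequence;
* diagonal-line entropy (ENT, bits) — Shannon entropy of the distribution of
  maximal diagonal line lengths: the complexity of the recurrence structure.

The line of identity (main diagonal, where every state trivially matches
itself) is excluded from all three measures via a Theiler window, so that RR
spans the full 0–100 range.  Diagonal lines are counted on the upper
triangle only; by symmetry the lower triangle duplicates every line and
cannot change DET or ENT.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RQAConfig",
    "RecurrencePlot",
    "RQAMeasures",
    "RQAError",
    "recurrence_matrix",
    "diagonal_line_histogram",
    "recurrence_rate",
    "determinism",
    "entropy",
    "rqa_measures",
    "export_plot",
    "read_plot",
]


class RQAError(ValueError):
    """Raised for undefined RQA quantities (e.g. DET with no recurrences)."""


@dataclass(frozen=True)
class RQAConfig:
    """Quantification settings.

    Parameters
    ----------
    lmin:
        Minimum diagonal line length counted as deterministic (>= 2).
    theiler:
        Half-width of the line-of-identity exclusion band.  The default 1
        excludes only the main diagonal itself.
    entropy_log_base:
        Base of the entropy logarithm; 2 gives bits.
    """

    lmin: int = 2
    theiler: int = 1
    entropy_log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.lmin < 2:
            raise ValueError(f"lmin must be >= 2, got {self.lmin}")
        if self.theiler < 1:
            raise ValueError(f"theiler must be >= 1, got {self.theiler}")
        if self.entropy_log_base <= 1:
            raise ValueError("entropy_log_base must be > 1")


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary N x N self-similarity matrix of a categorical sequence."""

    matrix: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape != (self.n, self.n):
            raise ValueError("matrix must be square of side n")


@dataclass(frozen=True)
class RQAMeasures:
    """Bundle of the three RQA measures for one sequence.

    ``det`` and ``ent`` are ``None`` when undefined (no off-diagonal
    recurrent point, or no diagonal line reaching ``lmin``).
    """

    rr: float
    det: float | None
    ent: float | None
    n_recurrent: int
    line_histogram: Mapping[int, int] = field(default_factory=dict)


def _as_codes(seq) -> np.ndarray:
    symbols = getattr(seq, "symbols", seq)
    arr = np.asarray(symbols)
    if arr.size < 2:
        raise RQAError("sequence must contain at least 2 symbols")
    # map arbitrary hashable symbols to integer codes
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def recurrence_matrix(seq) -> RecurrencePlot:
    """Build the categorical recurrence plot of a symbol sequence.

    Entry (i, j) is 1 iff symbol_i == symbol_j; the matrix is symmetric with
    an all-ones main diagonal (line of identity).
    """
    codes = _as_codes(seq)
    mat = (codes[:, None] == codes[None, :]).astype(np.uint8)
    return RecurrencePlot(matrix=mat, n=len(codes))


def diagonal_line_histogram(plot: RecurrencePlot, config: RQAConfig | None = None) -> dict[int, int]:
    """Histogram of maximal diagonal line lengths on the upper triangle.

    Every maximal run of consecutive recurrent cells along a diagonal at
    offset >= ``theiler`` contributes one count at its length.
    """
    config = config or RQAConfig()
    mat = plot.matrix
    hist: Counter[int] = Counter()
    for offset in range(config.theiler, plot.n):
        diag = np.diagonal(mat, offset=offset).astype(bool)
        if not diag.any():
            continue
        # run lengths of True values via edges of the padded boolean diagonal
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for length in ends - starts:
            hist[int(length)] += 1
    return dict(hist)


def _n_recurrent(plot: RecurrencePlot, config: RQAConfig) -> int:
    """Off-line-of-identity recurrent cell count (both triangles)."""
    mat = plot.matrix
    total = int(mat.sum())
    for offset in range(config.theiler):
        total -= int(np.diagonal(mat, offset=offset).sum())
        if offset > 0:
            total -= int(np.diagonal(mat, offset=-offset).sum())
    return total


def recurrence_rate(plot: RecurrencePlot, config: RQAConfig | None = None) -> float:
    """Recurrence rate in percent: off-diagonal recurrent cells / (N^2 - N).

    With the default Theiler window both triangles enter numerator and
    denominator, so a constant sequence scores 100 and an all-distinct
    sequence 0.
    """
    config = config or RQAConfig()
    n = plot.n
    if n < 2:
        raise RQAError("recurrence rate undefined for N < 2")
    denom = n * n - n
    for offset in range(1, config.theiler):
        denom -= 2 * (n - offset)
    return 100.0 * _n_recurrent(plot, config) / denom


def determinism(plot: RecurrencePlot, config: RQAConfig | None = None) -> float:
    """Percent of recurrent points on diagonal lines of length >= lmin.

    Undefined (raises :class:`RQAError`) when the plot has no off-diagonal
    recurrent point at all.
    """
    config = config or RQAConfig()
    hist = diagonal_line_histogram(plot, config)
    total = sum(l * c for l, c in hist.items())
    if total == 0:
        raise RQAError("determinism undefined: no off-diagonal recurrent points")
    det_points = sum(l * c for l, c in hist.items() if l >= config.lmin)
    return 100.0 * det_points / total


def entropy(plot: RecurrencePlot, config: RQAConfig | None = None) -> float:
    """Shannon entropy (bits by default) of diagonal line lengths >= lmin."""
    config = config or RQAConfig()
    hist = diagonal_line_histogram(plot, config)
    return entropy_from_histogram(hist, config)


def entropy_from_histogram(hist: Mapping[int, int], config: RQAConfig | None = None) -> float:
    config = config or RQAConfig()
    counts = np.array([c for l, c in hist.items() if l >= config.lmin], dtype=float)
    if counts.size == 0:
        raise RQAError(f"entropy undefined: no diagonal line of length >= {config.lmin}")
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / np.log(config.entropy_log_base))).sum()) + 0.0


def rqa_measures(seq, config: RQAConfig | None = None) -> RQAMeasures:
    """Compute RR, DET and ENT for a symbol sequence in one pass.

    DET and ENT are reported as ``None`` where undefined rather than raising,
    so batch runs over many groups degrade gracefully.
    """
    config = config or RQAConfig()
    plot = recurrence_matrix(seq)
    hist = diagonal_line_histogram(plot, config)
    n_rec = _n_recurrent(plot, config)
    rr = recurrence_rate(plot, config)
    det = determinism(plot, config) if n_rec > 0 else None
    try:
        ent = entropy_from_histogram(hist, config)
    except RQAError:
        ent = None
    return RQAMeasures(rr=rr, det=det, ent=ent, n_recurrent=n_rec, line_histogram=hist)


def export_plot(plot: RecurrencePlot, path) -> None:
    """Write the binary recurrence matrix as CSV with 1-based time labels."""
    if not str(path):
        raise ValueError("empty output path")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t"] + [str(i + 1) for i in range(plot.n)])
        for i in range(plot.n):
            writer.writerow([str(i + 1)] + [str(int(v)) for v in plot.matrix[i]])


def read_plot(path) -> RecurrencePlot:
    """Read a recurrence matrix written by :func:`export_plot`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    data = np.array([[int(v) for v in row[1:]] for row in rows[1:]], dtype=np.uint8)
    return RecurrencePlot(matrix=data, n=data.shape[0])
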
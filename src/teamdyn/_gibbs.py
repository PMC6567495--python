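"""Collapsed Gibbs sampling kernels for LDA (numba-compiled inner loops).

The hot loop touches every token once per sweep, so it is kept free of
Python objects and compiled with numba.  Randomness uses the legacy numpy
global generator inside the jitted function, seeded explicitly on entry —
the same seed reproduces the same trajectory on any platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_discrete(p, total):
    u = np.random.random() * total
    acc = 0.0
    for k in range(p.shape[0]):
        acc += p[k]
        if u < acc:
            return k
    return p.shape[0] - 1


@njit(cache=True)
def run_gibbs(doc_ids, word_ids, n_docs, n_vocab, n_topics, alpha, beta, n_iter, seed):
    """Sweep token-topic assignments n_iter times; return final count tables.

    Conditional for token i in document d with word w:
        p(t) ∝ (n_wt + beta) / (n_t + V beta) * (n_dt + alpha)
    """
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    n_dt = np.zeros((n_docs, n_topics), dtype=np.int64)
    n_wt = np.zeros((n_vocab, n_topics), dtype=np.int64)
    n_t = np.zeros(n_topics, dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int32)
    for i in range(n_tokens):
        t = np.random.randint(0, n_topics)
        z[i] = t
        n_dt[doc_ids[i], t] += 1
        n_wt[word_ids[i], t] += 1
        n_t[t] += 1
    p = np.empty(n_topics, dtype=np.float64)
    for _ in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            t = z[i]
            n_dt[d, t] -= 1
            n_wt[w, t] -= 1
            n_t[t] -= 1
            total = 0.0
            for k in range(n_topics):
                p[k] = (n_wt[w, k] + beta) / (n_t[k] + n_vocab * beta) * (n_dt[d, k] + alpha)
                total += p[k]
            t = _sample_discrete(p, total)
            z[i] = t
            n_dt[d, t] += 1
            n_wt[w, t] += 1
            n_t[t] += 1
    return n_dt, n_wt, n_t


@njit(cache=True)
def run_fold_in(doc_ids, word_ids, n_docs, phi, alpha, n_sweeps, seed):
    """Gibbs over held-out tokens with phi frozen; returns doc-topic counts."""
    np.random.seed(seed)
    n_topics = phi.shape[0]
    n_tokens = doc_ids.shape[0]
    n_dt = np.zeros((n_docs, n_topics), dtype=np.int64)
    z = np.empty(n_tokens, dtype=np.int32)
    for i in range(n_tokens):
        t = np.random.randint(0, n_topics)
        z[i] = t
        n_dt[doc_ids[i], t] += 1
    p = np.empty(n_topics, dtype=np.float64)
    for _ in range(n_sweeps):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            n_dt[d, z[i]] -= 1
            total = 0.0
            for k in range(n_topics):
                p[k] = phi[k, w] * (n_dt[d, k] + alpha)
                total += p[k]
            t = _sample_discrete(p, total)
            z[i] = t
            n_dt[d, t] += 1
    return n_dt
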
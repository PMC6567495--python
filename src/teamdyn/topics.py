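"""Transcript preprocessing, LDA by collapsed Gibbs sampling, and
perplexity-based selection of the number of topics.

Meeting transcripts (one document per group) are reduced to stemmed token
streams: lowercase, punctuation stripped, whitespace-tokenised, stopwords
removed, tokens of length <= 2 or >= 15 dropped, then Porter-stemmed.  The
corpus is modelled with latent Dirichlet allocation — each document a
mixture theta_d over T topics, each topic a distribution phi_t over the
vocabulary — fitted by collapsed Gibbs sampling of token-topic assignments
with conditional

    p(z_i = t | ...)  ∝  (n_wt + beta) / (n_t + V beta) · (n_dt + alpha).

The number of topics is chosen by held-out perplexity: a seeded 10%
document-level partition is scored under each candidate T (document mixtures
for held-out documents estimated by fold-in Gibbs with phi frozen), and the
T with the lowest perplexity wins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._stopwords import DEFAULT_STOPWORDS
from .porter import porter_stem

logger = logging.getLogger(__name__)

_NON_ALPHA = re.compile(r"[^a-z]+")


@dataclass(frozen=True)
class PreprocessConfig:
    """Token filtering settings.

    ``min_len``/``max_len`` are the inclusive bounds of retained token
    length, applied before stemming.
    """

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    min_len: int = 3
    max_len: int = 14
    stem: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.max_len <= self.min_len:
            raise ValueError("require 1 <= min_len < max_len")


def preprocess(text: str, config: PreprocessConfig | None = None) -> list[str]:
    """Turn raw transcript text into an ordered list of stemmed tokens."""
    config = config or PreprocessConfig()
    tokens = _NON_ALPHA.sub(" ", text.lower()).split()
    out = []
    for tok in tokens:
        if tok in config.stopwords:
            continue
        if not config.min_len <= len(tok) <= config.max_len:
            continue
        out.append(porter_stem(tok) if config.stem else tok)
    return out


def load_stopwords(path) -> frozenset[str]:
    """Read a one-word-per-line stopword file."""
    words = {line.strip().lower() for line in Path(path).read_text().splitlines()}
    return frozenset(w for w in words if w)


@dataclass(frozen=True)
class Corpus:
    """Bag-of-words corpus: a shared vocabulary and per-document counts."""

    vocabulary: tuple[str, ...]
    docs: tuple[dict[int, int], ...]
    doc_ids: tuple[str, ...]

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_vocab(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return sum(sum(d.values()) for d in self.docs)

    def subset(self, indices: Sequence[int]) -> "Corpus":
        """Document subset sharing this corpus's vocabulary."""
        return Corpus(
            vocabulary=self.vocabulary,
            docs=tuple(self.docs[i] for i in indices),
            doc_ids=tuple(self.doc_ids[i] for i in indices),
        )


def build_corpus(token_lists: Iterable[Sequence[str]], doc_ids: Sequence[str] | None = None) -> Corpus:
    """Build a corpus from preprocessed token lists.

    The vocabulary is ordered by first appearance; empty documents are
    dropped with a warning.
    """
    token_lists = list(token_lists)
    if doc_ids is None:
        doc_ids = [f"doc{i}" for i in range(len(token_lists))]
    vocab_index: dict[str, int] = {}
    docs: list[dict[int, int]] = []
    kept_ids: list[str] = []
    for doc_id, tokens in zip(doc_ids, token_lists):
        if not tokens:
            logger.warning("dropping empty document %s", doc_id)
            continue
        counts: dict[int, int] = {}
        for tok in tokens:
            idx = vocab_index.setdefault(tok, len(vocab_index))
            counts[idx] = counts.get(idx, 0) + 1
        docs.append(counts)
        kept_ids.append(doc_id)
    if not docs:
        raise ValueError("all documents are empty after preprocessing")
    vocabulary = tuple(sorted(vocab_index, key=vocab_index.get))
    return Corpus(vocabulary=vocabulary, docs=tuple(docs), doc_ids=tuple(kept_ids))


def read_transcripts(directory, config: PreprocessConfig | None = None) -> Corpus:
    """Preprocess every ``*.txt`` transcript in a directory into a corpus."""
    paths = sorted(Path(directory).glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no .txt transcripts under {directory}")
    return build_corpus(
        [preprocess(p.read_text(encoding="utf-8"), config) for p in paths],
        doc_ids=[p.stem for p in paths],
    )


@dataclass(frozen=True)
class LDAConfig:
    """Sampler settings; ``alpha=None`` means the 50/T heuristic."""

    n_topics: int
    alpha: float | None = None
    beta: float = 0.01
    n_iter: int = 1000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("require n_iter > burn_in >= 0")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.n_topics


@dataclass(frozen=True)
class TopicModel:
    """Fitted (or ground-truth) topic-word and document-topic matrices."""

    phi: np.ndarray  # T x V, rows sum to 1
    theta: np.ndarray  # D x T, rows sum to 1
    vocabulary: tuple[str, ...]
    config: LDAConfig | None = None

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]


@dataclass(frozen=True)
class PerplexityCurve:
    candidate_T: tuple[int, ...]
    perplexity: tuple[float, ...]
    best_T: int


def _expand_tokens(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    """Flatten per-doc counts into parallel (doc_id, word_id) token arrays."""
    doc_ids, word_ids = [], []
    for d, counts in enumerate(corpus.docs):
        for w in sorted(counts):
            c = counts[w]
            doc_ids.extend([d] * c)
            word_ids.extend([w] * c)
    return np.asarray(doc_ids, dtype=np.int32), np.asarray(word_ids, dtype=np.int32)


def fit_lda(corpus: Corpus, config: LDAConfig) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling.

    Token-topic assignments are swept ``n_iter`` times; phi and theta are
    estimated from the final counts with the same Dirichlet smoothing the
    sampler uses.  The same corpus, config and seed reproduce the same model
    bit for bit.
    """
    from ._gibbs import run_gibbs  # deferred: numba compilation on first use

    T, V, D = config.n_topics, corpus.n_vocab, corpus.n_docs
    if V == 0 or D == 0:
        raise ValueError("empty corpus")
    doc_ids, word_ids = _expand_tokens(corpus)
    if T > doc_ids.size:
        raise ValueError(f"n_topics={T} exceeds total token count {doc_ids.size}")
    alpha, beta = config.effective_alpha, config.beta
    n_dt, n_wt, n_t = run_gibbs(
        doc_ids, word_ids, D, V, T, alpha, beta, config.n_iter, config.seed
    )
    phi = (n_wt.T + beta) / (n_t[:, None] + V * beta)
    theta = (n_dt + alpha) / (n_dt.sum(axis=1, keepdims=True) + T * alpha)
    return TopicModel(phi=phi, theta=theta, vocabulary=corpus.vocabulary, config=config)


def _map_heldout(model: TopicModel, heldout: Corpus) -> tuple[np.ndarray, np.ndarray, int]:
    """Re-index held-out tokens into the model vocabulary; drop OOV tokens."""
    vocab_index = {w: i for i, w in enumerate(model.vocabulary)}
    doc_ids, word_ids = [], []
    n_oov = 0
    for d, counts in enumerate(heldout.docs):
        for w, c in sorted(counts.items()):
            idx = vocab_index.get(heldout.vocabulary[w])
            if idx is None:
                n_oov += c
                continue
            doc_ids.extend([d] * c)
            word_ids.extend([idx] * c)
    if n_oov:
        logger.info("perplexity: dropped %d out-of-vocabulary held-out tokens", n_oov)
    return (
        np.asarray(doc_ids, dtype=np.int32),
        np.asarray(word_ids, dtype=np.int32),
        n_oov,
    )


def fold_in_theta(
    model: TopicModel, heldout: Corpus, n_sweeps: int = 50, seed: int = 0
) -> np.ndarray:
    """Estimate document-topic mixtures for unseen documents.

    Gibbs sampling over the held-out tokens with the topic-word matrix
    frozen; returns the smoothed theta-hat for each held-out document.
    """
    from ._gibbs import run_fold_in

    doc_ids, word_ids, _ = _map_heldout(model, heldout)
    if doc_ids.size == 0:
        raise ValueError("held-out corpus has no in-vocabulary tokens")
    alpha = model.config.effective_alpha if model.config else 50.0 / model.n_topics
    n_dt = run_fold_in(doc_ids, word_ids, heldout.n_docs, model.phi, alpha, n_sweeps, seed)
    return (n_dt + alpha) / (n_dt.sum(axis=1, keepdims=True) + model.n_topics * alpha)


def perplexity(
    model: TopicModel, heldout: Corpus, n_fold_in_sweeps: int = 50, seed: int = 0
) -> float:
    """Held-out perplexity exp(-mean per-token log-likelihood); lower is better."""
    doc_ids, word_ids, _ = _map_heldout(model, heldout)
    if doc_ids.size == 0:
        raise ValueError("empty held-out set (or all tokens out of vocabulary)")
    theta = fold_in_theta(model, heldout, n_sweeps=n_fold_in_sweeps, seed=seed)
    p_w_d = (theta[doc_ids] * model.phi[:, word_ids].T).sum(axis=1)
    return float(np.exp(-np.log(p_w_d).mean()))


def select_num_topics(
    corpus: Corpus,
    candidates: Sequence[int],
    holdout_fraction: float = 0.1,
    seed: int = 0,
    lda_config: LDAConfig | None = None,
) -> PerplexityCurve:
    """Choose the number of topics by held-out perplexity.

    A single seeded document-level split reserves ``holdout_fraction`` of the
    documents; each candidate T is fitted on the remainder and scored on the
    held-out documents.  Ties go to the smallest T.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(holdout_fraction * corpus.n_docs)))
    if n_hold >= corpus.n_docs:
        raise ValueError("corpus too small for the requested held-out fraction")
    perm = rng.permutation(corpus.n_docs)
    hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    fit_corpus, hold_corpus = corpus.subset(fit_idx), corpus.subset(hold_idx)

    perps = []
    for T in candidates:
        base = lda_config or LDAConfig(n_topics=T)
        cfg = LDAConfig(
            n_topics=T,
            alpha=base.alpha,
            beta=base.beta,
            n_iter=base.n_iter,
            burn_in=base.burn_in,
            seed=int(rng.integers(2**31 - 1)),
        )
        model = fit_lda(fit_corpus, cfg)
        perps.append(perplexity(model, hold_corpus, seed=cfg.seed))
    best_T = candidates[int(np.argmin(perps))]  # argmin takes the first, i.e. smallest T
    return PerplexityCurve(candidate_T=tuple(candidates), perplexity=tuple(perps), best_T=best_T)


def top_words(model: TopicModel, topic: int, k: int = 10) -> list[tuple[str, float]]:
    """The k most probable stems of one topic, descending; ties alphabetical."""
    if not 0 <= topic < model.n_topics:
        raise IndexError(f"topic {topic} out of range 0..{model.n_topics - 1}")
    if k < 1:
        raise ValueError("k must be >= 1")
    row = model.phi[topic]
    order = sorted(range(len(row)), key=lambda w: (-row[w], model.vocabulary[w]))
    return [(model.vocabulary[w], float(row[w])) for w in order[:k]]
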
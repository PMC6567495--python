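"""Synthetic study generator with known ground truth.

Recordings, transcripts and questionnaires from real team studies are
rarely shareable, so every downstream stage is exercised on simulated data
whose generating parameters are known and therefore recoverable:

* interaction sequences from a first-order Markov mixture whose two weights
  map directly onto the recurrence-rate ("stability") and determinism
  constructs: at each step the previous symbol is repeated with probability
  ``stability``, its fixed cyclic successor follows with probability
  ``determinism_strength``, and otherwise a uniform symbol is drawn;
* two 7-point Likert subscales (quality of participation, social support)
  whose latent group means depend linearly on the group's RR and DET with
  group-, participant- and item-level Gaussian noise, rounded and clamped
  to 1..7;
* a bag-of-words corpus from the standard LDA generative process (topics
  Dirichlet(beta), document mixtures Dirichlet(alpha), Poisson lengths).

Defaults describe a typical role-play study: 28 groups of 3–5 members, sequence
lengths Normal(157, 67) floored at 10, subscale group means near 5.68
(participation) and 4.78 (support), and a 28-document corpus of roughly
53,000 tokens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import rqa
from .sequences import (
    TEAM,
    InteractionEvent,
    SymbolSequence,
    dyad_alphabet,
    write_event_log,
    write_sequence,
)
from .topics import Corpus, TopicModel

SCALE_PARTICIPATION = "quality of participation"
SCALE_SUPPORT = "social support"


@dataclass(frozen=True)
class InteractionGenConfig:
    """Markov-mixture knobs for one group's interaction sequence."""

    n_members: int = 4
    length: int = 157
    stability: float = 0.15
    determinism_strength: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name in ("stability", "determinism_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stability + self.determinism_strength > 1:
            raise ValueError("stability + determinism_strength must be <= 1")


def generate_interaction_sequence(
    config: InteractionGenConfig,
    alphabet: Sequence[str] | None = None,
    group_id: str = "",
) -> SymbolSequence:
    """Simulate one session's who-with-whom symbol sequence.

    The cyclic successor map is "next symbol in sorted alphabet order"; the
    first symbol is uniform.  The same config and seed reproduce the same
    sequence exactly.
    """
    if alphabet is None:
        alphabet = sorted(dyad_alphabet(config.n_members))
    else:
        alphabet = sorted(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = np.random.default_rng(config.seed)
    k = len(alphabet)
    idx = int(rng.integers(k))
    indices = [idx]
    for _ in range(config.length - 1):
        u = rng.random()
        if u < config.stability:
            pass  # repeat previous
        elif u < config.stability + config.determinism_strength:
            idx = (idx + 1) % k
        else:
            idx = int(rng.integers(k))
        indices.append(idx)
    return SymbolSequence(
        symbols=tuple(alphabet[i] for i in indices),
        alphabet=frozenset(alphabet),
        group_id=group_id,
    )


@dataclass(frozen=True)
class StudyGenConfig:
    """Whole-study generator: groups, sequences and both questionnaire scales.

    The latent subscale value of group g is

        beta0(+_rr RR_g + beta_det DET_g) + group noise,

    with participant- and item-level noise added before rounding to the
    1..7 Likert range.  Participation slopes default to zero (the study
    found no association for that scale); support defaults follow the
    reported positive-stability / negative-determinism pattern.
    """

    n_groups: int = 28
    members_range: tuple[int, int] = (3, 5)
    events_mean: float = 157.0
    events_sd: float = 67.0
    stability_range: tuple[float, float] = (0.05, 0.25)
    determinism_range: tuple[float, float] = (0.15, 0.45)
    beta_support_rr: float = 0.022
    beta_support_det: float = -0.008
    beta0: float = 4.81
    beta_participation_rr: float = 0.0
    beta_participation_det: float = 0.0
    beta0_participation: float = 5.68
    noise_sd_group: float = 0.30
    noise_sd_individual: float = 0.45
    noise_sd_item: float = 0.60
    items_per_scale: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.items_per_scale < 2:
            raise ValueError("items_per_scale must be >= 2")
        for name in ("events_sd", "noise_sd_group", "noise_sd_individual", "noise_sd_item"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.members_range[0] < 2 or self.members_range[1] < self.members_range[0]:
            raise ValueError("invalid members_range")


@dataclass(frozen=True)
class GroupData:
    group_id: str
    n_members: int
    sequence: SymbolSequence
    events: tuple[InteractionEvent, ...]
    rr: float
    det: float
    ent: float


@dataclass(frozen=True)
class StudyDataset:
    groups: tuple[GroupData, ...]
    responses: pd.DataFrame  # participant, group, scale, item, value
    truth: dict

    def measures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [g.group_id for g in self.groups],
                "rr": [g.rr for g in self.groups],
                "det": [g.det for g in self.groups],
                "ent": [g.ent for g in self.groups],
            }
        )


def _events_from_symbols(seq: SymbolSequence, rng: np.random.Generator, session_s: float = 1800.0):
    """Materialise a symbol sequence as a coded event log (the reverse of
    encoding): dyad direction is random, IPA categories uniform 1..12."""
    events = []
    n = len(seq.symbols)
    for i, sym in enumerate(seq.symbols):
        time_s = round(session_s * (i + 1) / (n + 1), 1)
        ipa = int(rng.integers(1, 13))
        left, right = sym.split("-")
        if right == "T":
            source, target = int(left), TEAM
        else:
            a, b = int(left), int(right)
            source, target = (a, b) if rng.random() < 0.5 else (b, a)
        events.append(
            InteractionEvent(time_s=time_s, source=source, target=target, ipa_category=ipa)
        )
    return tuple(events)


def generate_study(config: StudyGenConfig) -> StudyDataset:
    """Simulate a full study: sequences, RQA measures, and both subscales.

    Ground-truth parameters are stored in ``truth`` alongside the realised
    per-group stability/determinism draws.
    """
    rng = np.random.default_rng(config.seed)
    groups: list[GroupData] = []
    group_params = []
    for g in range(config.n_groups):
        n_members = int(rng.integers(config.members_range[0], config.members_range[1] + 1))
        length = max(10, int(round(rng.normal(config.events_mean, config.events_sd))))
        stability = float(rng.uniform(*config.stability_range))
        det_strength = float(rng.uniform(*config.determinism_range))
        gcfg = InteractionGenConfig(
            n_members=n_members,
            length=length,
            stability=stability,
            determinism_strength=det_strength,
            seed=int(rng.integers(2**31 - 1)),
        )
        group_id = f"g{g + 1:02d}"
        seq = generate_interaction_sequence(gcfg, group_id=group_id)
        m = rqa.rqa_measures(seq)
        groups.append(
            GroupData(
                group_id=group_id,
                n_members=n_members,
                sequence=seq,
                events=_events_from_symbols(seq, rng),
                rr=m.rr,
                det=m.det if m.det is not None else 0.0,
                ent=m.ent if m.ent is not None else 0.0,
            )
        )
        group_params.append({"group": group_id, "stability": stability,
                             "determinism_strength": det_strength, "length": length})

    scales = {
        SCALE_PARTICIPATION: (
            config.beta0_participation, config.beta_participation_rr, config.beta_participation_det
        ),
        SCALE_SUPPORT: (config.beta0, config.beta_support_rr, config.beta_support_det),
    }
    rows = []
    latent_means: dict[str, dict[str, float]] = {}
    for grp in groups:
        group_noise = {s: rng.normal(0.0, config.noise_sd_group) for s in scales}
        latent_means[grp.group_id] = {
            s: b0 + b_rr * grp.rr + b_det * grp.det + group_noise[s]
            for s, (b0, b_rr, b_det) in scales.items()
        }
        for member in range(1, grp.n_members + 1):
            participant = f"{grp.group_id}p{member}"
            indiv_noise = {s: rng.normal(0.0, config.noise_sd_individual) for s in scales}
            for scale, (b0, b_rr, b_det) in scales.items():
                latent = b0 + b_rr * grp.rr + b_det * grp.det + group_noise[scale] + indiv_noise[scale]
                for item in range(1, config.items_per_scale + 1):
                    value = int(round(latent + rng.normal(0.0, config.noise_sd_item)))
                    rows.append(
                        {
                            "participant": participant,
                            "group": grp.group_id,
                            "scale": scale,
                            "item": item,
                            "value": min(7, max(1, value)),
                        }
                    )
    responses = pd.DataFrame(rows)
    truth = {
        "config": asdict(config),
        "groups": group_params,
        "latent_group_means": latent_means,
        "coefficients": {
            SCALE_SUPPORT: {"intercept": config.beta0, "rr": config.beta_support_rr,
                            "det": config.beta_support_det, "ent": 0.0},
            SCALE_PARTICIPATION: {"intercept": config.beta0_participation,
                                  "rr": config.beta_participation_rr,
                                  "det": config.beta_participation_det, "ent": 0.0},
        },
    }
    return StudyDataset(groups=tuple(groups), responses=responses, truth=truth)


@dataclass(frozen=True)
class CorpusGenConfig:
    """LDA generative-process knobs for the synthetic transcript corpus."""

    n_topics: int = 15
    vocab_size: int = 1500
    n_docs: int = 28
    mean_doc_length: float = 1910.0
    alpha: float = 0.1
    beta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.vocab_size <= self.n_topics:
            raise ValueError("vocab_size must exceed n_topics")
        if self.n_docs < 1 or self.mean_doc_length <= 0:
            raise ValueError("n_docs and mean_doc_length must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")


_WORD_LETTERS = "bcdfghjkmnpqrtvwz"  # no vowels/s/y: tokens survive preprocessing


def _vocab_word(i: int, width: int = 4) -> str:
    base = len(_WORD_LETTERS)
    digits = []
    for _ in range(width):
        digits.append(_WORD_LETTERS[i % base])
        i //= base
    return "".join(reversed(digits))


def generate_corpus(config: CorpusGenConfig) -> tuple[Corpus, TopicModel]:
    """Draw a corpus from the LDA generative process; return it with truth.

    Topic-word rows phi_t ~ Dirichlet(beta 1_V), document mixtures
    theta_d ~ Dirichlet(alpha 1_T), document lengths Poisson (min 1),
    tokens sampled topic-then-word.
    """
    rng = np.random.default_rng(config.seed)
    T, V, D = config.n_topics, config.vocab_size, config.n_docs
    phi = rng.dirichlet(np.full(V, config.beta), size=T)
    theta = rng.dirichlet(np.full(T, config.alpha), size=D)
    vocabulary = tuple(_vocab_word(i) for i in range(V))
    docs = []
    for d in range(D):
        length = max(1, int(rng.poisson(config.mean_doc_length)))
        topic_counts = rng.multinomial(length, theta[d])
        counts: dict[int, int] = {}
        for t, c in enumerate(topic_counts):
            if c == 0:
                continue
            word_counts = rng.multinomial(c, phi[t])
            for w in np.flatnonzero(word_counts):
                counts[int(w)] = counts.get(int(w), 0) + int(word_counts[w])
        docs.append(counts)
    corpus = Corpus(vocabulary=vocabulary, docs=tuple(docs),
                    doc_ids=tuple(f"g{d + 1:02d}" for d in range(D)))
    truth = TopicModel(phi=phi, theta=theta, vocabulary=vocabulary, config=None)
    return corpus, truth


def write_corpus_transcripts(corpus: Corpus, directory, rng: np.random.Generator | None = None) -> None:
    """Write each document as a plain-text transcript of shuffled tokens."""
    rng = rng or np.random.default_rng(0)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc_id, counts in zip(corpus.doc_ids, corpus.docs):
        tokens = [corpus.vocabulary[w] for w, c in sorted(counts.items()) for _ in range(c)]
        order = rng.permutation(len(tokens))
        text_tokens = [tokens[i] for i in order]
        lines = [" ".join(text_tokens[i:i + 15]) for i in range(0, len(text_tokens), 15)]
        (directory / f"{doc_id}.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_study(dataset: StudyDataset, directory) -> None:
    """Write a dataset in the same formats the ingestion code reads:
    per-group event-log CSVs, sequence text files, a questionnaire CSV and
    a ground-truth JSON."""
    directory = Path(directory)
    (directory / "events").mkdir(parents=True, exist_ok=True)
    (directory / "sequences").mkdir(parents=True, exist_ok=True)
    for grp in dataset.groups:
        write_event_log(grp.events, directory / "events" / f"{grp.group_id}.csv")
        write_sequence(grp.sequence, directory / "sequences" / f"{grp.group_id}.txt")
    dataset.responses.to_csv(directory / "questionnaire.csv", index=False)
    (directory / "truth.json").write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
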
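"""End-to-end orchestration: simulate/ingest -> encode -> RQA -> topics -> GEE.

A single YAML config drives a seeded, reproducible run.  Each data stream
(interaction study, transcript corpus) comes either from real input paths or
from a ``simulate`` block — never both.  One global seed fans out to
per-stage seeds (stage-name hashed) so stages can be rerun in isolation;
identical config + seed gives byte-identical artifacts, which the manifest
records as SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, rqa, synthetic, topics as topics_mod
from .sequences import encode_sequence, read_event_log, read_sequence, write_sequence

logger = logging.getLogger(__name__)

STAGES = ("data", "rqa", "topics", "associate")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable across runs)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> list[str]:
    """Check every nested constraint; return a human-readable error list."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")

    sim = config.get("simulate") or {}
    inputs = config.get("inputs") or {}
    has_sim_study = "study" in sim
    has_real_study = "events_dir" in inputs and "questionnaire" in inputs
    if has_sim_study == has_real_study:
        errors.append(
            "exactly one of simulate.study or inputs.events_dir+questionnaire must be given"
        )
    has_sim_corpus = "corpus" in sim
    has_real_corpus = "transcripts_dir" in inputs
    if has_sim_corpus == has_real_corpus:
        errors.append("exactly one of simulate.corpus or inputs.transcripts_dir must be given")

    rqa_cfg = config.get("rqa") or {}
    try:
        rqa.RQAConfig(**rqa_cfg)
    except (TypeError, ValueError) as exc:
        errors.append(f"rqa: {exc}")
    lda_cfg = config.get("lda") or {}
    try:
        topics_mod.LDAConfig(n_topics=2, **lda_cfg)
    except (TypeError, ValueError) as exc:
        errors.append(f"lda: {exc}")
    top = config.get("topics") or {}
    candidates = top.get("candidates", [5, 10, 15, 20, 25, 30])
    if not candidates or any(not isinstance(c, int) or c < 1 for c in candidates):
        errors.append("topics.candidates must be positive integers")
    holdout = top.get("holdout_fraction", 0.1)
    if not 0 < holdout < 1:
        errors.append("topics.holdout_fraction must be in (0, 1)")
    if has_sim_study:
        try:
            synthetic.StudyGenConfig(**{k: _tuplify(v) for k, v in sim["study"].items()})
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate.study: {exc}")
    if has_sim_corpus:
        try:
            synthetic.CorpusGenConfig(**sim["corpus"])
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate.corpus: {exc}")
    gee = config.get("gee") or {}
    if gee.get("cov_struct", "exchangeable") not in ("exchangeable", "independence"):
        errors.append("gee.cov_struct must be 'exchangeable' or 'independence'")
    return errors


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_study_inputs(config: dict, out_dir: Path):
    """Return (sequences dict, responses frame), simulating if configured.

    Simulated studies are round-tripped through the on-disk CSV/text formats
    so synthetic runs exercise the same I/O path as real data.
    """
    sim = config.get("simulate") or {}
    inputs = config.get("inputs") or {}
    if "study" in sim:
        kwargs = {k: _tuplify(v) for k, v in sim["study"].items()}
        kwargs.setdefault("seed", stage_seed(config.get("seed", 0), "data"))
        dataset = synthetic.generate_study(synthetic.StudyGenConfig(**kwargs))
        data_dir = out_dir / "data"
        synthetic.write_study(dataset, data_dir)
        events_dir, questionnaire = data_dir / "events", data_dir / "questionnaire.csv"
    else:
        events_dir, questionnaire = Path(inputs["events_dir"]), Path(inputs["questionnaire"])
    sequences = {}
    for path in sorted(events_dir.glob("*.csv")):
        events = read_event_log(path)
        n_members = max(
            max(ev.source for ev in events),
            max((ev.target for ev in events if isinstance(ev.target, int)), default=0),
        )
        sequences[path.stem] = encode_sequence(events, n_members, group_id=path.stem)
    if not sequences:
        raise ConfigError(f"no event logs found under {events_dir}")
    responses = pd.read_csv(questionnaire)
    return sequences, responses


def _load_corpus(config: dict, out_dir: Path):
    sim = config.get("simulate") or {}
    inputs = config.get("inputs") or {}
    if "corpus" in sim:
        kwargs = dict(sim["corpus"])
        kwargs.setdefault("seed", stage_seed(config.get("seed", 0), "data"))
        corpus, _truth = synthetic.generate_corpus(synthetic.CorpusGenConfig(**kwargs))
        tdir = out_dir / "data" / "transcripts"
        synthetic.write_corpus_transcripts(
            corpus, tdir, rng=np.random.default_rng(kwargs["seed"])
        )
    else:
        tdir = Path(inputs["transcripts_dir"])
    stop_path = (config.get("topics") or {}).get("stopwords_file")
    pre = topics_mod.PreprocessConfig(
        stopwords=topics_mod.load_stopwords(stop_path)
        if stop_path
        else topics_mod.PreprocessConfig().stopwords
    )
    return topics_mod.read_transcripts(tdir, pre)


def run_all(config: dict, out_dir) -> Path:
    """Execute every stage and write the five artifacts plus a manifest.

    Artifacts: measures.json, topics.json, perplexity.csv, word_freq.csv,
    table1.csv; manifest.json records the config hash, seed, package
    versions and the SHA-256 of every artifact.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s starting", name)
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    try:
        _stage("data")
        sequences, responses = _load_study_inputs(config, out_dir)
        corpus = _load_corpus(config, out_dir)
        _done("data")
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    try:
        _stage("rqa")
        rqa_cfg = rqa.RQAConfig(**(config.get("rqa") or {}))
        seq_dir = out_dir / "sequences"
        seq_dir.mkdir(exist_ok=True)
        records = []
        for group_id in sorted(sequences):
            seq = sequences[group_id]
            m = rqa.rqa_measures(seq, rqa_cfg)
            write_sequence(seq, seq_dir / f"{group_id}.txt")
            records.append(
                {"group_id": group_id, "n": len(seq), "rr": m.rr, "det": m.det,
                 "ent": m.ent, "n_recurrent": m.n_recurrent}
            )
        (out_dir / "measures.json").write_text(json.dumps(records, indent=2, sort_keys=True))
        _done("rqa")
    except Exception as exc:
        raise RuntimeError(f"stage 'rqa' failed: {exc}") from exc

    try:
        _stage("topics")
        top_cfg = config.get("topics") or {}
        lda_kwargs = dict(config.get("lda") or {})
        lda_kwargs.pop("seed", None)  # per-stage seeds are derived from the global one
        candidates = top_cfg.get("candidates", [5, 10, 15, 20, 25, 30])
        curve = topics_mod.select_num_topics(
            corpus,
            candidates,
            holdout_fraction=top_cfg.get("holdout_fraction", 0.1),
            seed=stage_seed(seed, "topics"),
            lda_config=topics_mod.LDAConfig(n_topics=2, **lda_kwargs),
        )
        model = topics_mod.fit_lda(
            corpus,
            topics_mod.LDAConfig(
                n_topics=curve.best_T, seed=stage_seed(seed, "topics-final"), **lda_kwargs
            ),
        )
        k = int(top_cfg.get("top_k", 10))
        topics_out = {
            "best_T": curve.best_T,
            "topics": [
                {"topic": t, "top_words": [{"word": w, "p": round(p, 6)}
                                           for w, p in topics_mod.top_words(model, t, k)]}
                for t in range(model.n_topics)
            ],
            "theta": {doc: [round(x, 6) for x in model.theta[i]]
                      for i, doc in enumerate(corpus.doc_ids)},
        }
        (out_dir / "topics.json").write_text(json.dumps(topics_out, indent=2, sort_keys=True))
        pd.DataFrame(
            {"n_topics": curve.candidate_T, "perplexity": curve.perplexity}
        ).to_csv(out_dir / "perplexity.csv", index=False)
        freq: dict[str, int] = {}
        for counts in corpus.docs:
            for w, c in counts.items():
                word = corpus.vocabulary[w]
                freq[word] = freq.get(word, 0) + c
        pd.DataFrame(
            sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])), columns=["word", "count"]
        ).to_csv(out_dir / "word_freq.csv", index=False)
        _done("topics")
    except Exception as exc:
        raise RuntimeError(f"stage 'topics' failed: {exc}") from exc

    try:
        _stage("associate")
        measures = pd.DataFrame(
            [{"group": r["group_id"], "rr": r["rr"], "det": r["det"], "ent": r["ent"]}
             for r in records]
        )
        table, details = association.run_association(
            measures, responses,
            cov_struct=(config.get("gee") or {}).get("cov_struct", "exchangeable"),
        )
        association.write_results_table(table, out_dir / "table1.csv")
        _done("associate")
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    artifacts = ["measures.json", "topics.json", "perplexity.csv", "word_freq.csv", "table1.csv"]
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {"teamdyn": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "artifacts": {name: _sha256(out_dir / name) for name in artifacts},
        "cronbach_alpha": {k: round(v, 4) for k, v in details["alpha"].items()},
        "vif": {k: round(v, 4) for k, v in details["vif"].items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
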
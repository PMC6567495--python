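import numpy as np
import pytest

from teamdyn.synthetic import CorpusGenConfig, StudyGenConfig, generate_corpus, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study (8 groups) shared by read-only tests."""
    return generate_study(StudyGenConfig(n_groups=8, events_mean=60, events_sd=15, seed=42))


@pytest.fixture(scope="session")
def small_corpus():
    """A small LDA-generated corpus with known ground truth."""
    cfg = CorpusGenConfig(
        n_topics=3, vocab_size=60, n_docs=40, mean_doc_length=50, alpha=0.1, beta=0.1, seed=3
    )
    corpus, truth = generate_corpus(cfg)
    return corpus, truth, cfg


def random_symbol_sequences(n, rng, min_len=5, max_len=60, min_alpha=2, max_alpha=8):
    """Random categorical sequences for oracle-equivalence sweeps."""
    out = []
    for _ in range(n):
        k = int(rng.integers(min_alpha, max_alpha + 1))
        length = int(rng.integers(min_len, max_len + 1))
        out.append([str(s) for s in rng.integers(0, k, size=length)])
    return out
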
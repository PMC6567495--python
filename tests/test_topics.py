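"""Preprocessing, corpus building, Gibbs LDA and perplexity selection."""

import numpy as np
import pytest

from teamdyn.topics import (
    Corpus,
    LDAConfig,
    PreprocessConfig,
    build_corpus,
    fit_lda,
    fold_in_theta,
    load_stopwords,
    perplexity,
    preprocess,
    read_transcripts,
    select_num_topics,
    top_words,
)


class TestPreprocess:
    def test_inflections_reduce_to_common_stem(self):
        assert preprocess("Talks, talking, TALKED!") == ["talk", "talk", "talk"]

    def test_stopwords_removed(self):
        assert preprocess("of a and") == []

    def test_length_filters(self):
        # 2-char and 20-char tokens are dropped
        assert preprocess("an ox internationalisation") == []

    def test_digits_discarded(self):
        assert preprocess("room 101 discussion") == ["room", "discuss"]

    def test_empty_text_gives_empty_list(self):
        assert preprocess("") == []

    def test_filtering_is_idempotent(self):
        # The filter chain (casing, punctuation, stopwords, length) is a
        # fixed point after one pass.  Stemming itself is not idempotent
        # (Porter maps e.g. "nurs" -> "nur"), so idempotence is checked on
        # the unstemmed stream and on stem-stable text separately.
        cfg = PreprocessConfig(stem=False)
        text = "The nurses were reporting incidents repeatedly during meetings"
        once = preprocess(text, cfg)
        assert preprocess(" ".join(once), cfg) == once

    def test_idempotent_on_stem_stable_text(self):
        text = "team discuss patient error report check hospital"
        once = preprocess(text)
        assert preprocess(" ".join(once)) == once

    def test_custom_stopword_file(self, tmp_path):
        path = tmp_path / "stop.txt"
        path.write_text("nurse\ndoctor\n")
        cfg = PreprocessConfig(stopwords=load_stopwords(path), stem=False)
        assert preprocess("nurse doctor patient", cfg) == ["patient"]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(min_len=5, max_len=5)


class TestBuildCorpus:
    def test_counts_and_first_appearance_vocabulary(self):
        corpus = build_corpus([["a", "b", "a"]])
        assert corpus.vocabulary == ("a", "b")
        assert corpus.docs == ({0: 2, 1: 1},)

    def test_disjoint_documents_sum_vocabularies(self):
        corpus = build_corpus([["x", "y"], ["p", "q", "r"]])
        assert corpus.n_vocab == 5

    def test_empty_documents_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            corpus = build_corpus([["a"], [], ["b"]])
        assert corpus.n_docs == 2
        assert "empty document" in caplog.text

    def test_all_empty_is_an_error(self):
        with pytest.raises(ValueError):
            build_corpus([[], []])

    def test_study_scale_corpus_builds_quickly(self):
        import time

        rng = np.random.default_rng(0)
        vocab = [f"stem{i}" for i in range(2000)]
        docs = [
            [vocab[j] for j in rng.integers(0, 2000, size=1900)] for _ in range(28)
        ]
        t0 = time.perf_counter()
        corpus = build_corpus(docs)
        assert time.perf_counter() - t0 < 1.0
        assert corpus.n_tokens == 28 * 1900


class TestFitLDA:
    def test_single_topic_recovers_word_frequencies(self):
        corpus = build_corpus([["a", "a", "b"], ["b", "c"]])
        model = fit_lda(corpus, LDAConfig(n_topics=1, beta=1e-9, n_iter=5, burn_in=1, seed=0))
        np.testing.assert_allclose(model.phi[0], np.array([2, 2, 1]) / 5, atol=1e-6)
        np.testing.assert_allclose(model.theta, 1.0)

    def test_rows_are_distributions(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=3, n_iter=30, burn_in=10, seed=1))
        np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
        assert (model.phi >= 0).all() and (model.theta >= 0).all()

    def test_seeded_fit_is_reproducible(self, small_corpus):
        corpus, _, _ = small_corpus
        cfg = LDAConfig(n_topics=3, n_iter=20, burn_in=5, seed=9)
        m1, m2 = fit_lda(corpus, cfg), fit_lda(corpus, cfg)
        np.testing.assert_array_equal(m1.phi, m2.phi)
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_more_topics_than_tokens_rejected(self):
        corpus = build_corpus([["a", "b"]])
        with pytest.raises(ValueError):
            fit_lda(corpus, LDAConfig(n_topics=10, n_iter=2, burn_in=1))

    def test_training_likelihood_improves_over_sampling(self, small_corpus):
        """Perplexity on the training set should drop from a 1-sweep fit to a
        converged fit in the majority of seeds."""
        corpus, _, _ = small_corpus
        wins = 0
        for seed in range(5):
            early = fit_lda(corpus, LDAConfig(n_topics=3, alpha=0.1, beta=0.1,
                                              n_iter=1, burn_in=0, seed=seed))
            late = fit_lda(corpus, LDAConfig(n_topics=3, alpha=0.1, beta=0.1,
                                             n_iter=80, burn_in=40, seed=seed))
            if perplexity(late, corpus, seed=seed) <= perplexity(early, corpus, seed=seed):
                wins += 1
        assert wins >= 3


class TestPerplexity:
    def test_uniform_model_gives_vocabulary_size(self):
        v = 12
        vocab = tuple(f"w{i}" for i in range(v))
        corpus = Corpus(vocabulary=vocab, docs=({0: 2, 3: 1, 7: 1},), doc_ids=("d0",))
        from teamdyn.topics import TopicModel

        model = TopicModel(
            phi=np.full((1, v), 1.0 / v), theta=np.ones((1, 1)), vocabulary=vocab,
            config=LDAConfig(n_topics=1),
        )
        assert perplexity(model, corpus) == pytest.approx(v, rel=1e-9)

    def test_duplicated_document_same_per_token_perplexity(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=3, alpha=0.1, n_iter=30, burn_in=10, seed=2))
        hold = corpus.subset([0])
        doubled = Corpus(
            vocabulary=hold.vocabulary, docs=hold.docs * 2, doc_ids=("d", "d2")
        )
        p1 = perplexity(model, hold, seed=3)
        p2 = perplexity(model, doubled, seed=3)
        assert p2 == pytest.approx(p1, rel=0.05)  # fold-in is stochastic

    def test_out_of_vocabulary_tokens_dropped(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=2, n_iter=20, burn_in=5, seed=4))
        oov = Corpus(vocabulary=("zzzz",), docs=({0: 3},), doc_ids=("d",))
        with pytest.raises(ValueError, match="out of vocabulary|empty held-out"):
            perplexity(model, oov)

    def test_fold_in_theta_rows_normalized(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=3, alpha=0.1, n_iter=30, burn_in=10, seed=5))
        theta = fold_in_theta(model, corpus.subset([1, 2]), seed=6)
        np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-9)


class TestSelectNumTopics:
    def test_single_candidate_trivially_selected(self, small_corpus):
        corpus, _, _ = small_corpus
        curve = select_num_topics(
            corpus, [1], seed=0,
            lda_config=LDAConfig(n_topics=1, n_iter=10, burn_in=2),
        )
        assert curve.best_T == 1

    def test_same_seed_gives_identical_curve(self, small_corpus):
        corpus, _, _ = small_corpus
        kwargs = dict(candidates=[2, 4], seed=5,
                      lda_config=LDAConfig(n_topics=2, n_iter=20, burn_in=5))
        c1 = select_num_topics(corpus, **kwargs)
        c2 = select_num_topics(corpus, **kwargs)
        assert c1 == c2

    def test_degenerate_holdout_rejected(self):
        corpus = build_corpus([["a", "b"]])
        with pytest.raises(ValueError):
            select_num_topics(corpus, [1, 2], holdout_fraction=0.5)


class TestTopWords:
    def test_probabilities_non_increasing_and_ranked(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=3, n_iter=30, burn_in=10, seed=7))
        pairs = top_words(model, 0, k=10)
        probs = [p for _, p in pairs]
        assert probs == sorted(probs, reverse=True)
        assert len(pairs) == 10

    def test_uniform_single_topic_equal_probabilities(self):
        corpus = build_corpus([["a", "b", "c", "d"]])
        model = fit_lda(corpus, LDAConfig(n_topics=1, beta=1e-9, n_iter=5, burn_in=1, seed=0))
        pairs = top_words(model, 0, k=4)
        assert [w for w, _ in pairs] == ["a", "b", "c", "d"]  # ties alphabetical
        assert all(p == pytest.approx(0.25, abs=1e-6) for _, p in pairs)

    def test_topic_out_of_range(self, small_corpus):
        corpus, _, _ = small_corpus
        model = fit_lda(corpus, LDAConfig(n_topics=2, n_iter=10, burn_in=2, seed=8))
        with pytest.raises(IndexError):
            top_words(model, 2, 5)


class TestReadTranscripts:
    def test_directory_round_trip(self, tmp_path):
        (tmp_path / "g1.txt").write_text("Nurses reported the incident.\n")
        (tmp_path / "g2.txt").write_text("Doctors discussed hospital culture.\n")
        corpus = read_transcripts(tmp_path)
        assert corpus.n_docs == 2
        assert corpus.doc_ids == ("g1", "g2")
        assert "nurs" in corpus.vocabulary

    def test_missing_directory_contents(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_transcripts(tmp_path)
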
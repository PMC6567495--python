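"""Topic modelling with perplexity-based selection of the topic count.

Draws a corpus from the LDA generative process with 5 true topics, scores
candidate topic numbers by held-out perplexity (10% document split), then
fits the selected model and prints each topic's most probable words.
Lower perplexity = the model is less surprised by unseen documents.  The
curve drops sharply up to the true topic count and flattens beyond it, so
the argmin lands on the truth or its immediate neighbour; the elbow marks
the parsimonious choice.
"""

from teamdyn.synthetic import CorpusGenConfig, generate_corpus
from teamdyn.topics import LDAConfig, fit_lda, select_num_topics, top_words

corpus, truth = generate_corpus(
    CorpusGenConfig(n_topics=5, vocab_size=200, n_docs=200, mean_doc_length=100, seed=0)
)
print(f"corpus: {corpus.n_docs} documents, {corpus.n_tokens} tokens, V={corpus.n_vocab}")

curve = select_num_topics(
    corpus, candidates=[2, 5, 10], seed=0,
    lda_config=LDAConfig(n_topics=2, alpha=0.1, beta=0.05, n_iter=200, burn_in=100),
)
for T, p in zip(curve.candidate_T, curve.perplexity):
    marker = "  <- selected" if T == curve.best_T else ""
    print(f"  T={T:>2}: held-out perplexity {p:7.2f}{marker}")

model = fit_lda(corpus, LDAConfig(n_topics=curve.best_T, alpha=0.1, beta=0.05, seed=0))
for t in range(model.n_topics):
    words = ", ".join(f"{w} ({p:.3f})" for w, p in top_words(model, t, 5))
    print(f"topic {t}: {words}")
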
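# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## Categorical recurrence quantification

A coded session is a categorical time series `x_1..x_N` over the alphabet
of dyad symbols (`a-b` for the unordered member pair, `a-T` for a
member-to-team address; a group of *m* members has C(m,2) + m symbols).
Recurrence for categorical data is exact symbol equality — the categorical
limit of the usual closeness threshold used for continuous signals — so
the recurrence plot is `R[i,j] = [x_i = x_j]`, symmetric with an all-ones
main diagonal (line of identity, LOI).

Quantification excludes the LOI with a Theiler window of 1 (only the main
diagonal); this is what makes the 0–100 range of the recurrence rate
attainable, since the LOI is recurrent by construction.  The rate uses the
full off-LOI matrix (both triangles) in numerator and denominator:
`RR = 100 · #{(i,j): i≠j, x_i=x_j} / (N²−N)`.

Diagonal lines are *maximal* runs of consecutive recurrent cells along
upper-triangle diagonals; a run of length *l* contributes one histogram
count at *l* (no nested sub-runs).  By symmetry the lower triangle
duplicates every line, so counting one triangle cannot change determinism
or entropy; the brute-force test oracle enumerates the same triangle so
agreement is exact.  Determinism uses the minimum line length `l_min = 2`:
numerator sums `l·H(l)` over `l ≥ l_min`, denominator over `l ≥ 1`
(all off-LOI recurrent points).  Entropy is Shannon entropy in bits
(base configurable) of the normalised line-length distribution restricted
to `l ≥ l_min`.

Degenerate inputs are explicit error states, not NaNs: determinism is
undefined without any off-LOI recurrent point, entropy without any line
reaching `l_min`.  The batch API (`rqa_measures`) maps these to `None` so
a study run degrades gracefully for a pathological group.

## Sequence encoding and reliability

Dyads are unordered by default — an event from member 1 to member 2 and
its reverse are the same interaction state; a directed mode exists but is
off by default.  Events with equal timestamps keep file order.  IPA
categories (1–12) are ingested and exported as frequencies but do not
enter the recurrence alphabet: the recurrence analysis is over
who-with-whom states.

Coder agreement is ICC(2,1) — two-way random effects, single measures,
absolute agreement — computed from the two-way ANOVA decomposition:
`(BMS − EMS) / (BMS + (k−1)EMS + k(JMS − EMS)/n)`.  Single-measures is the
conservative choice when the reliability model family is otherwise
unspecified.  A constant ratings matrix raises an error rather than
returning 0/0.  The implementation is checked in the tests against both a
hand-computed ANOVA table and pingouin's `ICC(A,1)`.

## Questionnaire scales and marginal models

Participant scores are unweighted item means of each 7-point subscale;
group scores are means of participant scores.  Cronbach's alpha uses the
variance form `k/(k−1)·(1 − Σ s²_item / s²_sum)` with n−1 denominators.

The association models are GEEs with Gaussian family, identity link and an
exchangeable working correlation: group members are interchangeable, share
their group's predictors (RR, DET, ENT are cluster-level) and unmeasured
group context, so an exchangeable within-cluster correlation is the
natural structure; independence is available as an option.  Outcomes are
individual-level subscale scores with the group as cluster — the design
that makes GEE necessary in the first place.  Estimation and Pan's QIC are
delegated to statsmodels' GEE (robust sandwich covariance throughout); the
module adds per-term Wald statistics `(B/SE)²` against chi-square(1) and
95% intervals `B ± 1.96·SE` (normal quantile, matching symmetric-interval
reporting conventions).  SPSS's QIC variant differs slightly from Pan's;
this is documented, not chased.  A constant outcome short-circuits to the
exact flat fit (intercept = constant, zero slopes) since the sandwich has
no variability to estimate.  The estimated exchangeable correlation is
validity-checked against `(−1/(max cluster size − 1), 1)` and clamped with
a warning outside it.  Variance inflation factors are reported per
predictor and flagged above 10.

With one participant per cluster, exchangeable GEE degenerates to OLS with
sandwich errors; with the correlation fixed at zero it equals pooled OLS —
both are tested against a closed-form least-squares oracle at 1e-8.

## Transcript preprocessing and topic model

Preprocessing order: lowercase → strip non-alphabetic characters (digits
discarded) → whitespace tokenise → drop stopwords → drop tokens shorter
than 3 or longer than 14 characters → Porter stem.  The stopword list is
the classic 127-word English list, shipped verbatim and overridable by
file, because reproducibility requires pinning the exact list.  The
stemmer implements the original Porter algorithm (steps 1a–5b, longest
matching suffix per step, measure condition tested once); words of length
≤ 2 pass through.  Note the filter chain is idempotent but stemming is
not (`nurs → nur`), so repeated preprocessing of already-stemmed text is
not a supported operation.

LDA is fitted by collapsed Gibbs sampling with conditional
`p(z=t) ∝ (n_wt + β)/(n_t + Vβ)·(n_dt + α)`; the inner loop is
numba-compiled and uses the legacy numpy global generator seeded on entry,
so a seed fully determines the trajectory.  Φ and Θ are estimated from the
final count tables with the same smoothing.  Defaults follow widely used
toolbox conventions: α = 50/T, β = 0.01, 1000 sweeps with 500 burn-in,
single chain.  Convergence is not detected automatically; the recovery
tests showed that short chains (a few hundred sweeps) can linger in modes
where two similar topics merge, which the default schedule escapes.

Held-out perplexity is `exp(−Σ log p(w|d) / n_tokens)` with
`p(w|d) = Σ_t θ̂_dt φ_tw`; θ̂ for held-out documents comes from 50 fold-in
Gibbs sweeps with Φ frozen.  Because fold-in is stochastic, per-token
perplexity is reproducible under a fixed seed and approximately invariant
(not bit-identical) under document duplication.  Out-of-vocabulary
held-out tokens are dropped and counted.  Topic-number selection uses one
seeded document-level split (default 10% held out), fits every candidate T
on the remainder, and takes the argmin; ties and flat stretches resolve to
the smallest T.  On LDA-generated corpora the curve falls steeply up to
the true T and flattens beyond it, so the argmin lands on the truth or an
adjacent candidate.

## Synthetic-data generator

The generator defines the study conditions for every simulation:

- **Interactions**: first-order Markov mixture — repeat the previous
  symbol with probability `stability`, follow a fixed cyclic successor map
  (next symbol in sorted alphabet order) with probability
  `determinism_strength`, otherwise draw uniformly.  The two weights map
  directly onto the RR and DET constructs, which keeps recovery tests
  interpretable.  Defaults: 28 groups of 3–5 members, lengths
  Normal(157, 67) floored at 10 (keeping recurrence quantities defined),
  per-group stability ~ U(0.05, 0.25) and determinism ~ U(0.15, 0.45).
  Under these defaults group-level RR averages ≈ 11.4 (sd ≈ 4.3) and DET
  ≈ 36 (sd ≈ 11) — the regime of sparse, moderately predictable sessions
  the package targets; much of the RR spread comes from alphabet-size
  variation across 3/4/5-member groups.
- **Questionnaires**: latent group mean = intercept + slopes·(RR, DET) +
  group noise; participant and item Gaussian noise are added before
  rounding and clamping to 1..7.  Rounding+clamping was chosen over a
  cut-point threshold model as the simplest mechanism producing bounded
  ordinal data; it attenuates slopes only negligibly at these noise
  levels.  Defaults put the participation mean near 5.68 (zero slopes) and
  the support mean near 4.78 with slopes 0.022 on RR and −0.008 on DET;
  noise sds 0.30/0.45/0.60 (group/participant/item) give alphas near 0.8
  for 5-item scales.  True latent group means are stored in the ground
  truth so recovery is testable per group.
- **Corpus**: the standard LDA generative process (Φ rows ~ Dir(β),
  θ rows ~ Dir(α), Poisson lengths, topic-then-word sampling).  Defaults
  emulate a 28-transcript corpus of ≈ 53k tokens with 15 topics; recovery
  experiments use a denser 5-topic, 200-document configuration where the
  posterior is well identified.  Synthetic "words" are vowel-free letter
  strings so they pass the real preprocessing unchanged, letting pipeline
  runs exercise the true transcript I/O path.

What the generator does **not** emulate: IPA category semantics, real
dialogue content (tokens are abstract), turn-taking burstiness, coder
disagreement, or item-specific difficulty.  Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions — not that real team data satisfy those
assumptions.

## Simulation sizes and numerical tolerances

Recovery experiments are sized to be decisive yet quick: RQA oracle
equivalence uses 200 random sequences (alphabet 2–8, length ≤ 60; exact
agreement required for rates and histograms, 1e-12 for entropy); GEE
recovery uses 50 replicates of 100 groups (mean slope within ±25%,
coverage within [0.90, 0.99]); topic recovery uses three seeded fits at
T=5, V=200, D=200 (greedy-matched mean total-variation distance < 0.25)
and selection five seeds over candidates {2, 5, 10, 20}.  Probability
rows are validated to 1e-9; equality oracles to 1e-8 or exact.

## Pipeline reproducibility

One global seed fans out to per-stage seeds via a stage-name CRC hash, so
stages can be rerun in isolation.  All JSON artifacts are written with
sorted keys and no timestamps; the manifest records the config SHA-256 and
per-artifact digests, and an identical config + seed reproduces every
artifact byte for byte (asserted in the tests).

## Known limitations

- No continuous-signal RQA (embedding, delay, radius), cross-RQA, or
  laminarity measures; categorical self-recurrence only.
- The Gibbs sampler reports a single chain's endpoint; no R-hat style
  diagnostics, no assignment averaging across samples.
- Sandwich standard errors are used as-is; no small-sample corrections,
  so p-values with few clusters (< ~30) are mildly anti-conservative.
- Ordinal outcomes are modelled as Gaussian means of item scores, not via
  ordinal-link GEE.
- Transcript documents are one-per-group; per-speaker document splits are
  not implemented.
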
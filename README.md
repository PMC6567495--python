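# teamdyn

Quantitative and qualitative analysis of small-group interaction dynamics,
aimed at researchers studying healthcare teams (and small face-to-face
groups generally) who record meetings, code who-interacts-with-whom
behaviour, and collect post-session questionnaires.

The package implements a two-track pipeline:

**Quantitative track.** A coded session is an ordered categorical sequence
of interaction states: each event is an unordered member dyad (`1-2`,
`2-3`, ...) or a member-to-team address (`1-T`), optionally classified into
Bales' twelve Interaction Process Analysis categories.  The sequence's
*recurrence plot* is the binary matrix `R[i,j] = 1` iff the state at time
*i* equals the state at time *j*.  Excluding the line of identity, three
measures summarise it:

- **recurrence rate** `RR = 100 · Σ_{i≠j} R[i,j] / (N² − N)` — stability of
  the interaction pattern (0 = never revisits a state, 100 = one constant
  state);
- **determinism** `DET = 100 · Σ_{l ≥ l_min} l·H(l) / Σ_{l ≥ 1} l·H(l)` —
  the share of recurrent points on diagonal lines of length at least
  `l_min = 2`, where `H` is the histogram of maximal diagonal line lengths:
  predictability of the sequence;
- **entropy** `ENT = −Σ_{l ≥ l_min} p(l) log₂ p(l)` — complexity of the
  recurrence structure.

Group-level RR/DET/ENT are then related to two individual-level 7-point
Likert subscales (quality of participation, social support; internal
consistency by Cronbach's alpha, coder agreement by ICC(2,1)) with
generalized estimating equations — Gaussian family, identity link,
exchangeable working correlation, robust sandwich standard errors, Pan's
QIC — because members of one group share context and cannot be treated as
independent.

**Qualitative track.** Meeting transcripts are preprocessed (lowercasing,
punctuation stripping, stopword removal, 3–14 character length filter,
Porter stemming) and modelled with latent Dirichlet allocation fitted by
collapsed Gibbs sampling; the number of topics is chosen by held-out
perplexity on a seeded 10% document split.

Because the kind of study data this mirrors is typically not shareable, a
first-class synthetic generator produces interaction sequences (a Markov
mixture whose weights map onto RR and DET), Likert responses with known
regression structure, and LDA-generated corpora — so every stage is
verified by parameter recovery on data with known ground truth.

## Worked example

```bash
python examples/03_synthetic_study.py
```

prints (abridged):

```
groups: 28
RR mean 11.39 (sd 3.98); DET mean 37.25 (sd 9.72); ENT mean 0.86

findings table (B = coefficient, robust SE, 95% CI, Wald chi-square):
                 Outcome     QIC   Parameter       B     SE  ci_low  ci_high     Wald      p
quality of participation 113.824 (Intercept)  5.4767 0.2482  4.9903   5.9632 486.8999 0.0000
quality of participation 113.824   Stability  0.0375 0.0191  0.0000   0.0749   3.8513 0.0497
...
          social support 117.221   Stability  0.0152 0.0286 -0.0408   0.0712   0.2821 0.5953

Cronbach's alpha: {'quality of participation': 0.755, 'social support': 0.803}
variance inflation: {'rr': 1.98, 'det': 3.43, 'ent': 3.04}
```

Here 28 simulated groups average a recurrence rate of 11.4% (groups rarely
revisit the same dyadic state) with determinism around 37% (about a third
of recurrences form repeated sub-sequences).  Each `B` is the change in a
1–7 subscale score per unit of the group-level measure; the Stability rows
estimate the generating slope structure, with robust intervals reflecting
the 28-cluster design.  The other scripts in `examples/` walk through
single-sequence RQA, reliability coefficients, topic modelling with
perplexity selection, and the orchestrated end-to-end run.

A thin CLI wraps the same functions:

```bash
teamdyn simulate --out sim --seed 4
teamdyn rqa --sequences sim/sequences --lmin 2 --out measures.json
teamdyn associate --measures measures.json --questionnaire sim/questionnaire.csv --out table1.csv
teamdyn topics --transcripts sim/transcripts --candidates 5,10,15 --seed 4 --out topics.json
teamdyn run --config run.yaml --out out/   # everything, from one YAML
```

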
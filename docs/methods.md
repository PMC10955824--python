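# Methods

This note documents the models and procedures implemented in `chatthemes`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not establish.

## Data model and inclusion rule

The analysis unit is a conversation: an ordered sequence of speaker-tagged
messages with a calendar month. Labels are binary indicators in three
groups — six themes, seven volunteer strategies, three mental-health
issues — and each flag is 0, 1 or *unknown*. Unknown is a first-class
state: it is never coerced to 0, and every analysis stage that needs a
flag drops unknown rows with a logged count (the models are meant to run
on the expert-tagged subset, not to impute).

Conversations with fewer than 10 messages are excluded before any
analysis; a 10-message conversation is retained. Very short exchanges are
typically aborted contacts rather than support conversations. The
descriptive word count (≈742 words per included conversation in the
service this workflow targets) is computed on raw whitespace tokens,
before preprocessing, because it describes the data rather than the model
input.

## Preprocessing and features

Fixed pipeline order: select turns → concatenate → split on non-letter
boundaries → lowercase → POS-filter → lemmatize → remove stopwords.
Informal chat text argues for aggressive normalization: digits and
punctuation never survive tokenization. The POS filter and lemmatizer are
pluggable hooks that default to identity, keeping the core deterministic
and dependency-light; language-specific hooks (e.g. a Spanish lemmatizer)
can be injected without touching the pipeline.

By default only **user turns** are analyzed: the themes of interest are
stressors expressed by help-seekers, and volunteer turns would let the
dictionary fire on the volunteer's own vocabulary (e.g. a volunteer asking
"did they abuse you?"). This is a configuration choice (`turns`), not a
hard-coded rule.

Features are unigrams plus adjacent-pair bigrams joined with `_`. The
TF-IDF variant is pinned to the dominant convention of the Python
ecosystem — tf × (ln((1+N)/(1+df)) + 1), rows L2-normalized — so weights
are comparable across implementations. `min_df` defaults to 1; lexicon
quality is governed by top-k selection and refinement, not by frequency
pruning.

## Lexicon induction and refinement

Per family, a 500-tree random forest is trained on the TF-IDF rows of the
tagged conversations and features are ranked by mean impurity decrease
(permutation importance is available as an alternative backend). Ties are
broken lexicographically, making induction fully deterministic for a fixed
seed. The top 40 features seed the family's term list.

Raw top-40 lists need refinement: classifier importance measures
*association in the training sample*, and the ranking step itself selects
for it, so the tail of the list mixes genuinely thematic terms with
broadly common ones whose association is weak or overfit. Under the
any-word labeling rule a single common term floods a family with false
positives. The automated refinement pass therefore uses the criterion the
dictionary is ultimately judged by: terms are considered in importance
order and kept only if adding them strictly increases the family's
classification accuracy against the gold tags. (A per-term significance
filter was considered and rejected: terms pre-selected by the classifier
pass in-sample significance tests almost by construction.) Expert edits
remain available through `refine_lexicon`; expert-added terms are never
auto-pruned, and every addition/removal is logged with provenance.

Because refinement optimizes in-sample agreement greedily, it can keep
rare overfit bigrams (harmless: they fire on almost nothing) and can stop
adding signal terms once in-sample recall saturates. Held-out evaluation
of a refined dictionary is the user's responsibility where it matters.

## Dictionary classification

A conversation gets a family's label iff any lexicon unigram equals any of
its tokens or any lexicon bigram equals any of its adjacent-token bigrams.
Matching is exact on normalized forms — "eat" never fires inside
"heating"; surface variants are the lemmatizer's concern. There is no
match-count threshold, no negation handling and no weighting; the rule is
deliberately the simple, auditable word-count convention, and the matched
terms are retained as per-conversation evidence.

## Trend analysis

Monthly prevalence is the fraction of that month's conversations carrying
the family label (families counted independently; multi-label). The
pre/post comparison is an interrupted time series:

    y_t = α + ρ·y_{t−1} + β·D_t + ε_t,    D_t = 1{month_t ≥ break}

estimated by conditional least squares (OLS on the lagged regression over
t = 2..T). This is the simplest estimator consistent with an AR(1)-plus-
step specification, and its dummy t-test (df = n_used − 3) is standard
regression output, making alternatives easy to swap in. The break defaults
to March 2020 and March counts as pandemic regardless of day. Months with
zero conversations break the lag chain; only consecutive observed pairs
enter the regression, and fits require ≥ 8 usable pairs with both dummy
levels present. Residual whiteness is checked with the Ljung–Box Q at
min(10, ⌊n/5⌋) lags by default. No seasonal adjustment is attempted: with
three years of monthly data, seasonal terms are not identifiable
separately from the step.

## Association analysis

Per issue, a logistic regression on intercept + 6 theme + 7 strategy
indicators (optionally + a pandemic-period dummy), fitted by Newton
maximum likelihood. Wald statistics are reported as t values against the
normal reference; at tagged-sample sizes (~1000) the df convention changes
nothing visible. Stars follow the conventional thresholds (* p<0.1,
** p<0.05, *** p<0.01) with no multiple-testing correction, matching the
reporting style of the field. Pseudo-R² is McFadden's 1 − ℓ/ℓ₀. Complete
or quasi-complete separation is detected (diverging estimates or infinite
SEs) and flagged on the result rather than silently reported or silently
penalized, keeping estimates comparable to plain ML fits.

Pairwise association of two binary variables: φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)),
tested with χ² = N·φ² on 1 df; undefined (and raised) for constant inputs.

## Synthetic corpus generator

The generator emulates exactly the features downstream stages consume:

* months uniform over 2018-01..2020-12; theme flags Bernoulli with
  per-family base prevalence plus an additive step from the break month;
* bag-of-words text: ~20 messages per kept conversation (uniform 10–30,
  with a 0.2-probability short regime of 3–9 messages for the inclusion
  filter to remove), Poisson(37.1) words per message, targeting ≈742 raw
  words per kept conversation; in theme-positive conversations each user-
  turn token is a signal term of an active theme with probability 0.05
  (split evenly among active themes), else a background filler term;
* speakers alternate user/volunteer; signal terms appear only in user
  turns by default, exercising the turn-selection option;
* strategies are Bernoulli draws from logistic models on the theme
  indicators; issues are Bernoulli draws from a known logistic model on
  all 13 indicators, with default coefficients at magnitudes realistic for
  expert-tagged helpline conversations (issue base rates ≈ 0.1–0.35).

Default vocabulary sizes are 6×15 signal terms and 500 background terms —
large enough that induction must beat TF-IDF noise, small enough that it
succeeds at ~1000 tagged conversations. All vocabulary is letter-only by
construction, since tokenization drops digits. Base prevalences
(0.08–0.30 across families) are order-of-magnitude choices for a youth
helpline and are configuration, not claims about any real service.

What the generator does **not** emulate: word order and syntax (tokens are
i.i.d. within a conversation — downstream features are bag-of-words, so
sequence realism adds nothing testable), misspellings, negation ("not
ugly"), vocabulary drift over time, tagger disagreement, and any
correlation between text length and themes. Passing tests therefore
establish the *mechanics* of the pipeline — recovery, calibration,
determinism — not the semantic validity of any particular dictionary on
real text.

## Validation experiments and problem sizes

The standing experiments (in `chatthemes.experiments`, re-run by
`scripts/acceptance.py` and the acceptance tests) use the package's
standard study conditions: induction on ~1000-conversation tagged sets;
full-corpus runs of 5000 conversations; 36-month series; 500 Monte-Carlo
replicates for AR size/power, 1000 for Ljung–Box, 200 for logistic
coverage.

* **Planted recovery:** induction must place ≥ 12 of each family's 15
  planted terms in its top 40 (observed: 15/15).
* **Metric oracle:** dictionary evaluation must agree exactly with
  brute-force set-intersection counting on 50 randomized corpora.
* **AR(1)+dummy:** null rejection at α=0.01 inside the exact binomial 99%
  band; power ≥ 0.8 at β = 3× innovation SD; noise-free recursions
  recovered to machine precision.
* **Ljung–Box:** white-noise rejection at α=0.05 within [0.03, 0.07].
* **Logistic:** 2×2 closed-form log-odds and SE to 1e-6; per-coefficient
  3-SE coverage ≥ 95% over 200 replicates at n=5000.
* **End-to-end:** with planted mixed-sign deltas (+0.12, +0.12, −0.08,
  +0.12, 0, 0), the pipeline must flag all shifted families with correct
  signs *and* reproduce the flag set that the same trend test yields on
  the ground-truth prevalence series of the same conversations. The second
  clause is the fair reference: a finite draw occasionally puts a real
  step into a zero-delta family's true series, and the dictionary stage
  should match what perfect labels would decide, not outperform them.
* **Determinism:** identically-seeded runs produce byte-identical CSVs.

A single global seed is fanned out to the generator and classifier
training via `numpy.random.SeedSequence`, so every experiment is
reproducible from one integer.

## Known limitations

* The any-word rule has no notion of negation, sarcasm or context; its
  precision on real text is bounded by term polysemy, which the synthetic
  generator (disjoint vocabularies) cannot probe.
* Conditional least squares on 36 monthly points has limited power for
  small steps and cannot separate a step from a steep ramp at the break.
* Prevalence series are treated as continuous responses; the binomial
  month-to-month variance (larger in low-volume months) is not modeled.
* Logistic associations on the tagged subset are descriptive, not causal,
  and carry the tagging protocol's biases.
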
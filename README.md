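# chatthemes

Dictionary-based thematic analysis of mental-health helpline chat corpora.

Crisis and mental-health helplines produce large volumes of dialogical chat
data: sequences of user and volunteer messages, a small expert-tagged
subset, and — for research questions about population mental health — a
need to label the *entire* corpus by theme. `chatthemes` implements a
complete, tested version of the standard workflow for this setting:

1. **Lexicon induction.** On the expert-tagged conversations, a TF-IDF
   matrix of unigrams and bigrams feeds a random-forest classifier per
   thematic family; the top-40 most predictive features seed each family's
   term list, which is then refined (automatically or by experts) against
   the gold tags.
2. **Dictionary classification.** A conversation is labeled with every
   family whose term list intersects its normalized token/bigram stream
   (the any-word rule, as in LIWC-style word-count methods).
3. **Interrupted time series.** Each family's monthly prevalence
   y_t = labeled/total is tested for a level change at a known break month
   (pandemic onset, March 2020) with

   &nbsp;&nbsp;&nbsp;&nbsp;y_t = α + ρ·y_{t−1} + β·D_t + ε_t,&nbsp;&nbsp;D_t = 1{t ≥ break}

   fitted by conditional least squares; the t-test on β is the change
   test, and residual whiteness is checked with a Ljung–Box test.
4. **Issue associations.** Logistic regressions relate three mental-health
   issues (suicidal behavior, depressive and anxious symptomatology) to the
   13 binary theme/strategy indicators, reported with Wald t statistics,
   significance stars and McFadden pseudo-R²; pairwise binary associations
   use the phi coefficient with χ² = N·φ².

Because real helpline data are restricted, the package ships a
**synthetic-corpus generator** with known ground truth (planted theme
vocabularies, a step change in theme prevalence, strategies correlated with
themes, and issues drawn from a known logistic model), so every stage is
verifiable by parameter recovery. It also bundles the published six-family
term lists (`chatthemes.published_lexicon`) for users who want to classify
a corpus without inducing their own dictionary.

## Worked example

Run the full pipeline on a generated corpus of 5000 conversations with
planted prevalence shifts from March 2020 (+0.12 self-image, +0.12
relational, +0.12 emotional crisis, −0.08 performance, 0 elsewhere):

```python
from chatthemes import PipelineConfig, GeneratorConfig, run_pipeline

deltas = {"self_image": 0.12, "relational": 0.12, "performance": -0.08,
          "emotional_crisis": 0.12, "violence": 0.0, "sexual_diversity": 0.0}
config = PipelineConfig(
    generator=GeneratorConfig(n_conversations=5000, theme_break_delta=deltas),
    out_dir="run", seed=1,
)
run_pipeline(config)
```

`run/trend_report.csv` then contains (seed 1):

```
          family  dummy_coef       t      p  significant  ljung_box_p
      self_image      0.1423  6.4672 0.0000         True       0.8390
        violence      0.0085  0.9637 0.3424        False       0.7347
sexual_diversity      0.0001  0.0101 0.9920        False       0.5278
      relational      0.0947  4.3780 0.0001         True       0.0976
emotional_crisis      0.1410  5.8171 0.0000         True       0.5043
     performance     -0.1113 -5.8543 0.0000         True       0.5485
```

Exactly the four shifted families are flagged at the 0.01 level, each with
the planted direction (positive t = prevalence increase during the
pandemic months), and no residual autocorrelation is detected. The induced
dictionary itself scores accuracy ≥ 0.997 per family against the gold tags
of the 1000-conversation training subset (`run/lexicon_eval.csv`), and
`run/logit_table.txt` holds the three issue regressions, e.g. an
emotional-crisis coefficient of 0.595 (SE 0.081) for suicidal behavior —
close to the generating value of 0.599.

The same pipeline is scriptable from the shell:

```bash
chatthemes generate --n 5000 --seed 1 --out data/
chatthemes run --config pipeline.yaml --seed 1 --out run/
chatthemes classify --corpus data/corpus.jsonl --lexicon lex.json --out assignments.csv
```

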
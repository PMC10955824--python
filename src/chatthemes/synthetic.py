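"""Synthetic helpline-corpus generator with known ground truth.

The real helpline data are restricted, so every pipeline stage is validated
against corpora generated here, where the truth is known by construction:

* each conversation gets independent Bernoulli theme flags whose
  probabilities step up or down from a configurable break month (the
  pandemic onset, March 2020 by default);
* conversation text is a bag-of-words mixture: in a theme-positive
  conversation, each token of a user turn is a term from an active theme's
  signal vocabulary with probability ``signal_rate``, otherwise a background
  filler term;
* volunteer strategies are Bernoulli draws from logistic models on the theme
  indicators, and the three mental-health issues are Bernoulli draws from a
  known logistic model on all 13 theme/strategy indicators — so association
  models downstream can be checked by parameter recovery.

Token draws are i.i.d. within a conversation: downstream features are
unigram/bigram counts, so sequence realism would add nothing testable.
Messages alternate user/volunteer speakers starting with the user; signal
terms are emitted only in user turns by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .corpus import (
    ISSUES,
    STRATEGIES,
    THEMES,
    Conversation,
    Corpus,
    LabelSet,
    Message,
    month_index,
    month_range,
)
from .trends import MonthlyPrevalenceSeries


def _letters(i: int, width: int = 3) -> str:
    """Base-26 letter code, e.g. 0 -> 'aaa'; keeps terms free of digits."""
    chars = []
    for _ in range(width):
        chars.append(chr(ord("a") + i % 26))
        i //= 26
    return "".join(reversed(chars))


_THEME_PREFIX = {
    "self_image": "sim",
    "violence": "vio",
    "sexual_diversity": "sdv",
    "relational": "rel",
    "emotional_crisis": "emo",
    "performance": "per",
}


def default_signal_vocab(n_terms: int = 15) -> dict:
    """Pairwise-disjoint per-theme signal vocabularies (letter-only terms)."""
    return {
        theme: [f"{_THEME_PREFIX[theme]}{_letters(i, 2)}" for i in range(n_terms)]
        for theme in THEMES
    }


def default_background_vocab(n_terms: int = 500) -> list:
    return [f"bg{_letters(i)}" for i in range(n_terms)]


# Default prevalences are order-of-magnitude choices for a youth helpline
# (relational and emotional-crisis themes common, sexual diversity rarer);
# they are configuration, not assertions about the real service.
_DEFAULT_BASE_PREV = {
    "self_image": 0.20,
    "violence": 0.10,
    "sexual_diversity": 0.08,
    "relational": 0.30,
    "emotional_crisis": 0.25,
    "performance": 0.15,
}

# Strategy models: intercept + coefficients on theme indicators.  Chosen so
# strategies are correlated with themes (containment with emotional crisis,
# derivation with violence, ...) at plausible base rates.
_DEFAULT_STRATEGY_MODEL = {
    "exploration": (0.8, {}),
    "containment": (-1.0, {"emotional_crisis": 1.2, "self_image": 0.4}),
    "resources": (-0.8, {"performance": 0.8, "relational": 0.4}),
    "reflection": (-0.5, {"self_image": 0.6, "relational": 0.5}),
    "validation": (-0.4, {"emotional_crisis": 0.7, "sexual_diversity": 0.8}),
    "psychoeducation": (-1.2, {"emotional_crisis": 0.9, "violence": 0.5}),
    "derivation": (-1.6, {"violence": 1.3, "emotional_crisis": 0.6}),
}

# Issue models: intercept + coefficients over the 6 themes then 7 strategies,
# at magnitudes realistic for expert-tagged helpline conversations.
_DEFAULT_ISSUE_COEFS = {
    "suicidal": {
        "intercept": -0.693,
        "self_image": 0.405, "performance": -0.259, "sexual_diversity": -0.554,
        "emotional_crisis": 0.599, "relational": -0.350, "violence": 0.335,
        "containment": 0.529, "derivation": 0.290, "psychoeducation": 0.231,
        "exploration": -0.908, "resources": 0.503, "reflection": 0.050,
        "validation": 0.100,
    },
    "depressive": {
        "intercept": -1.354,
        "self_image": 0.481, "performance": 0.504, "sexual_diversity": -0.492,
        "emotional_crisis": 0.802, "relational": 0.140, "violence": 0.422,
        "containment": 0.233, "derivation": 0.247, "psychoeducation": -0.113,
        "exploration": -0.598, "resources": 0.849, "reflection": -0.111,
        "validation": 0.581,
    },
    "anxious": {
        "intercept": -2.269,
        "self_image": -0.186, "performance": 0.060, "sexual_diversity": -0.012,
        "emotional_crisis": 1.076, "relational": -0.190, "violence": -0.170,
        "containment": -0.125, "derivation": -0.130, "psychoeducation": 0.330,
        "exploration": 0.253, "resources": 0.336, "reflection": 0.256,
        "validation": 0.730,
    },
}

PREDICTORS = tuple(THEMES) + tuple(STRATEGIES)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration (probabilities out of range, ...)."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic corpus; defaults define the study conditions.

    Word/message counts target the real corpus descriptives: conversations
    kept by the >=10-message filter average ~20 messages of ~37 words, i.e.
    ~742 raw words per conversation.  ``short_prob`` puts mass on <10-message
    conversations so the inclusion filter has work to do.
    """

    n_conversations: int = 1000
    start: tuple = (2018, 1)
    end: tuple = (2020, 12)
    break_month: tuple = (2020, 3)
    theme_base_prev: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_PREV))
    theme_break_delta: dict = field(default_factory=lambda: {t: 0.0 for t in THEMES})
    signal_vocab: dict = field(default_factory=default_signal_vocab)
    background_vocab: list = field(default_factory=default_background_vocab)
    signal_rate: float = 0.05
    words_per_message: float = 37.1  # Poisson mean per message (min 1)
    messages_long: tuple = (10, 30)  # inclusive uniform range, kept by filter
    messages_short: tuple = (3, 9)  # inclusive uniform range, filtered out
    short_prob: float = 0.2
    signal_in_user_only: bool = True
    require_disjoint_signal: bool = True
    strategy_given_theme: dict = field(
        default_factory=lambda: {k: (v[0], dict(v[1])) for k, v in _DEFAULT_STRATEGY_MODEL.items()}
    )
    issue_coefs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_ISSUE_COEFS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        for t in THEMES:
            p = self.theme_base_prev[t]
            d = self.theme_break_delta.get(t, 0.0)
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(f"theme_base_prev[{t!r}]={p} outside [0,1]")
            if not 0.0 <= p + d <= 1.0:
                raise GeneratorConfigError(
                    f"theme_base_prev + theme_break_delta for {t!r} is {p + d}, outside [0,1]"
                )
        if not 0.0 <= self.signal_rate <= 1.0:
            raise GeneratorConfigError("signal_rate outside [0,1]")
        if not 0.0 <= self.short_prob <= 1.0:
            raise GeneratorConfigError("short_prob outside [0,1]")
        if self.n_conversations <= 0:
            raise GeneratorConfigError("n_conversations must be positive")
        if self.require_disjoint_signal:
            seen: dict = {}
            for theme, terms in self.signal_vocab.items():
                for term in terms:
                    if term in seen:
                        raise GeneratorConfigError(
                            f"signal term {term!r} appears in both {seen[term]!r} and {theme!r}"
                        )
                    seen[term] = theme
            overlap = set(seen) & set(self.background_vocab)
            if overlap:
                raise GeneratorConfigError(
                    f"signal terms also in background vocab: {sorted(overlap)[:5]}"
                )


@dataclass
class GroundTruth:
    """True per-conversation flags and the generative parameters used."""

    ids: list
    months: list  # (year, month) per conversation
    themes: dict  # theme -> np.ndarray of 0/1
    strategies: dict
    issues: dict
    issue_coefs: dict
    theme_prev_pre: dict
    theme_prev_post: dict
    break_month: tuple
    month_span: tuple  # (start, end)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_labels(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Draw months and theme/strategy/issue flags only (no text).

    This is the first stage of :func:`generate_corpus`; parameter-recovery
    experiments that do not touch text can use it directly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_conversations
    months_all = month_range(config.start, config.end)
    months = [months_all[k] for k in rng.integers(0, len(months_all), size=n)]
    post = np.array(
        [month_index(y, m) >= month_index(*config.break_month) for (y, m) in months]
    )

    themes = {}
    for t in THEMES:
        p = config.theme_base_prev[t] + config.theme_break_delta.get(t, 0.0) * post
        themes[t] = (rng.random(n) < p).astype(np.int8)

    strategies = {}
    for s in STRATEGIES:
        intercept, coefs = config.strategy_given_theme[s]
        z = np.full(n, float(intercept))
        for t, c in coefs.items():
            z += c * themes[t]
        strategies[s] = (rng.random(n) < _sigmoid(z)).astype(np.int8)

    issues = {}
    for iss in ISSUES:
        coefs = config.issue_coefs[iss]
        z = np.full(n, float(coefs.get("intercept", 0.0)))
        for name in PREDICTORS:
            c = coefs.get(name, 0.0)
            if c:
                src = themes[name] if name in themes else strategies[name]
                z += c * src
        issues[iss] = (rng.random(n) < _sigmoid(z)).astype(np.int8)

    ids = [f"conv{k:06d}" for k in range(n)]
    return GroundTruth(
        ids=ids,
        months=months,
        themes=themes,
        strategies=strategies,
        issues=issues,
        issue_coefs={k: dict(v) for k, v in config.issue_coefs.items()},
        theme_prev_pre={t: config.theme_base_prev[t] for t in THEMES},
        theme_prev_post={
            t: config.theme_base_prev[t] + config.theme_break_delta.get(t, 0.0) for t in THEMES
        },
        break_month=config.break_month,
        month_span=(config.start, config.end),
    )


def generate_corpus(config: GeneratorConfig) -> tuple:
    """Generate a fully labeled corpus and its ground truth.

    Returns ``(corpus, truth)``.  Identical config (including seed) yields a
    byte-identical corpus on disk.
    """
    rng = np.random.default_rng(config.seed)
    truth = generate_labels(config, rng)
    n = config.n_conversations

    bg = np.asarray(config.background_vocab, dtype=object)
    sig = {t: np.asarray(v, dtype=object) for t, v in config.signal_vocab.items()}
    theme_mat = np.stack([truth.themes[t] for t in THEMES], axis=1)

    conversations = []
    labels = {}
    for k in range(n):
        if rng.random() < config.short_prob:
            lo, hi = config.messages_short
        else:
            lo, hi = config.messages_long
        n_msgs = int(rng.integers(lo, hi + 1))
        words_per_msg = np.maximum(1, rng.poisson(config.words_per_message, size=n_msgs))

        active = [THEMES[j] for j in np.flatnonzero(theme_mat[k])]
        msgs = []
        for i in range(n_msgs):
            speaker = "user" if i % 2 == 0 else "volunteer"
            n_tok = int(words_per_msg[i])
            tokens = bg[rng.integers(0, len(bg), size=n_tok)]
            allow_signal = active and (speaker == "user" or not config.signal_in_user_only)
            if allow_signal and config.signal_rate > 0:
                is_sig = rng.random(n_tok) < config.signal_rate
                n_sig = int(is_sig.sum())
                if n_sig:
                    # split evenly among active themes: theme uniform, then term
                    which = rng.integers(0, len(active), size=n_sig)
                    repl = np.empty(n_sig, dtype=object)
                    for j, theme in enumerate(active):
                        mask = which == j
                        if mask.any():
                            v = sig[theme]
                            repl[mask] = v[rng.integers(0, len(v), size=int(mask.sum()))]
                    tokens = tokens.copy()
                    tokens[is_sig] = repl
            msgs.append(Message(speaker=speaker, text=" ".join(tokens), index=i))

        year, month = truth.months[k]
        cid = truth.ids[k]
        conversations.append(
            Conversation(id=cid, year=year, month=month, messages=tuple(msgs))
        )
        labels[cid] = LabelSet(
            themes={t: int(truth.themes[t][k]) for t in THEMES},
            strategies={s: int(truth.strategies[s][k]) for s in STRATEGIES},
            issues={i: int(truth.issues[i][k]) for i in ISSUES},
        )
    return Corpus(conversations=conversations, labels=labels), truth


def true_prevalence_series(truth: GroundTruth) -> MonthlyPrevalenceSeries:
    """Monthly fraction of conversations with true theme flag 1.

    Normalized by the monthly conversation total; months with zero
    conversations are flagged absent (NaN prevalence).
    """
    months = month_range(*truth.month_span)
    idx = {ym: i for i, ym in enumerate(months)}
    totals = np.zeros(len(months), dtype=int)
    counts = {t: np.zeros(len(months), dtype=int) for t in THEMES}
    for k, ym in enumerate(truth.months):
        i = idx[ym]
        totals[i] += 1
        for t in THEMES:
            counts[t][i] += int(truth.themes[t][k])
    return MonthlyPrevalenceSeries(months=months, totals=totals, counts=counts)


def truth_to_corpus(truth: GroundTruth) -> Corpus:
    """Wrap ground-truth flags in a message-less Corpus.

    Useful for label-level experiments (e.g. regression parameter recovery)
    where conversation text is irrelevant.
    """
    conversations = []
    labels = {}
    for k, cid in enumerate(truth.ids):
        year, month = truth.months[k]
        conversations.append(Conversation(id=cid, year=year, month=month, messages=()))
        labels[cid] = LabelSet(
            themes={t: int(truth.themes[t][k]) for t in THEMES},
            strategies={s: int(truth.strategies[s][k]) for s in STRATEGIES},
            issues={i: int(truth.issues[i][k]) for i in ISSUES},
        )
    return Corpus(conversations=conversations, labels=labels)


def truth_to_frame(truth: GroundTruth):
    """Ground-truth flags as a tidy DataFrame (one row per conversation)."""
    import pandas as pd

    data = {"id": truth.ids}
    data["year"] = [y for y, _ in truth.months]
    data["month"] = [m for _, m in truth.months]
    for t in THEMES:
        data[t] = truth.themes[t]
    for s in STRATEGIES:
        data[s] = truth.strategies[s]
    for i in ISSUES:
        data[i] = truth.issues[i]
    return pd.DataFrame(data)
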
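"""Published term lists of the six-family helpline theme dictionary.

These are the English renderings of the validated per-family word lists for
the six thematic families.  Hyphenated entries are stored as ``_``-joined
bigrams so they match adjacent tokens after the standard tokenization
(which splits on non-letter characters).

The lists ship as a ready-made dictionary for users who want to label a
corpus without inducing their own lexicon; pass them through
``Lexicon.from_term_lists(PUBLISHED_THEME_LEXICON)``.
"""

PUBLISHED_THEME_LEXICON = {
    "self_image": [
        "body", "self_esteem", "ugly", "insecure", "hate", "negative",
        "disgusted", "graceful", "attractive", "rejection", "eat", "abnormal",
        "fat", "pretty", "obesity", "obese", "self_image", "beautify",
    ],
    "violence": [
        "raped", "rape", "bullying", "abuse", "abused", "violence",
        "aggression", "hitting", "yelling", "humiliate", "harassment",
    ],
    "sexual_diversity": [
        "gay", "homosexual", "orientation", "trans", "bisexual", "lesbian",
        "closet", "gender", "homophobic", "straight", "transgender", "binary",
        "hermaphrodite", "intersex", "fluid", "demisexual", "pansexual",
        "non_gender",
    ],
    "relational": [
        "friend", "friends", "single", "alone", "lonely", "father", "dad",
        "family", "relatives", "parents", "partner", "boyfriend", "girlfriend",
        "discuss", "finished", "brothers", "mother", "mom", "toxic", "home",
    ],
    "emotional_crisis": [
        "crisis", "cry", "anxiety", "panic", "chest", "anguish", "breathing",
        "sweating", "trembling", "tremble", "pulse", "fears",
    ],
    "performance": [
        "career", "study", "salary", "university", "grades", "test",
        "insufficient", "work", "money", "performance", "effort", "try",
    ],
}
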
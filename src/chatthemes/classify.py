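"""Dictionary labeling rule: any shared term labels the conversation.

A conversation is labeled with a thematic family iff any of that family's
lexicon unigrams equals any token of the preprocessed conversation, or any
lexicon bigram equals any adjacent-token bigram.  Matching is exact on the
normalized forms — "eat" never fires inside "heating"; surface variants are
the lemmatizer hook's concern, not the matcher's.  There is no per-family
match-count threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass


@dataclass(frozen=True)
class ThemeAssignment:
    """Per-family flags for one conversation, with matched-term evidence.

    ``flags[family] == 1`` iff ``evidence[family]`` is nonempty; evidence
    lists are deduplicated and sorted.
    """

    conversation_id: str
    flags: dict
    evidence: dict


def classify(doc, lexicon) -> ThemeAssignment:
    """Label one tokenized conversation against every lexicon family."""
    token_set = set(doc.tokens)
    bigram_set = set(doc.bigrams)
    flags, evidence = {}, {}
    for fam in lexicon.family_names():
        hits = set()
        for term in lexicon.terms(fam):
            if "_" in term:
                if term in bigram_set:
                    hits.add(term)
            elif term in token_set:
                hits.add(term)
        evidence[fam] = sorted(hits)
        flags[fam] = 1 if hits else 0
    return ThemeAssignment(conversation_id=doc.conversation_id, flags=flags, evidence=evidence)


def classify_corpus(corpus, lexicon, preprocess_config) -> list:
    """One ThemeAssignment per conversation, in corpus order."""
    from .preprocess import tokenize

    return [classify(tokenize(conv, preprocess_config), lexicon) for conv in corpus.conversations]


def classify_docs(docs, lexicon) -> list:
    """Classify already-tokenized documents (skips re-tokenization)."""
    return [classify(d, lexicon) for d in docs]


def assignments_to_csv(assignments, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["conversation_id", "family", "flag", "evidence_terms"])
        for a in assignments:
            for fam in a.flags:
                writer.writerow([a.conversation_id, fam, a.flags[fam], ";".join(a.evidence[fam])])
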
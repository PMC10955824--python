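"""Conversation text → token sequences → TF-IDF unigram+bigram features.

Pipeline order is fixed: select turns → concatenate → split on non-letter
boundaries → lowercase → POS-filter → lemmatize → remove stopwords.  Chat
text is informal (frequent misspellings, emoji, digits), so tokenization is
aggressive: anything that is not a letter is a boundary and digits never
survive.  The POS filter and lemmatizer are pluggable hooks defaulting to
identity, keeping the core pipeline dependency-light and deterministic;
language-specific hooks (e.g. a Spanish lemmatizer) can be passed in.

The TF-IDF variant is pinned: smoothed idf ln((1+N)/(1+df)) + 1 with
L2-normalized rows — the dominant convention in the Python ecosystem — so
feature weights are comparable across implementations.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Conversation

_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

TURN_CHOICES = ("user_only", "volunteer_only", "all")


class PreprocessError(RuntimeError):
    """A preprocessing hook failed; carries the conversation id."""


class TfidfStateError(RuntimeError):
    """transform called before fit, or fit found no usable vocabulary."""


@dataclass
class PreprocessConfig:
    lowercase: bool = True
    stopwords: frozenset = frozenset()
    lemmatizer: Optional[Callable[[str], str]] = None  # token -> lemma; None = identity
    pos_filter: Optional[Callable[[list], list]] = None  # token list -> retained; None = all
    ngram_orders: frozenset = frozenset({1, 2})
    turns: str = "user_only"

    def __post_init__(self):
        self.stopwords = frozenset(self.stopwords)
        self.ngram_orders = frozenset(self.ngram_orders)
        if not self.ngram_orders or not self.ngram_orders <= {1, 2}:
            raise ValueError("ngram_orders must be a nonempty subset of {1, 2}")
        if self.turns not in TURN_CHOICES:
            raise ValueError(f"turns must be one of {TURN_CHOICES}")


@dataclass
class TokenizedDoc:
    """Retained unigram sequence for one conversation.

    Bigrams are exactly the adjacent pairs of the retained unigram sequence,
    joined with ``_``.
    """

    conversation_id: str
    tokens: list

    @property
    def bigrams(self) -> list:
        return [f"{a}_{b}" for a, b in zip(self.tokens, self.tokens[1:])]

    def terms(self, ngram_orders=frozenset({1, 2})) -> list:
        out = []
        if 1 in ngram_orders:
            out.extend(self.tokens)
        if 2 in ngram_orders:
            out.extend(self.bigrams)
        return out


def tokenize(conversation: Conversation, config: PreprocessConfig) -> TokenizedDoc:
    """Apply the fixed preprocessing pipeline to one conversation."""
    if config.turns == "user_only":
        texts = [m.text for m in conversation.messages if m.speaker == "user"]
    elif config.turns == "volunteer_only":
        texts = [m.text for m in conversation.messages if m.speaker == "volunteer"]
    else:
        texts = [m.text for m in conversation.messages]
    raw = " ".join(texts)
    tokens = _WORD_RE.findall(raw)
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    try:
        if config.pos_filter is not None:
            tokens = list(config.pos_filter(tokens))
        if config.lemmatizer is not None:
            tokens = [config.lemmatizer(t) for t in tokens]
    except Exception as exc:
        raise PreprocessError(
            f"preprocessing hook failed for conversation {conversation.id!r}: {exc}"
        ) from exc
    if config.stopwords:
        tokens = [t for t in tokens if t not in config.stopwords]
    return TokenizedDoc(conversation_id=conversation.id, tokens=tokens)


def tokenize_corpus(corpus, config: PreprocessConfig) -> list:
    return [tokenize(c, config) for c in corpus.conversations]


@dataclass
class TfidfMatrix:
    """Fitted TF-IDF features: weights, vocabulary and document frequencies.

    ``matrix[i, j]`` is the L2-normalized smoothed-idf weight of term
    ``terms[j]`` in document ``doc_ids[i]``.  The vocabulary is sorted
    lexicographically, so column order is deterministic.
    """

    doc_ids: list
    terms: np.ndarray
    matrix: sp.csr_matrix
    df: np.ndarray
    n_docs: int
    ngram_orders: frozenset
    _vectorizer: TfidfVectorizer = field(repr=False, default=None)

    def term_index(self) -> dict:
        return {t: j for j, t in enumerate(self.terms)}

    def rows_for(self, doc_ids) -> sp.csr_matrix:
        pos = {d: i for i, d in enumerate(self.doc_ids)}
        return self.matrix[[pos[d] for d in doc_ids]]


def fit_tfidf(docs: list, min_df: int = 1, ngram_orders=frozenset({1, 2})) -> TfidfMatrix:
    """Fit the TF-IDF vocabulary and weight matrix on tokenized documents.

    Terms are the union of unigrams and ``_``-joined bigrams (per
    ``ngram_orders``); terms appearing in fewer than ``min_df`` documents
    are dropped.  All-empty input raises :class:`TfidfStateError`.
    """
    ngram_orders = frozenset(ngram_orders)
    term_lists = [d.terms(ngram_orders) for d in docs]
    if not any(term_lists):
        raise TfidfStateError("cannot fit TF-IDF: all documents are empty")
    vec = TfidfVectorizer(analyzer=lambda d: d, min_df=min_df, norm="l2", smooth_idf=True)
    try:
        X = vec.fit_transform(term_lists)
    except ValueError as exc:
        raise TfidfStateError(f"cannot fit TF-IDF: {exc}") from exc
    terms = vec.get_feature_names_out()
    # document frequencies, recovered by exact counting (not from idf)
    vocab = vec.vocabulary_
    df = np.zeros(len(terms), dtype=int)
    for tl in term_lists:
        for t in set(tl):
            j = vocab.get(t)
            if j is not None:
                df[j] += 1
    return TfidfMatrix(
        doc_ids=[d.conversation_id for d in docs],
        terms=terms,
        matrix=X.tocsr(),
        df=df,
        n_docs=len(docs),
        ngram_orders=ngram_orders,
        _vectorizer=vec,
    )


def transform_tfidf(fitted: TfidfMatrix, docs: list) -> sp.csr_matrix:
    """Weight rows for new documents under the fitted vocabulary/df.

    Out-of-vocabulary terms are ignored; a document sharing no vocabulary
    terms maps to an all-zero row.
    """
    if fitted._vectorizer is None:
        raise TfidfStateError("TF-IDF matrix is not fitted")
    return fitted._vectorizer.transform([d.terms(fitted.ngram_orders) for d in docs]).tocsr()


def load_stopwords(path) -> frozenset:
    """Plain-text stopword list, one term per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip().lower() for line in fh if line.strip())


def export_tfidf(fitted: TfidfMatrix, matrix_path, vocab_path) -> None:
    """Write the sparse matrix as MTX and the vocabulary as a TSV."""
    from scipy.io import mmwrite

    mmwrite(str(matrix_path), fitted.matrix)
    with open(vocab_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["term", "column", "df"])
        for j, t in enumerate(fitted.terms):
            writer.writerow([t, j, int(fitted.df[j])])
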
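import numpy as np
import pytest

from chatthemes.classify import classify_corpus
from chatthemes.corpus import Corpus, LabelSet, THEMES
from chatthemes.lexicon import (
    EvaluationError,
    InductionConfig,
    InductionError,
    Lexicon,
    LexiconTerm,
    evaluate_lexicon,
    induce_lexicon,
    prune_uninformative,
    rank_features,
    refine_lexicon,
)
from chatthemes.preprocess import PreprocessConfig, TokenizedDoc, fit_tfidf
from .conftest import make_conv


def doc(cid, tokens):
    return TokenizedDoc(conversation_id=cid, tokens=list(tokens))


def _separable_matrix(rng, n=60):
    """Docs where the token 'marker' is present iff the label is 1."""
    noise = [f"n{j}" for j in range(9)]
    docs, labels = [], []
    for i in range(n):
        y = i % 2
        toks = list(rng.choice(noise, size=8))
        if y:
            toks.append("marker")
        docs.append(doc(f"d{i}", toks))
        labels.append(y)
    return fit_tfidf(docs, ngram_orders={1}), labels


class TestRankFeatures:
    def test_perfect_separator_ranked_first(self, rng):
        tfidf, labels = _separable_matrix(rng)
        ranked = rank_features(tfidf, labels, InductionConfig(n_trees=100, seed=0))
        assert ranked[0][0] == "marker"

    def test_importances_sum_to_one(self, rng):
        tfidf, labels = _separable_matrix(rng)
        ranked = rank_features(tfidf, labels, InductionConfig(n_trees=50, seed=0))
        assert sum(v for _, v in ranked) == pytest.approx(1.0)

    def test_single_class_labels_raise_named_error(self, rng):
        tfidf, _ = _separable_matrix(rng)
        with pytest.raises(InductionError, match="self_image"):
            rank_features(tfidf, [1] * tfidf.n_docs, InductionConfig(), family="self_image")

    def test_permuted_labels_spread_importance(self, rng):
        # under the permutation null no feature should dominate
        tfidf, labels = _separable_matrix(rng, n=80)
        ratios = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(labels)
            if len(np.unique(perm)) < 2:
                continue
            ranked = rank_features(tfidf, perm, InductionConfig(n_trees=50, seed=seed))
            imp = np.array([v for _, v in ranked])
            ratios.append(imp.max() / imp.mean())
        assert np.mean(ratios) < 3.0

    def test_deterministic_for_fixed_seed(self, rng):
        tfidf, labels = _separable_matrix(rng)
        cfg = InductionConfig(n_trees=50, seed=7)
        assert rank_features(tfidf, labels, cfg) == rank_features(tfidf, labels, cfg)

    def test_unigrams_only_excludes_bigrams(self, rng):
        noise = [f"n{j}" for j in range(5)]
        docs, labels = [], []
        for i in range(40):
            toks = list(rng.choice(noise, size=6)) + (["hit"] if i % 2 else [])
            docs.append(doc(f"d{i}", toks))
            labels.append(i % 2)
        tfidf = fit_tfidf(docs)  # includes bigrams
        ranked = rank_features(
            tfidf, labels, InductionConfig(n_trees=50, seed=0, unigrams_only=True)
        )
        assert all("_" not in t for t, _ in ranked)


class TestInduceRefine:
    def test_truncation_takes_all_when_few_features(self):
        rankings = {"violence": [(f"t{i}", 1.0 - i / 10) for i in range(10)]}
        lex = induce_lexicon(rankings, InductionConfig(top_k=40))
        assert lex.terms("violence") == [f"t{i}" for i in range(10)]
        assert all(lt.provenance == "induced" for lt in lex.families["violence"])

    def test_top_k_one_takes_single_best(self):
        rankings = {"violence": [("best", 0.9), ("worse", 0.1)]}
        lex = induce_lexicon(rankings, InductionConfig(top_k=1))
        assert lex.terms("violence") == ["best"]

    def test_added_terms_carry_expert_provenance(self):
        lex = Lexicon(families={"self_image": [LexiconTerm("body", "induced")]})
        out = refine_lexicon(lex, add={"self_image": ["beautify"]})
        assert out.families["self_image"][-1] == LexiconTerm("beautify", "expert_added")

    def test_add_then_remove_restores_terms_but_keeps_log(self):
        lex = Lexicon(families={"violence": [LexiconTerm("abuse", "induced")]})
        out = refine_lexicon(
            refine_lexicon(lex, add={"violence": ["rage"]}), remove={"violence": ["rage"]}
        )
        assert out.terms("violence") == ["abuse"]
        events = [(e["event"], e["term"]) for e in out.log]
        assert ("added", "rage") in events and ("removed", "rage") in events

    def test_removing_non_member_warns_not_errors(self):
        lex = Lexicon(families={"violence": [LexiconTerm("abuse", "induced")]})
        out = refine_lexicon(lex, remove={"violence": ["ghost"]})
        assert out.terms("violence") == ["abuse"]
        assert any(e["event"] == "warning" for e in out.log)

    def test_json_roundtrip(self, tmp_path):
        lex = Lexicon(families={"violence": [LexiconTerm("abuse", "induced"),
                                             LexiconTerm("rage", "expert_added")]})
        path = tmp_path / "lex.json"
        lex.to_json(path)
        back = Lexicon.from_json(path)
        assert back.families == lex.families


class TestPruning:
    def test_uninformative_common_term_removed_signal_kept(self):
        docs, gold = [], []
        for i in range(200):
            y = i % 4 == 0
            toks = ["filler"]  # present everywhere
            if y:
                toks.append("signal")
            docs.append(doc(f"d{i}", toks))
            gold.append(int(y))
        lex = Lexicon(families={"violence": [LexiconTerm("signal", "induced"),
                                             LexiconTerm("filler", "induced")]})
        out = prune_uninformative(lex, docs, {"violence": gold})
        assert out.terms("violence") == ["signal"]
        assert any(e["event"] == "auto_removed" and e["term"] == "filler" for e in out.log)

    def test_expert_terms_survive_pruning(self):
        docs = [doc(f"d{i}", ["alpha"] if i % 2 else ["beta"]) for i in range(40)]
        gold = [i % 2 for i in range(40)]
        lex = Lexicon(families={"violence": [LexiconTerm("rarity", "expert_added")]})
        out = prune_uninformative(lex, docs, {"violence": gold})
        assert out.terms("violence") == ["rarity"]


def _eval_corpus(texts, gold_flags, fam="violence"):
    convs = [make_conv(f"c{i}", 2020, 1, [t], speakers=["user"]) for i, t in enumerate(texts)]
    labels = {}
    for i, g in enumerate(gold_flags):
        themes = {fam: g} if g is not None else {}
        labels[f"c{i}"] = LabelSet(themes=themes)
    return Corpus(conversations=convs, labels=labels)


class TestEvaluate:
    lex = Lexicon(families={"violence": [LexiconTerm("hit", "induced")]})
    pp = PreprocessConfig()

    def test_confusion_counts_hand_enumeration(self):
        # gold [1,1,0,0], predicted [1,0,0,0]
        corpus = _eval_corpus(["he hit me", "it was bad", "fine day", "all good"],
                              [1, 1, 0, 0])
        ev = evaluate_lexicon(corpus, self.lex, self.pp)
        m = ev.metrics["violence"]
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 0, 2)
        assert m.accuracy == 0.75 and m.precision == 1.0 and m.recall == 0.5

    def test_perfect_prediction_all_ones(self):
        corpus = _eval_corpus(["hit hard", "no problem"], [1, 0])
        ev = evaluate_lexicon(corpus, self.lex, self.pp)
        m = ev.metrics["violence"]
        assert m.accuracy == 1.0 and m.precision == 1.0 and m.recall == 1.0

    def test_never_firing_dictionary_has_absent_precision(self):
        corpus = _eval_corpus(["quiet words", "calm words"], [1, 0])
        ev = evaluate_lexicon(corpus, self.lex, self.pp)
        m = ev.metrics["violence"]
        assert m.recall == 0.0 and m.precision is None

    def test_unknown_gold_excluded_from_counts(self):
        corpus = _eval_corpus(["he hit me", "hit again", "calm"], [1, None, 0])
        ev = evaluate_lexicon(corpus, self.lex, self.pp)
        m = ev.metrics["violence"]
        assert m.n == 2

    def test_no_evaluable_conversations_is_error(self):
        corpus = _eval_corpus(["he hit me"], [None])
        with pytest.raises(EvaluationError):
            evaluate_lexicon(corpus, self.lex, self.pp)

    def test_metrics_equal_brute_force_on_random_corpora(self, rng):
        # independent oracle: explicit set-intersection predictions and
        # direct confusion counting (letter-only vocab so tokenization
        # round-trips the raw words)
        vocab = [f"w{chr(97 + j)}" for j in range(12)]
        for _ in range(10):
            n = int(rng.integers(5, 15))
            texts = [" ".join(rng.choice(vocab, size=6)) for _ in range(n)]
            gold = [int(g) for g in rng.integers(0, 2, size=n)]
            lex_terms = list(rng.choice(vocab, size=3, replace=False))
            corpus = _eval_corpus(texts, gold)
            lex = Lexicon(families={"violence": [LexiconTerm(t, "induced") for t in lex_terms]})
            ev = evaluate_lexicon(corpus, lex, self.pp)
            tp = fp = fn = tn = 0
            for text, g in zip(texts, gold):
                pred = 1 if set(text.split()) & set(lex_terms) else 0
                tp += pred and g
                fp += pred and not g
                fn += (not pred) and g
                tn += (not pred) and (not g)
            m = ev.metrics["violence"]
            assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)

    def test_adding_term_never_decreases_recall_or_coverage(self, rng):
        vocab = [f"w{j}" for j in range(10)]
        texts = [" ".join(rng.choice(vocab, size=5)) for _ in range(30)]
        gold = [int(g) for g in rng.integers(0, 2, size=30)]
        corpus = _eval_corpus(texts, gold)
        lex = Lexicon(families={"violence": [LexiconTerm("w0", "induced")]})
        base = evaluate_lexicon(corpus, lex, self.pp).metrics["violence"]
        bigger = refine_lexicon(lex, add={"violence": ["w1", "w2"]})
        after = evaluate_lexicon(corpus, bigger, self.pp).metrics["violence"]
        base_recall = base.recall if base.recall is not None else 0.0
        after_recall = after.recall if after.recall is not None else 0.0
        assert after_recall >= base_recall
        assert (after.tp + after.fp) >= (base.tp + base.fp)
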
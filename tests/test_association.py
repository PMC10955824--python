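import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from chatthemes.association import (
    AssociationError,
    DesignError,
    DesignMatrix,
    ThemeIssueLogit,
    build_design,
    fit_logistic,
    mcfadden_r2,
    phi_association,
    phi_from_counts,
    regression_table,
    significance_stars,
)
from chatthemes.corpus import ISSUES, STRATEGIES, THEMES, Corpus, LabelSet
from chatthemes.synthetic import GeneratorConfig, generate_labels, truth_to_corpus
from .conftest import make_conv


def _design_from_arrays(X_cols: dict, y) -> DesignMatrix:
    X = pd.DataFrame({"const": np.ones(len(y)), **{k: np.asarray(v, float) for k, v in X_cols.items()}})
    return DesignMatrix(X=X, y=pd.Series(np.asarray(y, float), name="suicidal"),
                        issue="suicidal", n_dropped=0)


class TestBuildDesign:
    def _labeled_corpus(self, n=40, holes=()):
        cfg = GeneratorConfig(n_conversations=n, seed=31)
        corpus = truth_to_corpus(generate_labels(cfg))
        for cid in holes:
            old = corpus.labels[cid]
            strategies = dict(old.strategies)
            strategies["containment"] = None
            corpus.labels[cid] = LabelSet(themes=old.themes, strategies=strategies,
                                          issues=old.issues)
        return corpus

    def test_fourteen_columns_with_intercept(self):
        design = build_design(self._labeled_corpus(), "suicidal")
        assert design.X.shape == (40, 14)
        assert list(design.X.columns[:1]) == ["const"]
        assert set(design.X.columns) == {"const", *THEMES, *STRATEGIES}

    def test_pandemic_dummy_adds_column(self):
        design = build_design(self._labeled_corpus(), "suicidal", include_pandemic_dummy=True)
        assert design.X.shape[1] == 15 and "pandemic" in design.X.columns

    def test_unknown_label_rows_dropped_and_counted(self):
        corpus = self._labeled_corpus(holes=("conv000003",))
        design = build_design(corpus, "suicidal")
        assert design.n == 39 and design.n_dropped == 1

    def test_indicators_are_binary_with_zero_reference(self):
        design = build_design(self._labeled_corpus(), "depressive")
        vals = design.X.drop(columns="const").to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_empty_design_is_error(self):
        corpus = Corpus(conversations=[make_conv("a", 2020, 1, ["x"])], labels={})
        with pytest.raises(DesignError):
            build_design(corpus, "suicidal")

    def test_unknown_issue_name_rejected(self):
        with pytest.raises(ValueError):
            build_design(self._labeled_corpus(), "stress")


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        design = _design_from_arrays({}, y)
        fit = fit_logistic(design)
        assert fit.params["const"] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_two_by_two_closed_form_log_odds_and_se(self):
        a, b, c, d = 20, 15, 10, 30  # (x=1,y=1),(x=1,y=0),(x=0,y=1),(x=0,y=0)
        x = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        fit = fit_logistic(_design_from_arrays({"x": x}, y))
        assert fit.params["x"] == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.bse["x"] == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)

    def test_matches_direct_likelihood_maximization(self, rng):
        # independent oracle: numerically maximize the written log-likelihood
        n = 50
        X = np.column_stack([np.ones(n)] + [rng.integers(0, 2, n) for _ in range(3)])
        z = X @ np.array([-0.5, 0.8, -0.4, 0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
        design = DesignMatrix(
            X=pd.DataFrame(X, columns=["const", "x1", "x2", "x3"]),
            y=pd.Series(y, name="suicidal"), issue="suicidal", n_dropped=0,
        )
        fit = fit_logistic(design)

        def negll(beta):
            eta = X @ beta
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        res = optimize.minimize(negll, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-5)

    def test_single_class_outcome_is_error(self):
        design = _design_from_arrays({"x": [0, 1, 0, 1]}, [1, 1, 1, 1])
        with pytest.raises(DesignError):
            ThemeIssueLogit(design).fit()

    def test_separation_flagged_with_column(self):
        x = np.array([1] * 10 + [0] * 10)
        fit = fit_logistic(_design_from_arrays({"x": x}, x))  # x predicts y perfectly
        assert fit.separation
        assert "x" in fit.separation_columns

    def test_parameter_recovery_within_three_se(self):
        # single replicate: nearly all of the 42 coefficients should sit
        # inside their 3-SE band (full coverage study in the acceptance suite)
        cfg = GeneratorConfig(n_conversations=5000, seed=77)
        corpus = truth_to_corpus(generate_labels(cfg))
        hits = total = 0
        for issue in ISSUES:
            fit = fit_logistic(build_design(corpus, issue))
            true = cfg.issue_coefs[issue]
            for name in fit.params.index:
                truth_val = true.get("intercept" if name == "const" else name, 0.0)
                total += 1
                hits += abs(fit.params[name] - truth_val) < 3 * fit.bse[name]
        assert hits >= total - 2


class TestMcFadden:
    def test_intercept_only_model_has_zero_r2(self):
        y = np.array([1] * 25 + [0] * 75)
        fit = fit_logistic(_design_from_arrays({}, y))
        assert mcfadden_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_likelihood_arithmetic(self):
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        fit = fit_logistic(_design_from_arrays({"x": x}, y))
        X = np.column_stack([np.ones(8), x])
        beta = fit.params.to_numpy()
        eta = X @ beta
        ll = (y * eta - np.log1p(np.exp(eta))).sum()
        p0 = y.mean()
        ll0 = (y * math.log(p0 / (1 - p0)) + math.log(1 - p0)).sum()
        assert fit.llf == pytest.approx(ll, abs=1e-8)
        assert fit.llnull == pytest.approx(ll0, abs=1e-8)
        assert fit.pseudo_r2 == pytest.approx(1 - ll / ll0, abs=1e-8)


class TestPhi:
    def test_identical_vectors_give_one(self):
        x = np.array([0, 1, 1, 0, 1])
        assert phi_association(x, x).phi == pytest.approx(1.0)

    def test_balanced_independence_gives_zero(self):
        pa = phi_from_counts(25, 25, 25, 25)
        assert pa.phi == 0.0 and pa.chi2 == 0.0 and pa.p == 1.0

    def test_hand_arithmetic(self):
        pa = phi_from_counts(30, 10, 10, 50)
        assert pa.phi == pytest.approx(1400 / 2400)
        assert pa.chi2 == pytest.approx(100 * (1400 / 2400) ** 2)

    def test_symmetric_and_relabel_invariant(self, rng):
        x = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        assert phi_association(x, y).phi == pytest.approx(phi_association(y, x).phi)
        assert phi_association(1 - x, 1 - y).phi == pytest.approx(phi_association(x, y).phi)

    def test_constant_vector_undefined(self):
        with pytest.raises(AssociationError):
            phi_association(np.ones(10, dtype=int), np.array([0, 1] * 5))


class TestReporting:
    def test_star_thresholds(self):
        assert significance_stars(0.003) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.07) == "*"
        assert significance_stars(0.5) == ""

    def test_table_layout_and_footer(self):
        cfg = GeneratorConfig(n_conversations=600, seed=19)
        corpus = truth_to_corpus(generate_labels(cfg))
        fits = {i: fit_logistic(build_design(corpus, i)) for i in ISSUES}
        table = regression_table(fits)
        header = table.splitlines()[0]
        assert header.index("suicidal") < header.index("depressive") < header.index("anxious")
        assert "Observations" in table and "Pseudo R2" in table
        assert "*p < 0.1; **p < 0.05; ***p < 0.01" in table


def test_pandemic_dummy_leaves_estimates_stable():
    # issues do not depend on period, so adding the dummy should barely
    # move the theme/strategy coefficients
    cfg = GeneratorConfig(n_conversations=4000, seed=23)
    corpus = truth_to_corpus(generate_labels(cfg))
    moves = []
    for issue in ISSUES:
        base = fit_logistic(build_design(corpus, issue))
        with_dummy = fit_logistic(build_design(corpus, issue, include_pandemic_dummy=True))
        for name in base.params.index:
            if name == "const":
                continue
            moves.append(abs(base.params[name] - with_dummy.params[name]) / base.bse[name])
    assert np.mean(moves) < 1.0
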
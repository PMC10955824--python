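"""Issue-level logistic regressions and pairwise binary associations.

For each mental-health issue (suicidal behavior, depressive and anxious
symptomatology) a logistic regression is fitted on the 13 binary
theme/strategy indicators of the expert-tagged conversations (optionally
plus a pandemic-period dummy).  Wald statistics are reported as t values
against the normal reference — at the tagged-sample sizes involved the df
convention is negligible — with the conventional significance stars
(* p<0.1, ** p<0.05, *** p<0.01) and McFadden's pseudo-R².

Pairwise association between two binary variables is summarized by the phi
coefficient phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) on the 2x2 table,
tested via chi-square = N * phi^2 with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import ISSUES, STRATEGIES, THEMES, month_index


class DesignError(ValueError):
    """No usable rows for the regression design."""


class AssociationError(ValueError):
    """Pairwise association undefined (constant vector)."""


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class DesignMatrix:
    """Intercept + binary indicators, with the issue outcome vector."""

    X: pd.DataFrame  # columns: const, 6 themes, 7 strategies [, pandemic]
    y: pd.Series
    issue: str
    n_dropped: int

    @property
    def n(self) -> int:
        return len(self.y)


def build_design(
    corpus,
    issue: str,
    include_pandemic_dummy: bool = False,
    break_month: tuple = (2020, 3),
) -> DesignMatrix:
    """Assemble the regression design from a corpus's labeled subset.

    Conversations missing any needed label (the outcome or any of the 13
    indicators) are dropped; the drop count is recorded on the result.  The
    reference category of every indicator is 0 (absence).
    """
    if issue not in ISSUES:
        raise ValueError(f"unknown issue {issue!r}; expected one of {ISSUES}")
    predictors = list(THEMES) + list(STRATEGIES)
    rows, outcomes, ids = [], [], []
    n_dropped = 0
    bi = month_index(*break_month)
    for conv in corpus.conversations:
        ls = corpus.labels.get(conv.id)
        if ls is None:
            n_dropped += 1
            continue
        flat = {**ls.themes, **ls.strategies}
        y = ls.issues.get(issue)
        if y is None or any(flat.get(p) is None for p in predictors):
            n_dropped += 1
            continue
        row = {"const": 1.0}
        row.update({p: float(flat[p]) for p in predictors})
        if include_pandemic_dummy:
            row["pandemic"] = float(month_index(conv.year, conv.month) >= bi)
        rows.append(row)
        outcomes.append(float(y))
        ids.append(conv.id)
    if not rows:
        raise DesignError(f"no fully labeled conversations for issue {issue!r}")
    X = pd.DataFrame(rows, index=ids)
    y = pd.Series(outcomes, index=ids, name=issue)
    return DesignMatrix(X=X, y=y, issue=issue, n_dropped=n_dropped)


@dataclass
class LogitFit:
    """Maximum-likelihood logistic fit with Wald tests and diagnostics."""

    issue: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    llf: float
    llnull: float
    nobs: int
    converged: bool
    separation: bool = False
    separation_columns: list = field(default_factory=list)

    @property
    def pseudo_r2(self) -> float:
        return mcfadden_r2(self)

    def stars(self) -> pd.Series:
        return self.pvalues.map(significance_stars)

    def summary(self) -> str:
        lines = [
            f"Logistic regression: outcome = {self.issue}",
            f"n = {self.nobs}, log-likelihood = {self.llf:.3f}, "
            f"null = {self.llnull:.3f}, McFadden R2 = {self.pseudo_r2:.5g}",
        ]
        if self.separation:
            lines.append(
                f"WARNING: separation detected (columns: {', '.join(self.separation_columns)}); "
                "estimates are not finite maximum-likelihood values"
            )
        lines.append(f"{'':22s}{'coef':>9s}{'se':>9s}{'t':>8s}{'p':>10s}")
        for name in self.params.index:
            lines.append(
                f"{name:22s}{self.params[name]:9.3f}{self.bse[name]:9.3f}"
                f"{self.tvalues[name]:8.2f}{self.pvalues[name]:10.3g} "
                f"{significance_stars(self.pvalues[name])}"
            )
        return "\n".join(lines)


class ThemeIssueLogit:
    """Model object wrapping a design matrix; ``fit()`` returns a LogitFit."""

    def __init__(self, design: DesignMatrix):
        self.design = design

    def fit(self, maxiter: int = 100) -> LogitFit:
        y = self.design.y.to_numpy()
        if len(np.unique(y)) < 2:
            raise DesignError(
                f"outcome {self.design.issue!r} has a single class; cannot fit"
            )
        import statsmodels.api as sm

        model = sm.Logit(self.design.y, self.design.X)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(disp=0, method="newton", maxiter=maxiter, tol=1e-10)
                except Exception:
                    res = model.fit(disp=0, method="bfgs", maxiter=500)
        params = pd.Series(res.params, index=self.design.X.columns)
        bse = pd.Series(res.bse, index=self.design.X.columns)
        # quasi/complete separation shows up as diverging estimates
        sep_cols = [c for c in params.index if abs(params[c]) > 15 or not np.isfinite(bse[c])]
        tvals = params / bse
        pvals = pd.Series(2 * stats.norm.sf(np.abs(tvals)), index=params.index)
        return LogitFit(
            issue=self.design.issue,
            params=params,
            bse=bse,
            tvalues=tvals,
            pvalues=pvals,
            llf=float(res.llf),
            llnull=float(res.llnull),
            nobs=int(res.nobs),
            converged=bool(res.mle_retvals.get("converged", True)),
            separation=bool(sep_cols),
            separation_columns=sep_cols,
        )


def fit_logistic(design: DesignMatrix) -> LogitFit:
    """Functional wrapper around :class:`ThemeIssueLogit`."""
    return ThemeIssueLogit(design).fit()


def mcfadden_r2(fit: LogitFit) -> float:
    """McFadden pseudo-R² = 1 - llf/llnull on the same rows."""
    if fit.llnull == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R2 undefined")
    return 1.0 - fit.llf / fit.llnull


@dataclass(frozen=True)
class PairwiseAssociation:
    """2x2 table (a=n11, b=n10, c=n01, d=n00), phi, chi-square and p."""

    a: int
    b: int
    c: int
    d: int
    phi: float
    chi2: float
    p: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def phi_from_counts(a: int, b: int, c: int, d: int) -> PairwiseAssociation:
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise AssociationError("phi undefined: a table margin is zero")
    phi = (a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins]))
    n = a + b + c + d
    chi2 = n * phi**2
    p = float(stats.chi2.sf(chi2, df=1))
    return PairwiseAssociation(a=a, b=b, c=c, d=d, phi=float(phi), chi2=float(chi2), p=p)


def phi_association(x, y) -> PairwiseAssociation:
    """Phi coefficient and chi-square test for two binary vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise AssociationError("phi undefined for a constant vector")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return phi_from_counts(a, b, c, d)


def regression_table(fits: dict) -> str:
    """Plain-text results table: coefficient (SE) with stars, one issue per column.

    Column order is suicidal, depressive, anxious; the footer carries the
    observation counts and McFadden pseudo-R² per model.
    """
    order = [i for i in ISSUES if i in fits] + [i for i in fits if i not in ISSUES]
    rownames = list(fits[order[0]].params.index)
    width = 22
    cw = 18
    lines = ["".join([" " * width] + [f"{i:>{cw}s}" for i in order])]
    for name in rownames:
        coefs, ses = [], []
        for i in order:
            f = fits[i]
            if name in f.params.index:
                coefs.append(f"{f.params[name]:.3f}{significance_stars(f.pvalues[name])}")
                ses.append(f"({f.bse[name]:.3f})")
            else:
                coefs.append("")
                ses.append("")
        lines.append("".join([f"{name:{width}s}"] + [f"{c:>{cw}s}" for c in coefs]))
        lines.append("".join([" " * width] + [f"{s:>{cw}s}" for s in ses]))
    lines.append(
        "".join([f"{'Observations':{width}s}"] + [f"{fits[i].nobs:>{cw}d}" for i in order])
    )
    lines.append(
        "".join([f"{'Pseudo R2':{width}s}"] + [f"{fits[i].pseudo_r2:>{cw}.5g}" for i in order])
    )
    lines.append("*p < 0.1; **p < 0.05; ***p < 0.01")
    return "\n".join(lines)


def fits_to_frame(fits: dict) -> pd.DataFrame:
    rows = []
    for issue, f in fits.items():
        for name in f.params.index:
            rows.append(
                {
                    "issue": issue,
                    "term": name,
                    "estimate": f.params[name],
                    "se": f.bse[name],
                    "t": f.tvalues[name],
                    "p": f.pvalues[name],
                    "stars": significance_stars(f.pvalues[name]),
                }
            )
        rows.append({"issue": issue, "term": "__pseudo_r2__", "estimate": f.pseudo_r2,
                     "se": np.nan, "t": np.nan, "p": np.nan, "stars": ""})
    return pd.DataFrame(rows)
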
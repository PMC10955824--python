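"""Monthly theme prevalence and the pre/post-pandemic level-change test.

The change test is an interrupted time series on each theme's monthly
prevalence y_t:

    y_t = alpha + rho * y_{t-1} + beta * D_t + eps_t

where D_t is a step dummy equal to 1 from the break month onwards (March
2020 by default; March counts as pandemic regardless of day).  The model is
estimated by conditional least squares — ordinary least squares on the
lagged regression over t = 2..T — so the dummy's t-test is standard
regression output with n_used - 3 degrees of freedom.  A positive t on the
dummy means the theme's prevalence rose during the pandemic months.
Residual whiteness is checked with a Ljung-Box portmanteau test.

Months with zero conversations break the lag chain: only consecutive-month
pairs with both months observed enter the regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import THEMES, month_index


class TrendDesignError(ValueError):
    """Series unusable for the AR(1)+dummy fit (too short, constant dummy, ...)."""


@dataclass
class MonthlyPrevalenceSeries:
    """Per-family monthly labeled counts and prevalences.

    ``prevalence[family][i] = counts[family][i] / totals[i]``; months with a
    zero conversation total have absent (NaN) prevalence.
    """

    months: list  # ordered contiguous (year, month) pairs
    totals: np.ndarray
    counts: dict  # family -> np.ndarray of labeled counts

    def prevalence(self, family: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.totals > 0, self.counts[family] / np.maximum(self.totals, 1), np.nan)
        return out

    @property
    def families(self) -> list:
        return list(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.counts:
            prev = self.prevalence(fam)
            for i, (y, m) in enumerate(self.months):
                rows.append(
                    {
                        "family": fam,
                        "year": y,
                        "month": m,
                        "labeled": int(self.counts[fam][i]),
                        "total": int(self.totals[i]),
                        "prevalence": prev[i],
                    }
                )
        return pd.DataFrame(rows)


def prevalence_series(assignments, corpus, families=THEMES) -> MonthlyPrevalenceSeries:
    """Count labeled conversations per family per calendar month.

    Families are counted independently (a conversation may carry several
    labels).  The month range is the corpus's full min..max span, contiguous.
    """
    by_id = {c.id: c for c in corpus.conversations}
    for a in assignments:
        if a.conversation_id not in by_id:
            raise KeyError(f"assignment for unknown conversation {a.conversation_id!r}")
    if not corpus.conversations:
        raise ValueError("empty corpus")
    mi = [month_index(c.year, c.month) for c in corpus.conversations]
    lo, hi = min(mi), max(mi)
    months = [(k // 12, k % 12 + 1) for k in range(lo, hi + 1)]
    totals = np.zeros(len(months), dtype=int)
    for c in corpus.conversations:
        totals[month_index(c.year, c.month) - lo] += 1
    counts = {f: np.zeros(len(months), dtype=int) for f in families}
    for a in assignments:
        c = by_id[a.conversation_id]
        i = month_index(c.year, c.month) - lo
        for f in families:
            if a.flags.get(f, 0) == 1:
                counts[f][i] += 1
    return MonthlyPrevalenceSeries(months=months, totals=totals, counts=counts)


# ---------------------------------------------------------------------------
# AR(1) + dummy model


@dataclass
class Ar1FitResult:
    """Conditional-least-squares fit of y_t = a + rho*y_{t-1} + beta*D_t + e_t."""

    params: dict  # {"intercept","ar1","dummy"} -> estimate
    bse: dict
    tvalues: dict
    pvalues: dict
    resid: np.ndarray
    sigma2: float
    n_used: int
    df_resid: int
    ljung_box_stat: Optional[float] = None
    ljung_box_p: Optional[float] = None
    ljung_box_lags: Optional[int] = None
    notes: list = field(default_factory=list)

    @property
    def dummy_t(self) -> float:
        return self.tvalues["dummy"]

    @property
    def dummy_p(self) -> float:
        return self.pvalues["dummy"]

    def summary(self) -> str:
        lines = [
            "AR(1) + intervention dummy (conditional least squares)",
            f"n_used = {self.n_used}, df_resid = {self.df_resid}",
            f"{'':12s}{'coef':>10s}{'se':>10s}{'t':>9s}{'p':>12s}",
        ]
        for name in ("intercept", "ar1", "dummy"):
            lines.append(
                f"{name:12s}{self.params[name]:10.4f}{self.bse[name]:10.4f}"
                f"{self.tvalues[name]:9.2f}{self.pvalues[name]:12.3g}"
            )
        if self.ljung_box_p is not None:
            lines.append(
                f"Ljung-Box (lags={self.ljung_box_lags}): "
                f"Q = {self.ljung_box_stat:.3f}, p = {self.ljung_box_p:.3g}"
            )
        return "\n".join(lines)


class Ar1DummyModel:
    """Interrupted-time-series model for one theme's monthly prevalence.

    Parameters
    ----------
    y : sequence of float
        Monthly values aligned with ``months``; NaN marks absent months.
    months : sequence of (year, month)
        Contiguous calendar months.
    break_month : (year, month)
        First month of the intervention period; D_t = 1 for months >= it.
    """

    def __init__(self, y, months, break_month=(2020, 3)):
        y = np.asarray(y, dtype=float)
        if len(y) != len(months):
            raise ValueError("y and months must be the same length")
        self.y = y
        self.months = list(months)
        self.break_month = tuple(break_month)

    def _design(self):
        bi = month_index(*self.break_month)
        rows = []  # (y_t, y_{t-1}, D_t)
        for t in range(1, len(self.y)):
            prev_idx = month_index(*self.months[t - 1])
            cur_idx = month_index(*self.months[t])
            if cur_idx - prev_idx != 1:
                raise ValueError("months must be contiguous")
            if math.isnan(self.y[t]) or math.isnan(self.y[t - 1]):
                continue  # absent month breaks the lag chain
            rows.append((self.y[t], self.y[t - 1], 1.0 if cur_idx >= bi else 0.0))
        return rows

    def fit(self, lb_lags: Optional[int] = None) -> Ar1FitResult:
        rows = self._design()
        n = len(rows)
        if n < 8:
            raise TrendDesignError(f"need >= 8 usable month pairs, have {n}")
        yv = np.array([r[0] for r in rows])
        X = np.column_stack(
            [np.ones(n), np.array([r[1] for r in rows]), np.array([r[2] for r in rows])]
        )
        if len(np.unique(X[:, 2])) < 2:
            raise TrendDesignError("intervention dummy is constant over the usable range")
        if np.linalg.matrix_rank(X) < 3:
            raise TrendDesignError("collinear regressors in AR(1)+dummy design")

        import statsmodels.api as sm

        res = sm.OLS(yv, X).fit()
        names = ("intercept", "ar1", "dummy")
        fit = Ar1FitResult(
            params=dict(zip(names, res.params)),
            bse=dict(zip(names, res.bse)),
            tvalues=dict(zip(names, res.tvalues)),
            pvalues=dict(zip(names, res.pvalues)),
            resid=np.asarray(res.resid),
            sigma2=float(res.ssr / res.df_resid),
            n_used=n,
            df_resid=int(res.df_resid),
        )
        if lb_lags is None:
            lb_lags = min(10, n // 5)
        if lb_lags >= 1 and lb_lags < n:
            try:
                q, p = ljung_box(fit.resid, lb_lags)
                fit.ljung_box_stat, fit.ljung_box_p, fit.ljung_box_lags = q, p, lb_lags
            except ValueError as exc:
                fit.notes.append(f"Ljung-Box unavailable: {exc}")
        return fit


def fit_ar1_dummy(y, months, break_month=(2020, 3), lb_lags: Optional[int] = None) -> Ar1FitResult:
    """Functional wrapper around :class:`Ar1DummyModel`."""
    return Ar1DummyModel(y, months, break_month).fit(lb_lags=lb_lags)


def ljung_box(residuals, lags: int) -> tuple:
    """Ljung-Box portmanteau test: Q = n(n+2) sum_k r_k^2/(n-k), chi2(L).

    Returns ``(Q, p_value)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if lags >= n:
        raise ValueError("lags must be smaller than the series length")
    if np.ptp(residuals) == 0:
        raise ValueError("autocorrelation undefined for constant residuals")

    from statsmodels.stats.diagnostic import acorr_ljungbox

    tab = acorr_ljungbox(residuals, lags=[lags], return_df=True)
    return float(tab["lb_stat"].iloc[0]), float(tab["lb_pvalue"].iloc[0])


def simulate_ar1_dummy(
    n_months: int,
    break_index: int,
    alpha: float,
    rho: float,
    beta: float,
    sigma: float,
    rng: np.random.Generator,
    burn_in: int = 50,
) -> np.ndarray:
    """Simulate y_t = alpha + rho*y_{t-1} + beta*D_t + sigma*eps_t.

    The pre-break process is burned in so y_1 starts near its stationary
    distribution; D_t switches on at ``break_index`` (0-based).
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be inside (-1, 1) for a stationary burn-in")
    y = alpha / (1 - rho)
    for _ in range(burn_in):
        y = alpha + rho * y + sigma * rng.standard_normal()
    out = np.empty(n_months)
    for t in range(n_months):
        d = 1.0 if t >= break_index else 0.0
        y = alpha + rho * y + beta * d + sigma * rng.standard_normal()
        out[t] = y
    return out


def trend_report(fits: dict, alpha: float = 0.01) -> pd.DataFrame:
    """Tabulate per-family dummy tests and diagnostics.

    Flags families whose dummy p-value is below ``alpha`` (0.01 by default);
    the sign of t gives the direction of the prevalence change.
    """
    rows = []
    for family, fit in fits.items():
        rows.append(
            {
                "family": family,
                "dummy_coef": fit.params["dummy"],
                "t": fit.dummy_t,
                "p": fit.dummy_p,
                "direction": "increase" if fit.dummy_t > 0 else "decrease",
                "significant": bool(fit.dummy_p < alpha),
                "ljung_box_stat": fit.ljung_box_stat,
                "ljung_box_p": fit.ljung_box_p,
                "n_used": fit.n_used,
            }
        )
    return pd.DataFrame(rows)
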
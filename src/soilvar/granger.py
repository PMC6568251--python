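"""Bivariate Granger causality F-tests.

``y`` Granger-causes ``x`` when past values of ``y`` significantly improve
the prediction of ``x`` beyond x's own history.  The test compares

    unrestricted:  x_t = c + Σ a_i x_{t-i} + Σ b_i y_{t-i} + u_t   → RSS_0
    restricted:    x_t = c + Σ a_i x_{t-i}               + e_t   → RSS_1

through

    F = ((RSS_1 − RSS_0) / p) / (RSS_0 / (T − 2p − 1)) ~ F(p, T − 2p − 1)

where T is the regression sample size.  Rejection means the y-lag block is
jointly informative — temporal, not mechanistic, causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .process import VARError
from .series import DeseasonalizedSeries, align_pair

__all__ = ["GrangerResult", "granger_causality", "granger_table"]

LEVELS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class GrangerResult:
    """Outcome of one directional Granger test (predictor → predictand)."""

    predictand: str
    predictor: str
    p: int
    T: int
    rss_unrestricted: float
    rss_restricted: float
    f_stat: float
    p_value: float
    critical_values: dict[float, float]
    decisions: dict[float, str]

    def causes(self, level: float = 0.05) -> bool:
        return self.decisions[level] == "causes"

    def to_rows(self) -> list[dict]:
        """Decision-table rows: one per significance level."""
        return [
            {
                "direction": f"{self.predictor} -> {self.predictand}",
                "significance": lv,
                "f_stat": round(self.f_stat, 4),
                "critical_value": round(self.critical_values[lv], 4),
                "conclusion": "Yes" if self.causes(lv) else "No",
            }
            for lv in LEVELS
        ]


def _arr(v) -> np.ndarray:
    return v.values if isinstance(v, DeseasonalizedSeries) else np.asarray(v, float)


def granger_causality(
    x, y, p: int, *, intercept: bool = True, labels: tuple[str, str] | None = None
) -> GrangerResult:
    """Test whether ``y`` Granger-causes ``x`` at lag order ``p``.

    Parameters
    ----------
    x, y : DeseasonalizedSeries or array-like
        Aligned series of equal length; ``x`` is the predictand.
    p : int
        Number of lags of each variable in the unrestricted regression.
    """
    if labels is None:
        labels = (
            getattr(x, "label", "x"),
            getattr(y, "label", "y"),
        )
    if isinstance(x, DeseasonalizedSeries) and isinstance(y, DeseasonalizedSeries):
        x, y = align_pair(x, y)
    xv, yv = _arr(x), _arr(y)
    if xv.size != yv.size:
        raise VARError("order", "x and y must have equal length (align first)")
    if p < 1:
        raise VARError("order", f"lag order must be >= 1, got {p}")
    N = xv.size
    T = N - p  # regression rows: all lags available
    df_denom = T - 2 * p - 1
    if df_denom <= 0:
        raise VARError("insufficient-data", f"T - 2p - 1 = {df_denom} <= 0")

    target = xv[p:]
    xlags = np.column_stack([xv[p - i : N - i] for i in range(1, p + 1)])
    ylags = np.column_stack([yv[p - i : N - i] for i in range(1, p + 1)])
    const = [np.ones((T, 1))] if intercept else []
    X_u = np.hstack(const + [xlags, ylags])
    X_r = np.hstack(const + [xlags])

    def rss(X):
        if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
            raise VARError("collinear", "Granger design matrix is rank deficient")
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        e = target - X @ beta
        return float(e @ e)

    rss0 = rss(X_u)
    rss1 = rss(X_r)
    f_stat = ((rss1 - rss0) / p) / (rss0 / df_denom)
    cvs = {lv: float(stats.f.isf(lv, p, df_denom)) for lv in LEVELS}
    return GrangerResult(
        predictand=labels[0],
        predictor=labels[1],
        p=p,
        T=T,
        rss_unrestricted=rss0,
        rss_restricted=rss1,
        f_stat=float(f_stat),
        p_value=float(stats.f.sf(f_stat, p, df_denom)),
        critical_values=cvs,
        decisions={
            lv: ("causes" if f_stat > cv else "does-not-cause") for lv, cv in cvs.items()
        },
    )


def granger_table(
    a, b, p_forward: int, p_reverse: int | None = None, *, intercept: bool = True
) -> tuple[GrangerResult, GrangerResult, pd.DataFrame]:
    """Run both causal directions and format the decision table.

    ``forward`` tests b → a (does ``b`` help predict ``a``); ``reverse``
    tests a → b.  Per-direction lag orders may differ, since whitening one
    equation can need a different history length than the other.
    """
    p_reverse = p_forward if p_reverse is None else p_reverse
    fwd = granger_causality(a, b, p_forward, intercept=intercept)
    rev = granger_causality(b, a, p_reverse, intercept=intercept)
    table = pd.DataFrame(fwd.to_rows() + rev.to_rows())
    return fwd, rev, table
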
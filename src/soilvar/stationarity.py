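"""Augmented Dickey-Fuller unit-root testing.

Deseasonalized soil series must be (weakly) stationary before a VAR is
fitted: constant mean and variance, and autocovariance depending only on
the lag.  The ADF test checks the unit-root null against a stationary
alternative with the regression

    Δy_t = ρ·y_{t-1} + β_1 Δy_{t-1} + ... + β_q Δy_{t-q} [+ c [+ δ·t]] + ε_t

in three variants:

* ``AR``  — no deterministic terms (appropriate for near-zero-mean
  differenced series; the pipeline default),
* ``ARD`` — with a constant (drift),
* ``TS``  — with constant and linear trend.

The test statistic is the t-ratio of ρ̂.  Its null distribution is
non-standard; 1/5/10% critical values come from the MacKinnon (1996, 2010)
response surfaces, and continuous p-values are interpolated from a frozen
quantile table of the null distribution generated by this module's own
seeded Monte Carlo (see :mod:`soilvar._dfquant`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._dfquant import DF_QUANT_PROBS, DF_QUANTILES
from .series import DeseasonalizedSeries

__all__ = [
    "ADFResult",
    "ADFRegression",
    "adf_regression",
    "adf_critical_values",
    "select_adf_lags",
    "adf_test",
    "ljung_box",
    "simulate_df_distribution",
]

log = logging.getLogger(__name__)

VARIANTS = ("AR", "ARD", "TS")
LEVELS = (0.01, 0.05, 0.10)

# MacKinnon response-surface coefficients for the tau statistic (one
# variable): cv(level, n) = b0 + b1/n + b2/n^2 + b3/n^3.  AR = no
# deterministic terms, ARD = constant, TS = constant + trend.
_SURFACE = {
    "AR": {
        0.01: (-2.56574, -2.2358, -3.627, 0.0),
        0.05: (-1.94100, -0.2686, -3.365, 31.223),
        0.10: (-1.61682, 0.2656, -2.714, 25.364),
    },
    "ARD": {
        0.01: (-3.43035, -6.5393, -16.786, -79.433),
        0.05: (-2.86154, -2.8903, -4.234, -40.040),
        0.10: (-2.56677, -1.5384, -2.809, 0.0),
    },
    "TS": {
        0.01: (-3.95877, -9.0531, -28.428, -134.155),
        0.05: (-3.41049, -4.3904, -9.036, -45.374),
        0.10: (-3.12705, -2.5856, -3.925, -22.380),
    },
}


class StationarityError(ValueError):
    """Raised for unusable ADF inputs (``collinear``, ``insufficient-data``,
    ``level``, ``variant``)."""

    def __init__(self, kind: str, message: str):
        self.kind = kind
        super().__init__(f"{kind}: {message}")


def _check_variant(variant: str) -> str:
    if variant not in VARIANTS:
        raise StationarityError("variant", f"unknown ADF variant {variant!r}")
    return variant


def _values(y) -> np.ndarray:
    if isinstance(y, DeseasonalizedSeries):
        return y.values
    return np.asarray(y, dtype=float)


@dataclass(frozen=True)
class ADFRegression:
    """OLS diagnostics of one ADF regression."""

    variant: str
    aug_lags: int
    t_stat: float
    rho: float
    rho_se: float
    resid: np.ndarray = field(repr=False)
    nobs: int
    nparams: int

    @property
    def rss(self) -> float:
        return float(self.resid @ self.resid)

    @property
    def bic(self) -> float:
        n = self.nobs
        sigma2 = self.rss / n
        return n * np.log(sigma2) + self.nparams * np.log(n)


def adf_regression(y, variant: str = "AR", aug_lags: int = 0) -> ADFRegression:
    """Fit the ADF regression and return the t-ratio of the unit-root term.

    Parameters
    ----------
    y : DeseasonalizedSeries or array-like
    variant : {"AR", "ARD", "TS"}
    aug_lags : int
        Number q of lagged-difference terms added to whiten the residual.
    """
    _check_variant(variant)
    y = _values(y)
    q = int(aug_lags)
    if q < 0:
        raise StationarityError("insufficient-data", "aug_lags must be >= 0")
    dy = np.diff(y)
    n = dy.size - q  # usable observations
    k = 1 + q + {"AR": 0, "ARD": 1, "TS": 2}[variant]
    if n <= k + 1:
        raise StationarityError(
            "insufficient-data", f"{y.size} observations cannot support q={q} ({variant})"
        )
    target = dy[q:]
    cols = [y[q:-1]]
    cols += [dy[q - i : -i] for i in range(1, q + 1)]
    if variant in ("ARD", "TS"):
        cols.append(np.ones(n))
    if variant == "TS":
        cols.append(np.arange(1.0, n + 1))
    X = np.column_stack(cols)

    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise StationarityError("collinear", "ADF design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ beta
    sigma2 = resid @ resid / (n - X.shape[1])
    cov = sigma2 * np.linalg.inv(xtx)
    return ADFRegression(
        variant=variant,
        aug_lags=q,
        t_stat=float(beta[0] / np.sqrt(cov[0, 0])),
        rho=float(beta[0]),
        rho_se=float(np.sqrt(cov[0, 0])),
        resid=resid,
        nobs=n,
        nparams=X.shape[1],
    )


def adf_critical_values(
    variant: str,
    n: int,
    level: float | None = None,
    *,
    method: str = "surface",
    nrep: int = 100_000,
    seed: int = 186_553_121,
):
    """Dickey-Fuller critical value(s) for a given variant and sample size.

    ``method="surface"`` evaluates the MacKinnon response surface
    (default); ``method="montecarlo"`` simulates ``nrep`` driftless random
    walks of length ``n`` with a fixed documented seed and takes empirical
    quantiles — slower, but independent of the published coefficients.

    With ``level=None`` a dict over the three standard levels is returned.
    """
    _check_variant(variant)
    if n < 25:
        raise StationarityError("insufficient-data", f"n={n} too small for tabulated values")
    if level is None:
        return {
            lv: adf_critical_values(variant, n, lv, method=method, nrep=nrep, seed=seed)
            for lv in LEVELS
        }
    if level not in LEVELS:
        raise StationarityError("level", f"level must be one of {LEVELS}, got {level}")
    if method == "surface":
        b0, b1, b2, b3 = _SURFACE[variant][level]
        return float(b0 + b1 / n + b2 / n**2 + b3 / n**3)
    if method == "montecarlo":
        t = simulate_df_distribution(variant, T=n, nrep=nrep, seed=seed)
        return float(np.quantile(t, level))
    raise StationarityError("level", f"unknown method {method!r}")


def simulate_df_distribution(
    variant: str, T: int, nrep: int, seed: int, chunk: int = 20_000
) -> np.ndarray:
    """Simulate the null distribution of the DF t-statistic (q = 0).

    Draws ``nrep`` driftless Gaussian random walks of length ``T`` and
    computes the t-ratio of the unit-root coefficient under ``variant``.
    Vectorized over replicates; memory bounded by ``chunk``.
    """
    _check_variant(variant)
    rng = np.random.default_rng(seed)
    out = np.empty(nrep)
    done = 0
    while done < nrep:
        b = min(chunk, nrep - done)
        walks = np.cumsum(rng.standard_normal((b, T)), axis=1)
        ylag = walks[:, :-1]
        dy = np.diff(walks, axis=1)
        n = T - 1
        if variant == "AR":
            Xs = [ylag]
        elif variant == "ARD":
            Xs = [ylag, np.ones((b, n))]
        else:
            Xs = [ylag, np.ones((b, n)), np.broadcast_to(np.arange(1.0, n + 1), (b, n))]
        k = len(Xs)
        X = np.stack(Xs, axis=2)  # (b, n, k)
        xtx = np.einsum("bnk,bnl->bkl", X, X)
        xty = np.einsum("bnk,bn->bk", X, dy)
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
        resid = dy - np.einsum("bnk,bk->bn", X, beta)
        sigma2 = np.einsum("bn,bn->b", resid, resid) / (n - k)
        var_rho = sigma2 * np.linalg.inv(xtx)[:, 0, 0]
        out[done : done + b] = beta[:, 0] / np.sqrt(var_rho)
        done += b
    return out


def adf_pvalue(t_stat: float, variant: str) -> float:
    """Left-tail p-value by interpolation of the frozen null-quantile grid.

    Values beyond the tabulated tails are clipped to the outermost grid
    probabilities; report p-values below 0.001 as "< 0.001".
    """
    _check_variant(variant)
    qs = DF_QUANTILES[variant]
    return float(np.interp(t_stat, qs, DF_QUANT_PROBS))


def ljung_box(resid: np.ndarray, lags: int = 24, fitted_params: int = 0):
    """Ljung-Box portmanteau statistic for residual whiteness.

    Q = n(n+2) Σ_{k=1..L} r_k² / (n−k), compared to χ² with
    ``lags − fitted_params`` degrees of freedom.
    """
    e = np.asarray(resid, dtype=float)
    e = e - e.mean()
    n = e.size
    denom = e @ e
    acf = np.array([(e[k:] @ e[:-k]) / denom for k in range(1, lags + 1)])
    Q = n * (n + 2) * np.sum(acf**2 / (n - np.arange(1, lags + 1)))
    df = max(lags - fitted_params, 1)
    return float(Q), float(stats.chi2.sf(Q, df))


def select_adf_lags(
    y, variant: str = "AR", q_max: int = 12, *, whiteness_lags: int = 24, alpha: float = 0.05
) -> int:
    """Choose the augmentation order q.

    Returns the smallest q ≤ ``q_max`` whose ADF-regression residuals pass
    a Ljung-Box whiteness test at ``whiteness_lags`` lags (p > alpha).  If
    none passes, returns the BIC-minimizing q with a warning.
    """
    if q_max < 0:
        raise StationarityError("insufficient-data", "q_max must be >= 0")
    yv = _values(y)
    bics = []
    for q in range(q_max + 1):
        reg = adf_regression(yv, variant, q)
        _, p = ljung_box(reg.resid, lags=whiteness_lags, fitted_params=q)
        if p > alpha:
            return q
        # BIC fallback candidates refit on a common sample (drop the
        # first q_max - q values) so they are comparable across q
        bics.append(adf_regression(yv[q_max - q :], variant, q).bic)
    q_bic = int(np.argmin(bics))
    warnings.warn(
        f"no q <= {q_max} whitens the ADF residuals at {whiteness_lags} lags; "
        f"returning BIC-minimizing q = {q_bic}",
        stacklevel=2,
    )
    return q_bic


@dataclass(frozen=True)
class ADFResult:
    """Outcome of an augmented Dickey-Fuller test.

    ``decision[level]`` is ``"stationary"`` when the t-statistic falls
    below the critical value at that level (unit-root null rejected).
    """

    label: str
    variant: str
    aug_lags: int
    t_stat: float
    p_value: float
    critical_values: dict[float, float]
    n_used: int
    decision: dict[float, str]

    #: Printed floor for interpolated p-values.
    P_FLOOR = 0.001

    def stationary(self, level: float = 0.05) -> bool:
        return self.decision[level] == "stationary"

    @property
    def p_value_text(self) -> str:
        return f"< {self.P_FLOOR}" if self.p_value < self.P_FLOOR else f"{self.p_value:.3f}"

    def summary_row(self) -> dict:
        """Row in the shape of a unit-root report table."""
        cv = self.critical_values
        return {
            "label": self.label,
            "t_stat": round(self.t_stat, 3),
            "model": f"{self.variant}({self.aug_lags})",
            "p_value": self.p_value_text,
            "cv_1pct": round(cv[0.01], 3),
            "cv_5pct": round(cv[0.05], 3),
            "cv_10pct": round(cv[0.10], 3),
            "conclusion": (
                "stationary" if self.stationary(0.05) else "non-stationary"
            ),
        }


def adf_test(y, variant: str = "AR", q_max: int = 12, *, aug_lags: int | None = None) -> ADFResult:
    """Run the full ADF test: lag choice, regression, critical values, p-value.

    Parameters
    ----------
    y : DeseasonalizedSeries or array-like
    variant : {"AR", "ARD", "TS"}
    q_max : int
        Upper bound for the automatic augmentation-lag search.
    aug_lags : int, optional
        Fix q explicitly instead of searching.
    """
    q = select_adf_lags(y, variant, q_max) if aug_lags is None else int(aug_lags)
    reg = adf_regression(y, variant, q)
    cvs = adf_critical_values(variant, reg.nobs)
    decision = {
        lv: ("stationary" if reg.t_stat < cv else "non-stationary") for lv, cv in cvs.items()
    }
    label = getattr(y, "label", "series")
    return ADFResult(
        label=label,
        variant=variant,
        aug_lags=q,
        t_stat=reg.t_stat,
        p_value=adf_pvalue(reg.t_stat, variant),
        critical_values=cvs,
        n_used=reg.nobs,
        decision=decision,
    )
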
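"""Bivariate VAR estimation with information-criterion lag selection.

The model object is built from data (a pair of aligned deseasonalized
series, a DataFrame, or a plain (T, m) array); ``fit(p)`` returns a
:class:`VARResults` carrying the Gaussian maximum-likelihood estimates,
which for the conditional likelihood coincide with equation-wise least
squares on the common regressor set.  The residual covariance uses the ML
divisor n and the log-likelihood is

    ln L̂ = −(n/2)·(m·ln 2π + ln det Σ̂ + m).

Lag order is chosen by fitting p = 1..p_max on a common trimmed sample and
comparing AIC = 2k − 2 ln L̂ and BIC = ln(n)·k − 2 ln L̂ with
k = m(m·p + 1) free mean parameters (intercept plus lag coefficients;
covariance parameters excluded).  When the two criteria disagree the
smaller of the two minimizers is taken (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process import StabilityReport, VARError, VARProcess
from .series import DeseasonalizedSeries, align_pair

__all__ = [
    "VAR",
    "VARResults",
    "LagSelectionTable",
    "information_criteria",
    "select_lag_order",
    "fit_var",
]


def information_criteria(loglik: float, p: int, m: int, n: int, *, intercept: bool = True):
    """AIC and BIC from a log-likelihood.

    k counts the mean parameters: m·(m·p + 1) with an intercept, m²·p
    without.
    """
    if n <= 1:
        raise VARError("order", "n must exceed 1")
    k = m * (m * p + (1 if intercept else 0))
    return 2 * k - 2 * loglik, float(np.log(n)) * k - 2 * loglik


def select_lag_order(rows) -> int:
    """Pick the lag order from (p, loglik, aic, bic) rows.

    Returns the common minimizer when AIC and BIC agree, otherwise the
    smaller of the two minimizers — the more parsimonious model has fewer
    parameters to estimate and hence smaller estimation error.
    """
    rows = list(rows)
    if not rows:
        raise VARError("order", "empty lag-selection table")
    ps = [r[0] for r in rows]
    p_aic = ps[int(np.argmin([r[2] for r in rows]))]
    p_bic = ps[int(np.argmin([r[3] for r in rows]))]
    return p_aic if p_aic == p_bic else min(p_aic, p_bic)


@dataclass(frozen=True)
class LagSelectionTable:
    """Per-order fit summary used to choose p."""

    rows: list  # (p, loglik, aic, bic)
    chosen_p: int
    rule: str
    n: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["p", "loglik", "AIC", "BIC"])
        df["chosen"] = df["p"] == self.chosen_p
        return df


def _as_endog(data, labels=None):
    """Coerce supported inputs to a (T, m) array plus labels."""
    if isinstance(data, (tuple, list)) and len(data) == 2 and isinstance(
        data[0], DeseasonalizedSeries
    ):
        a, b = align_pair(*data)
        return np.column_stack([a.values, b.values]), (a.label, b.label)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(map(str, data.columns))
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise VARError("order", f"endog must be (T, m), got shape {arr.shape}")
    if labels is None:
        labels = tuple(f"y{i + 1}" for i in range(arr.shape[1]))
    return arr, tuple(labels)


class VAR:
    """Vector-autoregression model for an aligned multivariate series.

    Parameters
    ----------
    endog : array-like, DataFrame, or (DeseasonalizedSeries, DeseasonalizedSeries)
        Observations in rows, variables in columns.  A pair of
        deseasonalized series is aligned on its common time range.
    labels : sequence of str, optional

    Examples
    --------
    >>> model = VAR.from_pair(moisture_sd, temperature_sd)   # doctest: +SKIP
    >>> res = model.fit(5)                                    # doctest: +SKIP
    >>> res.stability().stable                                # doctest: +SKIP
    True
    """

    def __init__(self, endog, labels=None):
        self.endog, self.labels = _as_endog(endog, labels)
        self.nobs_total, self.m = self.endog.shape

    @classmethod
    def from_pair(cls, a: DeseasonalizedSeries, b: DeseasonalizedSeries) -> "VAR":
        return cls((a, b))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None) -> "VAR":
        if columns is not None:
            df = df[list(columns)]
        return cls(df)

    # -- estimation ----------------------------------------------------

    def _design(self, p: int, intercept: bool, trim: int):
        """Stack targets Y and regressors Z = [1, y_{t-1}, ..., y_{t-p}]."""
        y = self.endog
        T = self.nobs_total
        if p < 1:
            raise VARError("order", f"lag order must be >= 1, got {p}")
        if trim < p:
            raise VARError("order", "trim must be >= p")
        rows = T - trim
        if rows <= self.m * p + 1:
            raise VARError("order", f"sample of {T} cannot support p={p}")
        Y = y[trim:]
        blocks = ([np.ones((rows, 1))] if intercept else []) + [
            y[trim - s : T - s] for s in range(1, p + 1)
        ]
        return Y, np.hstack(blocks)

    def fit(self, p: int, intercept: bool = True, *, trim: int | None = None) -> "VARResults":
        """Estimate a VAR(p) by conditional Gaussian maximum likelihood.

        ``trim`` reserves that many leading observations as presample
        (defaults to p); lag selection passes trim = p_max so that models
        of different order share the same fitting sample.
        """
        trim = p if trim is None else int(trim)
        Y, Z = self._design(p, intercept, trim)
        n = Y.shape[0]
        ztz = Z.T @ Z
        if np.linalg.matrix_rank(ztz) < Z.shape[1]:
            raise VARError("collinear", "singular regressor cross-product")
        B = np.linalg.solve(ztz, Z.T @ Y)  # (1 + m p, m) columns = equations
        resid = Y - Z @ B
        sigma = resid.T @ resid / n
        return VARResults(
            model=self,
            p=p,
            has_intercept=intercept,
            params=B,
            sigma_u=sigma,
            resid=resid,
            nobs=n,
            trim=trim,
        )

    def select_order(self, p_max: int = 8, intercept: bool = True) -> LagSelectionTable:
        """Fit p = 1..p_max on a common sample and tabulate AIC/BIC.

        All candidate orders reserve the first ``p_max`` observations so
        their likelihoods are computed on identical data and the criteria
        are directly comparable.
        """
        if p_max < 1:
            raise VARError("order", "p_max must be >= 1")
        rows = []
        for p in range(1, p_max + 1):
            res = self.fit(p, intercept, trim=p_max)
            aic, bic = information_criteria(
                res.llf, p, self.m, res.nobs, intercept=intercept
            )
            rows.append((p, res.llf, aic, bic))
        chosen = select_lag_order(rows)
        p_aic = rows[int(np.argmin([r[2] for r in rows]))][0]
        p_bic = rows[int(np.argmin([r[3] for r in rows]))][0]
        rule = (
            f"AIC and BIC agree at p={chosen}"
            if p_aic == p_bic
            else f"AIC min at p={p_aic}, BIC min at p={p_bic}; parsimony picks p={chosen}"
        )
        return LagSelectionTable(rows=rows, chosen_p=chosen, rule=rule, n=self.nobs_total - p_max)


def fit_var(pair, p: int, intercept: bool = True) -> "VARResults":
    """Functional wrapper: ``VAR(pair).fit(p, intercept)``."""
    return VAR(pair).fit(p, intercept)


@dataclass(frozen=True)
class VARResults:
    """Fitted VAR(p): estimates, likelihood, diagnostics and downstream tools."""

    model: VAR = field(repr=False)
    p: int
    has_intercept: bool
    params: np.ndarray = field(repr=False)  # (1 + m p, m); columns = equations
    sigma_u: np.ndarray = field(repr=False)  # ML convention (divide by n)
    resid: np.ndarray = field(repr=False)
    nobs: int
    trim: int

    # -- parameter views -----------------------------------------------

    @property
    def m(self) -> int:
        return self.model.m

    @property
    def labels(self):
        return self.model.labels

    @property
    def intercept(self) -> np.ndarray:
        if not self.has_intercept:
            return np.zeros(self.m)
        return self.params[0]

    @property
    def coefs(self) -> np.ndarray:
        """Lag matrices Φ_1..Φ_p, shape (p, m, m); rows = equations."""
        off = 1 if self.has_intercept else 0
        m = self.m
        return np.stack(
            [self.params[off + s * m : off + (s + 1) * m].T for s in range(self.p)]
        )

    @property
    def process(self) -> VARProcess:
        """The estimated process (for simulation, MA form, stability)."""
        return VARProcess(
            coefs=self.coefs,
            intercept=self.intercept,
            sigma=self.sigma_u,
            labels=self.labels,
        )

    # -- likelihood and criteria ----------------------------------------

    @property
    def llf(self) -> float:
        """Gaussian log-likelihood −(n/2)(m ln 2π + ln det Σ̂ + m)."""
        sign, logdet = np.linalg.slogdet(self.sigma_u)
        if sign <= 0:
            raise VARError("degenerate", "residual covariance is singular")
        m = self.m
        return float(-(self.nobs / 2) * (m * np.log(2 * np.pi) + logdet + m))

    @property
    def aic(self) -> float:
        return information_criteria(self.llf, self.p, self.m, self.nobs,
                                    intercept=self.has_intercept)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.llf, self.p, self.m, self.nobs,
                                    intercept=self.has_intercept)[1]

    # -- structure ------------------------------------------------------

    def companion_matrix(self) -> np.ndarray:
        return self.process.companion_matrix()

    def stability(self) -> StabilityReport:
        return self.process.stability()

    def fittedvalues(self) -> np.ndarray:
        Y, Z = self.model._design(self.p, self.has_intercept, self.trim)
        return Z @ self.params

    def predict_one_step(self, state: np.ndarray) -> np.ndarray:
        """One-step forecast from the last p observations (rows: newest last)."""
        state = np.asarray(state, float).reshape(self.p, self.m)
        acc = self.intercept.copy()
        for s in range(1, self.p + 1):
            acc = acc + self.coefs[s - 1] @ state[-s]
        return acc

    # -- downstream analyses ---------------------------------------------

    def irf(self, horizon: int = 120, scheme: str = "generalized"):
        """Unit-shock impulse responses of the fitted system."""
        from .irf import ImpulseResponse

        return ImpulseResponse.from_results(self, horizon=horizon, scheme=scheme)

    def granger(self, caused: int | str = 0, p: int | None = None):
        """F-test that the *other* variable Granger-causes ``caused``."""
        from .granger import granger_causality

        idx = self.labels.index(caused) if isinstance(caused, str) else int(caused)
        other = 1 - idx
        y = self.model.endog
        return granger_causality(
            y[:, idx], y[:, other], self.p if p is None else p,
            labels=(self.labels[idx], self.labels[other]),
        )

    # -- reporting --------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable model dump."""
        return {
            "labels": list(self.labels),
            "p": self.p,
            "intercept": self.intercept.tolist(),
            "coeffs": self.coefs.tolist(),
            "sigma": self.sigma_u.tolist(),
            "loglik": self.llf,
            "n": self.nobs,
        }

    def summary(self) -> str:
        lab = self.labels
        stab = self.stability()
        lines = [
            f"VAR({self.p}) results — variables: {', '.join(lab)}",
            f"  observations: {self.nobs}   log-likelihood: {self.llf:.1f}",
            f"  AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"  max companion-root modulus: {stab.max_modulus:.4f} "
            f"({'stable' if stab.stable else 'UNSTABLE'})",
            f"  intercept: {np.array2string(self.intercept, precision=4)}",
        ]
        for s in range(self.p):
            lines.append(f"  Phi_{s + 1}:")
            for row in self.coefs[s]:
                lines.append("    " + np.array2string(row, precision=4))
        lines.append("  residual covariance (ML):")
        for row in self.sigma_u:
            lines.append("    " + np.array2string(row, precision=6))
        return "\n".join(lines)
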
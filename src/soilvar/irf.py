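"""Impulse-response analysis of a fitted (or known) VAR.

For a stable VAR the moving-average form y_t = μ + Σ_i Ψ_i ε_{t-i}
propagates a one-off innovation through the system.  Three unit-shock
conventions are supported:

* ``reduced``     — shock one reduced-form error by one unit:
                    φ(i) = Ψ_i (cross-responses are zero at horizon 0);
* ``cholesky``    — shock one orthogonalized error, scaled so the own
                    contemporaneous response is one unit:
                    φ(i) = Ψ_i P diag(P)⁻¹ with P the lower Cholesky
                    factor of Σ (order-dependent);
* ``generalized`` — order-invariant unit shock through the innovation
                    covariance: column k of φ(i) is Ψ_i Σ e_k / σ_kk.

Two scalar summaries quantify the coupling seen in a response curve
φ_jk(·): the **intensity** is the gap between the largest positive and the
largest negative response (each clamped at zero), and the **time lag** is
the first horizon after which the curve stays within a small fraction
(default 5%) of that intensity — the point where the response
"approximates zero" for good.

Confidence bands come from a nonparametric residual-resampling bootstrap:
refit on rebuilt series, recompute the IRF, take percentile intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process import VARError, VARProcess

__all__ = ["ImpulseResponse", "BootstrapBands", "ma_coefficients", "unit_shock_irf"]

log = logging.getLogger(__name__)

SCHEMES = ("reduced", "cholesky", "generalized")


def ma_coefficients(process_or_results, horizon: int) -> np.ndarray:
    """Ψ_0..Ψ_H of the moving-average representation."""
    proc = getattr(process_or_results, "process", process_or_results)
    return proc.ma_coefficients(horizon)


def _shock_transform(sigma: np.ndarray, scheme: str) -> np.ndarray:
    """Right-multiplier turning Ψ_i into unit-shock responses."""
    m = sigma.shape[0]
    if scheme == "reduced":
        return np.eye(m)
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise VARError("degenerate", f"sigma must be positive definite for {scheme} shocks")
    if scheme == "cholesky":
        P = np.linalg.cholesky(sigma)
        return P / np.diag(P)[None, :]
    if scheme == "generalized":
        return sigma / np.diag(sigma)[None, :]
    raise VARError("order", f"unknown scheme {scheme!r}; choose from {SCHEMES}")


@dataclass(frozen=True)
class BootstrapBands:
    level: float
    lower: np.ndarray  # (H+1, m, m)
    upper: np.ndarray
    replicates_used: int
    replicates_discarded: int


@dataclass(frozen=True)
class ImpulseResponse:
    """Unit-shock response curves φ_jk(i) with summary statistics.

    ``responses[i, j, k]`` is the response of variable ``j`` at horizon
    ``i`` to a one-unit positive shock in variable ``k``.
    """

    scheme: str
    horizon: int
    responses: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    bands: BootstrapBands | None = None

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_process(
        cls, process: VARProcess, horizon: int = 120, scheme: str = "generalized"
    ) -> "ImpulseResponse":
        if scheme not in SCHEMES:
            raise VARError("order", f"unknown scheme {scheme!r}; choose from {SCHEMES}")
        if not process.is_stable:
            warnings.warn("impulse responses of an unstable VAR do not decay", stacklevel=2)
        psi = process.ma_coefficients(horizon)
        W = _shock_transform(process.sigma, scheme)
        return cls(
            scheme=scheme,
            horizon=horizon,
            responses=psi @ W,
            labels=process.labels,
        )

    @classmethod
    def from_results(cls, results, horizon: int = 120, scheme: str = "generalized"):
        return cls.from_process(results.process, horizon=horizon, scheme=scheme)

    # -- summaries -------------------------------------------------------

    def _jk(self, j, k):
        j = self.labels.index(j) if isinstance(j, str) else int(j)
        k = self.labels.index(k) if isinstance(k, str) else int(k)
        return j, k

    def curve(self, j, k) -> np.ndarray:
        j, k = self._jk(j, k)
        return self.responses[:, j, k]

    def cumulative_response(self, j, k, n: int | None = None) -> float:
        """Partial sum Σ_{i=0..n} φ_jk(i) (accumulated impact of the shock)."""
        n = self.horizon if n is None else int(n)
        if n > self.horizon:
            raise VARError("order", f"n={n} exceeds horizon {self.horizon}")
        return float(self.curve(j, k)[: n + 1].sum())

    def intensity(self, j, k) -> float:
        """Gap between the largest positive and largest negative response.

        Extremes are clamped at zero, so a one-signed curve contributes
        only its peak magnitude.
        """
        c = self.curve(j, k)
        return float(max(0.0, c.max()) - min(0.0, c.min()))

    def time_lag(self, j, k, epsilon_frac: float = 0.05) -> int:
        """First horizon after which |φ_jk| stays ≤ epsilon_frac × intensity.

        Returns 0 for an identically zero curve and ``horizon + 1`` when
        the response has not settled by the end of the window (check
        :meth:`settled`).
        """
        c = np.abs(self.curve(j, k))
        intens = self.intensity(j, k)
        if intens == 0:
            return 0
        thr = epsilon_frac * intens
        above = np.flatnonzero(c > thr)
        if above.size == 0:
            return 0
        last = int(above[-1])
        return last + 1  # horizon+1 when the last point still exceeds thr

    def settled(self, j, k, epsilon_frac: float = 0.05) -> bool:
        """Whether the response returns to ≈0 within the horizon."""
        return self.time_lag(j, k, epsilon_frac) <= self.horizon

    # -- bootstrap bands ---------------------------------------------------

    def with_bands(self, bands: BootstrapBands) -> "ImpulseResponse":
        return ImpulseResponse(
            scheme=self.scheme, horizon=self.horizon,
            responses=self.responses, labels=self.labels, bands=bands,
        )

    # -- output ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per horizon, one column per (response, shock)."""
        m = len(self.labels)
        data = {"horizon": np.arange(self.horizon + 1)}
        for j in range(m):
            for k in range(m):
                if j == k:
                    continue
                data[f"{self.labels[j]}<-{self.labels[k]}"] = self.responses[:, j, k]
        for j in range(m):
            data[f"{self.labels[j]}<-{self.labels[j]}"] = self.responses[:, j, j]
        return pd.DataFrame(data)

    def plot(self, pairs=None, level_label: bool = True):
        """Point estimates (solid) with optional bootstrap bands (dashed)."""
        import matplotlib.pyplot as plt

        m = len(self.labels)
        if pairs is None:
            pairs = [(j, k) for j in range(m) for k in range(m) if j != k]
        fig, axes = plt.subplots(1, len(pairs), figsize=(4.5 * len(pairs), 3.2), squeeze=False)
        x = np.arange(self.horizon + 1)
        for ax, (j, k) in zip(axes[0], pairs):
            j, k = self._jk(j, k)
            ax.plot(x, self.responses[:, j, k], "-", lw=1.5)
            if self.bands is not None:
                ax.plot(x, self.bands.lower[:, j, k], "r--", lw=1)
                ax.plot(x, self.bands.upper[:, j, k], "r--", lw=1)
            ax.axhline(0, color="0.6", lw=0.6)
            title = f"{self.labels[j]} response to unit shock in {self.labels[k]}"
            if self.bands is not None and level_label:
                title += f" ({self.bands.level:.0%} band)"
            ax.set_title(title, fontsize=9)
            ax.set_xlabel("horizon (h)")
        fig.tight_layout()
        return fig


def unit_shock_irf(model, scheme: str = "generalized", horizon: int = 120) -> ImpulseResponse:
    """Functional wrapper accepting a VARResults or VARProcess."""
    proc = getattr(model, "process", model)
    return ImpulseResponse.from_process(proc, horizon=horizon, scheme=scheme)


def bootstrap_bands(
    results,
    scheme: str = "generalized",
    horizon: int = 120,
    level: float = 0.90,
    B: int = 1000,
    seed: int | None = None,
) -> ImpulseResponse:
    """Residual-resampling bootstrap confidence bands for the IRF.

    Fitted residuals are resampled with replacement, a series is rebuilt
    from the fitted coefficients, the VAR is refitted and the IRF
    recomputed; bands are percentile intervals per (variable, shock,
    horizon).  Deterministic given ``seed``.  Replicates whose refit is
    explosive are discarded and logged; more than 20% discards raises a
    "fragile" warning.
    """
    if B < 100:
        raise VARError("order", "use at least 100 bootstrap replicates")
    point = ImpulseResponse.from_results(results, horizon=horizon, scheme=scheme)
    rng = np.random.default_rng(seed)
    resid = results.resid - results.resid.mean(axis=0)
    n, m = resid.shape
    p = results.p
    proc = results.process
    presample = results.model.endog[results.trim - p : results.trim]

    from .model import VAR

    draws = np.empty((B, horizon + 1, m, m))
    used = discarded = 0
    while used < B:
        e_star = resid[rng.integers(0, n, size=n)]
        y = np.empty((p + n, m))
        y[:p] = presample
        for t in range(n):
            acc = proc.intercept + e_star[t]
            for s in range(1, p + 1):
                acc = acc + proc.coefs[s - 1] @ y[p + t - s]
            y[p + t] = acc
        try:
            refit = VAR(y, labels=results.labels).fit(p, results.has_intercept)
        except VARError:
            discarded += 1
        else:
            if not refit.stability().stable:
                discarded += 1
                log.debug("discarding unstable bootstrap refit")
            else:
                draws[used] = ImpulseResponse.from_results(
                    refit, horizon=horizon, scheme=scheme
                ).responses
                used += 1
        if discarded > 5 * B:
            raise VARError("degenerate", "bootstrap cannot produce stable refits")
    if discarded > 0.20 * (used + discarded):
        warnings.warn(
            f"fragile bootstrap: {discarded} of {used + discarded} refits unstable",
            stacklevel=2,
        )
    alpha = (1 - level) / 2
    bands = BootstrapBands(
        level=level,
        lower=np.quantile(draws, alpha, axis=0),
        upper=np.quantile(draws, 1 - alpha, axis=0),
        replicates_used=used,
        replicates_discarded=discarded,
    )
    return point.with_bands(bands)
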
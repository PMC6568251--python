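"""Known-coefficient VAR(p) processes.

A :class:`VARProcess` holds the lag-coefficient matrices Φ_1..Φ_p, an
intercept and an innovation covariance of a vector autoregression

    y_t = c + Φ_1 y_{t-1} + ... + Φ_p y_{t-p} + ε_t,   ε_t ~ N(0, Σ)

independently of any data.  It provides the companion form, the stability
check, the moving-average coefficients, exact simulation and the
stationary mean — used both by the synthetic-data generator (processes
with known truth) and by fitted results (which wrap a process built from
the estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VARProcess", "StabilityReport", "companion_matrix"]


class VARError(ValueError):
    """Raised for invalid VAR specifications (``order``, ``collinear``,
    ``degenerate``, ``unstable``)."""

    def __init__(self, kind: str, message: str):
        self.kind = kind
        super().__init__(f"{kind}: {message}")


def companion_matrix(coefs: np.ndarray) -> np.ndarray:
    """Stack Φ_1..Φ_p into the (m·p × m·p) companion matrix.

    Top block-row is [Φ_1 ... Φ_p]; identity blocks sit on the first block
    subdiagonal; everything else is zero.  For p = 1 this is Φ_1 itself.
    """
    coefs = np.asarray(coefs, dtype=float)
    p, m, _ = coefs.shape
    F = np.zeros((m * p, m * p))
    F[:m] = coefs.transpose(1, 0, 2).reshape(m, m * p)
    if p > 1:
        F[m:, : m * (p - 1)] = np.eye(m * (p - 1))
    return F


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue-modulus check of the companion matrix.

    The VAR is stable iff every eigenvalue of the companion matrix lies
    strictly inside the unit circle.
    """

    companion: np.ndarray = field(repr=False)
    moduli: np.ndarray
    stable: bool

    @property
    def max_modulus(self) -> float:
        return float(self.moduli[0])


@dataclass(frozen=True)
class VARProcess:
    """A bivariate (or m-variate) VAR(p) with known parameters."""

    coefs: np.ndarray  # (p, m, m); row = equation, column = lagged variable
    intercept: np.ndarray | None = None  # (m,)
    sigma: np.ndarray | None = None  # (m, m) innovation covariance
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        coefs = np.atleast_3d(np.asarray(self.coefs, dtype=float))
        if coefs.ndim != 3 or coefs.shape[1] != coefs.shape[2]:
            raise VARError("order", f"coefs must be (p, m, m), got {coefs.shape}")
        object.__setattr__(self, "coefs", coefs)
        m = coefs.shape[1]
        ic = np.zeros(m) if self.intercept is None else np.asarray(self.intercept, float)
        if ic.shape != (m,):
            raise VARError("order", f"intercept must have length {m}")
        object.__setattr__(self, "intercept", ic)
        sig = np.eye(m) if self.sigma is None else np.asarray(self.sigma, float)
        if sig.shape != (m, m) or not np.allclose(sig, sig.T):
            raise VARError("degenerate", "sigma must be symmetric (m, m)")
        if np.linalg.eigvalsh(sig).min() < -1e-10:
            raise VARError("degenerate", "sigma must be positive semi-definite")
        object.__setattr__(self, "sigma", sig)
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"y{i + 1}" for i in range(m)))

    @property
    def m(self) -> int:
        return self.coefs.shape[1]

    @property
    def p(self) -> int:
        return self.coefs.shape[0]

    def companion_matrix(self) -> np.ndarray:
        return companion_matrix(self.coefs)

    def stability(self) -> StabilityReport:
        F = self.companion_matrix()
        moduli = np.sort(np.abs(np.linalg.eigvals(F)))[::-1]
        return StabilityReport(companion=F, moduli=moduli, stable=bool(moduli[0] < 1))

    @property
    def is_stable(self) -> bool:
        return self.stability().stable

    def mean(self) -> np.ndarray:
        """Stationary mean μ = (I − ΣΦ_s)⁻¹ c (stable process only)."""
        A = np.eye(self.m) - self.coefs.sum(axis=0)
        return np.linalg.solve(A, self.intercept)

    def ma_coefficients(self, horizon: int) -> np.ndarray:
        """Moving-average matrices Ψ_0..Ψ_H of the stable representation.

        Ψ_0 = I and Ψ_i = Σ_{s=1..min(i,p)} Φ_s Ψ_{i−s}; for a VAR(1),
        Ψ_i = Φ_1^i.
        """
        m, p = self.m, self.p
        psi = np.zeros((horizon + 1, m, m))
        psi[0] = np.eye(m)
        for i in range(1, horizon + 1):
            for s in range(1, min(i, p) + 1):
                psi[i] += self.coefs[s - 1] @ psi[i - s]
        return psi

    def simulate(
        self,
        T: int,
        seed: int | np.random.Generator | None = None,
        burn_in: int = 200,
        *,
        initial: np.ndarray | None = None,
        allow_unstable: bool = False,
    ) -> np.ndarray:
        """Draw a length-``T`` sample path with Gaussian innovations.

        The first ``burn_in`` draws are discarded so the path starts near
        the stationary regime.  Deterministic given ``seed``.

        Raises
        ------
        VARError
            ``"unstable"`` unless ``allow_unstable`` for an explosive
            coefficient set.
        """
        if T < 1:
            raise VARError("order", "T must be >= 1")
        if burn_in < 0:
            raise VARError("order", "burn_in must be >= 0")
        if not self.is_stable and not allow_unstable:
            raise VARError("unstable", "coefficients are explosive; pass allow_unstable=True")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        m, p = self.m, self.p
        total = T + burn_in
        if np.allclose(self.sigma, 0):
            eps = np.zeros((total, m))
        else:
            chol = np.linalg.cholesky(self.sigma + 1e-300 * np.eye(m))
            eps = rng.standard_normal((total, m)) @ chol.T
        y = np.zeros((total + p, m))
        if initial is not None:
            y[:p] = np.asarray(initial, float).reshape(p, m)
        for t in range(total):
            acc = self.intercept + eps[t]
            for s in range(1, p + 1):
                acc = acc + self.coefs[s - 1] @ y[p + t - s]
            y[p + t] = acc
        return y[p + burn_in :]

    def stationary_acov(self, nlags: int = 0) -> np.ndarray:
        """Autocovariances Γ_0..Γ_nlags via the companion-form Lyapunov equation.

        Solves vec(Γ̃_0) = (I − F⊗F)⁻¹ vec(Σ̃) for the stacked state and
        reads off the blocks; the Yule-Walker oracle for simulation tests.
        """
        from scipy.linalg import solve_discrete_lyapunov

        F = self.companion_matrix()
        m, p = self.m, self.p
        Q = np.zeros((m * p, m * p))
        Q[:m, :m] = self.sigma
        G0 = solve_discrete_lyapunov(F, Q)
        out = np.empty((nlags + 1, m, m))
        out[0] = G0[:m, :m]
        cur = G0
        for k in range(1, nlags + 1):
            cur = F @ cur
            out[k] = cur[:m, :m]
        return out
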
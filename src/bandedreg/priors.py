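"""Prior specification: hyperpriors, smoothness structure, prior/noise states.

The weight prior is zero-mean Gaussian with block-diagonal covariance
``Lambda = blockdiag(lambda_1 Omega_1, ..., lambda_J Omega_J)``: one positive
scale ``lambda_j`` per predictor group and a fixed within-group correlation
``Omega_j`` (identity, or a Matérn-3/2 kernel for smooth weight profiles).
Inverse-Gamma hyperpriors sit on every ``lambda_j`` (shape eta, scale tau)
and on the residual variance ``nu`` (shape phi, scale kappa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._linalg import chol_factor, chol_inverse, chol_logdet, chol_solve
from .design import GroupedDesign
from .exceptions import DomainError
from .kernels import matern_covariance


@dataclass(frozen=True)
class Hyperpriors:
    """Inverse-Gamma hyperprior parameters for the shrinkage scales and noise.

    ``eta``/``tau`` are the shape/scale of the prior on every group scale
    ``lambda_j``; ``phi``/``kappa`` the shape/scale of the prior on the
    residual variance ``nu``.  The Inv-Gamma(a, b) density is
    ``b^a / Gamma(a) * x^{-(a+1)} exp(-b/x)`` with mode ``b/(a+1)``; small
    equal values make the hyperpriors broad, allowing excessive shrinkage of
    irrelevant groups while still putting mass on large scales.

    A single ``gamma`` sets all four parameters equal — the conventional
    one-knob simplification used throughout the simulations.
    """

    eta: float = 1e-4
    tau: float = 1e-4
    phi: float = 1e-4
    kappa: float = 1e-4
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.gamma is not None:
            g = float(self.gamma)
            object.__setattr__(self, "eta", g)
            object.__setattr__(self, "tau", g)
            object.__setattr__(self, "phi", g)
            object.__setattr__(self, "kappa", g)
        for name in ("eta", "tau", "phi", "kappa"):
            v = float(getattr(self, name))
            if not (v > 0) or not np.isfinite(v):
                raise DomainError(f"hyperprior {name} must be strictly positive, got {v}")
            object.__setattr__(self, name, v)

    @classmethod
    def broad(cls, gamma: float = 1e-4) -> "Hyperpriors":
        return cls(gamma=gamma)

    def log_density(self, lambdas: np.ndarray, nu: float) -> float:
        """Summed Inverse-Gamma log densities of all lambda_j and nu."""
        lp = float(
            np.sum(stats.invgamma.logpdf(lambdas, self.eta, scale=self.tau))
        )
        lp += float(stats.invgamma.logpdf(nu, self.phi, scale=self.kappa))
        return lp


@dataclass(frozen=True)
class SmoothnessSpec:
    """Per-group Matérn length scales; groups absent from ``h`` use identity.

    The length scales are fixed a priori — they are part of the model
    specification and never updated during fitting.
    """

    h: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = {str(k): float(v) for k, v in dict(self.h).items()}
        for name, val in h.items():
            if not (val > 0):
                raise DomainError(f"length scale for group {name!r} must be > 0, got {val}")
        object.__setattr__(self, "h", h)

    def omega(self, name: str, size: int) -> np.ndarray | None:
        """Omega_j for a group, or None meaning the identity."""
        if name in self.h:
            return matern_covariance(size, self.h[name])
        return None

    def omegas_for(self, design: GroupedDesign) -> list[np.ndarray | None]:
        unknown = set(self.h) - set(design.names)
        if unknown:
            raise DomainError(f"smoothness given for unknown groups: {sorted(unknown)}")
        return [
            self.omega(name, int(size))
            for name, size in zip(design.names, design.sizes)
        ]


class OmegaFactor:
    """Cached factorization of one fixed within-group correlation Omega_j.

    ``None``-based fast paths are used elsewhere when Omega_j is the
    identity; this class only ever holds a non-trivial matrix.
    """

    def __init__(self, omega: np.ndarray, context: str = "Omega"):
        omega = np.asarray(omega, dtype=float)
        self.omega = omega
        self.chol, self.jitter = chol_factor(omega, context=context)
        self.inv = chol_inverse(self.chol)
        self.logdet = chol_logdet(self.chol)

    def quad(self, v: np.ndarray) -> float | np.ndarray:
        """``v^T Omega^{-1} v`` (columnwise for 2-D v)."""
        sol = chol_solve(self.chol, v)
        return np.sum(v * sol, axis=0)

    def trace_inv_times(self, S: np.ndarray) -> float:
        """``Tr(Omega^{-1} S)``."""
        return float(np.trace(chol_solve(self.chol, S)))


@dataclass
class PriorState:
    """Group scales lambda_j plus the fixed Omega_j blocks (None = identity)."""

    lambdas: np.ndarray
    omegas: list[OmegaFactor | None]
    design: GroupedDesign

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float).copy()
        if self.lambdas.shape != (self.design.n_groups,):
            raise DomainError("one lambda per group is required")
        if np.any(self.lambdas <= 0):
            raise DomainError("all lambda_j must be strictly positive")
        if len(self.omegas) != self.design.n_groups:
            raise DomainError("one Omega per group is required")

    @classmethod
    def from_spec(
        cls,
        design: GroupedDesign,
        lambdas: np.ndarray | float,
        smooth: SmoothnessSpec | None = None,
        omegas: Sequence[np.ndarray | None] | None = None,
    ) -> "PriorState":
        if np.isscalar(lambdas):
            lambdas = np.full(design.n_groups, float(lambdas))
        if omegas is None:
            smooth = smooth or SmoothnessSpec()
            omegas = smooth.omegas_for(design)
        factors: list[OmegaFactor | None] = []
        for name, om in zip(design.names, omegas):
            factors.append(None if om is None else OmegaFactor(om, context=f"Omega[{name}]"))
        return cls(np.asarray(lambdas, dtype=float), factors, design)

    def with_lambdas(self, lambdas: np.ndarray) -> "PriorState":
        return PriorState(np.asarray(lambdas, dtype=float), self.omegas, self.design)

    @property
    def Lambda(self) -> np.ndarray:
        """The full D x D block-diagonal prior covariance."""
        D = self.design.n_predictors
        out = np.zeros((D, D))
        for j, (lam, om) in enumerate(zip(self.lambdas, self.omegas)):
            sl = self.design.group_slice(j)
            if om is None:
                idx = np.arange(sl.start, sl.stop)
                out[idx, idx] = lam
            else:
                out[sl, sl] = lam * om.omega
        return out

    @property
    def Lambda_inv(self) -> np.ndarray:
        """The full D x D block-diagonal prior precision."""
        D = self.design.n_predictors
        out = np.zeros((D, D))
        for j, (lam, om) in enumerate(zip(self.lambdas, self.omegas)):
            sl = self.design.group_slice(j)
            if om is None:
                idx = np.arange(sl.start, sl.stop)
                out[idx, idx] = 1.0 / lam
            else:
                out[sl, sl] = om.inv / lam
        return out

    @property
    def logdet_Lambda(self) -> float:
        """log|Lambda| = sum_j (D_j log lambda_j + log|Omega_j|)."""
        total = 0.0
        for lam, om, size in zip(self.lambdas, self.omegas, self.design.sizes):
            total += size * np.log(lam) + (0.0 if om is None else om.logdet)
        return float(total)


@dataclass(frozen=True)
class NoiseState:
    """Residual variance nu of the homoscedastic Gaussian noise."""

    nu: float

    def __post_init__(self) -> None:
        if not (self.nu > 0) or not np.isfinite(self.nu):
            raise DomainError(f"nu must be strictly positive, got {self.nu}")
        object.__setattr__(self, "nu", float(self.nu))
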
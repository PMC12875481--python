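"""Drift specifications, DDM parameter sets, and priors.

The drift rate on trial *t* is a linear combination of the scaled task
regressors, ``delta_t = sum_X beta(X) * X_t`` for a chosen subset X of
{SR, AI, DI, OR}, or a bare constant for the intercept-only specification.
Exactly nine drift specifications are admissible (the regressor subsets the
task design can distinguish, plus the constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecMismatchError
from .task import InequityFeatures

REGRESSOR_COLUMNS = {"sr": "sr", "ai": "ai", "di": "di", "or": "or_"}


@dataclass(frozen=True)
class DriftSpec:
    """A drift-rate specification: which regressors enter the drift."""

    regressors: tuple[str, ...] = ()
    constant_only: bool = False

    def __post_init__(self):
        if self.constant_only and self.regressors:
            raise SpecMismatchError("constant-only spec admits no regressors")
        unknown = [r for r in self.regressors if r not in REGRESSOR_COLUMNS]
        if unknown:
            raise SpecMismatchError(f"unknown regressor(s): {unknown}")
        if not self.constant_only and not self.regressors:
            raise SpecMismatchError("empty spec: pass constant_only=True for the intercept model")

    @property
    def name(self) -> str:
        return "constant" if self.constant_only else "+".join(self.regressors)

    @property
    def param_names(self) -> list[str]:
        base = ["alpha", "z", "tau"]
        if self.constant_only:
            return base + ["beta0"]
        return base + [f"beta_{r}" for r in self.regressors]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def design(self, features: pd.DataFrame) -> np.ndarray:
        """(T, K) design matrix of drift regressors (a ones column when
        constant-only)."""
        if self.constant_only:
            return np.ones((len(features), 1))
        cols = [REGRESSOR_COLUMNS[r] for r in self.regressors]
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise SpecMismatchError(f"feature column(s) missing: {missing}")
        return features[cols].to_numpy(float)

    @classmethod
    def from_name(cls, name: str) -> "DriftSpec":
        if name == "constant":
            return cls(constant_only=True)
        return cls(regressors=tuple(name.split("+")))


#: The nine admissible drift specifications, in a stable order.
DRIFT_SPECS: tuple[DriftSpec, ...] = (
    DriftSpec(("sr",)),
    DriftSpec(("ai",)),
    DriftSpec(("di",)),
    DriftSpec(("sr", "ai")),
    DriftSpec(("sr", "di")),
    DriftSpec(("ai", "di")),
    DriftSpec(("sr", "or")),
    DriftSpec(("sr", "ai", "di")),
    DriftSpec(constant_only=True),
)

BEST_SPEC = DriftSpec(("sr", "ai", "di"))


def enumerate_drift_specs() -> list[DriftSpec]:
    """The nine admissible drift specifications, stable order."""
    return list(DRIFT_SPECS)


@dataclass(frozen=True)
class DDMParams:
    """One parameter set: boundary, bias, nondecision time, drift weights.

    ``z`` is the relative starting point toward the upper (rejection)
    boundary; ``betas`` maps regressor name -> drift coefficient; ``beta0``
    is the constant drift of the intercept-only spec.
    """

    alpha: float
    z: float
    tau: float
    betas: dict[str, float] = field(default_factory=dict)
    beta0: float | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 < self.z < 1.0):
            raise ValueError("z must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    def vector(self, spec: DriftSpec) -> np.ndarray:
        """Parameter vector in ``spec.param_names`` order."""
        if spec.constant_only:
            if self.beta0 is None:
                raise SpecMismatchError("constant-only spec requires beta0")
            tail = [self.beta0]
        else:
            missing = [r for r in spec.regressors if r not in self.betas]
            if missing:
                raise SpecMismatchError(f"missing drift coefficient(s): {missing}")
            tail = [self.betas[r] for r in spec.regressors]
        return np.array([self.alpha, self.z, self.tau, *tail], dtype=float)

    @classmethod
    def from_vector(cls, spec: DriftSpec, vec: np.ndarray) -> "DDMParams":
        vec = np.asarray(vec, dtype=float)
        alpha, z, tau = vec[:3]
        if spec.constant_only:
            return cls(alpha=alpha, z=z, tau=tau, beta0=float(vec[3]))
        betas = {r: float(b) for r, b in zip(spec.regressors, vec[3:])}
        return cls(alpha=alpha, z=z, tau=tau, betas=betas)


def drift_rate(spec: DriftSpec, params: DDMParams, features) -> float | np.ndarray:
    """Drift ``delta = sum_X beta(X) * X`` (or beta0 for constant-only)."""
    if spec.constant_only:
        if params.beta0 is None:
            raise SpecMismatchError("constant-only spec requires beta0")
        if isinstance(features, (InequityFeatures, dict)):
            return float(params.beta0)
        return np.full(len(features), float(params.beta0))
    missing = [r for r in spec.regressors if r not in params.betas]
    if missing:
        raise SpecMismatchError(f"missing drift coefficient(s): {missing}")
    if isinstance(features, InequityFeatures):
        values = {"sr": features.sr, "ai": features.ai, "di": features.di, "or": features.or_}
        return float(sum(params.betas[r] * values[r] for r in spec.regressors))
    X = spec.design(features)
    b = np.array([params.betas[r] for r in spec.regressors])
    return X @ b


@dataclass(frozen=True)
class PriorSpec:
    """Priors: alpha, tau ~ HalfNormal(sigma); z ~ U(0,1); beta ~ U(-3,3)."""

    alpha_sigma: float = 2.0
    tau_sigma: float = 2.0
    z_bounds: tuple[float, float] = (0.0, 1.0)
    beta_bounds: tuple[float, float] = (-3.0, 3.0)

    def log_density(self, spec: DriftSpec, theta: np.ndarray, tau_max: float | np.ndarray = np.inf):
        """Unnormalized log prior over stacked parameter vectors.

        ``theta[..., :]`` is ordered as ``spec.param_names``; ``tau_max``
        optionally truncates the nondecision-time support below the minimum
        observed RT (broadcastable against the leading axes).
        """
        alpha = theta[..., 0]
        z = theta[..., 1]
        tau = theta[..., 2]
        betas = theta[..., 3:]
        lo, hi = self.beta_bounds
        zlo, zhi = self.z_bounds
        ok = (
            (alpha > 0)
            & (z > zlo)
            & (z < zhi)
            & (tau > 0)
            & (tau < tau_max)
            & (betas > lo).all(axis=-1)
            & (betas < hi).all(axis=-1)
        )
        lp = -(alpha**2) / (2.0 * self.alpha_sigma**2) - (tau**2) / (2.0 * self.tau_sigma**2)
        return np.where(ok, lp, -np.inf)
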
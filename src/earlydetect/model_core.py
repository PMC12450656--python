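"""Tumor-immune model with awareness-driven early detection.

Two coupled ODEs describe a logistically growing tumor attacked by cytotoxic
lymphocytes.  Screening and public awareness remove tumor cells at a rate
that saturates in tumor size (a Michaelis-Menten term).  The dimensional
system tracks tumor cells ``C(t)`` and lymphocytes ``L(t)``::

    dC/dt = a1*C*(1 - C/a2) - a3*C*L/(a4 + L) - K*C/(a + alpha_aw*c_tilde*C)
    dL/dt = a5*L*(1 - L/a6)*C/(a7 + C) - a8*C*L - a9*L

Rescaling populations by their carrying capacities (``x = C/a2``,
``y = L/a6``) and time by the tumor growth rate (``tau = a1*t``) gives the
dimensionless system used by every downstream analysis::

    dx/dtau = x*(1 - x) - beta*x*y/(gamma + y) - kappa*x/(alpha + delta*x)
    dy/dtau = rho*y*(1 - y)*x/(mu + x) - sigma*x*y - eta*y

Parameter meanings (all dimensionless):

=========  =============================================================
``beta``   immune kill rate of tumor cells
``gamma``  half-saturation of the immune kill term
``kappa``  maximum removal rate from early detection
``alpha``  baseline detection constant (detection denominator at x=0)
``delta``  awareness x detection-threshold product; larger values weaken
           the detection term at a given tumor burden
``rho``    immune proliferation rate
``mu``     half-saturation of tumor-stimulated immune activation
``sigma``  immune death rate induced by tumor cells
``eta``    immune apoptosis rate
=========  =============================================================

Note that the dimensional awareness parameter ``alpha_aw`` (which enters
the detection denominator together with the detection threshold
``c_tilde``) and the dimensionless group ``alpha = a/a2`` are distinct
quantities and are never aliased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace as _dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ParameterError",
    "DomainError",
    "DimensionalParams",
    "NondimParams",
    "DimensionalState",
    "NondimState",
    "detection_effect",
    "rhs_dimensional",
    "rhs_nondim",
    "jacobian",
    "param_partials",
    "nondimensionalize",
]

#: Canonical ordering of the nine dimensionless parameters.
PARAM_NAMES = ("beta", "gamma", "kappa", "delta", "alpha", "rho", "mu", "sigma", "eta")


class ParameterError(ValueError):
    """A parameter value violates its admissibility constraints."""


class DomainError(ValueError):
    """A state or argument lies outside the model's domain."""


def _check_positive(problems: list, name: str, value: float, strict: bool) -> None:
    if not math.isfinite(value):
        problems.append(f"{name} must be finite, got {value!r}")
    elif strict and value <= 0:
        problems.append(f"{name} must be strictly positive, got {value!r}")
    elif not strict and value < 0:
        problems.append(f"{name} must be nonnegative, got {value!r}")


# Symbols that sit in denominators evaluated at admissible states must be
# strictly positive; pure rates may vanish (e.g. kappa=0 switches detection
# off, the convention used for "without early detection" comparisons).
_DIM_STRICT = {"a1", "a2", "a4", "a6", "a7", "a", "c_tilde", "alpha_aw"}
_NONDIM_STRICT = {"gamma", "alpha", "mu"}


@dataclass(frozen=True)
class DimensionalParams:
    """The thirteen constants of the dimensional model.

    ``a1``: tumor growth rate (1/time); ``a2``: tumor carrying capacity
    (cells); ``a3``: lymphocyte kill rate (1/time); ``a4``: kill
    half-saturation (cells); ``a5``: lymphocyte proliferation rate (1/time);
    ``a6``: lymphocyte carrying capacity (cells); ``a7``: proliferation
    half-saturation (cells); ``a8``: lymphocyte death rate due to tumor
    (1/(cells*time)); ``a9``: lymphocyte apoptosis rate (1/time); ``K``:
    maximum early-detection effect (cells/time); ``a``: baseline detection
    constant (cells); ``c_tilde``: detection threshold (cells);
    ``alpha_aw``: dimensionless awareness parameter.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    a8: float
    a9: float
    K: float
    a: float
    c_tilde: float
    alpha_aw: float

    def __post_init__(self) -> None:
        problems: list = []
        for f in fields(self):
            _check_positive(problems, f.name, getattr(self, f.name), f.name in _DIM_STRICT)
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass(frozen=True)
class NondimParams:
    """The nine dimensionless groups of the rescaled system."""

    beta: float
    gamma: float
    kappa: float
    delta: float
    alpha: float
    rho: float
    mu: float
    sigma: float
    eta: float

    def __post_init__(self) -> None:
        problems: list = []
        for f in fields(self):
            _check_positive(problems, f.name, getattr(self, f.name), f.name in _NONDIM_STRICT)
        if problems:
            raise ParameterError("; ".join(problems))

    def as_array(self) -> np.ndarray:
        """Values in the canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "NondimParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes: float) -> "NondimParams":
        return _dc_replace(self, **changes)


@dataclass(frozen=True)
class DimensionalState:
    """Tumor cells ``C`` and lymphocytes ``L`` at time ``t`` (cells)."""

    C: float
    L: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.C < 0 or self.L < 0:
            raise DomainError(f"populations must be nonnegative, got C={self.C}, L={self.L}")


@dataclass(frozen=True)
class NondimState:
    """Scaled tumor burden ``x``, immune level ``y`` at scaled time ``tau``."""

    x: float
    y: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise DomainError(f"states must be nonnegative, got x={self.x}, y={self.y}")


def _as_xy(state) -> tuple:
    if isinstance(state, NondimState):
        return state.x, state.y
    x, y = state
    return float(x), float(y)


def _as_CL(state) -> tuple:
    if isinstance(state, DimensionalState):
        return state.C, state.L
    C, L = state
    return float(C), float(L)


def detection_effect(C, params: DimensionalParams):
    """Early-detection removal rate ``K*C/(a + alpha_aw*c_tilde*C)``.

    Vanishes at ``C=0``, is monotone nondecreasing in ``C`` and saturates at
    ``K/(alpha_aw*c_tilde)`` as ``C`` grows; accepts scalars or arrays.
    """
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise DomainError("tumor size C must be nonnegative")
    out = params.K * C_arr / (params.a + params.alpha_aw * params.c_tilde * C_arr)
    return out if out.ndim else float(out)


def rhs_dimensional(state, params: DimensionalParams) -> tuple:
    """Right-hand side ``(dC/dt, dL/dt)`` of the dimensional system."""
    C, L = _as_CL(state)
    if C < 0 or L < 0:
        raise DomainError(f"states must be nonnegative, got C={C}, L={L}")
    p = params
    dC = (
        p.a1 * C * (1.0 - C / p.a2)
        - p.a3 * C * L / (p.a4 + L)
        - p.K * C / (p.a + p.alpha_aw * p.c_tilde * C)
    )
    dL = p.a5 * L * (1.0 - L / p.a6) * C / (p.a7 + C) - p.a8 * C * L - p.a9 * L
    return dC, dL


def _rhs_xy(x: float, y: float, p: NondimParams) -> tuple:
    """Unvalidated dimensionless right-hand side; the integrator hot path."""
    dx = x * (1.0 - x) - p.beta * x * y / (p.gamma + y) - p.kappa * x / (p.alpha + p.delta * x)
    dy = p.rho * y * (1.0 - y) * x / (p.mu + x) - p.sigma * x * y - p.eta * y
    return dx, dy


def rhs_nondim(state, params: NondimParams) -> np.ndarray:
    """Right-hand side ``(dx/dtau, dy/dtau)`` of the dimensionless system."""
    x, y = _as_xy(state)
    if x < 0 or y < 0:
        raise DomainError(f"states must be nonnegative, got x={x}, y={y}")
    return np.array(_rhs_xy(x, y, params))


def jacobian(state, params: NondimParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the dimensionless right-hand side.

    Entries::

        J11 = 1 - 2x - beta*y/(gamma+y) - kappa*alpha/(alpha+delta*x)^2
        J12 = -beta*gamma*x/(gamma+y)^2
        J21 = rho*y*(1-y)*mu/(mu+x)^2 - sigma*y
        J22 = (x/(mu+x))*(rho - 2*rho*y) - sigma*x - eta
    """
    x, y = _as_xy(state)
    p = params
    gy = p.gamma + y
    mx = p.mu + x
    adx = p.alpha + p.delta * x
    if gy <= 0 or mx <= 0 or adx <= 0:
        raise DomainError("denominators gamma+y, mu+x, alpha+delta*x must be positive")
    j11 = 1.0 - 2.0 * x - p.beta * y / gy - p.kappa * p.alpha / adx**2
    j12 = -p.beta * p.gamma * x / gy**2
    j21 = p.rho * y * (1.0 - y) * p.mu / mx**2 - p.sigma * y
    j22 = (x / mx) * (p.rho - 2.0 * p.rho * y) - p.sigma * x - p.eta
    return np.array([[j11, j12], [j21, j22]])


def param_partials(state, params: NondimParams) -> np.ndarray:
    """Partial derivatives of the right-hand side w.r.t. the nine parameters.

    Returns a (2, 9) array with columns in :data:`PARAM_NAMES` order; used to
    drive the forward sensitivity equations.
    """
    x, y = _as_xy(state)
    p = params
    gy = p.gamma + y
    mx = p.mu + x
    adx = p.alpha + p.delta * x
    out = np.zeros((2, 9))
    # tumor equation: beta, gamma, kappa, delta, alpha
    out[0, 0] = -x * y / gy
    out[0, 1] = p.beta * x * y / gy**2
    out[0, 2] = -x / adx
    out[0, 3] = p.kappa * x**2 / adx**2
    out[0, 4] = p.kappa * x / adx**2
    # immune equation: rho, mu, sigma, eta
    out[1, 5] = y * (1.0 - y) * x / mx
    out[1, 6] = -p.rho * y * (1.0 - y) * x / mx**2
    out[1, 7] = -x * y
    out[1, 8] = -y
    return out


def nondimensionalize(dp: DimensionalParams, mode: str = "paper") -> NondimParams:
    """Map dimensional constants onto the nine dimensionless groups.

    Two variants are exposed.  ``mode="paper"`` applies the substitution
    list as conventionally printed for this model family::

        beta = a3*a6/(a1*a2)   kappa = K/a1

    which carries residual units under the change of variables
    ``x = C/a2, y = L/a6, tau = a1*t``.  ``mode="derived"`` applies the
    dimensionally consistent re-derivation::

        beta = a3/a1           kappa = K/(a1*a2)

    All seven remaining groups are identical between modes::

        gamma = a4/a6, delta = alpha_aw*c_tilde, alpha = a/a2,
        rho = a5/a1, mu = a7/a2, sigma = a8*a2/a1, eta = a9/a1
    """
    if mode not in ("paper", "derived"):
        raise ParameterError(f"mode must be 'paper' or 'derived', got {mode!r}")
    common = dict(
        gamma=dp.a4 / dp.a6,
        delta=dp.alpha_aw * dp.c_tilde,
        alpha=dp.a / dp.a2,
        rho=dp.a5 / dp.a1,
        mu=dp.a7 / dp.a2,
        sigma=dp.a8 * dp.a2 / dp.a1,
        eta=dp.a9 / dp.a1,
    )
    if mode == "paper":
        return NondimParams(beta=dp.a3 * dp.a6 / (dp.a1 * dp.a2), kappa=dp.K / dp.a1, **common)
    return NondimParams(beta=dp.a3 / dp.a1, kappa=dp.K / (dp.a1 * dp.a2), **common)
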
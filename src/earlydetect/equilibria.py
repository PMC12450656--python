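"""Equilibria and stability of the dimensionless tumor-immune system.

The system always admits the cancer-free equilibrium ``E0 = (0, 0)``, where
the Jacobian is diagonal with eigenvalues ``1 - kappa/alpha`` and ``-eta``:
``E0`` is locally asymptotically stable precisely when ``kappa > alpha``
(detection strong enough to beat intrinsic growth at small tumor burden).

Interior (coexistence) equilibria come from substituting the immune
nullcline

    y*(x) = 1 - (mu + x)*(sigma*x + eta)/(rho*x)

into the tumor equilibrium equation, leaving one scalar equation

    g(x) = 1 - x - beta*y*(x)/(gamma + y*(x)) - kappa/(alpha + delta*x) = 0

solved by a sign-change scan plus bisection refinement.  Only admissible
roots (``0 < x <= 1``, ``0 < y < 1``) are reported, since the dimensionless
populations are fractions of carrying capacity.

A linear Lyapunov candidate ``V = x + y`` yields the classical sufficient
conditions ``kappa > alpha`` and ``rho*mu < beta*gamma + sigma`` for global
stability of ``E0``; :func:`global_stability_report` evaluates both
inequalities and can additionally verify that ``V`` is nonincreasing along
a supplied trajectory.  The two inequalities are checked as stated, but see
``docs/methods.md``: they do not rule out admissible interior equilibria for
every parameter set, so descent of ``V`` should always be confirmed
numerically in unfamiliar regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model_core import DomainError, NondimParams, jacobian
from .dynamics import EPS_NUM, Trajectory

__all__ = [
    "MARGINAL_TOL",
    "EquilibriumReport",
    "GlobalStabilityReport",
    "cancer_free_report",
    "coexistence_y_of_x",
    "interior_residual",
    "find_coexistence",
    "global_stability_report",
]

#: Eigenvalue real parts smaller than this in magnitude are treated as
#: marginal: linearization is inconclusive and the verdict is "indeterminate",
#: never "stable".
MARGINAL_TOL = 1e-12


@dataclass(frozen=True)
class EquilibriumReport:
    """Location, eigenvalues and stability verdict of one equilibrium."""

    location: Tuple[float, float]
    kind: str  # "cancer_free" | "coexistence"
    eigenvalues: Tuple[complex, complex]
    locally_stable: bool
    admissible: bool
    indeterminate: bool = False

    def to_dict(self) -> dict:
        return {
            "location": list(self.location),
            "kind": self.kind,
            "eigenvalues": [[ev.real, ev.imag] for ev in map(complex, self.eigenvalues)],
            "locally_stable": self.locally_stable,
            "admissible": self.admissible,
            "indeterminate": self.indeterminate,
        }


@dataclass(frozen=True)
class GlobalStabilityReport:
    """The two sufficient inequalities plus an optional trajectory check."""

    condition_kappa: bool  # kappa > alpha
    condition_rate: bool  # rho*mu < beta*gamma + sigma
    both_hold: bool
    lyapunov_monotone: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "condition_kappa": self.condition_kappa,
            "condition_rate": self.condition_rate,
            "both_hold": self.both_hold,
            "lyapunov_monotone": self.lyapunov_monotone,
        }


def _classify(eigs) -> Tuple[bool, bool]:
    re = np.real(eigs)
    indeterminate = bool(np.any(np.abs(re) < MARGINAL_TOL))
    stable = bool(np.all(re < -MARGINAL_TOL))
    return stable, indeterminate


def cancer_free_report(params: NondimParams) -> EquilibriumReport:
    """Report for ``E0 = (0, 0)`` with closed-form eigenvalues."""
    lam1 = 1.0 - params.kappa / params.alpha
    lam2 = -params.eta
    stable, indeterminate = _classify([lam1, lam2])
    return EquilibriumReport(
        location=(0.0, 0.0),
        kind="cancer_free",
        eigenvalues=(complex(lam1), complex(lam2)),
        locally_stable=stable,
        admissible=True,
        indeterminate=indeterminate,
    )


def coexistence_y_of_x(x: float, params: NondimParams) -> float:
    """Immune level on the immune nullcline: ``1 - (mu+x)(sigma*x+eta)/(rho*x)``.

    May be nonpositive (inadmissible); callers filter.  ``rho = 0`` leaves
    no interior immune balance, so the value is undefined there as well.
    """
    if x <= 0:
        raise DomainError("y*(x) is undefined at x <= 0 (division by zero)")
    if params.rho == 0:
        raise DomainError("y*(x) is undefined for rho = 0")
    return 1.0 - (params.mu + x) * (params.sigma * x + params.eta) / (params.rho * x)


def interior_residual(x: float, params: NondimParams) -> float:
    """Scalar equilibrium residual ``g(x)`` after the ``y*(x)`` substitution."""
    y = coexistence_y_of_x(x, params)
    return (
        1.0
        - x
        - params.beta * y / (params.gamma + y)
        - params.kappa / (params.alpha + params.delta * x)
    )


def find_coexistence(
    params: NondimParams,
    x_bracket: Tuple[float, float] = (1e-6, 1.0),
    tol: float = 1e-12,
    n_scan: int = 2000,
) -> List[EquilibriumReport]:
    """All admissible interior equilibria on the bracket.

    Scans ``g(x)`` on an ``n_scan``-point grid restricted to where
    ``0 < y*(x) < 1``, refines each sign change by bisection to ``|g| < tol``
    and classifies each root through the analytic Jacobian.  Returns an
    empty list when detection is strong enough to preclude interior roots.
    """
    lo, hi = x_bracket
    if not (0 < lo < hi <= 1.0):
        raise DomainError(f"x_bracket must satisfy 0 < lo < hi <= 1, got {x_bracket}")
    if tol <= 0:
        raise DomainError("tol must be positive")
    if params.rho == 0:
        return []
    def eval_grid(xs: np.ndarray):
        ys = 1.0 - (params.mu + xs) * (params.sigma * xs + params.eta) / (params.rho * xs)
        valid = (ys > 0.0) & (ys < 1.0)
        g = np.where(
            valid,
            1.0 - xs - params.beta * ys / (params.gamma + ys) - params.kappa / (params.alpha + params.delta * xs),
            np.nan,
        )
        return valid, g

    roots: List[float] = []

    def scan(xs: np.ndarray, valid, g, refine: bool) -> None:
        for i in range(len(xs) - 1):
            if valid[i] and valid[i + 1]:
                gi, gj = g[i], g[i + 1]
                if gi == 0.0:
                    roots.append(float(xs[i]))
                elif gi * gj < 0:
                    roots.append(
                        float(brentq(interior_residual, xs[i], xs[i + 1], args=(params,), xtol=1e-15, rtol=8.9e-16))
                    )
            elif refine and (valid[i] or valid[i + 1]):
                # the admissibility region 0 < y*(x) < 1 starts or ends inside
                # this interval; a root can hide between the boundary and the
                # valid endpoint, so rescan the interval on a fine subgrid
                sub = np.linspace(xs[i], xs[i + 1], 257)
                scan(sub, *eval_grid(sub), refine=False)

    xs = np.linspace(lo, hi, n_scan)
    valid, g = eval_grid(xs)
    scan(xs, valid, g, refine=True)
    if valid[-1] and g[-1] == 0.0:
        roots.append(float(xs[-1]))

    reports: List[EquilibriumReport] = []
    seen: List[float] = []
    for x_star in roots:
        if any(abs(x_star - s) < 1e-9 for s in seen):
            continue
        seen.append(x_star)
        if abs(interior_residual(x_star, params)) > tol:
            continue
        y_star = coexistence_y_of_x(x_star, params)
        if not (0 < x_star <= 1.0 and 0 < y_star < 1.0):
            continue
        eigs = np.linalg.eigvals(jacobian((x_star, y_star), params))
        stable, indeterminate = _classify(eigs)
        reports.append(
            EquilibriumReport(
                location=(x_star, y_star),
                kind="coexistence",
                eigenvalues=(complex(eigs[0]), complex(eigs[1])),
                locally_stable=stable,
                admissible=True,
                indeterminate=indeterminate,
            )
        )
    return reports


def global_stability_report(
    params: NondimParams,
    traj: Optional[Trajectory] = None,
    eps: float = EPS_NUM,
) -> GlobalStabilityReport:
    """Evaluate the two sufficient inequalities; optionally check descent.

    With a trajectory supplied, ``lyapunov_monotone`` records whether
    ``V = x + y`` is nonincreasing along it within ``eps``.
    """
    cond_k = params.kappa > params.alpha
    cond_r = params.rho * params.mu < params.beta * params.gamma + params.sigma
    monotone = None
    if traj is not None:
        v = traj.x + traj.y
        monotone = bool(np.all(np.diff(v) <= eps))
    return GlobalStabilityReport(
        condition_kappa=cond_k,
        condition_rate=cond_r,
        both_hold=cond_k and cond_r,
        lyapunov_monotone=monotone,
    )
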
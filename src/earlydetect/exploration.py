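"""Parameter sweeps, phase-plane structure and basins of attraction.

Long-run behaviour is summarized by the terminal state of a ``t_end = 200``
integration from fixed initial conditions.  All attractors of this planar
autonomous system observed across the admissible box are fixed points
(Poincare-Bendixson rules out chaos), so terminal values rather than tail
averages are the right summary; sweeps are cross-checked against the
equilibrium solver.

The detection threshold ``kappa = alpha`` is where the tumor-free state
exchanges stability (its leading eigenvalue ``1 - kappa/alpha`` changes
sign), and sweeps over ``kappa`` or ``alpha`` report that analytic crossing
alongside the empirical regime-change estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import PARAM_NAMES, DomainError, NondimParams
from .dynamics import (
    EPS_NUM,
    IntegrationError,
    SimulationSettings,
    simulate,
    solve_states,
)
from .equilibria import coexistence_y_of_x, find_coexistence

__all__ = [
    "CONTROLLED_THRESHOLD",
    "SweepResult",
    "BasinGrid",
    "PhasePortraitData",
    "bifurcation_sweep",
    "awareness_surface",
    "nullclines",
    "phase_portrait",
    "basin_of_attraction",
    "TABLE3_ICS",
]

#: Terminal tumor burden below which a run counts as "controlled".  On the
#: benchmarks this separates exponential decay toward the tumor-free state
#: from interior attractors by more than two orders of magnitude.
CONTROLLED_THRESHOLD = 1e-3

#: Trajectory-bundle initial conditions used for phase portraits.
TABLE3_ICS: Tuple[Tuple[float, float], ...] = ((0.3, 0.6), (0.2, 0.8), (0.25, 0.5), (0.1, 0.9))


@dataclass(frozen=True)
class SweepResult:
    """Long-run states along a one-parameter grid."""

    parameter_name: str
    grid: np.ndarray
    longrun_x: np.ndarray
    longrun_y: np.ndarray
    regime: List[str]
    threshold_estimates: List[float]
    analytic_threshold: Optional[float]
    failures: List[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param_value": self.grid,
                "longrun_x": self.longrun_x,
                "longrun_y": self.longrun_y,
                "regime": self.regime,
            }
        )


@dataclass(frozen=True)
class BasinGrid:
    """Outcome classification over a grid of initial conditions."""

    x0_grid: np.ndarray
    y0_grid: np.ndarray
    outcome: np.ndarray  # strings: "controlled" | "persistent" | "failed"
    final_x: np.ndarray
    t_end: float
    threshold: float

    @property
    def controlled_fraction(self) -> float:
        return float(np.mean(self.outcome == "controlled"))

    @property
    def n_failed(self) -> int:
        return int(np.sum(self.outcome == "failed"))

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x0_grid, self.y0_grid, indexing="ij")
        return pd.DataFrame(
            {
                "x0": xx.ravel(),
                "y0": yy.ravel(),
                "final_x": self.final_x.ravel(),
                "label": self.outcome.ravel(),
            }
        )


@dataclass(frozen=True)
class PhasePortraitData:
    """Vector field, nullclines, their intersections and a trajectory bundle."""

    field_x: Optional[np.ndarray]
    field_y: Optional[np.ndarray]
    arrows_u: Optional[np.ndarray]
    arrows_v: Optional[np.ndarray]
    magnitude: Optional[np.ndarray]
    tumor_nullcline: Tuple[np.ndarray, np.ndarray]
    immune_nullcline: Tuple[np.ndarray, np.ndarray]
    intersections: List[Tuple[float, float]]
    trajectories: List

    def to_json_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "field_x": arr(self.field_x),
            "field_y": arr(self.field_y),
            "arrows_u": arr(self.arrows_u),
            "arrows_v": arr(self.arrows_v),
            "magnitude": arr(self.magnitude),
            "tumor_nullcline": [arr(self.tumor_nullcline[0]), arr(self.tumor_nullcline[1])],
            "immune_nullcline": [arr(self.immune_nullcline[0]), arr(self.immune_nullcline[1])],
            "intersections": [list(p) for p in self.intersections],
            "n_trajectories": len(self.trajectories),
        }


def _terminal(params, x0, y0, t_end, settings):
    base = settings or SimulationSettings()
    st = SimulationSettings(
        t_end=t_end, n_out=2, rel_tol=base.rel_tol, abs_tol=min(base.abs_tol, 1e-12),
        stiff_fallback=base.stiff_fallback,
    )
    return solve_states(params, x0, y0, [0.0, t_end], st)[-1]


def bifurcation_sweep(
    params: NondimParams,
    parameter_name: str,
    grid: Sequence[float],
    t_end: float = 200.0,
    x0: float = 0.35,
    y0: float = 0.08,
    settings: Optional[SimulationSettings] = None,
    threshold: float = CONTROLLED_THRESHOLD,
) -> SweepResult:
    """Long-run states as one parameter varies, others held fixed.

    Each grid value is integrated from the same initial conditions; a failed
    integration flags the point (NaN state) and the sweep continues.
    Empirical regime changes are midpoints of grid intervals where the
    controlled/persistent label flips; when sweeping ``kappa`` or ``alpha``
    the analytic stability crossing ``kappa = alpha`` is reported too.
    """
    if parameter_name not in PARAM_NAMES:
        raise DomainError(f"parameter_name must be one of {PARAM_NAMES}, got {parameter_name!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise DomainError("grid values must be nonnegative")
    lx = np.full(len(grid), np.nan)
    ly = np.full(len(grid), np.nan)
    failures: List[int] = []
    for i, v in enumerate(grid):
        try:
            p = params.replace(**{parameter_name: float(v)})
            lx[i], ly[i] = _terminal(p, x0, y0, t_end, settings)
        except IntegrationError:
            failures.append(i)
    regime = [
        "failed" if i in failures else ("controlled" if lx[i] < threshold else "persistent")
        for i in range(len(grid))
    ]
    estimates: List[float] = []
    for i in range(len(grid) - 1):
        a, b = regime[i], regime[i + 1]
        if "failed" not in (a, b) and a != b:
            estimates.append(float(0.5 * (grid[i] + grid[i + 1])))
    analytic = None
    if parameter_name == "kappa":
        analytic = params.alpha
    elif parameter_name == "alpha":
        analytic = params.kappa
    if analytic is not None and not (grid.min() <= analytic <= grid.max()):
        analytic = None
    return SweepResult(
        parameter_name=parameter_name,
        grid=grid,
        longrun_x=lx,
        longrun_y=ly,
        regime=regime,
        threshold_estimates=estimates,
        analytic_threshold=analytic,
        failures=failures,
    )


def awareness_surface(
    params: NondimParams,
    alpha_grid: Sequence[float],
    time_grid: Sequence[float],
    x0: float = 0.35,
    y0: float = 0.08,
    settings: Optional[SimulationSettings] = None,
) -> np.ndarray:
    """Tumor burden ``x(tau; alpha)``: one row per ``alpha``, one column per time.

    Because ``alpha`` enters the detection denominator, rows with larger
    ``alpha`` experience weaker detection and lie (weakly) higher.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(alpha_grid <= 0) or np.any(time_grid < 0) or np.any(np.diff(time_grid) <= 0):
        raise DomainError("alpha_grid must be positive; time_grid nonnegative and increasing")
    base = settings or SimulationSettings()
    st = SimulationSettings(
        t_end=float(time_grid[-1]) if time_grid[-1] > 0 else base.t_end,
        n_out=2,
        rel_tol=base.rel_tol,
        abs_tol=base.abs_tol,
        stiff_fallback=base.stiff_fallback,
    )
    out = np.empty((len(alpha_grid), len(time_grid)))
    for i, a in enumerate(alpha_grid):
        out[i] = solve_states(params.replace(alpha=float(a)), x0, y0, time_grid, st)[:, 0]
    return out


def _tumor_nullcline_y(x: np.ndarray, p: NondimParams):
    """Nontrivial tumor nullcline ``y = gamma*g/(beta - g)``, ``g = 1-x-kappa/(alpha+delta*x)``.

    Defined (with positive y) only where ``0 < g < beta``.
    """
    g = 1.0 - x - p.kappa / (p.alpha + p.delta * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = p.gamma * g / (p.beta - g)
    valid = (g > 0) & (g < p.beta)
    return np.where(valid, y, np.nan), valid


def nullclines(
    params: NondimParams,
    x_grid: Optional[Sequence[float]] = None,
) -> PhasePortraitData:
    """Nontrivial nullclines on a tumor-burden grid, with intersections.

    Intersections of the two curves are interior equilibria; each reported
    point satisfies both nullcline equations to 1e-8 (they are refined by
    bisection on the difference of the two curves).
    """
    if x_grid is None:
        x_grid = np.linspace(2.5e-3, 1.0, 400)
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0) or np.any(x > 1.0):
        raise DomainError("x_grid must lie in (0, 1]")
    y_t, valid_t = _tumor_nullcline_y(x, params)
    if params.rho > 0:
        y_i = 1.0 - (params.mu + x) * (params.sigma * x + params.eta) / (params.rho * x)
    else:
        y_i = np.full_like(x, np.nan)
    valid_i = (y_i > 0) & (y_i < 1)

    def diff(xv: float) -> float:
        yt, _ = _tumor_nullcline_y(np.asarray([xv]), params)
        return float(yt[0] - coexistence_y_of_x(xv, params))

    intersections: List[Tuple[float, float]] = []
    both = valid_t & valid_i
    d = np.where(both, y_t - y_i, np.nan)
    for i in range(len(x) - 1):
        if both[i] and both[i + 1] and d[i] * d[i + 1] <= 0 and not (d[i] == 0 and d[i + 1] == 0):
            if d[i] == 0.0:
                xs = float(x[i])
            else:
                xs = float(brentq(diff, x[i], x[i + 1], xtol=1e-14))
            ys = coexistence_y_of_x(xs, params)
            intersections.append((xs, float(ys)))
    return PhasePortraitData(
        field_x=None,
        field_y=None,
        arrows_u=None,
        arrows_v=None,
        magnitude=None,
        tumor_nullcline=(x[valid_t], y_t[valid_t]),
        immune_nullcline=(x[valid_i], y_i[valid_i]),
        intersections=intersections,
        trajectories=[],
    )


def phase_portrait(
    params: NondimParams,
    ics: Optional[Sequence[Tuple[float, float]]] = None,
    n_field: int = 25,
    t_end: float = 50.0,
    settings: Optional[SimulationSettings] = None,
) -> PhasePortraitData:
    """Vector field on the unit box, nullclines, and a trajectory bundle.

    Arrows are normalized to unit length with speed stored separately, the
    standard rendering choice so arrows near equilibria stay visible.
    """
    if ics is None:
        ics = TABLE3_ICS
    base = nullclines(params)
    xs = np.linspace(1.0 / n_field, 1.0, n_field)
    ys = np.linspace(1.0 / n_field, 1.0, n_field)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    u = xx * (1 - xx) - params.beta * xx * yy / (params.gamma + yy) - params.kappa * xx / (
        params.alpha + params.delta * xx
    )
    v = params.rho * yy * (1 - yy) * xx / (params.mu + xx) - params.sigma * xx * yy - params.eta * yy
    mag = np.hypot(u, v)
    safe = np.where(mag > 0, mag, 1.0)
    st = settings or SimulationSettings()
    st = SimulationSettings(t_end=t_end, n_out=st.n_out, rel_tol=st.rel_tol,
                            abs_tol=st.abs_tol, stiff_fallback=st.stiff_fallback)
    trajs = [simulate(params, x0, y0, st) for (x0, y0) in ics]
    return PhasePortraitData(
        field_x=xx,
        field_y=yy,
        arrows_u=u / safe,
        arrows_v=v / safe,
        magnitude=mag,
        tumor_nullcline=base.tumor_nullcline,
        immune_nullcline=base.immune_nullcline,
        intersections=base.intersections,
        trajectories=trajs,
    )


def basin_of_attraction(
    params: NondimParams,
    x0_grid: Sequence[float],
    y0_grid: Sequence[float],
    t_end: float = 200.0,
    threshold: float = CONTROLLED_THRESHOLD,
    settings: Optional[SimulationSettings] = None,
) -> BasinGrid:
    """Classify every initial condition by its terminal tumor burden."""
    x0_grid = np.asarray(x0_grid, dtype=float)
    y0_grid = np.asarray(y0_grid, dtype=float)
    if np.any(x0_grid <= 0) or np.any(x0_grid > 1) or np.any(y0_grid <= 0) or np.any(y0_grid > 1):
        raise DomainError("initial-condition grids must lie in (0, 1]")
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    outcome = np.empty((len(x0_grid), len(y0_grid)), dtype=object)
    final_x = np.full((len(x0_grid), len(y0_grid)), np.nan)
    for i, x0 in enumerate(x0_grid):
        for j, y0 in enumerate(y0_grid):
            try:
                fx, _ = _terminal(params, float(x0), float(y0), t_end, settings)
                final_x[i, j] = fx
                outcome[i, j] = "controlled" if fx < threshold else "persistent"
            except IntegrationError:
                outcome[i, j] = "failed"
    return BasinGrid(
        x0_grid=x0_grid,
        y0_grid=y0_grid,
        outcome=outcome,
        final_x=final_x,
        t_end=t_end,
        threshold=threshold,
    )
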
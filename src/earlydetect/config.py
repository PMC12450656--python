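"""Run configuration, validation, packaged defaults and the staged pipeline.

Configs are flat JSON or TOML files.  A config either gives the nine
dimensionless parameters directly (keys ``beta ... eta`` plus ``x0``,
``y0``, ``t_end``) or a ``dimensional`` table (keys ``a1 ... a9``, ``K``,
``a``, ``c_tilde``, ``alpha_aw`` and a ``mode`` selecting the printed or
the re-derived nondimensionalization) -- never both.  Unspecified values
fall back to the packaged default parameter set; validation reports every
problem at once rather than stopping at the first.

One top-level ``seed`` feeds the whole pipeline; per-stage seeds are split
from it deterministically, so a rerun with the same seed is bit-identical.
Stages append structured warnings to the run manifest when they detect
model behaviour that common narrative conventions get backwards (for
example, the awareness-linked constants ``alpha`` and ``delta`` sit in the
detection denominator, so increasing them weakens detection).
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from . import __version__
from .model_core import (
    PARAM_NAMES,
    DimensionalParams,
    NondimParams,
    ParameterError,
    nondimensionalize,
)
from .dynamics import SimulationSettings, simulate
from .equilibria import cancer_free_report, find_coexistence, global_stability_report
from .sensitivity import DegenerateHorizonError, rank_parameters, sensitivity_fd, sensitivity_forward
from .exploration import basin_of_attraction, bifurcation_sweep, phase_portrait
from .synthetic_fit import fit_parameters, generate_dataset

__all__ = [
    "STAGES",
    "ConfigError",
    "RunConfig",
    "RunManifest",
    "default_params",
    "table3_initial_conditions",
    "load_config",
    "run_pipeline",
]

#: Pipeline stages in execution order.
STAGES = (
    "simulate",
    "equilibria",
    "stability",
    "sensitivity",
    "bifurcate",
    "basin",
    "portrait",
    "generate-data",
    "fit",
)

_DIM_KEYS = ("a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8", "a9", "K", "a", "c_tilde", "alpha_aw")
_BLOCK_KEYS = ("simulation", "sweep", "basin", "sensitivity", "fit")
_SCALAR_KEYS = PARAM_NAMES + ("x0", "y0", "t_end")
_META_KEYS = ("seed", "out_dir", "stages", "dimensional") + _BLOCK_KEYS

_BLOCK_DEFAULTS: Dict[str, Dict] = {
    "simulation": {"n_out": 501, "rel_tol": 1e-9, "abs_tol": 1e-12, "stiff_fallback": True},
    "sweep": {"parameter": "kappa", "lo": 0.05, "hi": 3.0, "n": 21, "t_end": 200.0},
    "basin": {"n": 21, "t_end": 200.0, "threshold": 1e-3},
    # the default strong-detection regime drives x(tau) to ~1e-9 by tau=5;
    # longer horizons underflow the elasticity normalization
    "sensitivity": {"horizon": 5.0, "method": "ode"},
    "fit": {"free": ["kappa"], "noise_sd": 0.02, "n_points": 51, "t_obs": 25.0, "n_starts": 5},
}


class ConfigError(ValueError):
    """Aggregated configuration problems; ``errors`` lists all of them."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def default_params() -> dict:
    """The packaged default parameter set (params, ICs and horizon)."""
    with resources.files("earlydetect.data").joinpath("table2.json").open() as fh:
        return json.load(fh)


def table3_initial_conditions() -> List[Tuple[float, float]]:
    """The packaged trajectory-bundle initial conditions."""
    with resources.files("earlydetect.data").joinpath("table3_initial_conditions.json").open() as fh:
        return [tuple(ic) for ic in json.load(fh)]


@dataclass(frozen=True)
class RunConfig:
    """A validated, fully resolved run configuration."""

    params: NondimParams
    x0: float
    y0: float
    t_end: float
    seed: int = 0
    out_dir: str = "earlydetect_out"
    stages: Tuple[str, ...] = STAGES
    blocks: Dict[str, Dict] = field(default_factory=dict)

    def settings(self, **overrides) -> SimulationSettings:
        sim = dict(self.blocks.get("simulation", _BLOCK_DEFAULTS["simulation"]))
        sim.setdefault("t_end", self.t_end)
        sim.update(overrides)
        return SimulationSettings(**sim)

    def to_dict(self) -> dict:
        d = dict(self.params.to_dict())
        d.update(
            x0=self.x0, y0=self.y0, t_end=self.t_end, seed=self.seed,
            out_dir=self.out_dir, stages=list(self.stages),
        )
        for k, v in self.blocks.items():
            d[k] = dict(v)
        return d

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _parse_file(path: Path) -> dict:
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    return json.loads(path.read_text())


def load_config(path=None, overrides: Optional[Mapping] = None) -> RunConfig:
    """Load, merge and validate a configuration.

    Resolution order: packaged defaults, then the file at ``path`` (JSON or
    TOML by extension), then ``overrides``.  All validation errors are
    aggregated into one :class:`ConfigError`.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError([f"config file not found: {p}"])
        try:
            raw = _parse_file(p)
        except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError([f"could not parse {p}: {exc}"]) from exc
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    errors: List[str] = []
    allowed = set(_SCALAR_KEYS) | set(_META_KEYS)
    for k in raw:
        if k not in allowed:
            errors.append(f"unknown config key: {k!r}")

    has_nondim = any(k in raw for k in PARAM_NAMES)
    has_dim = "dimensional" in raw
    if has_nondim and has_dim:
        errors.append("config must contain either dimensionless parameter keys or a "
                      "'dimensional' block, not both")

    defaults = default_params()
    params: NondimParams
    if has_dim and not has_nondim:
        dim = dict(raw["dimensional"])
        mode = dim.pop("mode", "paper")
        unknown = set(dim) - set(_DIM_KEYS)
        if unknown:
            errors.append(f"unknown dimensional keys: {sorted(unknown)}")
        missing = set(_DIM_KEYS) - set(dim)
        if missing:
            errors.append(f"missing dimensional keys: {sorted(missing)}")
        params = NondimParams.from_dict({k: defaults[k] for k in PARAM_NAMES})
        if not errors:
            try:
                params = nondimensionalize(DimensionalParams(**{k: float(dim[k]) for k in _DIM_KEYS}), mode=mode)
            except ParameterError as exc:
                errors.append(str(exc))
    else:
        merged = {k: raw.get(k, defaults[k]) for k in PARAM_NAMES}
        try:
            params = NondimParams.from_dict({k: float(v) for k, v in merged.items()})
        except (ParameterError, TypeError, ValueError) as exc:
            errors.append(str(exc))
            params = NondimParams.from_dict({k: defaults[k] for k in PARAM_NAMES})

    x0 = raw.get("x0", defaults["x0"])
    y0 = raw.get("y0", defaults["y0"])
    t_end = raw.get("t_end", defaults["t_end"])
    if not (isinstance(x0, (int, float)) and x0 >= 0):
        errors.append(f"x0 must be a nonnegative number, got {x0!r}")
    if not (isinstance(y0, (int, float)) and y0 >= 0):
        errors.append(f"y0 must be a nonnegative number, got {y0!r}")
    if not (isinstance(t_end, (int, float)) and t_end > 0):
        errors.append(f"t_end must be a positive number, got {t_end!r}")

    stages = tuple(raw.get("stages", STAGES))
    bad_stages = [s for s in stages if s not in STAGES]
    if bad_stages:
        errors.append(f"unknown stages: {bad_stages}; valid stages are {list(STAGES)}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a nonnegative integer, got {seed!r}")

    blocks: Dict[str, Dict] = {}
    for name in _BLOCK_KEYS:
        block = dict(_BLOCK_DEFAULTS[name])
        user = raw.get(name, {})
        if not isinstance(user, dict):
            errors.append(f"{name!r} must be a table/object")
            user = {}
        unknown = set(user) - set(block)
        if unknown:
            errors.append(f"unknown keys in {name!r} block: {sorted(unknown)}")
        block.update({k: v for k, v in user.items() if k in block})
        blocks[name] = block

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        params=params, x0=float(x0), y0=float(y0), t_end=float(t_end),
        seed=int(seed), out_dir=str(raw.get("out_dir", "earlydetect_out")),
        stages=tuple(stages) if stages else STAGES, blocks=blocks,
    )


@dataclass
class RunManifest:
    """Record of one pipeline run: outputs, warnings and provenance."""

    package_version: str
    timestamp: str
    seed: int
    config: dict
    outputs: List[str] = field(default_factory=list)
    warnings: List[dict] = field(default_factory=list)
    success: bool = True

    def warn(self, stage: str, code: str, message: str) -> None:
        self.warnings.append({"stage": stage, "code": code, "message": message})

    def to_dict(self) -> dict:
        return {
            "package_version": self.package_version,
            "timestamp": self.timestamp,
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "success": self.success,
        }


def _stage_seeds(seed: int) -> Dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in order, writing outputs and a manifest.

    Raises the underlying exception on stage failure after recording the
    partial manifest (``success=False``) on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        seed=config.seed,
        config=config.to_dict(),
    )
    seeds = _stage_seeds(config.seed)
    p = config.params

    def emit(name: str) -> Path:
        manifest.outputs.append(name)
        return out / name

    try:
        traj = None
        if "simulate" in config.stages:
            traj = simulate(p, config.x0, config.y0, config.settings())
            traj.write(emit("trajectory.csv"), version=__version__)
            manifest.outputs.append("trajectory.meta.json")
        if "equilibria" in config.stages:
            reports = [cancer_free_report(p).to_dict()] + [
                r.to_dict() for r in find_coexistence(p)
            ]
            emit("equilibria.json").write_text(json.dumps(reports, indent=2))
        if "stability" in config.stages:
            traj_for_v = traj if traj is not None else simulate(p, config.x0, config.y0, config.settings())
            rep = global_stability_report(p, traj_for_v)
            emit("global_stability.json").write_text(json.dumps(rep.to_dict(), indent=2))
            if rep.both_hold and find_coexistence(p):
                manifest.warn(
                    "stability", "sufficient-conditions-violated",
                    "both global-stability inequalities hold yet an admissible interior "
                    "equilibrium exists; the inequalities are not sufficient for this "
                    "parameter set -- verify Lyapunov descent numerically",
                )
        if "sensitivity" in config.stages:
            sb = config.blocks["sensitivity"]
            fn = sensitivity_forward if sb["method"] == "ode" else sensitivity_fd
            try:
                res = fn(p, config.x0, config.y0, sb["horizon"],
                         settings=config.settings(t_end=sb["horizon"], abs_tol=1e-12))
                rank_parameters(res).to_csv(emit("sensitivity.csv"), index=False)
                if res.signs["alpha"] > 0:
                    manifest.warn(
                        "sensitivity", "alpha-direction",
                        "the alpha index is positive: alpha sits in the detection "
                        "denominator, so increasing it weakens detection; narratives "
                        "reading alpha as awareness strength invert this direction",
                    )
            except DegenerateHorizonError as exc:
                manifest.warn("sensitivity", "degenerate-horizon", str(exc))
                emit("sensitivity.csv").write_text("parameter,index,sign,rank,interpretation\n")
        if "bifurcate" in config.stages:
            sw = config.blocks["sweep"]
            grid = np.linspace(sw["lo"], sw["hi"], int(sw["n"]))
            res = bifurcation_sweep(p, sw["parameter"], grid, t_end=sw["t_end"],
                                    x0=config.x0, y0=config.y0)
            res.to_frame().to_csv(emit("sweep.csv"), index=False, float_format="%.17g")
        if "basin" in config.stages:
            bb = config.blocks["basin"]
            n = int(bb["n"])
            g = np.linspace(1.0 / n, 1.0, n)
            basin = basin_of_attraction(p, g, g, t_end=bb["t_end"], threshold=bb["threshold"])
            basin.to_frame().to_csv(emit("basin.csv"), index=False, float_format="%.17g")
        if "portrait" in config.stages:
            port = phase_portrait(p, ics=table3_initial_conditions())
            emit("portrait.json").write_text(json.dumps(port.to_json_dict()))
        dataset = None
        if "generate-data" in config.stages:
            fb = config.blocks["fit"]
            times = np.linspace(0.0, fb["t_obs"], int(fb["n_points"]))
            dataset = generate_dataset(p, config.x0, config.y0, times=times,
                                       noise_sd=fb["noise_sd"], seed=seeds["generate-data"])
            dataset.write(emit("data.csv"))
            manifest.outputs.append("data.meta.json")
        if "fit" in config.stages:
            fb = config.blocks["fit"]
            if dataset is None:
                times = np.linspace(0.0, fb["t_obs"], int(fb["n_points"]))
                dataset = generate_dataset(p, config.x0, config.y0, times=times,
                                           noise_sd=fb["noise_sd"], seed=seeds["generate-data"])
            fit = fit_parameters(dataset, fb["free"], n_starts=int(fb["n_starts"]),
                                 seed=seeds["fit"])
            emit("fit.json").write_text(json.dumps({
                "estimates": fit.estimates,
                "fixed": fit.fixed,
                "residual_rms": fit.residual_rms,
                "converged": fit.converged,
                "n_evaluations": fit.n_evaluations,
            }, indent=2))
    except Exception:
        manifest.success = False
        (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    manifest.outputs.append("manifest.json")
    return manifest
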
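"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own solution paths:
``rk4_states`` is a fixed-step classical Runge-Kutta integrator and
``scan_roots`` a brute-force sign scan of the interior equilibrium equation,
both written against the raw equations.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings, HealthCheck

from earlydetect import NondimParams

hyp_settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")

#: The package's default parameter set, spelled out so oracle code in the
#: tests is independent of the packaged fixture.
DEFAULTS = dict(
    beta=0.5, gamma=0.1, kappa=3.0, delta=1.0, alpha=0.65,
    rho=1.0, mu=0.1, sigma=0.3, eta=0.1,
)
DEFAULT_IC = (0.35, 0.08)


@pytest.fixture(scope="session")
def table2() -> NondimParams:
    return NondimParams(**DEFAULTS)


@pytest.fixture(scope="session")
def benchmark(table2) -> NondimParams:
    """Persistent-tumor benchmark: defaults with weak detection."""
    return table2.replace(kappa=0.3)


def raw_rhs(x, y, p: NondimParams):
    """The model equations written out independently of the package."""
    dx = x * (1 - x) - p.beta * x * y / (p.gamma + y) - p.kappa * x / (p.alpha + p.delta * x)
    dy = p.rho * y * (1 - y) * x / (p.mu + x) - p.sigma * x * y - p.eta * y
    return dx, dy


def rk4_states(p: NondimParams, x0, y0, t_end, h=1e-3, sample_every=100):
    """Fixed-step classical RK4; returns (times, states) sampled coarsely."""
    n = int(round(t_end / h))
    x, y = float(x0), float(y0)
    times, states = [0.0], [(x, y)]
    for i in range(1, n + 1):
        k1 = raw_rhs(x, y, p)
        k2 = raw_rhs(x + h / 2 * k1[0], y + h / 2 * k1[1], p)
        k3 = raw_rhs(x + h / 2 * k2[0], y + h / 2 * k2[1], p)
        k4 = raw_rhs(x + h * k3[0], y + h * k3[1], p)
        x += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if i % sample_every == 0:
            times.append(i * h)
            states.append((x, y))
    return np.array(times), np.array(states)


def scan_roots(p: NondimParams, step=1e-4):
    """Brute-force sign scan of the interior equilibrium equation on (0, 1]."""
    xs = np.arange(step, 1.0 + step / 2, step)
    ys = 1.0 - (p.mu + xs) * (p.sigma * xs + p.eta) / (p.rho * xs)
    ok = (ys > 0) & (ys < 1)
    g = np.where(
        ok, 1 - xs - p.beta * ys / (p.gamma + ys) - p.kappa / (p.alpha + p.delta * xs), np.nan
    )
    roots = []
    for i in range(len(xs) - 1):
        if ok[i] and ok[i + 1] and g[i] * g[i + 1] < 0:
            roots.append(0.5 * (xs[i] + xs[i + 1]))
    return roots


def random_params(rng, lo=0.01, hi=5.0) -> NondimParams:
    """One parameter set with every rate log-uniform on [lo, hi]."""
    names = ("beta", "gamma", "kappa", "delta", "alpha", "rho", "mu", "sigma", "eta")
    vals = np.exp(rng.uniform(np.log(lo), np.log(hi), 9))
    return NondimParams(**dict(zip(names, vals)))
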
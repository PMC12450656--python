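"""Model structure: detection term, right-hand sides, Jacobian, rescaling."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, strategies as st

from earlydetect import (
    DimensionalParams,
    DomainError,
    NondimParams,
    ParameterError,
    detection_effect,
    jacobian,
    nondimensionalize,
    param_partials,
    rhs_dimensional,
    rhs_nondim,
)
from earlydetect.model_core import PARAM_NAMES

from conftest import DEFAULTS, random_params


def dim_params(**overrides) -> DimensionalParams:
    base = dict(a1=1.0, a2=1.0, a3=1.0, a4=1.0, a5=1.0, a6=1.0, a7=1.0, a8=1.0,
                a9=1.0, K=1.0, a=1.0, c_tilde=1.0, alpha_aw=1.0)
    base.update(overrides)
    return DimensionalParams(**base)


class TestDetectionEffect:
    def test_vanishes_at_zero_tumor(self):
        assert detection_effect(0.0, dim_params()) == 0.0

    def test_half_saturation_point(self):
        # K=1, a=1, alpha_aw=1, c_tilde=1 at C=1: 1/(1+1)
        assert detection_effect(1.0, dim_params()) == pytest.approx(0.5)

    def test_saturates_at_K_over_awareness_threshold(self):
        p = dim_params(K=3.0, a=0.65)
        assert detection_effect(1e6, p) == pytest.approx(3.0, abs=1e-4)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_monotone_in_tumor_size(self, c1, c2):
        p = dim_params(K=2.0, a=0.3, alpha_aw=0.8, c_tilde=1.5)
        lo, hi = sorted((c1, c2))
        assert detection_effect(hi, p) >= detection_effect(lo, p)

    def test_negative_tumor_rejected(self):
        with pytest.raises(DomainError):
            detection_effect(-1.0, dim_params())

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ParameterError):
            dim_params(a=0.0)
        with pytest.raises(ParameterError):
            dim_params(alpha_aw=-0.1)
        with pytest.raises(ParameterError):
            dim_params(c_tilde=0.0)


class TestDimensionalRhs:
    def test_origin_is_fixed(self):
        assert rhs_dimensional((0.0, 0.0), dim_params()) == (0.0, 0.0)

    def test_detection_off_reduces_to_base_model(self):
        """With K=0 the equations are the plain tumor-immune model."""
        p = dim_params(K=0.0, a1=0.8, a2=2.0, a3=0.4, a4=0.6, a5=1.1, a6=3.0,
                       a7=0.5, a8=0.2, a9=0.15)
        C, L = 0.7, 1.2
        dC, dL = rhs_dimensional((C, L), p)
        dC_base = p.a1 * C * (1 - C / p.a2) - p.a3 * C * L / (p.a4 + L)
        dL_base = p.a5 * L * (1 - L / p.a6) * C / (p.a7 + C) - p.a8 * C * L - p.a9 * L
        assert dC == pytest.approx(dC_base, rel=1e-15)
        assert dL == pytest.approx(dL_base, rel=1e-15)

    def test_pure_logistic_growth(self):
        p = dim_params(a3=0.0, K=0.0, a5=0.0, a8=0.0, a9=0.0)
        dC, _ = rhs_dimensional((0.5, 0.3), p)
        assert dC == pytest.approx(0.25)

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            rhs_dimensional((-0.1, 0.5), dim_params())


class TestNondimRhs:
    def test_origin_is_fixed(self, table2):
        assert tuple(rhs_nondim((0.0, 0.0), table2)) == (0.0, 0.0)

    def test_default_parameter_evaluation(self, table2):
        # term-by-term hand evaluation at (0.35, 0.08):
        # 0.35*0.65 - 0.5*0.35*0.08/0.18 - 3*0.35/1.0 = -0.9002777...
        # 0.08*0.92*0.35/0.45 - 0.3*0.35*0.08 - 0.1*0.08 = 0.0408444...
        dx, dy = rhs_nondim((0.35, 0.08), table2)
        assert dx == pytest.approx(-0.90027777777777778, rel=1e-12)
        assert dy == pytest.approx(0.04084444444444444, rel=1e-12)

    def test_logistic_fixed_point_without_interactions(self, table2):
        p = table2.replace(kappa=0.0, beta=0.0)
        assert tuple(rhs_nondim((1.0, 0.0), p)) == (0.0, 0.0)

    def test_detection_off_reduction(self, table2):
        """kappa=0 removes exactly the detection term for any state."""
        p = table2.replace(kappa=0.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.uniform(0, 1, 2)
            full = rhs_nondim((x, y), table2)
            off = rhs_nondim((x, y), p)
            assert off[0] - full[0] == pytest.approx(
                table2.kappa * x / (table2.alpha + table2.delta * x), rel=1e-12
            )
            assert off[1] == full[1]

    def test_negative_state_rejected(self, table2):
        with pytest.raises(DomainError):
            rhs_nondim((0.1, -0.2), table2)


class TestJacobian:
    def test_closed_form_at_origin(self, table2):
        J = jacobian((0.0, 0.0), table2)
        expected = [[1 - 3.0 / 0.65, 0.0], [0.0, -0.1]]
        np.testing.assert_allclose(J, expected, atol=1e-14)

    def test_matches_finite_differences_on_random_states(self):
        rng = np.random.default_rng(11)
        h = 1e-7
        for _ in range(100):
            p = random_params(rng)
            x, y = rng.uniform(0.05, 1.0, 2)
            J = jacobian((x, y), p)
            fd = np.empty((2, 2))
            fd[:, 0] = (rhs_nondim((x + h, y), p) - rhs_nondim((x - h, y), p)) / (2 * h)
            fd[:, 1] = (rhs_nondim((x, y + h), p) - rhs_nondim((x, y - h), p)) / (2 * h)
            np.testing.assert_allclose(J, fd, atol=1e-6)

    def test_symbolic_derivatives_match_implementation(self):
        """Differentiating the symbolic right-hand side reproduces both the
        Jacobian entries and the parameter-partials table term for term."""
        x, y = sp.symbols("x y", positive=True)
        syms = sp.symbols("beta gamma kappa delta alpha rho mu sigma eta", positive=True)
        beta, gamma, kappa, delta, alpha, rho, mu, sigma, eta = syms
        f1 = x * (1 - x) - beta * x * y / (gamma + y) - kappa * x / (alpha + delta * x)
        f2 = rho * y * (1 - y) * x / (mu + x) - sigma * x * y - eta * y
        vals = dict(zip(syms, [DEFAULTS[n] for n in PARAM_NAMES]))
        p = NondimParams(**{n: DEFAULTS[n] for n in PARAM_NAMES})
        state = {x: sp.Rational(35, 100), y: sp.Rational(8, 100)}
        J_sym = np.array([
            [float(sp.diff(f, v).subs(vals).subs(state)) for v in (x, y)]
            for f in (f1, f2)
        ])
        np.testing.assert_allclose(jacobian((0.35, 0.08), p), J_sym, rtol=1e-12)
        P_sym = np.array([
            [float(sp.diff(f, s).subs(vals).subs(state)) for s in syms]
            for f in (f1, f2)
        ])
        np.testing.assert_allclose(param_partials((0.35, 0.08), p), P_sym, rtol=1e-12)

    def test_nonpositive_denominator_rejected(self, table2):
        with pytest.raises(DomainError):
            jacobian((0.1, -table2.gamma), table2)


class TestNondimensionalize:
    @given(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5))
    def test_modes_agree_when_scales_are_unity(self, a3, K, a4):
        dp = dim_params(a3=a3, K=K, a4=a4)  # a1 = a2 = a6 = 1
        assert nondimensionalize(dp, "paper") == nondimensionalize(dp, "derived")

    def test_modes_differ_only_in_beta_and_kappa(self):
        dp = dim_params(a1=2.0, a2=10.0, a3=1.0, a6=5.0, K=4.0)
        paper = nondimensionalize(dp, "paper")
        derived = nondimensionalize(dp, "derived")
        assert paper.beta == pytest.approx(0.25)     # a3*a6/(a1*a2)
        assert derived.beta == pytest.approx(0.5)    # a3/a1
        assert paper.kappa == pytest.approx(2.0)     # K/a1
        assert derived.kappa == pytest.approx(0.2)   # K/(a1*a2)
        for name in ("gamma", "delta", "alpha", "rho", "mu", "sigma", "eta"):
            assert getattr(paper, name) == getattr(derived, name)

    def test_shared_formulas(self):
        dp = dim_params(a4=0.5, a6=5.0)
        for mode in ("paper", "derived"):
            assert nondimensionalize(dp, mode).gamma == pytest.approx(0.1)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ParameterError):
            nondimensionalize(dim_params(), "rescaled")


class TestParameterValidation:
    def test_detection_off_is_admissible(self, table2):
        assert table2.replace(kappa=0.0).kappa == 0.0

    def test_denominator_constants_must_be_positive(self):
        for name in ("gamma", "alpha", "mu"):
            with pytest.raises(ParameterError, match=name):
                NondimParams(**{**DEFAULTS, name: 0.0})

    def test_all_problems_reported_together(self):
        with pytest.raises(ParameterError) as exc:
            NondimParams(**{**DEFAULTS, "beta": -1.0, "eta": -2.0})
        assert "beta" in str(exc.value) and "eta" in str(exc.value)

    def test_dict_round_trip(self, table2):
        assert NondimParams.from_dict(table2.to_dict()) == table2
        with pytest.raises(ParameterError):
            NondimParams.from_dict({**table2.to_dict(), "extra": 1.0})
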
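"""Closed-form MK relations: PLL decay, lethal coefficients, survival,
alpha decomposition and error arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from mkmodel.core import (
    DomainGeometry,
    KineticRates,
    LQParameters,
    SingularKineticsError,
    alpha_decomposition,
    beta_from_kinetics,
    lethal_coefficients,
    pll_count,
    single_event_dose_mean,
    survival,
)
from mkmodel.uncertainty import ValueWithError


class TestPllCount:
    def test_no_decay_at_time_zero(self):
        rates = KineticRates(a=0.2, b_d=0.0, c=1.0, t_r=10.0)
        assert pll_count(rates, k_d=10.0, z=1.0, t=0.0) == 10.0

    def test_exponential_decay(self):
        rates = KineticRates(a=0.5, b_d=0.0, c=1.5, t_r=10.0)
        assert pll_count(rates, k_d=10.0, z=1.0, t=1.0) == pytest.approx(
            10.0 * math.exp(-2.0), rel=1e-12
        )

    def test_fast_removal_limit(self):
        rates = KineticRates(a=1e8, b_d=0.0, c=1e8, t_r=10.0)
        assert pll_count(rates, k_d=10.0, z=1.0, t=1.0) == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("bad", [{"t": -0.1}, {"z": -1.0}])
    def test_negative_inputs_rejected(self, bad):
        rates = KineticRates(a=0.5, b_d=0.0, c=1.5, t_r=10.0)
        kwargs = {"k_d": 10.0, "z": 1.0, "t": 1.0, **bad}
        with pytest.raises(ValueError):
            pll_count(rates, **kwargs)


class TestLethalCoefficients:
    def test_all_plls_lethal_without_repair(self):
        # c = 0 and a long deadline: every PLL converts first-order
        rates = KineticRates(a=0.4, b_d=0.05, c=0.0, t_r=200.0)
        k_d = 7.0
        coeffs = lethal_coefficients(rates, k_d)
        assert coeffs.A == pytest.approx(k_d, rel=1e-12)
        assert coeffs.B == pytest.approx(rates.b_d * k_d**2 / (2 * rates.a), rel=1e-12)

    def test_no_second_order_channel(self):
        rates = KineticRates(a=0.3, b_d=0.0, c=1.0, t_r=5.0)
        assert lethal_coefficients(rates, k_d=12.0).B == 0.0

    def test_matches_quadrature_of_linearized_kinetics(self):
        # independent oracle: integrate dL/dt = a P + b_d P**2 with the
        # exponential P(t), then add the PLLs surviving to the deadline
        rates = KineticRates(a=0.1, b_d=0.02, c=1.9, t_r=10.0)
        k_d = 25.0
        coeffs = lethal_coefficients(rates, k_d)
        ac = rates.a + rates.c
        for z in (0.3, 1.0, 2.5):
            def integrand(t):
                p = k_d * z * math.exp(-ac * t)
                return rates.a * p + rates.b_d * p**2

            integral, _ = quad(integrand, 0.0, rates.t_r, epsabs=1e-13, epsrel=1e-12)
            leftover = k_d * z * math.exp(-ac * rates.t_r)
            assert coeffs.lesions(z) == pytest.approx(integral + leftover, rel=1e-8)

    def test_singular_kinetics_rejected(self):
        with pytest.raises(SingularKineticsError):
            lethal_coefficients(KineticRates(a=0.0, b_d=0.1, c=0.0, t_r=5.0), k_d=1.0)


class TestBetaFromKinetics:
    GEOM = DomainGeometry(N=500)

    def test_exact_to_approximate_ratio_at_hawkins_threshold(self):
        # (a+c) t_r = 3 exactly: the finite-deadline factor is 1 - e^-6
        rates = KineticRates(a=1.0, b_d=0.01, c=2.0, t_r=1.0)
        with pytest.warns(UserWarning):  # exactly at, not above, the threshold
            res = beta_from_kinetics(rates, k=100.0, geometry=self.GEOM)
        assert res.exact / res.approximate == pytest.approx(1.0 - math.exp(-6.0), rel=1e-12)

    def test_zero_yield_gives_zero_beta(self):
        rates = KineticRates(a=1.0, b_d=0.01, c=2.0, t_r=5.0)
        res = beta_from_kinetics(rates, k=0.0, geometry=self.GEOM)
        assert res.exact == 0.0 and res.approximate == 0.0

    @given(
        k1=st.floats(1.0, 1e3),
        k2=st.floats(1.0, 1e3),
    )
    def test_beta_over_k_squared_is_invariant(self, k1, k2):
        rates = KineticRates(a=0.3, b_d=0.004, c=1.1, t_r=8.0)
        r1 = beta_from_kinetics(rates, k1, self.GEOM)
        r2 = beta_from_kinetics(rates, k2, self.GEOM)
        assert r1.exact / k1**2 == pytest.approx(r2.exact / k2**2, rel=1e-12)

    def test_doubling_k_quadruples_beta(self):
        rates = KineticRates(a=0.3, b_d=0.004, c=1.1, t_r=8.0)
        r1 = beta_from_kinetics(rates, 10.0, self.GEOM)
        r2 = beta_from_kinetics(rates, 20.0, self.GEOM)
        assert r2.exact == pytest.approx(4.0 * r1.exact, rel=1e-12)

    def test_warns_when_hawkins_condition_fails(self):
        rates = KineticRates(a=0.1, b_d=0.01, c=0.1, t_r=1.0)  # (a+c) t_r = 0.2
        with pytest.warns(UserWarning, match="exact beta"):
            res = beta_from_kinetics(rates, k=10.0, geometry=self.GEOM)
        assert res.value == res.exact

    def test_uses_approximation_when_condition_holds(self):
        rates = KineticRates(a=1.0, b_d=0.01, c=2.0, t_r=5.0)
        res = beta_from_kinetics(rates, k=10.0, geometry=self.GEOM)
        assert res.well_approximated and res.value == res.approximate


class TestSurvival:
    def test_unit_survival_at_zero_dose(self):
        assert survival(LQParameters(alpha=0.5, beta=0.1), 0.0) == 1.0

    def test_mean_inactivation_dose_of_reference_quality(self):
        # D solving alpha D + beta D**2 = 1 gives S = 1/e; root found by
        # brute-force bisection as the independent check
        lq = LQParameters(alpha=0.284, beta=0.0425)
        lo, hi = 0.0, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if lq.alpha * mid + lq.beta * mid**2 < 1.0:
                lo = mid
            else:
                hi = mid
        assert lo == pytest.approx(2.549, abs=5e-4)
        assert survival(lq, lo) == pytest.approx(math.exp(-1.0), rel=1e-9)

    @given(
        d1=st.integers(0, 10_000),
        d2=st.integers(0, 10_000),
    )
    def test_strictly_decreasing_in_dose(self, d1, d2):
        d1, d2 = d1 / 1000.0, d2 / 1000.0
        lq = LQParameters(alpha=0.2, beta=0.03)
        s1, s2 = survival(lq, d1), survival(lq, d2)
        if d1 < d2:
            assert s1 > s2
        elif d1 > d2:
            assert s1 < s2

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            survival(LQParameters(alpha=0.2, beta=0.03), -1.0)

    def test_vectorized_over_dose(self):
        lq = LQParameters(alpha=0.2, beta=0.03)
        out = survival(lq, np.array([0.0, 1.0, 2.0]))
        assert out.shape == (3,) and out[0] == 1.0


class TestAlphaDecomposition:
    def test_reference_quality_row(self):
        lq = LQParameters(alpha=0.284, beta=0.0425, alpha_se=0.051, beta_se=0.0083)
        a0 = alpha_decomposition(lq, y_d=4.51)
        assert a0.value == pytest.approx(0.245, abs=0.003)

    def test_cs137_row(self):
        lq = LQParameters(alpha=0.113, beta=0.0474)
        assert alpha_decomposition(lq, y_d=2.90).value == pytest.approx(0.085, abs=0.003)

    def test_zero_beta_leaves_alpha_unchanged(self):
        lq = LQParameters(alpha=0.3, beta=0.0, alpha_se=0.02)
        a0 = alpha_decomposition(lq, y_d=4.0)
        assert a0.value == 0.3 and a0.se == 0.02

    def test_nonfinite_yd_rejected(self):
        with pytest.raises(ValueError):
            alpha_decomposition(LQParameters(alpha=0.3, beta=0.01), y_d=math.nan)

    @given(y_d=st.floats(0.0, 20.0), beta=st.floats(0.0, 0.2))
    def test_alpha0_never_exceeds_alpha(self, y_d, beta):
        lq = LQParameters(alpha=0.5, beta=beta)
        assert alpha_decomposition(lq, y_d).value <= lq.alpha + 1e-15

    def test_unit_constant_from_dimensional_analysis(self):
        # 1 keV / (2/3 μm chord ... domain cross-section): with unit density
        # and r_d = 0.5 μm, z̄₁ = 0.1602/(π 0.25) Gy per keV/μm of y_D
        assert single_event_dose_mean(1.0) == pytest.approx(0.1602 / (math.pi * 0.25), rel=1e-12)


class TestValueWithError:
    def test_product_combines_relative_errors_in_quadrature(self):
        a, b = ValueWithError(2.0, 0.2), ValueWithError(5.0, 1.0)
        p = a * b
        assert p.value == 10.0
        assert p.rel_se == pytest.approx(math.hypot(0.1, 0.2), rel=1e-12)

    def test_sqrt_halves_relative_error(self):
        x = ValueWithError(4.0, 0.8)
        r = x**0.5
        assert r.value == 2.0 and r.rel_se == pytest.approx(0.1, rel=1e-12)

    def test_difference_combines_absolute_errors(self):
        d = ValueWithError(1.0, 0.3) - ValueWithError(0.4, 0.4)
        assert d.value == pytest.approx(0.6) and d.se == pytest.approx(0.5)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            ValueWithError(1.0, -0.1)

    def test_scalar_operations(self):
        x = 2.0 * ValueWithError(3.0, 0.3)
        assert x.value == 6.0 and x.se == pytest.approx(0.6)


class TestDomainTypes:
    @pytest.mark.parametrize("kwargs", [{"r_d": 0.0}, {"rho": -1.0}, {"N": 0}])
    def test_geometry_invariants(self, kwargs):
        with pytest.raises(ValueError):
            DomainGeometry(**kwargs)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticRates(a=-0.1, b_d=0.0, c=1.0, t_r=5.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            LQParameters(alpha=0.1, beta=-0.01)

    def test_hawkins_flag(self):
        assert KineticRates(a=1.0, b_d=0.0, c=1.0, t_r=2.0).well_approximated
        assert not KineticRates(a=1.0, b_d=0.0, c=1.0, t_r=1.0).well_approximated
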
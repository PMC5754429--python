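"""Kernel families: allometric homogeneity, normalisation, doubling period."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import planktospec as pk
from planktospec.errors import DomainError, InfeasibleGrowthError, KernelError

# independently computed by adaptive quadrature of the doubling-period
# integrand with the canonical constants (a=0.7, b=0.5, alpha=0.85, beta=1)
TAU_CANONICAL = 2.9418599140686577


class TestGrowthRate:
    def test_value_at_maximum_size(self, gp):
        # g(1) = a - b regardless of exponents
        assert pk.growth_rate(1.0, 1.0, gp, 0.7) == pytest.approx(0.2, abs=1e-15)

    def test_pure_exponential_limit(self):
        # b -> 0, alpha = 1, xi -> 0: G = a w
        gp = pk.GrowthParams(a_inf=1.0, b=1e-12, alpha=1.0, beta=2.0, xi=1e-12)
        for w in (0.3, 1.0, 7.5):
            assert pk.growth_rate(w, 10.0, gp, 0.5) == pytest.approx(0.5 * w, rel=1e-6)

    def test_positive_on_interval_when_a_exceeds_b(self, gp):
        w = np.linspace(1e-3, 1.0, 50)
        assert np.all(pk.growth_rate(w, 1.0, gp, 0.7) > 0)

    def test_rejects_nonpositive_sizes(self, gp):
        with pytest.raises(DomainError):
            pk.growth_rate(0.0, 1.0, gp, 0.7)
        with pytest.raises(DomainError):
            pk.growth_rate(0.5, -1.0, gp, 0.7)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(lam=st.sampled_from([0.5, 2.0, 10.0]),
           x=st.floats(0.05, 1.0), w_star=st.floats(0.01, 100.0))
    def test_homogeneity_degree_one_minus_xi(self, gp, lam, x, w_star):
        w = x * w_star
        lhs = pk.growth_rate(lam * w, lam * w_star, gp, 0.7)
        rhs = lam ** (1 - gp.xi) * pk.growth_rate(w, w_star, gp, 0.7)
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)


class TestMonod:
    def test_limits_and_half_saturation(self, gp):
        assert pk.monod_uptake(0.0, gp) == 0.0
        assert pk.monod_uptake(gp.r, gp) == pytest.approx(gp.a_inf / 2, rel=1e-14)
        assert pk.monod_uptake(1e9, gp) == pytest.approx(gp.a_inf, rel=1e-6)

    def test_monotone_and_inverse(self, gp):
        Ns = np.linspace(0.0, 10.0, 40)
        a = pk.monod_uptake(Ns, gp)
        assert np.all(np.diff(a) > 0)
        for N in (0.3, 1.7, 6.0):
            assert pk.nutrient_for_uptake(pk.monod_uptake(N, gp), gp) == \
                pytest.approx(N, rel=1e-12)

    def test_negative_nutrient_rejected(self, gp):
        with pytest.raises(DomainError):
            pk.monod_uptake(-0.1, gp)


class TestDoublingTime:
    def test_canonical_tau_regression(self, gp):
        assert pk.tau_constant(gp, 0.7) == pytest.approx(TAU_CANONICAL, rel=1e-10)

    def test_allometric_scaling_T_ratio(self, gp):
        for ws in (0.01, 1.0, 30.0):
            ratio = pk.doubling_time(2 * ws, gp, 0.7) / pk.doubling_time(ws, gp, 0.7)
            assert ratio == pytest.approx(2 ** gp.xi, rel=1e-12)

    def test_tau_power_law_across_decades(self, gp):
        tau = pk.tau_constant(gp, 0.7)
        for ws in (1e-2, 1.0, 1e2, 1e4):
            assert pk.doubling_time(ws, gp, 0.7) == \
                pytest.approx(tau * ws ** gp.xi, rel=1e-8)

    def test_closed_form_alpha_zero(self):
        # alpha=0, beta=1: tau = (1/b) log((a - b/2)/(a - b))
        gp = pk.GrowthParams(a_inf=1.4, b=0.5, alpha=0.0, beta=1.0, xi=0.15)
        a = 0.7
        expected = (1 / gp.b) * np.log((a - gp.b / 2) / (a - gp.b))
        assert pk.tau_constant(gp, a) == pytest.approx(expected, rel=1e-12)

    def test_stalling_growth_is_infeasible(self, gp):
        with pytest.raises(InfeasibleGrowthError):
            pk.doubling_time(1.0, gp, gp.b)


class TestDivisionKernel:
    def test_rate_shape_values(self, ds, gp):
        # k(x) = 4 (x - 0.7)^2 / (1 - x)
        assert ds.k(0.7) == 0.0
        assert ds.k(0.9) == pytest.approx(4 * 0.2 ** 2 / 0.1, rel=1e-14)
        assert pk.division_rate(0.9, 1.0, ds, gp) == pytest.approx(1.6, rel=1e-14)

    def test_pole_returns_inf_not_nan(self, ds, gp):
        val = pk.division_rate(1.0, 1.0, ds, gp)
        assert np.isinf(val) and not np.isnan(val)

    def test_hazard_integral_diverges(self, ds):
        # integral to 1 - eps keeps growing as eps is squared
        i1, _ = quad(ds.k, ds.xth, 1 - 1e-4, limit=200)
        i2, _ = quad(ds.k, ds.xth, 1 - 1e-8, limit=200)
        assert i2 - i1 > 0.9 * (i1 - quad(ds.k, ds.xth, 1 - 1e-2, limit=200)[0])

    def test_homogeneity_degree_minus_xi(self, ds, gp):
        for lam in (0.5, 2.0, 10.0):
            lhs = pk.division_rate(lam * 0.85, lam * 1.0, ds, gp)
            rhs = lam ** (-gp.xi) * pk.division_rate(0.85, 1.0, ds, gp)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_daughter_overlap_with_threshold_rejected(self):
        with pytest.raises(KernelError):
            pk.DivisionSpec.sloppy(xth=0.5, delta=0.2)

    def test_convergent_rate_shape_rejected(self):
        with pytest.raises(KernelError):
            pk.DivisionSpec(xth=0.7, delta=0.2,
                            k_shape=lambda x: 4 * (x - 0.7) ** 2,  # no pole
                            q_shape=lambda x: np.full_like(x, 5.0))


class TestDaughterDensity:
    @pytest.mark.parametrize("w_parent", [1.0, 10.0])
    def test_normalisation(self, ds, w_parent):
        val, _ = quad(lambda w: pk.daughter_density(w, w_parent, ds),
                      0.0, w_parent, limit=200)
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_uniform_height(self, ds):
        # uniform on [0.4, 0.6]: q = 1/0.2 = 5
        assert ds.q(0.5) == pytest.approx(5.0, rel=1e-14)
        assert ds.q(0.39) == 0.0 and ds.q(0.61) == 0.0

    def test_symmetry_and_mean_half_parent(self, ds):
        xs = np.linspace(0.401, 0.599, 41)
        assert np.allclose(ds.q(xs), ds.q(1 - xs), rtol=1e-12)
        mean, _ = quad(lambda w: w * pk.daughter_density(w, 3.0, ds), 0, 3.0,
                       limit=200)
        assert mean == pytest.approx(1.5, rel=1e-10)

    def test_scaling_degree_minus_one(self, ds):
        for lam in (0.5, 2.0, 10.0):
            lhs = pk.daughter_density(lam * 0.5, lam * 1.0, ds)
            rhs = pk.daughter_density(0.5, 1.0, ds) / lam
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_asymmetric_daughter_density_rejected(self):
        with pytest.raises(KernelError):
            pk.DivisionSpec(xth=0.7, delta=0.2,
                            k_shape=lambda x: 4 * (x - 0.7) ** 2 / (1 - x),
                            q_shape=lambda x: 50 * (x - 0.39))


class TestMortality:
    def test_constant_shape_is_size_independent(self, gp):
        ms = pk.MortalitySpec.constant(0.3)
        w = np.array([0.2, 0.5, 0.9])
        out = pk.mortality_rate(w, 1.0, ms, gp)
        assert np.allclose(out, 0.3)
        assert pk.mortality_rate(0.5, 2.0, ms, gp) == \
            pytest.approx(0.3 * 2 ** (-gp.xi), rel=1e-14)

    def test_homogeneity_at_lambda_three(self, gp, m01):
        lhs = pk.mortality_rate(3 * 0.6, 3 * 1.0, m01, gp)
        rhs = 3 ** (-gp.xi) * pk.mortality_rate(0.6, 1.0, m01, gp)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_mortality_limit(self, gp):
        ms = pk.MortalitySpec.zero()
        assert pk.mortality_rate(0.7, 5.0, ms, gp) == 0.0


class TestGrowthParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(alpha=1.0, beta=0.85),       # alpha >= beta
        dict(a_inf=0.4, b=0.5),           # a_inf <= b
        dict(xi=1.5),                     # xi outside (0,1)
        dict(r=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            pk.GrowthParams(**kwargs)
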
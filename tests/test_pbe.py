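"""Time-dependent PBE simulator: conservation bookkeeping, oracle
equivalence with the analytic steady states, scale invariance."""

import numpy as np
import pytest

import planktospec as pk
from planktospec.errors import CFLError, EstimationError
from planktospec.pbe import division_operator, rhs


@pytest.fixture(scope="module")
def grid():
    return pk.make_grid(256)


@pytest.fixture(scope="module")
def cfg_growth_only(gp, ds, grid):
    return pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.zero(), grid=grid,
                        a_fixed=0.7)


def cohort_state(grid, w_stars=(1.0,)):
    x = grid.centers
    p = np.exp(-(x - 0.5) ** 2 / (2 * 0.05 ** 2))
    p /= np.trapezoid(p, x)
    ws = np.asarray(w_stars, float)
    return pk.PBEState(w_stars=ws, p=np.tile(p, (ws.size, 1)))


class TestDivisionOperator:
    def test_each_parent_yields_two_daughters_with_parent_biomass(self, grid, ds):
        k, Dg = division_operator(grid, ds)
        for j in np.nonzero(k > 0)[0][::13]:
            num = float(Dg[:, j] @ grid.widths) / (k[j] * grid.widths[j])
            bio = float(Dg[:, j] @ (grid.widths * grid.centers)) \
                / (k[j] * grid.widths[j] * grid.centers[j])
            assert num == pytest.approx(2.0, abs=1e-12)
            assert bio == pytest.approx(1.0, abs=1e-12)

    def test_daughters_land_in_the_daughter_band(self, grid, ds):
        k, Dg = division_operator(grid, ds)
        for j in np.nonzero(k > 0)[0][::29]:
            recv = np.nonzero(Dg[:, j])[0]
            lo, hi = grid.centers[recv[0]], grid.centers[recv[-1]]
            assert lo >= 0.4 * grid.centers[j] - grid.widths[recv[0]]
            assert hi <= 0.6 * grid.centers[j] + grid.widths[recv[-1]]


class TestStep:
    def test_identity_without_any_process(self, gp, ds, grid):
        # zero uptake at b -> 0 limit makes growth vanish; no division
        # reachable below threshold; no mortality: state unchanged
        gp0 = pk.GrowthParams(a_inf=1.0, b=1e-12, alpha=0.85, beta=1.0, xi=0.15)
        cfg = pk.SimConfig(gp=gp0, ds=ds, mb=pk.MortalitySpec.zero(),
                           grid=grid, a_fixed=1e-12)
        state = cohort_state(grid)
        state.p[:, grid.centers > ds.xth] = 0.0   # keep below the threshold
        new = pk.step(state, cfg, 1e-3)
        # residual motion is the 1e-12-scale vestigial growth velocity only
        assert np.allclose(new.p, state.p, rtol=0, atol=1e-13)

    def test_cfl_violation_refused(self, cfg_growth_only, grid):
        state = cohort_state(grid)
        with pytest.raises(CFLError):
            pk.step(state, cfg_growth_only, 1e3)

    def test_number_nondecreasing_without_death(self, cfg_growth_only, grid):
        state = cohort_state(grid)
        res = pk.simulate(state, 3.0, cfg_growth_only, record_every=10)
        assert np.all(np.diff(res.number) >= -1e-12)

    def test_biomass_balance_per_division_step(self, cfg_growth_only, grid, ds):
        # the discrete division operator moves biomass from parents to
        # daughters exactly: two daughters of half the parent size each, so
        # the biomass gain rate equals the biomass loss rate
        state = cohort_state(grid)
        state.p[0] = np.exp(-(grid.centers - 0.85) ** 2 / (2 * 0.03 ** 2))
        k, Dg = cfg_growth_only._div
        gain_bio = float((Dg @ state.p[0]) @ (grid.centers * grid.widths))
        loss_bio = float((k * state.p[0]) @ (grid.centers * grid.widths))
        assert gain_bio == pytest.approx(loss_bio, rel=1e-12)
        # and the number gain rate is exactly twice the number loss rate
        gain_num = float((Dg @ state.p[0]) @ grid.widths)
        loss_num = float((k * state.p[0]) @ grid.widths)
        assert gain_num == pytest.approx(2 * loss_num, rel=1e-12)

    def test_nonnegativity_preserved(self, cfg_growth_only, grid):
        state = cohort_state(grid)
        res = pk.simulate(state, 5.0, cfg_growth_only, record_every=50)
        assert np.all(res.final.p >= 0)


class TestNutrientDerivative:
    def test_empty_chemostat_at_capacity(self, gp, ds, grid):
        nut = pk.canonical_chemostat()
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.zero(),
                           grid=grid, nutrient=nut)
        state = cohort_state(grid)
        state.p[:] = 0.0
        state.N = nut.N0
        assert pk.pbe.nutrient_derivative(state, cfg) == pytest.approx(0.0, abs=1e-14)
        state.N = 0.5 * nut.N0
        assert pk.pbe.nutrient_derivative(state, cfg) > 0

    def test_consumption_linear_in_density(self, gp, ds, grid):
        nut = pk.canonical_chemostat()
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.zero(),
                           grid=grid, nutrient=nut)
        state = cohort_state(grid)
        state.N = 1.0
        d1 = nut.replenishment(1.0) - pk.pbe.nutrient_derivative(state, cfg)
        state.p *= 2.0
        d2 = nut.replenishment(1.0) - pk.pbe.nutrient_derivative(state, cfg)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)


class TestGrowthRateMeasurement:
    def test_exact_exponential(self):
        t = np.linspace(0, 10, 200)
        assert pk.measure_growth_rate(t, np.exp(0.3 * t)) == \
            pytest.approx(0.3, abs=1e-10)
        assert pk.measure_growth_rate(t, 7.5 * np.exp(0.3 * t)) == \
            pytest.approx(0.3, abs=1e-10)

    def test_refuses_non_growing_series(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(EstimationError):
            pk.measure_growth_rate(t, np.exp(-0.1 * t) + 0.5 * np.sin(t) ** 2)

    def test_simulated_rate_matches_eigenvalue(self, gp, ds, cohort_initial):
        # the dynamic population growth rate agrees with the renewal
        # eigenvalue from quadrature to 1e-3 relative
        grid = pk.make_grid(512)
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.zero(),
                           grid=grid, a_fixed=0.7)
        state = pk.PBEState(w_stars=np.array([1.0]),
                            p=cohort_initial(grid)[None, :].copy())
        res = pk.simulate(state, 60.0, cfg, record_every=25)
        lam_sim = pk.measure_growth_rate(res.times, res.number, window=0.3)
        lam_eig = pk.solve_growth_eigenvalue(1.0, ds, gp, 0.7).Lambda
        assert lam_sim == pytest.approx(lam_eig, rel=1e-3)

    def test_scale_free_rate_from_simulation(self, gp, ds, cohort_initial):
        grid = pk.make_grid(256)
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.zero(),
                           grid=grid, a_fixed=0.7)
        ells = []
        for ws in (1.0, 10.0, 100.0):
            state = pk.PBEState(w_stars=np.array([ws]),
                                p=cohort_initial(grid)[None, :].copy())
            res = pk.simulate(state, 40.0 * ws ** 0.15, cfg, record_every=25)
            lam = pk.measure_growth_rate(res.times, res.number, window=0.3)
            ells.append(lam * ws ** gp.xi)
        assert max(ells) / min(ells) - 1 < 1e-3


class TestSteadyStateOracle:
    def test_chemostat_run_converges_to_psi(self, gp, ds, m01, cohort_initial):
        # settled nutrient and profile agree with the analytic solution
        grid = pk.make_grid(512)
        nut = pk.canonical_chemostat(N=1.0)
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=m01, grid=grid, nutrient=nut)
        state = pk.PBEState(w_stars=np.array([1.0]),
                            p=cohort_initial(grid)[None, :].copy(), N=1.0)
        res = pk.simulate(state, 120.0, cfg, record_every=200)
        prof = pk.build_general_profile(ds, m01, gp, N_star=res.final.N)
        x = grid.centers
        sim = res.final.p[0] / np.trapezoid(res.final.p[0], x)
        psi = prof(x) / np.trapezoid(prof(x), x)
        assert np.trapezoid(np.abs(sim - psi), x) < 1e-2
        N_star = pk.solve_nutrient_general(ds, m01, gp, N_hi=nut.N0)
        assert res.final.N == pytest.approx(N_star, rel=5e-3)

    def test_grid_refinement_improves_profile(self, gp, ds, m01, cohort_initial):
        # first-order scheme: halving the cell width reduces the L1 error
        errs = []
        for n in (128, 256):
            grid = pk.make_grid(n)
            nut = pk.canonical_chemostat(N=1.0)
            cfg = pk.SimConfig(gp=gp, ds=ds, mb=m01, grid=grid, nutrient=nut)
            state = pk.PBEState(w_stars=np.array([1.0]),
                                p=cohort_initial(grid)[None, :].copy(), N=1.0)
            res = pk.simulate(state, 120.0, cfg, record_every=200)
            prof = pk.build_general_profile(ds, m01, gp, N_star=res.final.N)
            x = grid.centers
            sim = res.final.p[0] / np.trapezoid(res.final.p[0], x)
            psi = prof(x) / np.trapezoid(prof(x), x)
            errs.append(np.trapezoid(np.abs(sim - psi), x))
        assert errs[0] / errs[1] > 1.5

    def test_idealised_division_is_periodic_not_convergent(self, gp, ds_ideal,
                                                           cohort_initial):
        # a cohort returns to its shape after one doubling period instead of
        # settling: the profile distance after a full period is much smaller
        # than after half a period
        grid = pk.make_grid(512, x_min=0.4)
        cfg = pk.SimConfig(gp=gp, ds=ds_ideal, mb=pk.MortalitySpec.zero(),
                           grid=grid, a_fixed=0.7)
        x = grid.centers
        p = np.exp(-(x - 0.7) ** 2 / (2 * 0.03 ** 2))
        state = pk.PBEState(w_stars=np.array([1.0]), p=(p / np.trapezoid(p, x))[None, :])
        T = pk.doubling_time(1.0, gp, 0.7)
        res = pk.simulate(state, 3 * T, cfg,
                          snapshot_times=[2 * T, 2.5 * T, 3 * T])
        def norm_shape(st):
            v = st.p[0]
            return v / np.trapezoid(v, x)
        full = np.trapezoid(np.abs(norm_shape(res.snapshots[2])
                                   - norm_shape(res.snapshots[0])), x)
        half = np.trapezoid(np.abs(norm_shape(res.snapshots[1])
                                   - norm_shape(res.snapshots[0])), x)
        assert full < 0.5 * half
        # and the population doubles over each period (boundary reinjection)
        n0 = res.snapshots[0].total_number(grid)
        n1 = res.snapshots[2].total_number(grid)
        assert n1 / n0 == pytest.approx(2.0, rel=0.05)


class TestScaleTransform:
    def test_identity_and_composition(self, grid):
        state = cohort_state(grid, w_stars=(0.5, 1.0, 2.0))
        st1 = pk.scale_transform(state, 1.0, 2.0)
        assert np.allclose(st1.p, state.p) and np.allclose(st1.w_stars, state.w_stars)
        a = pk.scale_transform(pk.scale_transform(state, 2.0, 2.0), 3.0, 2.0)
        b = pk.scale_transform(state, 6.0, 2.0)
        assert np.allclose(a.p, b.p, rtol=1e-12)
        assert np.allclose(a.w_stars, b.w_stars, rtol=1e-12)

    def test_transformed_coupled_steady_state_stays_steady(self, gp, ds,
                                                           coupled_general):
        # the coupled power-law steady state, scale-transformed by lambda=2,
        # has the same PBE residual as the untransformed state (community
        # predation integrals evaluated on the finite assemblage)
        sol = coupled_general
        asm = pk.make_assemblage(48, 1e-4, 1e4)
        grid = pk.make_grid(96)
        state = pk.state_from_profiles(
            asm.w_stars, grid, sol.phyto_profile, sol.p_norm(asm.w_stars),
            zoo_profile=sol.zoo_profile, zoo_norms=sol.z_norm(asm.w_stars),
            trait_weights=asm.trapezoid_weights(), N=sol.N_hat)
        cfg = pk.SimConfig(gp=gp, ds=ds, mb=pk.MortalitySpec.constant(0.05),
                           grid=grid, a_fixed=sol.a_hat,
                           coupling=pk.CommunityCoupling(pk.canonical_predation()))
        r_orig = pk.steady_residual_norm(state, cfg)
        for lam in (0.5, 2.0):
            r_tran = pk.steady_residual_norm(
                pk.scale_transform(state, lam, sol.gamma), cfg)
            interior = slice(18, 30)
            ratio = r_tran[interior].mean() / r_orig[interior].mean()
            assert 0.5 < ratio < 2.0
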
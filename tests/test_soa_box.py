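import numpy as np
import pytest

from smlvoc.photo_potential import PhotochemConfig, PotentialField
from smlvoc.soa_box import (
    BoxState,
    VBSConfig,
    box_run,
    box_step,
    cstar_at_T,
    mixing_ratio,
    partition_equilibrium,
    soa_contribution_map,
    steady_state_voc,
)
from smlvoc.voc_emissions import Species

EXAMPLE = dict(E=4.1e9, h_m=600.0, c_poa=0.4, temperature_c=20.0)


def brute_force_partition(totals, cstar, seed, n_scan=4000, n_bisect=80):
    """Independent absorbing-mass scan: locate the fixed point of
    C_abs = seed + sum(totals / (1 + cstar/C_abs)) on a dense grid, then
    refine by bisection."""
    tot = totals.sum()
    if tot == 0:
        return 0.0

    def g(c):
        return seed + np.sum(totals / (1.0 + cstar / c)) - c

    lo, hi = max(seed, 1e-12), seed + tot + 1e-12
    grid = np.geomspace(lo, hi, n_scan)
    vals = np.array([g(c) for c in grid])
    if vals[-1] >= 0:
        c = hi
    else:
        i = int(np.argmax(vals < 0))
        a, b = grid[max(i - 1, 0)], grid[i]
        for _ in range(n_bisect):
            m = 0.5 * (a + b)
            if g(m) >= 0:
                a = m
            else:
                b = m
        c = 0.5 * (a + b)
    xi = 1.0 / (1.0 + cstar / c)
    return float((xi * totals).sum())


class TestCstarShift:
    def test_reference_temperature_identity(self):
        cs = cstar_at_T(np.arange(-3, 7, dtype=float), 300.0, 30.0)
        np.testing.assert_allclose(cs, 10.0 ** np.arange(-3, 7), rtol=1e-12)

    def test_switch_off_is_identity_at_any_temperature(self):
        cs = cstar_at_T(np.array([0.0]), 250.0, None)
        assert cs[0] == 1.0

    def test_clausius_clapeyron_value_at_288K(self):
        # (300/288) * exp(30000/R * (1/300 - 1/288)) evaluated by hand
        expect = (300 / 288) * np.exp(30000 / 8.314462618 * (1 / 300 - 1 / 288))
        assert expect == pytest.approx(0.6311, abs=2e-4)
        assert cstar_at_T(np.array([0.0]), 288.0, 30.0)[0] == pytest.approx(
            expect, rel=1e-12
        )

    def test_cooling_lowers_volatility(self):
        warm = cstar_at_T(np.array([2.0]), 300.0, 30.0)[0]
        cold = cstar_at_T(np.array([2.0]), 280.0, 30.0)[0]
        assert cold < warm


class TestPartitionEquilibrium:
    def test_all_zero_totals(self):
        G, P, c = partition_equilibrium(np.zeros(10), np.ones(10), 0.0)
        assert c == 0.0 and not P.any() and not G.any()

    def test_single_bin_supersaturated_closed_form(self):
        # one bin, total T*, C*: C_OA = T* - C* when T* > C*, seedless
        G, P, c = partition_equilibrium(np.array([2.0]), np.array([1.0]), 0.0)
        assert c == pytest.approx(1.0, rel=1e-9)
        assert P[0] == pytest.approx(1.0, rel=1e-9)
        assert G[0] == pytest.approx(1.0, rel=1e-9)

    def test_single_bin_subsaturated_all_gas(self):
        G, P, c = partition_equilibrium(np.array([0.5]), np.array([1.0]), 0.0)
        assert c == 0.0 and P[0] == 0.0 and G[0] == 0.5

    def test_mass_conservation_and_xi_bounds(self, rng):
        for _ in range(50):
            totals = rng.uniform(0, 5, size=10)
            cstar = 10.0 ** np.arange(-3, 7, dtype=float)
            seed = rng.uniform(0, 2)
            G, P, c = partition_equilibrium(totals, cstar, seed)
            np.testing.assert_allclose(G + P, totals, rtol=1e-12, atol=1e-300)
            xi = np.divide(P, totals, out=np.zeros_like(P), where=totals > 0)
            assert np.all((xi >= 0) & (xi <= 1))
            # xi monotone decreasing in C*
            pos = totals > 0
            assert np.all(np.diff(xi[pos]) <= 1e-12)

    def test_matches_bruteforce_scan(self, rng):
        cstar = 10.0 ** np.arange(-3, 7, dtype=float)
        for _ in range(100):
            totals = rng.uniform(0, 3, size=10) * (rng.random(10) < 0.7)
            seed = float(rng.choice([0.0, rng.uniform(0.01, 1.0)]))
            _, _, c = partition_equilibrium(totals, cstar, seed)
            expect = brute_force_partition(totals, cstar, seed)
            assert c == pytest.approx(expect, rel=1e-4, abs=1e-10)


class TestBoxStep:
    def test_quiescent_state_unchanged(self):
        cfg = VBSConfig()
        s0 = BoxState(0.0, 0.0, np.zeros(10), np.zeros(10), 0.4)
        s1 = box_step(s0, 60.0, 0.0, 6.0e4, cfg)
        assert s1.c_voc == 0.0 and s1.delta_oa == 0.0

    def test_first_step_from_zero_is_pure_emission(self):
        cfg = VBSConfig()
        s0 = BoxState(0.0, 0.0, np.zeros(10), np.zeros(10), 0.4)
        s1 = box_step(s0, 60.0, 4.1e9, 6.0e4, cfg)
        assert s1.c_voc == pytest.approx(60.0 * 4.1e9 / 6.0e4, rel=1e-12)

    def test_mass_closure_per_step(self):
        cfg = VBSConfig()
        state = BoxState(0.0, 5.0e8, np.zeros(10), np.zeros(10), 0.4)
        before = (state.G + state.P).sum()
        new = box_step(state, 60.0, 0.0, 6.0e4, cfg)
        oxidised = 60.0 * cfg.k_first_order * 5.0e8
        dm = oxidised * 68.0 * 1e12 / 6.02214076e23
        expect_gain = sum(cfg.alpha) * dm
        assert (new.G + new.P).sum() - before == pytest.approx(expect_gain,
                                                               rel=1e-12)

    def test_stability_guard(self):
        cfg = VBSConfig()
        s0 = BoxState(0.0, 0.0, np.zeros(10), np.zeros(10), 0.4)
        with pytest.raises(ValueError, match="stability"):
            box_step(s0, 1.0e4, 0.0, 6.0e4, cfg)


class TestBoxRun:
    def test_precursor_monotone_and_bounded_by_steady_state(self):
        traj = box_run(**EXAMPLE)
        css = steady_state_voc(EXAMPLE["E"], EXAMPLE["h_m"], VBSConfig())
        assert np.all(np.diff(traj.c_voc) >= -1e-9)
        assert np.all(traj.c_voc <= css * (1 + 1e-9))
        assert traj.c_voc[-1] == pytest.approx(css, rel=1e-2)

    def test_plateau_matches_analytic_within_1pct(self):
        traj = box_run(duration_h=8.0, **EXAMPLE)
        css = steady_state_voc(EXAMPLE["E"], EXAMPLE["h_m"], VBSConfig())
        assert traj.c_voc[-1] == pytest.approx(css, rel=1e-2)
        assert css == pytest.approx(4.0e8, rel=5e-2)

    def test_delta_oa_nondecreasing(self):
        traj = box_run(**EXAMPLE)
        assert np.all(np.diff(traj.delta_oa) >= -1e-12)

    def test_timestep_convergence(self):
        coarse = box_run(dt=60.0, **EXAMPLE)
        fine = box_run(dt=30.0, **EXAMPLE)
        assert fine.delta_oa[-1] == pytest.approx(coarse.delta_oa[-1], rel=5e-3)
        assert fine.c_voc[-1] == pytest.approx(coarse.c_voc[-1], rel=5e-3)

    def test_no_emission_stays_flat_zero(self):
        traj = box_run(0.0, 600.0, 0.4, 20.0)
        assert not traj.c_voc.any() and not traj.delta_oa.any()

    def test_literature_yield_alignment_produces_far_less_aerosol(self):
        default = box_run(**EXAMPLE)
        lit = box_run(cfg=VBSConfig.with_literature_yields(), **EXAMPLE)
        assert lit.delta_oa[-1] < 0.1 * default.delta_oa[-1]


class TestMixingRatio:
    def test_zero_is_zero(self):
        assert mixing_ratio(0.0, 293.15) == 0.0

    def test_air_number_density_ideal_gas(self):
        n_air = 101325 / (1.380649e-23 * 293.0) * 1e-6
        assert n_air == pytest.approx(2.504e19, rel=1e-3)
        # one part per trillion of that density maps back to 1 ppt
        assert mixing_ratio(n_air * 1e-12, 293.0) == pytest.approx(1.0, rel=1e-12)

    def test_example_number_density(self):
        assert mixing_ratio(4.15e8, 293.0) == pytest.approx(16.6, abs=0.1)


class TestContributionMap:
    def _potential(self, value, shape=(4, 6)):
        vals = np.full((12,) + shape, float(value))
        return PotentialField(vals, np.linspace(-30, 30, shape[0]),
                              np.linspace(-60, 60, shape[1]), PhotochemConfig())

    def _species(self):
        return Species("alkene-mix", 1.0, 1.0, molar_mass=68.0, unsaturated=True)

    def test_zero_emission_gives_zero_percent(self):
        seasons = soa_contribution_map(self._potential(0.0), self._species(),
                                       0.4, 600.0)
        for frac in seasons.values():
            np.testing.assert_allclose(frac, 0.0)

    def test_worked_example_uniform_inputs_near_22pct(self):
        # mu chosen so voc_lab * mu spread over the 12-h window equals the
        # example emission rate of 4.1e9 molecules cm-2 s-1
        mu = 4.1e9 * 12 * 3600.0
        seasons = soa_contribution_map(
            self._potential(mu), self._species(), 0.4, 600.0,
            temperature_c=20.0, voc_lab=1.0,
        )
        for frac in seasons.values():
            np.testing.assert_allclose(frac, 21.2, atol=1.5)

    def test_shallower_mbl_increases_aerosol(self):
        mu = 4.1e9 * 12 * 3600.0
        deep = soa_contribution_map(self._potential(mu), self._species(),
                                    0.4, 600.0, temperature_c=20.0, voc_lab=1.0)
        shallow = soa_contribution_map(self._potential(mu), self._species(),
                                       0.4, 300.0, temperature_c=20.0, voc_lab=1.0)
        assert np.all(shallow["Jan-Mar"] > deep["Jan-Mar"])

    def test_closed_form_matches_time_stepping(self):
        traj = box_run(**EXAMPLE)
        mu = 4.1e9 * 12 * 3600.0
        seasons = soa_contribution_map(
            self._potential(mu, shape=(1, 1)), self._species(), 0.4, 600.0,
            temperature_c=20.0, voc_lab=1.0,
        )
        frac = seasons["Jan-Mar"][0, 0]
        assert frac == pytest.approx(100 * traj.delta_oa[-1] / 0.4, rel=1e-2)
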
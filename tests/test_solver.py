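"""Integrator contracts: chemostat algebra, representation equivalence,
mass conservation, replicates, and diagnostics."""

import numpy as np
import pytest

import colonsim as cs
from colonsim.errors import ConfigurationError
from colonsim.transport import DietSchedule


def _chemostat_scenario(transport_params, mtt, s_in=10.0):
    """Single stage, constant fiber feed with near-instant hydrolysis, SD only."""
    p = transport_params  # all exchange off, all kinetics off
    p.hydrolysis.k_hyd = 200.0
    p.hydrolysis.law = "first_order"
    p.groups["SD"] = cs.state.GroupKinetics(k_m=2.5, K_S=0.5, Y=0.25, k_dec=8.3e-4)
    p.physical.mean_transit_time = mtt
    flow_q = p.physical.lumen_volume / mtt
    fiber_per_day = s_in * flow_q * 24.0  # feed concentration s_in, g/L
    diet = DietSchedule(fiber_per_day=fiber_per_day, meal_times=(0.0,), meal_duration=24.0)
    sc = cs.Scenario(params=p, diet=diet, t_end=4000.0)
    layout = cs.build_state_layout()
    field = np.zeros((1, 2, layout.n_local))
    field[0, 0, layout.local_index("X_SD", 1)] = 1.0
    return sc, field, layout


class TestChemostat:
    def test_steady_state_matches_closed_form(self, transport_params):
        """S* = K_S * D_eff / (k_m Y - D_eff) with D_eff = D + k_dec."""
        sc, field, layout = _chemostat_scenario(transport_params, mtt=24.0)
        res = cs.simulate_cstr_chain(sc, n_stages=1, output_every=100.0,
                                     initial_field=field)
        g = sc.params.groups["SD"]
        D = 1.0 / 24.0
        D_eff = D + g.k_dec
        s_star = g.K_S * D_eff / (g.k_m * g.Y - D_eff)
        # substrate balance includes the decay -> fiber -> sugar recycle
        x_star = g.Y * D * (10.0 - s_star) / (D_eff - g.Y * g.k_dec)
        sugar = res.lumen[-1, 0, layout.local_index("sugar")]
        x = res.lumen[-1, 0, layout.local_index("X_SD", 1)]
        assert sugar == pytest.approx(s_star, rel=1e-3)
        assert x == pytest.approx(x_star, rel=1e-3)

    def test_washout_above_maximal_growth(self, transport_params):
        """D > k_m Y - k_dec empties the reactor."""
        sc, field, layout = _chemostat_scenario(transport_params, mtt=1.2)
        sc.t_end = 200.0
        res = cs.simulate_cstr_chain(sc, n_stages=1, output_every=50.0,
                                     initial_field=field)
        assert res.lumen[-1, 0, layout.local_index("X_SD", 1)] < 1e-6


class TestRepresentationEquivalence:
    def test_pfr_on_three_cells_equals_three_stage_chain(self):
        """Upwind finite volumes on 3 cells are exactly a 3-stage cascade."""
        sc = cs.standard_scenario(t_end_days=7.0)
        a = cs.simulate_pfr(sc, grid_n=3, t_end=7 * 24.0, output_every=6.0,
                            allow_coarse=True)
        b = cs.simulate_cstr_chain(sc, n_stages=3, t_end=7 * 24.0, output_every=6.0)
        scale = np.abs(b.states).max()
        assert np.abs(a.states - b.states).max() / scale < 1e-6

    def test_split_integration_converges_to_monolithic(self):
        """Operator splitting carries an O(dt) error from step-averaging the
        meal pulse; it must agree with the monolithic solution in integral
        quantities and smooth fields, and the gap must shrink as the CFL
        step is refined."""
        sc = cs.standard_scenario(t_end_days=1.0)
        ref = cs.simulate_pfr(sc, t_end=24.0, output_every=12.0)
        bio = ref.layout.local_category_mask("biomass")

        out_gaps, muc_gaps = [], []
        scale = ref.mucus[-1][:, bio].max()
        for cfl in (0.9, 0.3):
            sc2 = cs.standard_scenario(t_end_days=1.0)
            sc2.params.numerics.cfl = cfl
            b = cs.simulate_pfr(sc2, t_end=24.0, output_every=12.0, method="split")
            assert b.inflow[-1].sum() == pytest.approx(ref.inflow[-1].sum(), rel=1e-9)
            out_gaps.append(abs(b.outflow[-1].sum() - ref.outflow[-1].sum()))
            muc_gaps.append(np.abs(ref.mucus[-1][:, bio] - b.mucus[-1][:, bio]).max())
        assert out_gaps[1] < 0.6 * out_gaps[0]   # ~first order in the CFL step
        assert muc_gaps[1] < 0.6 * muc_gaps[0]
        # the day-1 start-up transient is the harshest case for the splitting
        assert out_gaps[1] / ref.outflow[-1].sum() < 4e-2
        assert muc_gaps[1] / scale < 1.5e-1


class TestConservationAndDiagnostics:
    @pytest.fixture(scope="class")
    def short_run(self):
        sc = cs.standard_scenario(t_end_days=3.0)
        return cs.simulate_cstr_chain(sc, n_stages=3)

    def test_global_mass_audit(self, short_run):
        assert cs.mass_audit(short_run)["relative"] < 1e-6

    def test_states_nonnegative(self, short_run):
        assert short_run.states.min() >= -1e-9

    def test_times_strictly_increasing(self, short_run):
        assert np.all(np.diff(short_run.times) > 0)

    def test_absorbed_mass_is_nondecreasing(self, short_run):
        absorbed = cs.absorbed_mass(short_run)
        assert np.all(np.diff(absorbed.sum(axis=1)) >= -1e-9)
        assert absorbed.sum() > 0

    def test_gas_inclusive_three_stage_run_reports_102_odes(self):
        sc = cs.standard_scenario(t_end_days=0.5)
        sc.gas_mode = "with_gas"
        res = cs.simulate_cstr_chain(sc, n_stages=3, output_every=6.0)
        assert res.diagnostics["n_ode"] == 102

    def test_grid_floor_enforced(self):
        sc = cs.standard_scenario(t_end_days=1.0)
        with pytest.raises(ConfigurationError):
            cs.simulate_pfr(sc, grid_n=10)

    def test_tolerance_robustness(self):
        """A 10x tighter tolerance barely moves the outflow biomass share."""
        sc = cs.standard_scenario(t_end_days=4.0)
        a = cs.simulate_cstr_chain(sc, n_stages=3)
        sc2 = cs.standard_scenario(t_end_days=4.0)
        sc2.params.numerics.rtol = sc.params.numerics.rtol / 10
        sc2.params.numerics.atol = sc.params.numerics.atol / 10
        b = cs.simulate_cstr_chain(sc2, n_stages=3)
        pa = cs.percent_biomass(a, t=4 * 24.0)
        pb = cs.percent_biomass(b, t=4 * 24.0)
        assert abs(pa - pb) < 1e-3


class TestReplicates:
    def test_zero_deviation_replicates_are_identical(self):
        sc = cs.standard_scenario(t_end_days=1.0)
        sc.strain_counts = {"SD": 2, "LD": 1, "HDA": 1, "HDM": 1}
        sc.deviation = 0.0
        sc.mode = "cstr"
        a, b = cs.run_replicates(sc, 2, base_seed=5, t_end=24.0, output_every=12.0)
        assert np.array_equal(a.states, b.states)

    def test_replicates_carry_distinct_seeds_and_strains(self):
        sc = cs.standard_scenario(t_end_days=0.5)
        sc.strain_counts = {"SD": 3, "LD": 1, "HDA": 1, "HDM": 1}
        sc.deviation = 0.01
        sc.mode = "cstr"
        reps = cs.run_replicates(sc, 3, base_seed=10, t_end=12.0, output_every=6.0)
        assert [r.seed for r in reps] == [10, 11, 12]
        finals = [r.states[-1] for r in reps]
        assert not np.array_equal(finals[0], finals[1])

    def test_multi_strain_zero_deviation_matches_single_strain_totals(self):
        """Splitting a group into identical strains must not change dynamics."""
        sc1 = cs.standard_scenario(t_end_days=2.0)
        r1 = cs.simulate_cstr_chain(sc1, n_stages=3, output_every=12.0)
        scn = cs.standard_scenario(t_end_days=2.0)
        scn.strain_counts = {"SD": 5, "LD": 2, "HDA": 1, "HDM": 1}
        scn.deviation = 0.0
        rn = cs.simulate_cstr_chain(scn, n_stages=3, output_every=12.0)
        lay1, layn = r1.layout, rn.layout
        for g in cs.BFGS:
            li1 = lay1.local_index(f"X_{g}", 1)
            lin = [layn.local_index(f"X_{g}", s) for s in layn.strains_of(g)]
            tot1 = r1.lumen[-1, :, li1]
            totn = rn.lumen[-1][:, lin].sum(axis=1)
            assert np.allclose(totn, tot1, rtol=1e-5, atol=1e-8)
        for name in ("fiber", "sugar", "acetate", "water"):
            assert np.allclose(
                rn.lumen[-1, :, layn.local_index(name)],
                r1.lumen[-1, :, lay1.local_index(name)],
                rtol=1e-5, atol=1e-8,
            )
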
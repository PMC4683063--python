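"""Reaction network structure, rate laws, and mass closure."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import colonsim as cs
from colonsim.errors import ConfigurationError, NumericalError


def _seeded_state(layout, sugar=5.0, fiber=3.0, biomass=0.5):
    c = np.zeros(layout.n_local)
    c[layout.local_index("fiber")] = fiber
    c[layout.local_index("sugar")] = sugar
    c[layout.local_index("co2_dissolved")] = 0.5
    for g in cs.BFGS:
        for s in layout.strains_of(g):
            c[layout.local_index(f"X_{g}", s)] = biomass / layout.strain_counts[g]
    return c


class TestNetworkStructure:
    def test_single_strain_network_has_nine_processes(self, network):
        assert network.n_processes == 9
        kinds = [p.kind for p in network.processes]
        assert kinds == ["hydrolysis"] + ["uptake"] * 4 + ["decay"] * 4

    def test_strain_expanded_process_count(self, params):
        layout = cs.build_state_layout({"SD": 5, "LD": 1, "HDA": 1, "HDM": 1})
        strains = cs.state.single_strain_parameters()
        strains["SD"] = cs.sample_strain_parameters(params, "SD", 5, 0.1, seed=1)
        net = cs.build_reaction_network(layout, params, strains)
        assert net.n_processes == 1 + 2 * 8

    def test_columns_sum_to_zero(self, network, params):
        assert np.abs(network.stoichiometry.sum(axis=0)).max() < 1e-10
        layout = cs.build_state_layout({g: 3 for g in cs.BFGS})
        strains = {g: cs.sample_strain_parameters(params, g, 3, 0.1, seed=5) for g in cs.BFGS}
        net = cs.build_reaction_network(layout, params, strains)
        assert np.abs(net.stoichiometry.sum(axis=0)).max() < 1e-10

    def test_substrate_wiring(self, network, layout):
        by_name = {p.name: p for p in network.processes}
        assert by_name["glucose_utilization"].substrate == layout.local_index("sugar")
        assert by_name["lactate_utilization"].substrate == layout.local_index("lactate")
        assert by_name["acetogenesis"].substrate == layout.local_index("h2_dissolved")
        assert by_name["methanogenesis"].substrate == layout.local_index("h2_dissolved")

    def test_mismatched_strain_counts_raise(self, params):
        layout = cs.build_state_layout({"SD": 2, "LD": 1, "HDA": 1, "HDM": 1})
        with pytest.raises(ConfigurationError):
            cs.build_reaction_network(layout, params, cs.state.single_strain_parameters())


class TestRates:
    def test_zero_state_zero_rates(self, network, layout):
        assert np.all(cs.process_rates(np.zeros(layout.n_local), network) == 0)

    def test_monod_half_saturation(self, network, layout, params):
        c = np.zeros(layout.n_local)
        c[layout.local_index("sugar")] = params.groups["SD"].K_S
        c[layout.local_index("X_SD", 1)] = 1.0
        rho = cs.process_rates(c, network)
        assert rho[1] == pytest.approx(params.groups["SD"].k_m / 2)

    def test_decay_is_linear_in_biomass(self, network, layout):
        c = _seeded_state(layout)
        r1 = cs.process_rates(c, network)[-4:]
        c2 = c.copy()
        for g in cs.BFGS:
            c2[layout.local_index(f"X_{g}", 1)] *= 2
        r2 = cs.process_rates(c2, network)[-4:]
        assert np.allclose(r2, 2 * r1)

    def test_negative_concentrations_clamped(self, network, layout):
        c = _seeded_state(layout)
        c[layout.local_index("sugar")] = -1.0
        rho = cs.process_rates(c, network)
        assert np.all(rho >= 0) and rho[1] == 0.0

    def test_non_finite_input_raises(self, network, layout):
        c = _seeded_state(layout)
        c[0] = np.nan
        with pytest.raises(NumericalError):
            cs.process_rates(c, network)

    def test_sugar_only_state_is_inert(self, network, layout):
        c = np.zeros(layout.n_local)
        c[layout.local_index("sugar")] = 10.0
        assert np.all(cs.reaction_term(c, network) == 0)

    def test_reaction_term_conserves_mass(self, network, layout):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.uniform(0, 5, layout.n_local)
            assert abs(cs.reaction_term(c, network).sum()) < 1e-10


class TestBatchDynamics:
    def _integrate(self, network, c0, t_end=100.0, rtol=1e-8, method="BDF"):
        sol = solve_ivp(
            lambda t, c: cs.reaction_term(c, network), (0, t_end), c0,
            method=method, rtol=rtol, atol=1e-10, dense_output=False,
        )
        assert sol.success
        return sol

    def test_batch_mass_closure_against_fine_explicit_oracle(self, network, layout):
        """A closed batch must conserve total mass; cross-check the stiff
        trajectory against an explicit fine-step integration."""
        c0 = _seeded_state(layout)
        sol = self._integrate(network, c0, t_end=10.0)
        masses = sol.y.sum(axis=0)
        assert np.abs(masses - masses[0]).max() < 1e-6 * masses[0]
        oracle = solve_ivp(
            lambda t, c: cs.reaction_term(c, network), (0, 10.0), c0,
            method="RK45", rtol=1e-8, atol=1e-10, t_eval=sol.t,
        )
        assert np.abs(oracle.y - sol.y).max() < 1e-4

    def test_batch_stays_nonnegative(self, network, layout):
        sol = self._integrate(network, _seeded_state(layout), t_end=200.0)
        assert sol.y.min() > -1e-9

    def test_sugar_monotone_with_only_sd(self, params, layout):
        """Uptake alone can only consume sugar (decay recycling disabled)."""
        p = params.copy()
        p.groups["SD"].k_dec = 0.0
        c0 = np.zeros(layout.n_local)
        c0[layout.local_index("sugar")] = 5.0
        c0[layout.local_index("X_SD", 1)] = 1.0
        net = cs.build_reaction_network(layout, p)
        sol = self._integrate(net, c0, t_end=20.0)
        sugar = sol.y[layout.local_index("sugar")]
        assert np.all(np.diff(sugar) <= 1e-10)

    def test_strain_split_invariance_at_zero_deviation(self, params):
        """n identical strains must reproduce the single-strain group totals."""
        lay1 = cs.build_state_layout()
        net1 = cs.build_reaction_network(lay1, params)
        c1 = _seeded_state(lay1)
        sol1 = self._integrate(net1, c1, t_end=100.0)

        counts = {"SD": 4, "LD": 2, "HDA": 1, "HDM": 3}
        layn = cs.build_state_layout(counts)
        strains = {
            g: cs.sample_strain_parameters(params, g, counts[g], 0.0, seed=9)
            for g in cs.BFGS
        }
        netn = cs.build_reaction_network(layn, params, strains)
        cn = _seeded_state(layn)
        soln = self._integrate(netn, cn, t_end=100.0)

        for name in ("fiber", "sugar", "acetate", "h2_dissolved", "water"):
            a = sol1.y[lay1.local_index(name), -1]
            b = soln.y[layn.local_index(name), -1]
            assert b == pytest.approx(a, rel=1e-5, abs=1e-8)
        for g in cs.BFGS:
            a = sol1.y[lay1.local_index(f"X_{g}", 1), -1]
            b = sum(soln.y[layn.local_index(f"X_{g}", s), -1] for s in layn.strains_of(g))
            assert b == pytest.approx(a, rel=1e-5, abs=1e-8)

    def test_decay_boost_speeds_only_target_strain(self, params):
        layout = cs.build_state_layout({"SD": 3, "LD": 1, "HDA": 1, "HDM": 1})
        strains = {g: cs.sample_strain_parameters(params, g, layout.strain_counts[g], 0.0, 1)
                   for g in cs.BFGS}
        net = cs.build_reaction_network(layout, params, strains)
        boosted = net.with_decay_boost("SD", 2, 10.0)
        c = _seeded_state(layout)
        r0 = cs.process_rates(c, net)
        r1 = cs.process_rates(c, boosted)
        decays = slice(net.n_processes - 6, net.n_processes)
        diff = r1[decays] - r0[decays]
        assert diff[1] > 0 and np.all(diff[[0, 2, 3, 4, 5]] == 0)


class TestTables:
    def test_stoichiometry_and_rate_tables_round_trip_names(self, network, layout):
        from colonsim.kinetics import rate_table, stoichiometry_table

        st = stoichiometry_table(network)
        assert st.shape == (layout.n_local, network.n_processes)
        assert abs(st.sum(axis=0)).max() < 1e-10
        assert list(st.index[:2]) == ["fiber", "sugar"]
        rt = rate_table(network)
        assert rt.loc["glucose_utilization", "k_m"] > 0
        assert set(rt["kind"]) == {"hydrolysis", "uptake", "decay"}
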
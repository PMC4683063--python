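"""Composition statistics, representation deviation, periodicity and recovery."""

import numpy as np
import pytest

import colonsim as cs
from colonsim import analysis
from colonsim.errors import ValidationError


def _make_result(states, times=None, n_local=14, mucus_fraction=0.10):
    """Wrap a raw (nt, n_loc, 2*n_local) array as a minimal result object."""
    layout = cs.build_state_layout()
    sc = cs.standard_scenario(t_end_days=1.0)
    sc.params.physical.mucus_volume_fraction = mucus_fraction
    states = np.asarray(states, dtype=float)
    nt, n_loc = states.shape[:2]
    if times is None:
        times = np.arange(nt, dtype=float)
    return cs.SimulationResult(
        times=np.asarray(times, dtype=float),
        states=states,
        layout=layout,
        scenario=sc,
        mode="pfr",
        x_centers=(np.arange(n_loc) + 0.5) * (1.5 / n_loc),
        inflow=np.zeros((nt, n_local)),
        outflow=np.zeros((nt, n_local)),
        absorbed=np.zeros((nt, n_local)),
        produced=np.zeros((nt, n_local)),
    )


class TestPercentBiomass:
    def test_sterile_state_is_zero_and_empty_state_flagged(self):
        layout = cs.build_state_layout()
        states = np.zeros((1, 2, layout.n_states))
        states[0, 0, layout.index("lumen", "fiber")] = 3.0  # fiber only
        res = _make_result(states)
        assert analysis.percent_biomass(res, x=0, t=0.0) == 0.0
        assert np.isnan(analysis.percent_biomass(res, x=1, t=0.0))  # no mass at all

    def test_biomass_only_state_is_one(self):
        layout = cs.build_state_layout()
        states = np.zeros((1, 1, layout.n_states))
        states[0, 0, layout.index("mucus", "X_HDM")] = 2.0
        res = _make_result(states)
        assert analysis.percent_biomass(res, x=0, t=0.0) == 1.0

    def test_volume_weighted_desk_arithmetic(self):
        """Hand-built state: 2 g/L biomass in lumen, 8 g/L fiber in mucus."""
        layout = cs.build_state_layout()
        states = np.zeros((1, 1, layout.n_states))
        states[0, 0, layout.index("lumen", "X_SD")] = 2.0
        states[0, 0, layout.index("mucus", "fiber")] = 8.0
        res = _make_result(states, mucus_fraction=0.10)
        want = (0.9 * 2.0) / (0.9 * 2.0 + 0.1 * 8.0)
        assert analysis.percent_biomass(res, x=0, t=0.0) == pytest.approx(want)
        lum_only = analysis.percent_biomass(res, x=0, t=0.0, environment="lumen")
        assert lum_only == 1.0

    def test_coarse_fractions_sum_to_one(self):
        layout = cs.build_state_layout()
        rng = np.random.default_rng(4)
        states = rng.uniform(0, 2, size=(3, 5, layout.n_states))
        comp = analysis.coarse_composition(_make_result(states))
        total = comp.stack().sum(axis=-1)
        assert np.allclose(total, 1.0, atol=1e-9)


class TestPercentDeviation:
    def _uniform_result(self, n_loc, pb, nt=2):
        layout = cs.build_state_layout()
        states = np.zeros((nt, n_loc, layout.n_states))
        states[:, :, layout.index("lumen", "X_SD")] = pb
        states[:, :, layout.index("lumen", "fiber")] = 1.0 - pb
        return _make_result(states)

    def test_identical_fields_give_zero(self):
        d = self._uniform_result(3, 0.4)
        c = self._uniform_result(51, 0.4)
        dev = analysis.percent_deviation(d, c)
        assert np.allclose(dev.values, 0.0, atol=1e-12)

    def test_arithmetic_of_the_deviation_ratio(self):
        """%B_D = 0.4 vs %B_C = 0.3 -> +0.25 everywhere."""
        d = self._uniform_result(3, 0.4)
        c = self._uniform_result(51, 0.3)
        dev = analysis.percent_deviation(d, c)
        assert np.allclose(dev.values, 0.25)

    def test_stage_blocks_extrapolate_piecewise_constant(self):
        layout = cs.build_state_layout()
        states = np.zeros((1, 3, layout.n_states))
        for stage, pb in enumerate((0.2, 0.4, 0.8)):
            states[0, stage, layout.index("lumen", "X_SD")] = pb
            states[0, stage, layout.index("lumen", "fiber")] = 1 - pb
        d = _make_result(states)
        c = self._uniform_result(51, 0.4, nt=1)
        dev = analysis.percent_deviation(d, c)
        assert dev.values.shape == (1, 51)
        # grid cells 0-16 -> stage 1, 17-33 -> stage 2, 34-50 -> stage 3
        assert dev.values[0, 0] == pytest.approx((0.2 - 0.4) / 0.2)
        assert dev.values[0, 25] == pytest.approx(0.0)
        assert dev.values[0, 50] == pytest.approx((0.8 - 0.4) / 0.8)

    def test_mismatched_times_rejected(self):
        d = self._uniform_result(3, 0.4)
        c = self._uniform_result(51, 0.4, nt=3)
        with pytest.raises(ValidationError):
            analysis.percent_deviation(d, c)


class TestPeriodicOnset:
    def test_exactly_periodic_signal_onsets_at_start(self):
        t = np.arange(0, 24 * 10, 1.0)
        y = np.sin(2 * np.pi * t / 24.0)
        assert analysis.detect_periodic_onset(t, y) == 0.0

    def test_constant_signal_onsets_at_start(self):
        t = np.arange(0, 24 * 5, 1.0)
        assert analysis.detect_periodic_onset(t, np.ones_like(t)) == 0.0

    def test_transient_onset_matches_brute_force_scan(self):
        """Exponentially decaying transients of varied time constants agree
        with an exhaustive window-by-window comparison."""
        t = np.arange(0, 24 * 40, 1.0)
        rng = np.random.default_rng(7)
        for tau in (10.0, 40.0, 120.0):
            y = np.cos(2 * np.pi * t / 24.0) + 3.0 * np.exp(-t / tau)
            y = y + 0.0 * rng.standard_normal(len(t))
            fast = analysis.detect_periodic_onset(t, y, tol=0.01)

            # oracle: direct nested-loop scan over whole-period windows
            n = 24
            nw = len(t) // n
            wins = y[: nw * n].reshape(nw, n)
            onset = np.nan
            for j0 in range(nw - 1):
                ok = True
                for j in range(j0, nw - 1):
                    scale = max(np.abs(wins[j]).max(), 1e-12)
                    if np.abs(wins[j + 1] - wins[j]).max() / scale >= 0.01:
                        ok = False
                        break
                if ok:
                    onset = t[0] + j0 * 24.0
                    break
            assert fast == pytest.approx(onset, nan_ok=True)

    def test_onset_grows_with_time_constant(self):
        t = np.arange(0, 24 * 40, 1.0)
        onsets = []
        for tau in (10.0, 40.0, 120.0):
            y = np.cos(2 * np.pi * t / 24.0) + 3.0 * np.exp(-t / tau)
            onsets.append(analysis.detect_periodic_onset(t, y, tol=0.01))
        assert onsets == sorted(onsets) and onsets[0] < onsets[-1]

    def test_never_periodic_returns_nan(self):
        t = np.arange(0, 24 * 5, 1.0)
        assert np.isnan(analysis.detect_periodic_onset(t, t))  # linear drift

    def test_short_series_rejected(self):
        t = np.arange(0, 48, 1.0)
        with pytest.raises(ValidationError):
            analysis.detect_periodic_onset(t, np.sin(t))


class TestRecoveryTime:
    def _series(self, disturb, tau=None):
        t = np.arange(0, 24 * 30, 1.0)
        base = 0.5 + 0.1 * np.sin(2 * np.pi * t / 24.0)
        y = base.copy()
        if disturb:
            t_end = 10 * 24.0
            mask = t >= t_end
            y[mask] += disturb * np.exp(-(t[mask] - t_end) / tau)
        return t, y

    def test_unperturbed_series_recovers_immediately(self):
        t, y = self._series(disturb=0.0)
        d = analysis.recovery_time(t, y, t_pert_end=10 * 24.0, t_pert_start=8 * 24.0)
        assert d == 0.0

    def test_exponential_return_matches_analytic_crossing(self):
        """Recovery when the residual decays below tol*baseline for a period."""
        tau = 30.0
        t, y = self._series(disturb=-0.3, tau=tau)
        d = analysis.recovery_time(t, y, t_pert_end=10 * 24.0, t_pert_start=8 * 24.0,
                                   tol=0.05)
        # worst-case bound: |0.3 e^(-d/tau)| <= 0.05 * min(baseline) = 0.02
        # holds for every phase at d_bound = tau ln(15); the tolerance is
        # phase-dependent, so the detected crossing lies within one period
        # below that bound.
        d_bound = tau * np.log(0.3 / (0.05 * 0.4))
        assert d_bound - 24.0 <= d <= d_bound + 1.0

    def test_unrecovered_horizon_returns_nan(self):
        tau = 1e5
        t, y = self._series(disturb=-0.3, tau=tau)
        assert np.isnan(
            analysis.recovery_time(t, y, t_pert_end=10 * 24.0, t_pert_start=8 * 24.0)
        )

    def test_missing_baseline_rejected(self):
        t, y = self._series(disturb=0.0)
        with pytest.raises(ValidationError):
            analysis.recovery_time(t, y, t_pert_end=24.0, t_pert_start=24.0)


class TestCommunityComposition:
    def test_fractions_sum_to_one_and_flag_extinction(self):
        layout5 = cs.build_state_layout({"SD": 5, "LD": 1, "HDA": 1, "HDM": 1})
        sc = cs.community_perturbation_scenario(0.0, seed=2, n_sd_strains=5)
        sc.t_end = 24.0
        res = cs.simulate_cstr_chain(sc, n_stages=3, output_every=12.0)
        comp = cs.community_composition(res, "SD", 24.0)
        assert comp.shape == (5,)
        assert comp.sum() == pytest.approx(1.0)
        dead = res.states.copy()
        dead[:] = 0.0
        res.states = dead
        assert np.all(np.isnan(cs.community_composition(res, "SD", 24.0)))
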
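"""Integration, steady states, portraits, ratios and sweeps."""

import numpy as np
import pytest

from clonedyn import (
    FIRST_ORDER,
    CloneState,
    GrowthParams,
    InteractionParams,
    ModelParams,
    TherapyParams,
    concentration_sweep,
    gr_ratio_series,
    phase_portrait,
    simulate,
    steady_state,
)
from clonedyn.pharm import ConstantTherapy
from clonedyn.simulate import SimulationBlowUp


def closed_form_logistic(t, n, y0, k):
    return n / (1.0 + ((n - y0) / y0) * np.exp(-k * t))


class TestSimulate:
    def test_pure_culture_matches_closed_form(self, plain_params):
        """A single-clone run is the textbook logistic to integrator accuracy."""
        days = np.linspace(0, 10, 41)
        traj = simulate(plain_params, (5e4, 0.0), 10.0, sample_days=days)
        expected = closed_form_logistic(days, 6e5, 5e4, 1.0)
        assert np.allclose(traj.sensitive, expected, rtol=1e-6)
        assert np.all(traj.resistant == 0.0)

    def test_day10_total_approaches_capacity(self, plain_params, equal_seed):
        traj = simulate(plain_params, equal_seed, 10.0)
        assert traj.total[-1] == pytest.approx(6e5, rel=1e-3)

    def test_absent_clone_never_appears(self, mutualistic_params):
        traj = simulate(mutualistic_params, (1e5, 0.0), 20.0)
        assert np.all(traj.resistant == 0.0)

    def test_nonnegativity_across_parameter_draws(self, rng):
        for _ in range(10):
            growth = GrowthParams(
                rng.uniform(0.2, 2.0), rng.uniform(0.2, 2.0), rng.uniform(1e5, 1e6)
            )
            inter = InteractionParams(
                rng.uniform(-1e-6, 1e-6), rng.uniform(-1e-6, 1e-6), weighted=False
            )
            init = rng.uniform(0, 2e5, size=2)
            traj = simulate(ModelParams(growth, inter), init, 30.0)
            assert np.all(traj.states >= 0.0)

    def test_total_grows_monotonically_to_capacity(self, plain_params):
        """Below capacity, no interaction, no therapy: the total is strictly
        increasing and converges to N."""
        traj = simulate(plain_params, (2e4, 1e4), 40.0)
        totals = traj.total
        growing = totals[:-1] < 0.9999 * 6e5
        assert np.all(np.diff(totals)[growing] > 0.0)  # strict until saturation
        assert np.all(np.diff(totals) > -1e-3)  # flat at saturation, sub-cell wiggle
        assert totals[-1] == pytest.approx(6e5, rel=1e-6)

    def test_tolerance_halving_changes_little(self, plain_params, equal_seed):
        """Integrator independence: halving tolerances moves day-10 states by
        far less than 0.01%."""
        a = simulate(plain_params, equal_seed, 10.0)
        b = simulate(plain_params, equal_seed, 10.0, rtol=5e-9, atol=5e-3)
        assert np.allclose(a.states[-1], b.states[-1], rtol=1e-4)

    def test_runaway_interaction_signals_blowup(self, base_growth):
        params = ModelParams(
            base_growth, InteractionParams(1e-3, 1e-3, weighted=False)
        )
        with pytest.raises(SimulationBlowUp):
            simulate(params, (5e4, 5e4), 50.0)

    def test_conservation_slope_is_rate_ratio(self, plain_params, equal_seed):
        """Drug-free, non-interacting: ln G is affine in ln R with slope
        k_G/k_R along the trajectory."""
        days = np.arange(0.0, 8.25, 0.25)
        traj = simulate(plain_params, equal_seed, 8.0, sample_days=days)
        slope = np.polyfit(np.log(traj.resistant), np.log(traj.sensitive), 1)[0]
        assert slope == pytest.approx(2.0, rel=1e-3)


class TestSteadyState:
    def test_noninteracting_partition(self, plain_params, equal_seed):
        """Capacity splits 3:1 from an equal seed (conservation law + G+R=N)."""
        res = steady_state(plain_params, equal_seed)
        assert res.converged
        assert res.state.sensitive == pytest.approx(450000, rel=1e-3)
        assert res.state.resistant == pytest.approx(150000, rel=1e-3)

    def test_parasitic_extinguishes_sensitive(self, base_growth):
        params = ModelParams(
            base_growth, InteractionParams(-1e-7, 1e-7, weighted=False)
        )
        res = steady_state(params, (5e4, 5e4), t_max=1500.0)
        assert res.state.sensitive < 1.0
        assert res.state.resistant > 5.9e5

    def test_mutualistic_steady_state_is_mixture_independent(self, mutualistic_params):
        states = []
        for f in (0.25, 0.5, 0.75):
            res = steady_state(
                mutualistic_params, (1e5 * (1 - f), 1e5 * f), t_max=400.0
            )
            assert res.converged
            states.append(res.state.as_array())
        states = np.array(states)
        assert np.allclose(states, states[0], rtol=1e-3)
        assert np.all(states.sum(axis=1) > 6e5)  # beyond the logistic capacity


class TestPhasePortrait:
    def test_pure_sensitive_fraction_stays_on_axis(self, plain_params):
        port = phase_portrait(plain_params, 1e5, [0.0], t_end=20.0)
        assert np.all(port.trajectories[0].resistant == 0.0)

    def test_noninteracting_fractions_diverge(self, plain_params):
        port = phase_portrait(plain_params, 1e5, [0.25, 0.5, 0.75], t_end=100.0)
        ends = port.marks_end
        assert np.all(np.ptp(ends, axis=0) > 0.05 * 6e5)

    def test_mutualistic_fractions_converge(self, mutualistic_params):
        port = phase_portrait(
            mutualistic_params, 1e5, [0.25, 0.5, 0.75], t_end=200.0
        )
        ends = port.marks_end
        assert np.allclose(ends, ends[0], rtol=1e-2)


class TestGrRatio:
    def test_equal_clones_give_unit_ratio(self, base_growth):
        growth = GrowthParams(1.0, 1.0, 6e5)
        traj = simulate(ModelParams(growth), (5e4, 5e4), 10.0)
        assert np.allclose(gr_ratio_series(traj), 1.0, rtol=1e-9)

    def test_pure_sensitive_ratio_is_undefined(self, plain_params):
        traj = simulate(plain_params, (1e5, 0.0), 5.0)
        assert np.all(np.isnan(gr_ratio_series(traj)))

    def test_mutualistic_ratios_converge_across_mixtures(self, mutualistic_params):
        """The sensitive/resistant ratio forgets its initial mixture."""
        finals = []
        for f in (0.25, 0.5, 0.75):
            traj = simulate(mutualistic_params, (1e5 * (1 - f), 1e5 * f), 200.0)
            finals.append(gr_ratio_series(traj)[-1])
        finals = np.array(finals)
        spread0 = np.ptp([(1 - f) / f for f in (0.25, 0.5, 0.75)])
        assert np.ptp(finals) < 0.01 * spread0


def therapy_params(growth, c_gr=0.0, c_rg=0.0, m=1.0, a_g=1.0, a_r=1.0):
    inter = (
        InteractionParams(c_gr, c_rg, m=m, weighted=True)
        if (c_gr or c_rg)
        else None
    )
    return ModelParams(
        growth,
        inter,
        TherapyParams(a_g, a_r, death_order=FIRST_ORDER),
        ConstantTherapy(1.0),
    )


class TestConcentrationSweep:
    def test_zero_grid_matches_drug_free_steady_state(self, base_growth, equal_seed):
        params = therapy_params(base_growth)
        sweep = concentration_sweep(params, [0.0], equal_seed, 300.0)
        free = steady_state(ModelParams(base_growth), equal_seed, t_max=300.0)
        assert np.allclose(sweep.end_states[0], free.state.as_array(), rtol=1e-4)
        assert sweep.shift_type == "none"

    def test_equal_potency_totals_nonincreasing(self, base_growth, equal_seed):
        """First-order kill with a_G=a_R: terminal totals cannot rise with
        concentration (comparison principle, checked on a coarse grid)."""
        params = therapy_params(base_growth, a_g=1.0, a_r=1.0)
        sweep = concentration_sweep(
            params, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0], equal_seed, 300.0
        )
        totals = sweep.end_states.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-6 * totals[:-1] + 1e-6)

    def test_resistant_decreases_after_sensitive_extinction(
        self, invitro_growth, equal_seed
    ):
        params = therapy_params(
            invitro_growth, c_gr=0.5, c_rg=0.4, m=2.0, a_g=1.0, a_r=0.25
        )
        sweep = concentration_sweep(
            params, np.arange(0.0, 1.01, 0.1), equal_seed, 500.0
        )
        g = sweep.end_states[:, 0]
        r = sweep.end_states[:, 1]
        extinct = g == 0.0
        assert extinct.any()
        assert np.all(np.diff(r[extinct]) < 0.0)

    def test_sweep_requires_therapy(self, plain_params, equal_seed):
        with pytest.raises(ValueError):
            concentration_sweep(plain_params, [0.0, 1.0], equal_seed, 10.0)
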
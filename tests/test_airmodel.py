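"""Box-model integrator, partitioning and time-averaging oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evpexposure.airmodel import (
    AirState,
    SourceProfile,
    average_concentration,
    mass_balance_error,
    partition_equilibrium,
    simulate_box,
)


class TestSimulateBox:
    def test_pure_decay_closed_form(self):
        state = simulate_box(1.0, 1.0, SourceProfile.continuous(0.0), 2.0,
                             initial_concentration=10.0)
        expected = 10.0 * np.exp(-state.time)
        np.testing.assert_allclose(state.total, expected, rtol=1e-6)
        assert state.total[-1] == pytest.approx(10.0 * math.exp(-2.0), rel=1e-6)

    def test_constant_source_closed_form_everywhere(self):
        V, lam, S, T = 50.0, 3.0, 1000.0, 2.0
        state = simulate_box(V, lam, SourceProfile.continuous(S), T)
        expected = S / (lam * V) * (1.0 - np.exp(-lam * state.time))
        np.testing.assert_allclose(state.total[1:], expected[1:], rtol=1e-6)

    def test_no_ventilation_linear_accumulation(self):
        V, S, T = 20.0, 500.0, 1.0
        state = simulate_box(V, 0.0, SourceProfile.continuous(S), T)
        np.testing.assert_allclose(state.total, S * state.time / V, rtol=1e-12)

    def test_source_linearity_superposition(self):
        a = simulate_box(10.0, 2.0, SourceProfile.continuous(100.0), 1.0)
        b = simulate_box(10.0, 2.0, SourceProfile.continuous(200.0), 1.0)
        np.testing.assert_allclose(2.0 * a.total, b.total, rtol=1e-12)

    def test_mass_balance_continuous(self):
        src = SourceProfile.continuous(1234.5)
        state = simulate_box(33.0, 4.5, src, 3.0)
        assert mass_balance_error(state, src) < 1e-3

    def test_mass_balance_puffs(self):
        times = np.arange(0.0, 1.0, 30.0 / 3600.0)
        src = SourceProfile.puffs(times, 10.0)
        state = simulate_box(5.0, 10.0, src, 1.0, timestep=1.0 / 3600.0)
        assert mass_balance_error(state, src) < 1e-3

    def test_puff_and_continuous_converge_at_high_frequency(self):
        """Equal-mass sources agree on the time average at 30-s puff spacing."""
        V, lam, T = 50.0, 60.0, 1.0
        times = np.arange(0.0, T, 30.0 / 3600.0)
        total_mass = 1000.0
        puffy = simulate_box(
            V, lam, SourceProfile.puffs(times, total_mass / len(times)), T,
            timestep=1.0 / 3600.0,
        )
        smooth = simulate_box(V, lam, SourceProfile.continuous(total_mass / T), T)
        a, b = average_concentration(puffy), average_concentration(smooth)
        assert a == pytest.approx(b, rel=0.01)

    @given(lam=st.floats(min_value=0.1, max_value=30.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_average_strictly_decreasing_in_ach(self, lam):
        src = SourceProfile.continuous(100.0)
        low = average_concentration(simulate_box(10.0, lam, src, 1.0))
        high = average_concentration(simulate_box(10.0, lam * 1.5, src, 1.0))
        assert high < low

    def test_steady_state_limit(self):
        V, lam, S, T = 10.0, 50.0, 700.0, 10.0  # lam*T = 500 >> 1
        state = simulate_box(V, lam, SourceProfile.continuous(S), T)
        assert average_concentration(state) == pytest.approx(S / (lam * V), rel=5e-3)

    def test_timestep_validation(self):
        src = SourceProfile.continuous(1.0)
        with pytest.raises(ValueError, match="timestep"):
            simulate_box(1.0, 1.0, src, 1.0, timestep=0.5)

    def test_puff_timestep_must_resolve_events(self):
        src = SourceProfile.puffs([0.1, 0.1005], 1.0)
        with pytest.raises(ValueError, match="resolve"):
            simulate_box(1.0, 1.0, src, 1.0, timestep=0.005)

    def test_nonfinite_source_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SourceProfile.continuous(float("nan"))
        with pytest.raises(ValueError, match="finite"):
            SourceProfile.puffs([0.5], float("inf"))

    def test_partitioning_applied_on_trajectory(self):
        state = simulate_box(
            1.0, 0.0, SourceProfile.continuous(100.0), 1.0,
            saturation_mass_concentration=30.0,
        )
        np.testing.assert_allclose(state.vapor + state.particle, state.total)
        assert state.vapor.max() == pytest.approx(30.0)
        assert state.particle[-1] == pytest.approx(state.total[-1] - 30.0)
        assert ((state.vapor_fraction >= 0) & (state.vapor_fraction <= 1)).all()


class TestPartitionEquilibrium:
    @pytest.mark.parametrize(
        "total,cstar,vapor,particle",
        [
            (100.0, None, 100.0, 0.0),  # fully volatile
            (100.0, 30.0, 30.0, 70.0),  # supersaturated split
            (20.0, 30.0, 20.0, 0.0),  # subsaturated, all vapor
            (0.0, 30.0, 0.0, 0.0),
        ],
    )
    def test_equilibrium_split(self, total, cstar, vapor, particle):
        assert partition_equilibrium(total, cstar) == (vapor, particle)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            partition_equilibrium(-1.0, 10.0)
        with pytest.raises(ValueError):
            partition_equilibrium(1.0, -10.0)

    @given(
        total=st.floats(min_value=0, max_value=1e6),
        cstar=st.floats(min_value=0, max_value=1e6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_phases_sum_and_stay_nonnegative(self, total, cstar):
        vapor, particle = partition_equilibrium(total, cstar)
        assert vapor + particle == pytest.approx(total)
        assert vapor >= 0 and particle >= 0
        assert vapor <= cstar or particle == 0


class TestAverageConcentration:
    def test_constant_concentration(self):
        state = simulate_box(1.0, 0.0, SourceProfile.continuous(0.0), 1.0,
                             initial_concentration=7.5)
        assert average_concentration(state, (0.2, 0.9)) == pytest.approx(7.5)

    def test_decay_window_closed_form(self):
        C0, lam, T = 10.0, 1.0, 2.0
        state = simulate_box(1.0, lam, SourceProfile.continuous(0.0), T,
                             initial_concentration=C0)
        expected = C0 * (1.0 - math.exp(-lam * T)) / (lam * T)
        assert average_concentration(state, (0.0, T)) == pytest.approx(expected, rel=1e-6)

    def test_linear_ramp_exact(self):
        # trapezoid is exact on a linear trajectory (no-ventilation box)
        V, S, T = 2.0, 100.0, 1.0
        state = simulate_box(V, 0.0, SourceProfile.continuous(S), T)
        peak = S * T / V
        assert average_concentration(state) == pytest.approx(peak / 2.0, rel=1e-12)

    def test_empty_window_rejected(self):
        state = simulate_box(1.0, 1.0, SourceProfile.continuous(0.0), 1.0,
                             initial_concentration=1.0)
        with pytest.raises(ValueError, match="window"):
            average_concentration(state, (0.5, 0.5))
        with pytest.raises(ValueError, match="window"):
            average_concentration(state, (0.5, 1.5))
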
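"""Tests for the stress-ramp protocol, binning, hysteresis and zones."""

import numpy as np
import pytest
from scipy.special import expit

from symptomnet.core_model import ModelConfig, SimulationTrace, DimensionMismatchError
from symptomnet.stress_protocol import (
    HysteresisCurve,
    ProtocolError,
    bin_hysteresis_curve,
    forbidden_zone,
    hysteresis_area,
    make_ramp_schedule,
    run_stress_experiment,
)


def _mk_trace(D_values, stress, direction):
    """Build a minimal stress trace with 2 nodes faked up to the D values."""
    D_values = np.asarray(D_values)
    J = int(D_values.max()) if D_values.max() > 0 else 1
    J = max(J, 2)
    states = np.zeros((len(D_values), J), dtype=np.int8)
    for t, d in enumerate(D_values):
        states[t, :d] = 1
    return SimulationTrace(
        states=states,
        D=states.sum(axis=1).astype(int),
        stress=np.asarray(stress, dtype=float),
        config_echo=ModelConfig(seed=0, n_steps=len(D_values)),
        stress_direction=np.asarray(direction, dtype=np.int8),
    )


class TestRampSchedule:
    def test_full_cycle_spans_6000_steps(self):
        sched = make_ramp_schedule(-15, 15, 0.01, n_steps=6000)
        assert sched.values[0] == pytest.approx(-15.0)
        assert sched.values.max() == pytest.approx(15.0)
        assert sched.values.min() == pytest.approx(-15.0)
        # consecutive values differ by exactly one step everywhere
        assert np.allclose(np.abs(np.diff(sched.values)), 0.01)
        # a 6001st step would start the next ascent at s_min again
        longer = make_ramp_schedule(-15, 15, 0.01, n_steps=6001)
        assert longer.values[6000] == pytest.approx(-15.0)
        assert longer.direction[6000] == 1

    def test_default_protocol_holds_one_cycle_plus_partial_ascent(self):
        sched = make_ramp_schedule(n_steps=10_000)
        assert sched.n_steps == 10_000
        # full cycle = 6000 steps, then a complete second ascent (3000)
        # and the start of its descent (1000 steps)
        assert np.all(sched.direction[6000:9000] == 1)
        assert np.all(sched.direction[9000:] == -1)
        # descent starts at t=9000 with the peak value 15
        assert sched.values[9000] == pytest.approx(15.0)
        assert sched.values[9999] == pytest.approx(15.0 - 0.01 * 999)

    def test_degenerate_and_invalid_ranges_rejected(self):
        with pytest.raises(ProtocolError):
            make_ramp_schedule(0.0, 0.0, 0.01, 100)
        with pytest.raises(ProtocolError, match="positive"):
            make_ramp_schedule(-1, 1, -0.01, 100)
        with pytest.raises(ProtocolError, match="divide"):
            make_ramp_schedule(0.0, 1.0, 0.3, 100)


class TestRunStressExperiment:
    def test_schedule_must_match_config_length(self, uncoupled_network):
        sched = make_ramp_schedule(-1, 1, 0.01, n_steps=400)
        with pytest.raises(DimensionMismatchError):
            run_stress_experiment(uncoupled_network, ModelConfig(seed=0, n_steps=500), sched)

    def test_uncoupled_response_matches_logistic_closed_form(self, uncoupled_network):
        """With W=0 and b=5 every symptom is an independent Bernoulli with
        rate expit(S - 5), so the binned curve is the logistic itself."""
        n = 12_000
        sched = make_ramp_schedule(-15, 15, 0.01, n_steps=n)
        cfg = ModelConfig(connectivity=1.0, seed=1, n_steps=n)
        trace = run_stress_experiment(uncoupled_network, cfg, sched)
        curve = bin_hysteresis_curve(trace, 0.20)
        J = uncoupled_network.J
        # highest bin actually visited on the ascending leg
        top = np.flatnonzero(curve.count_up > 0)[-1]
        s_top = curve.bin_centers[top]
        assert curve.mean_D_up[top] == pytest.approx(J * expit(s_top - 5), abs=0.15)
        assert curve.mean_D_up[0] == pytest.approx(0.0, abs=0.05)

    def test_uncoupled_branches_coincide(self, uncoupled_network):
        """No coupling means no memory: up and down curves agree to
        within binomial sampling error in every bin."""
        n = 24_000
        sched = make_ramp_schedule(-15, 15, 0.01, n_steps=n)
        trace = run_stress_experiment(
            uncoupled_network, ModelConfig(seed=3, n_steps=n), sched
        )
        curve = bin_hysteresis_curve(trace, 0.20)
        shared = (curve.count_up > 0) & (curve.count_down > 0)
        gap = np.abs(curve.mean_D_up[shared] - curve.mean_D_down[shared])
        # worst-case per-bin sd of the mean difference at p=1/2:
        # sqrt(2 * J/4 / n_bin); allow 4.5 sigma for the max over ~150 bins
        n_bin = min(curve.count_up[shared].min(), curve.count_down[shared].min())
        bound = 4.5 * np.sqrt(2 * uncoupled_network.J / 4 / n_bin)
        assert gap.max() < bound


class TestBinning:
    def test_constant_state_gives_constant_bins(self):
        n = 200
        stress = np.linspace(-1, 1, n)
        direction = np.where(np.arange(n) < n // 2, 1, -1)
        trace = _mk_trace(np.full(n, 3), stress, direction)
        curve = bin_hysteresis_curve(trace, 0.20)
        assert np.all(curve.mean_D_up[curve.count_up > 0] == 3)
        assert np.all(curve.mean_D_down[curve.count_down > 0] == 3)

    def test_worked_average_example(self):
        # 15 ascending steps whose stress falls in one 0.20-wide bin and
        # whose D values sum to 45 must average to exactly 3.0
        D = [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1, 2, 3, 2, 2]
        assert sum(D) == 45
        stress = np.linspace(9.80, 9.99, 15)
        trace = _mk_trace(D, stress, np.ones(15))
        curve = bin_hysteresis_curve(trace, 0.20)
        assert curve.count_up.sum() == 15
        filled = curve.count_up > 0
        assert filled.sum() == 1
        assert curve.mean_D_up[filled][0] == pytest.approx(3.0)

    def test_single_direction_leaves_other_branch_undefined(self):
        n = 100
        trace = _mk_trace(np.arange(n) % 4, np.linspace(0, 5, n), np.ones(n))
        curve = bin_hysteresis_curve(trace, 0.20)
        assert np.all(np.isnan(curve.mean_D_down))
        assert curve.count_down.sum() == 0

    def test_mass_conservation(self, uncoupled_network):
        n = 3000
        sched = make_ramp_schedule(-3, 3, 0.01, n_steps=n)
        trace = run_stress_experiment(uncoupled_network, ModelConfig(seed=0, n_steps=n), sched)
        curve = bin_hysteresis_curve(trace, 0.20)
        assert curve.count_up.sum() + curve.count_down.sum() == n

    def test_unstressed_trace_rejected(self, uncoupled_network):
        from symptomnet.core_model import simulate

        trace = simulate(uncoupled_network, ModelConfig(seed=0, n_steps=100))
        with pytest.raises(ProtocolError, match="stress"):
            bin_hysteresis_curve(trace)


class TestHysteresisArea:
    def _curve(self, up, down, width=0.2):
        n = len(up)
        return HysteresisCurve(
            bin_centers=np.arange(n) * width,
            mean_D_up=np.asarray(up, dtype=float),
            mean_D_down=np.asarray(down, dtype=float),
            count_up=np.ones(n, dtype=int),
            count_down=np.ones(n, dtype=int),
            bin_width=width,
        )

    def test_identical_branches_give_zero(self):
        c = self._curve([1, 2, 3, 4], [1, 2, 3, 4])
        assert hysteresis_area(c) == 0.0

    def test_rectangle(self):
        # up = 0, down = J over 10 bins of width 0.2 -> area = J * 2.0
        J = 14
        c = self._curve([0] * 10, [J] * 10)
        assert hysteresis_area(c) == pytest.approx(J * 2.0)

    def test_insufficient_shared_bins(self):
        c = HysteresisCurve(
            bin_centers=np.array([0.1, 0.3]),
            mean_D_up=np.array([1.0, np.nan]),
            mean_D_down=np.array([np.nan, 2.0]),
            count_up=np.array([5, 0]),
            count_down=np.array([0, 5]),
            bin_width=0.2,
        )
        with pytest.raises(ProtocolError, match="bin"):
            hysteresis_area(c)


class TestForbiddenZone:
    def test_bimodal_alternation_yields_full_interior(self):
        n = 400
        J = 6
        D = np.where(np.arange(n) % 2 == 0, 0, J)
        trace = _mk_trace(D, np.linspace(-1, 1, n), np.ones(n))
        assert forbidden_zone(trace) == (1, J - 1)

    def test_unimodal_occupancy_has_no_zone(self):
        """Independent fair-coin symptoms: D is binomial around J/2 with
        every level well occupied, so no interior gap exists."""
        J = 6
        from symptomnet.core_model import SymptomNetwork, simulate

        net = SymptomNetwork(tuple(f"s{i}" for i in range(J)), np.zeros((J, J)), np.zeros(J))
        trace = simulate(net, ModelConfig(seed=5, n_steps=20_000))
        # fake a ramp so the zone code sees a stress experiment shape
        assert forbidden_zone(trace) is None
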
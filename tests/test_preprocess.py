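import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from gpckin.preprocess import (
    drop_inactive_cycles,
    drop_short_cycles,
    enforce_consecutive,
    filter_min_pressure,
    preprocess,
    segment_cycles,
    smooth,
    trim_after_max,
)
from gpckin.simulate import ArtifactSpec, SimulationTruth, default_program, inject_artifacts, simulate_run
from gpckin.types import Cycle, PressureTrace

from conftest import sawtooth_trace
from naive_reference import naive_preprocess, naive_smooth


def make_cycle(pressures, dt=10.0, index=1, t0=0.0):
    p = np.asarray(pressures, dtype=float)
    return Cycle(index=index, times=t0 + np.arange(len(p)) * dt, pressures=p)


class TestMinPressure:
    def test_zero_floor_is_identity(self, small_config):
        trace = sawtooth_trace()
        out = filter_min_pressure(trace, small_config.replace(min_pressure=0.0))
        assert np.array_equal(out.pressures, trace.pressures)

    def test_direct_thresholding(self, small_config):
        trace = PressureTrace([0, 10, 20, 30], [3000.0, 2900.0, 1400.0, 3900.0])
        out = filter_min_pressure(trace, small_config.replace(min_pressure=1500.0))
        assert list(out.pressures) == [3000.0, 2900.0, 3900.0]

    @settings(max_examples=50, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(pressures=st.lists(st.floats(500, 5000), min_size=1, max_size=60),
           floor=st.floats(500, 5000))
    def test_matches_brute_force_comprehension(self, small_config, pressures, floor):
        trace = PressureTrace(np.arange(len(pressures)) * 10.0, pressures)
        cfg = small_config.replace(min_pressure=floor)
        out = filter_min_pressure(trace, cfg)
        expected = [p for p in pressures if p >= floor]
        assert list(out.pressures) == expected
        # idempotence
        again = filter_min_pressure(out, cfg)
        assert np.array_equal(again.pressures, out.pressures)


class TestSegmentation:
    def test_two_cycle_sawtooth(self, small_config):
        cycles = segment_cycles(sawtooth_trace(n_cycles=2), small_config)
        assert len(cycles) == 2
        for c in cycles:
            assert c.p_max == 2500.0 and c.p_end == 2000.0

    def test_monotone_rising_trace_has_no_cycle(self, small_config):
        trace = PressureTrace(np.arange(20) * 10.0, np.linspace(1500, 4000, 20))
        assert segment_cycles(trace, small_config) == []

    def test_simulated_loops_segment_one_to_one(self, mm_config):
        truth = SimulationTruth(mu_true=0.3, qch4_true=170.0, x0=0.05,
                                gtr_coeff=20.0, noise_sd=0.0, seed=0,
                                sample_each_cycle=False)
        trace, _, truth = simulate_run(
            mm_config, default_program(4000.0, loops=20), truth)
        # raw segmentation also sees the 2-point flush vent; the short-cycle
        # filter removes it, leaving the 20 programmed methanation cycles
        cycles = drop_short_cycles(segment_cycles(trace, mm_config), mm_config)
        assert len(cycles) == 20

    def test_stop_threshold_cuts_the_tail(self, small_config):
        # decay 2500 -> 1400 with a 1 bar programmed drop: cycle ends at 1500
        p = np.concatenate(([1200.0], np.arange(2500.0, 1390.0, -100.0)))
        trace = PressureTrace(np.arange(len(p)) * 10.0, p)
        (cycle,) = segment_cycles(trace, small_config)
        assert cycle.p_max == 2500.0
        assert cycle.p_end == 1500.0  # first point at/below 2500 - 1000


class TestShortAndInactive:
    def test_len_one_threshold_is_identity(self, small_config):
        cycles = [make_cycle([2500, 2400]), make_cycle([2500] * 30)]
        assert drop_short_cycles(cycles, small_config.replace(len_cycles=1)) == cycles

    def test_short_cycles_removed_all_when_all_short(self, small_config):
        cycles = [make_cycle([2500, 2400, 2300])]
        assert drop_short_cycles(cycles, small_config.replace(len_cycles=10)) == []

    @pytest.mark.parametrize("drop,kept", [(40.0, False), (50.0, True), (60.0, True)])
    def test_activity_threshold_is_inclusive(self, small_config, drop, kept):
        c = make_cycle(np.linspace(2500.0, 2500.0 - drop, 20))
        out = drop_inactive_cycles([c], small_config)
        assert (len(out) == 1) is kept

    def test_noise_only_negative_control_loses_every_cycle(self, mm_config):
        """A dead culture's cycles never show a 50 mbar drop (noise 5 mbar)."""
        for seed in range(5):
            truth = SimulationTruth(mu_true=0.0, qch4_true=0.0, x0=0.02,
                                    noise_sd=5.0, seed=seed, max_cycle_h=0.5)
            trace, _, _ = simulate_run(
                mm_config, default_program(4000.0, loops=3), truth)
            assert preprocess(trace, mm_config) == []


class TestConsecutive:
    def test_uniform_spacing_is_identity(self, small_config):
        c = make_cycle(np.linspace(2500, 2300, 20))
        assert enforce_consecutive(c, small_config) is c

    def test_cycle_truncated_at_oversized_gap(self, small_config):
        t = np.arange(10) * 10.0
        t[6:] += 40.0  # 50 s gap between points 5 and 6
        c = Cycle(index=1, times=t, pressures=np.linspace(2500, 2400, 10))
        out = enforce_consecutive(c, small_config)
        assert out.n_points == 6  # everything after the gap is untrustworthy

    def test_gap_before_final_point_drops_exactly_that_point(self, small_config):
        t = np.arange(10) * 10.0
        t[-1] += 40.0
        c = Cycle(index=1, times=t, pressures=np.linspace(2500, 2400, 10))
        assert enforce_consecutive(c, small_config).n_points == 9

    def test_exact_double_interval_is_retained(self, small_config):
        t = np.array([0.0, 10.0, 30.0, 40.0])  # one gap of exactly 2x
        c = Cycle(index=1, times=t, pressures=np.array([2500.0, 2490, 2480, 2470]))
        assert enforce_consecutive(c, small_config).n_points == 4

    def test_idempotent(self, small_config):
        t = np.arange(30) * 10.0
        t[12:] += 35.0
        c = Cycle(index=1, times=t, pressures=np.linspace(2500, 2200, 30))
        once = enforce_consecutive(c, small_config)
        twice = enforce_consecutive(once, small_config)
        assert np.array_equal(once.times, twice.times)


class TestMoveMax:
    def test_zero_is_identity(self, small_config):
        c = make_cycle(np.linspace(2500, 2300, 100))
        assert trim_after_max(c, small_config) is c

    def test_index_arithmetic(self, small_config):
        c = make_cycle(np.linspace(2500, 2300, 100))
        out = trim_after_max(c, small_config.replace(move_max=10))
        assert out.n_points == 89
        assert out.times[0] == c.times[11]  # former peak + 11

    def test_too_short_cycle_is_dropped(self, small_config):
        c = make_cycle(np.linspace(2500, 2400, 12))
        assert trim_after_max(c, small_config.replace(move_max=11)) is None

    def test_dissolution_spike_is_neutralized(self, mm_config):
        """Trimming recovers the steady slope a refill spike would corrupt."""
        from gpckin.kinetics import conversion_rate_series
        from gpckin.simulate import GassingProgram, GassingStep

        cfg = mm_config.replace(calculation=30, move_max=10)
        truth = SimulationTruth(mu_true=0.0, qch4_true=100.0, x0=0.1,
                                noise_sd=0.0, seed=0, sample_each_cycle=False)
        prog = GassingProgram([GassingStep("methanation", 4000.0, 1)])
        trace, _, _ = simulate_run(cfg, prog, truth)
        spec = ArtifactSpec(dissolution_spike_mbar=150.0,
                            dissolution_spike_points=10, seed=1)
        spiked, _ = inject_artifacts(trace, spec, cfg)
        true_slope = 882.509  # hand ideal-gas value for Q = 10 mmol/L/h

        untrimmed = preprocess(spiked, cfg.replace(move_max=0))
        rate_raw = conversion_rate_series(untrimmed[0], cfg)["conv_rate_mbar_h"].iloc[0]
        assert rate_raw > 1.1 * true_slope  # spike exaggerates the early rate

        trimmed = preprocess(spiked, cfg)
        rate = conversion_rate_series(trimmed[0], cfg)["conv_rate_mbar_h"].iloc[0]
        assert rate == pytest.approx(true_slope, rel=0.10)


class TestSmoothing:
    def test_width_one_is_identity_and_constant_unchanged(self):
        v = np.array([3.0, 1.0, 2.0])
        assert np.array_equal(smooth(v, 1), v)
        assert np.allclose(smooth(np.full(40, 7.0), 9), 7.0)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 1.0, 10_000)
        w = 25
        smoothed = smooth(noise, w)[w:-w]  # interior windows only
        assert np.std(smoothed) == pytest.approx(1.0 / np.sqrt(w), rel=0.2)

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(1)
        v = rng.normal(2500.0, 5.0, 200)
        for w in (2, 3, 9, 30):
            assert np.allclose(smooth(v, w), naive_smooth(list(v), w), rtol=1e-12)


class TestPipelineComposition:
    def test_filter_order_matters_for_sub_floor_dips(self, small_config):
        """A below-floor dip mid-decay must be removed before segmentation.

        Run in the canonical order the dip is erased and one cycle remains;
        segmenting first would split the decay in two at the dip.
        """
        decay1 = np.arange(3000.0, 2440.0, -50.0)
        dip = [1000.0, 990.0, 995.0]
        decay2 = np.arange(2400.0, 1990.0, -50.0)
        p = np.concatenate(([1200.0], decay1, dip, decay2))
        trace = PressureTrace(np.arange(len(p)) * 10.0, p)
        cfg = small_config.replace(min_pressure=1100.0, len_cycles=3)

        canonical = preprocess(trace, cfg)
        # the dip is erased by (i); the sampling hole it leaves then
        # truncates the cycle at the gap, leaving one clean decay
        assert len(canonical) == 1
        assert canonical[0].p_max == 3000.0 and canonical[0].p_end == 2450.0

        reordered = segment_cycles(trace, cfg)  # (ii) before (i)
        assert len(reordered) == 2  # the dip fakes a refill boundary

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalent_to_brute_force_reference(self, mm_config, seed):
        truth = SimulationTruth(mu_true=0.55, qch4_true=170.0, x0=0.02,
                                gtr_coeff=20.0, noise_sd=5.0, seed=seed)
        trace, _, _ = simulate_run(
            mm_config, default_program(4000.0, loops=8), truth)
        spec = ArtifactSpec(spurious_cycles=2, spurious_len=4,
                            inactive_cycles=1, below_min_points=3,
                            gaps=[50.0], seed=seed)
        dirty, _ = inject_artifacts(trace, spec, mm_config)
        got = preprocess(dirty, mm_config)
        expected = naive_preprocess(dirty.times, dirty.pressures, mm_config)
        assert len(got) == len(expected)
        for c, (ts, ps) in zip(got, expected):
            assert np.array_equal(c.times, np.array(ts))
            assert np.array_equal(c.pressures, np.array(ps))  # bitwise

    def test_smoothed_pipeline_matches_reference_numerically(self, mm_config):
        cfg = mm_config.replace(average=9)
        truth = SimulationTruth(mu_true=0.55, qch4_true=170.0, x0=0.02,
                                gtr_coeff=20.0, noise_sd=5.0, seed=3)
        trace, _, _ = simulate_run(cfg, default_program(4000.0, loops=6), truth)
        got = preprocess(trace, cfg)
        expected = naive_preprocess(trace.times, trace.pressures, cfg)
        assert len(got) == len(expected)
        for c, (ts, ps) in zip(got, expected):
            assert np.allclose(c.pressures, ps, rtol=1e-12)
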
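import numpy as np
import pytest

from caflux.spikeclass import (
    SpikeCriteriaConfig,
    annotate_calbryte,
    baseline_adjust,
    calls_to_frame,
    classify_population,
    cluster_nonspiking,
    criterion_fft,
    criterion_flat,
    criterion_threshold,
    criterion_zero_slope,
    overestimation_rate,
    spiking_fraction,
)
from caflux.synthgen import (
    AcquisitionParams,
    SpikeShapeParams,
    default_shape_mix,
    gen_population,
    gen_trace,
)
from caflux.traceio import TracePopulation

RAW = SpikeCriteriaConfig(baseline_method="none")


def brute_force_dft_exceeds(values, threshold):
    """O(N²) DFT oracle: any nonzero-frequency magnitude above threshold?"""
    y = np.asarray(values, dtype=float)
    y = y - y.mean()
    n = y.size
    for k in range(1, n // 2 + 1):
        re = sum(y[j] * np.cos(2 * np.pi * k * j / n) for j in range(n))
        im = sum(-y[j] * np.sin(2 * np.pi * k * j / n) for j in range(n))
        if np.hypot(re, im) > threshold:
            return True
    return False


class TestCriterionZeroSlope:
    def test_constant_trace_true(self, make_trace):
        assert criterion_zero_slope(make_trace(np.full(100, 0.8)))

    def test_ramp_beyond_tolerance_false(self, make_trace):
        # closed form: OLS slope of a pure ramp equals its increment
        values = 0.01 * np.arange(100)
        cfg = SpikeCriteriaConfig(slope_tolerance=1e-4)
        assert not criterion_zero_slope(make_trace(values), cfg)

    def test_noisy_flat_true(self, make_trace, rng):
        values = 0.8 + rng.normal(0, 0.005, 481)
        cfg = SpikeCriteriaConfig(slope_tolerance=1e-3)
        # brute-force refit oracle
        slope = np.polyfit(np.arange(481.0), values, 1)[0]
        assert abs(slope) <= 1e-3
        assert criterion_zero_slope(make_trace(values), cfg)


class TestCriterionFlat:
    # thresholds: mean < 0.05 AND sd < 0.01 (baseline-adjusted units)
    def test_quiet_trace_true(self, make_trace, rng):
        values = 0.03 + rng.normal(0, 0.005, 200)
        assert criterion_flat(make_trace(values), RAW)

    def test_high_mean_false(self, make_trace, rng):
        values = 0.06 + rng.normal(0, 0.005, 200)
        assert not criterion_flat(make_trace(values), RAW)

    def test_high_sd_false(self, make_trace, rng):
        values = 0.03 + rng.normal(0, 0.02, 200)
        assert not criterion_flat(make_trace(values), RAW)


class TestCriterionFFT:
    def test_zero_trace_true(self, make_trace):
        assert criterion_fft(make_trace(np.zeros(64)))

    def test_sinusoid_magnitudes_match_analytic_peak(self, make_trace):
        # a pure sinusoid at DFT bin k has peak magnitude N·A/2
        n, k = 64, 5
        t = np.arange(n)
        for amp, expected in ((2 * 10.5 / n, False), (2 * 9.9 / n, True)):
            values = amp * np.sin(2 * np.pi * k * t / n)
            assert criterion_fft(make_trace(values)) is expected
            assert brute_force_dft_exceeds(values, 10.0) is (not expected)

    def test_agrees_with_brute_force_dft(self, make_trace, rng):
        for _ in range(30):
            n = int(rng.integers(16, 65))
            values = rng.normal(0, rng.uniform(0.5, 3.0), n)
            assert criterion_fft(make_trace(values)) == (
                not brute_force_dft_exceeds(values, 10.0)
            )


class TestCriterionThreshold:
    def test_boundary_cases(self, make_trace):
        base = np.zeros(50)
        for peak, expected in ((0.20, False), (0.16, True), (0.17, True)):
            values = base.copy()
            values[25] = peak
            assert criterion_threshold(make_trace(values), RAW) is expected

    def test_rolling_min_baseline_ignores_offset(self, make_trace):
        # raw ratio sits at 0.8 — far above 0.17 — but baseline
        # subtraction makes a quiet trace pass
        values = np.full(100, 0.8)
        assert criterion_threshold(make_trace(values))
        assert baseline_adjust(make_trace(values), SpikeCriteriaConfig()).max() == 0.0


class TestClusterNonspiking:
    def test_flat_vs_oscillatory_two_groups(self, rng):
        acq = AcquisitionParams(noise_sd=0.005)
        osc = SpikeShapeParams(
            "oscillatory", amplitude=2.0, rise_time=6, decay_time=20,
            frequency=1 / 90, n_events=12,
        )
        flat_pop, _ = gen_population(100, 0.0, acq=acq, seed=11)
        spik_pop, _ = gen_population(100, 1.0, shape_mix=osc, acq=acq, seed=12)
        traces = [
            t.__class__(cell_id=f"f{i}", times=t.times, values=t.values)
            for i, t in enumerate(flat_pop)
        ] + [
            t.__class__(cell_id=f"s{i}", times=t.times, values=t.values)
            for i, t in enumerate(spik_pop)
        ]
        pop = TracePopulation(traces)
        flags_ab = [True] * 100 + [False] * 100
        flags_c, clusters = cluster_nonspiking(pop, flags_ab)
        flat_flags = flags_c[:100]
        spike_flags = flags_c[100:]
        assert sum(bool(f) for f in flat_flags) >= 95
        assert sum(bool(f) for f in spike_flags) == 0

    def test_too_few_traces_inapplicable(self, make_trace, rng):
        pop = TracePopulation(
            [make_trace(rng.normal(size=50), cell_id=f"c{i}") for i in range(10)]
        )
        flags, clusters = cluster_nonspiking(pop, [True] * 10)
        assert flags == [None] * 10 and clusters == [None] * 10

    def test_identical_traces_single_cluster(self, make_trace):
        values = np.sin(np.linspace(0, 6 * np.pi, 100))
        pop = TracePopulation(
            [make_trace(values, cell_id=f"c{i}") for i in range(25)]
        )
        flags_ab = [True] * 25
        flags, clusters = cluster_nonspiking(pop, flags_ab)
        assert len(set(clusters)) == 1 and all(flags)
        # with zero A∧B overlap the lone cluster is not designated
        flags2, _ = cluster_nonspiking(pop, [False] * 25)
        assert not any(flags2)


class TestClassifyPopulation:
    def test_flat_noiseless_population_all_quiet(self):
        acq = AcquisitionParams(noise_sd=0.0)
        pop, _ = gen_population(30, 0.0, acq=acq, seed=3)
        calls = classify_population(pop)
        assert spiking_fraction(calls) == 0.0

    def test_single_transient_trace_is_spiking(self):
        shape = SpikeShapeParams("transient", amplitude=0.3, event_times=(600.0,))
        trace = gen_trace(shape, AcquisitionParams(noise_sd=0.005), seed=5)
        calls = classify_population(TracePopulation([trace]))
        assert calls[0].is_spiking
        assert calls[0].criterion_flags["C_cluster"] is None  # too few for DBSCAN
        assert calls[0].criterion_flags["E_threshold"] is False

    def test_recovers_spike_fraction(self):
        pop, truth = gen_population(150, 0.6, seed=21)
        calls = classify_population(pop)
        recovered = spiking_fraction(calls)
        assert abs(recovered - 0.6) <= 0.05

    def test_deterministic(self):
        pop, _ = gen_population(60, 0.5, seed=8)
        a = calls_to_frame(classify_population(pop))
        b = calls_to_frame(classify_population(pop))
        assert a.equals(b)

    def test_amplitude_monotonicity(self):
        # growing every spike amplitude never lowers the detected fraction
        fractions = []
        for scale in (0.6, 1.0, 1.6):
            pop, _ = gen_population(
                80, 0.5, shape_mix=default_shape_mix(scale), seed=13
            )
            fractions.append(spiking_fraction(classify_population(pop)))
        assert fractions == sorted(fractions)

    def test_leading_frame_exclusion_drops_early_spike(self):
        shape = SpikeShapeParams(
            "transient", amplitude=0.5, rise_time=5, decay_time=10, event_times=(10.0,)
        )
        trace = gen_trace(shape, AcquisitionParams(noise_sd=0.0), seed=0)
        keep = classify_population(TracePopulation([trace]))
        drop = classify_population(
            TracePopulation([trace]), SpikeCriteriaConfig(exclude_first_frames=10)
        )
        assert keep[0].is_spiking and not drop[0].is_spiking


class TestOverestimationRate:
    def _calls(self, flags):
        pop, _ = gen_population(len(flags), 0.0, seed=1)
        calls = classify_population(pop)
        return [
            c.__class__(c.cell_id, bool(f), c.criterion_flags, c.cluster_id)
            for c, f in zip(calls, flags)
        ]

    def test_identical_labelings_zero(self):
        calls = self._calls([True] * 5 + [False] * 5)
        labels = {c.cell_id: c.is_spiking for c in calls}
        assert overestimation_rate(calls, labels) == 0.0

    def test_arithmetic_and_sign(self):
        calls = self._calls([True] * 5 + [False] * 95)
        labels = dict.fromkeys([c.cell_id for c in calls], False)
        labels[calls[0].cell_id] = True
        assert overestimation_rate(calls, labels) == pytest.approx(0.04)
        # auto below reference gives a negative rate
        calls0 = self._calls([False] * 100)
        labels0 = dict.fromkeys([c.cell_id for c in calls0], False)
        labels0[calls0[0].cell_id] = labels0[calls0[1].cell_id] = True
        assert overestimation_rate(calls0, labels0) == pytest.approx(-0.02)

    def test_mismatched_cells_rejected(self):
        calls = self._calls([True] * 4)
        with pytest.raises(ValueError, match="same cells"):
            overestimation_rate(calls, {"nope": True})


class TestAnnotateCalbryte:
    ACQ = AcquisitionParams(
        dye_mode="calbryte_intensity", bleach_rate=5e-4,
        baseline_level=1000.0, noise_sd=2.0,
    )

    def test_pure_bleaching_not_spiking(self):
        trace = gen_trace(None, self.ACQ, seed=4)
        assert not annotate_calbryte(trace)

    def test_large_transient_detected(self):
        # 8σ excursion (noise_sd = 2) well after the leading frames
        shape = SpikeShapeParams(
            "transient", amplitude=16.0, rise_time=8, decay_time=30,
            event_times=(1200.0,),
        )
        trace = gen_trace(shape, self.ACQ, seed=4)
        assert annotate_calbryte(trace)

    def test_early_spike_excluded_under_atp_rule(self):
        shape = SpikeShapeParams(
            "transient", amplitude=30.0, rise_time=5, decay_time=10,
            event_times=(15.0,),
        )
        trace = gen_trace(shape, self.ACQ, seed=4)
        cfg = SpikeCriteriaConfig(exclude_first_frames=10)
        assert annotate_calbryte(trace)  # visible without exclusion
        assert not annotate_calbryte(trace, cfg)


class TestConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError, match="dbscan_min_points"):
            SpikeCriteriaConfig(dbscan_min_points=1)
        with pytest.raises(ValueError, match="combination_rule"):
            SpikeCriteriaConfig(combination_rule="majority")

    def test_disjunction_mode_is_stricter_about_spiking(self, make_trace, rng):
        # disjunction calls non-spiking if ANY criterion passes, so it can
        # only ever call fewer cells spiking than conjunction
        pop, _ = gen_population(40, 0.5, seed=17)
        conj = spiking_fraction(classify_population(pop))
        disj = spiking_fraction(
            classify_population(pop, SpikeCriteriaConfig(combination_rule="disjunction"))
        )
        assert disj <= conj
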
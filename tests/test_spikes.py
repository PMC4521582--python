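"""Spike detection and spike-train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgfilter.circuit import _spike_waveform
from dgfilter.params import DT_MS
from dgfilter.spikes import (
    SpikeRaster,
    assign_spikes,
    build_raster,
    detect_spikes,
    efficacy,
    frequency_following_test,
    latency_and_jitter,
    mean_total_spikes,
    per_pulse_probability,
    pulse_response_latencies,
)
from conftest import make_trace


def _loose_patch_trace(spike_times, noise_sd=3.0, amp=60.0, dur_ms=500.0,
                       stim_times=(100.0,), seed=0):
    rng = np.random.default_rng(seed)
    n = int(dur_ms / DT_MS) + 1
    y = rng.normal(0.0, noise_sd, n)
    wave, pk = _spike_waveform(DT_MS, amp)
    for s in spike_times:
        i0 = int(round(s / DT_MS)) - pk
        y[i0: i0 + wave.size] += wave
    return make_trace(y, stim_times=stim_times)


class TestDetector:
    def test_recovers_inserted_spikes_within_150us(self):
        truth = [120.0, 200.5, 333.3]
        tr = _loose_patch_trace(truth, seed=5)
        found = detect_spikes(tr)
        assert found.size == 3
        np.testing.assert_allclose(found, truth, atol=0.15)

    def test_pure_noise_rarely_triggers(self):
        """False-positive control: k=5 on pure noise yields zero events in at
        least 99% of seeds."""
        zero = sum(
            detect_spikes(_loose_patch_trace([], seed=s)).size == 0
            for s in range(100)
        )
        assert zero >= 99

    def test_silent_noiseless_trace_gives_empty_result(self):
        tr = _loose_patch_trace([], noise_sd=0.0)
        assert detect_spikes(tr).size == 0

    def test_saturated_trace_rejected(self):
        tr = _loose_patch_trace([], seed=1)
        tr.y[5000:9000] = 1000.0
        with pytest.raises(ValueError, match="saturated"):
            detect_spikes(tr)

    def test_artifact_not_detected_as_spike(self):
        tr = _loose_patch_trace([], seed=2)
        i0 = int(100.0 / DT_MS)
        tr.y[i0: i0 + 10] += 150.0  # stimulus artifact at the stim time
        assert detect_spikes(tr).size == 0

    def test_detector_matches_generator_exactly_without_noise(self, mature):
        import dataclasses

        from dgfilter import StimulationProtocol, simulate_cell

        cell = dataclasses.replace(mature, loose_patch_noise_sd=0.0)
        proto = StimulationProtocol(frequency=10.0, n_trains=3)
        for tr in simulate_cell(cell, proto):
            found = detect_spikes(tr)
            assert found.size == len(tr.meta["spike_times"])


def _raster(spikes_per_train, freq=10.0, n_pulses=10):
    ipi = 1000.0 / freq
    stim = 100.0 + ipi * np.arange(n_pulses)
    return SpikeRaster(
        cell_id="c0", phenotype="mature", condition="control", frequency=freq,
        spike_times=[np.asarray(s, float) for s in spikes_per_train],
        stim_times=[stim] * len(spikes_per_train),
        n_pulses=n_pulses,
    )


def _raster_from_pulses(pulse_sets, freq=10.0, offset=3.0):
    ipi = 1000.0 / freq
    return _raster(
        [[100.0 + ipi * (p - 1) + offset for p in sorted(pulses)] for pulses in pulse_sets],
        freq=freq,
    )


class TestAssignment:
    def test_every_pulse_answered_gives_unit_probabilities(self):
        r = _raster_from_pulses([range(1, 11)] * 4)
        np.testing.assert_array_equal(per_pulse_probability(r), np.ones(10))
        assert mean_total_spikes(r) == 10.0

    def test_fractional_probability(self):
        """Pulse 1 answered in 3 of 5 trains -> probability 0.6."""
        r = _raster_from_pulses([[1], [1], [1], [], []])
        assert per_pulse_probability(r)[0] == pytest.approx(0.6)

    def test_multiple_spikes_in_window_count_once(self):
        r = _raster([[103.0, 105.0, 108.0]])
        assert mean_total_spikes(r) == 1.0

    def test_spike_before_first_stimulus_is_spontaneous(self):
        r = _raster([[50.0, 103.0]])
        hits, spont = assign_spikes(r)
        assert spont == 1
        assert hits.sum() == 1

    def test_last_pulse_window_capped_at_100ms(self):
        # 1 Hz: a spike 150 ms after the last pulse is outside the capped window
        r = _raster([[9100.0 + 150.0]], freq=1.0)
        assert mean_total_spikes(r) == 0.0

    def test_no_spikes(self):
        r = _raster([[], []])
        assert mean_total_spikes(r) == 0.0
        assert efficacy(r) == 0.0


class TestEfficacy:
    def test_five_consecutive_pulses_give_four_ninths(self):
        r = _raster_from_pulses([[1, 2, 3, 4, 5]])
        assert efficacy(r) == pytest.approx(4 / 9)

    def test_five_alternating_pulses_give_zero(self):
        r = _raster_from_pulses([[1, 3, 5, 7, 9]])
        assert efficacy(r) == 0.0

    def test_all_pulses_give_one(self):
        r = _raster_from_pulses([range(1, 11)])
        assert efficacy(r) == 1.0

    def test_average_over_trains(self):
        r = _raster_from_pulses([[1, 2, 3, 4, 5], [1, 3, 5, 7, 9]])
        assert efficacy(r) == pytest.approx((4 / 9 + 0.0) / 2)

    @given(
        st.lists(
            st.sets(st.integers(min_value=1, max_value=10)),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_saturation(self, pulse_sets):
        r = _raster_from_pulses(pulse_sets)
        e = efficacy(r)
        assert 0.0 <= e <= 1.0
        # efficacy is 1 iff every pulse of every train carries a spike
        assert (e == 1.0) == all(set(p) == set(range(1, 11)) for p in pulse_sets)
        # at most (answered pulses - 1) adjacent pairs per train
        m = mean_total_spikes(r)
        assert e <= m / (r.n_pulses - 1) + 1e-12


class TestFrequencyFollowing:
    def test_counts_of_exactly_one_are_not_different(self):
        res = frequency_following_test(np.ones(8))
        assert not res.significant

    def test_clear_transmission_is_significant(self):
        res = frequency_following_test(np.array([5, 6, 5, 4, 6, 5, 5, 6.0]))
        assert res.significant and res.p_value < 0.01

    def test_requires_five_cells(self):
        with pytest.raises(ValueError, match="at least 5"):
            frequency_following_test(np.array([2.0, 3.0]))


class TestLatencyJitter:
    def test_identical_latencies_have_zero_jitter(self):
        r = _raster_from_pulses([[1], [1], [1]], offset=4.0)
        summ = latency_and_jitter([r])
        assert summ.jitter_sd == 0.0
        np.testing.assert_allclose(summ.latencies, 4.0)

    def test_simple_arithmetic(self):
        """Latencies 3, 4, 5 ms -> jitter -1, 0, +1."""
        r = _raster(
            [[103.0], [104.0], [105.0]], freq=10.0
        )
        summ = latency_and_jitter([r])
        np.testing.assert_allclose(np.sort(summ.jitter_values), [-1.0, 0.0, 1.0])
        assert summ.jitter_sd == pytest.approx(1.0)

    def test_cells_with_too_few_trials_excluded(self):
        good = _raster([[103.2], [103.4], [103.9]])
        bad = _raster([[103.0], [], []])
        summ = latency_and_jitter([good, bad])
        assert summ.n_cells == 1
        assert summ.excluded_cells == ["c0"]

    def test_all_pulse_mode_uses_every_answered_pulse(self):
        r = _raster_from_pulses([[1, 2, 3]], freq=1.0)
        lats = pulse_response_latencies(r, pulses="all")
        assert np.isfinite(lats).sum() == 3


class TestBuildRaster:
    def test_round_trip_through_rendered_traces(self, mature):
        from dgfilter import StimulationProtocol, simulate_cell

        proto = StimulationProtocol(frequency=20.0, n_trains=3)
        traces = simulate_cell(mature, proto)
        r = build_raster(traces, cell_id="cellA")
        assert r.n_trains == 3
        assert r.frequency == pytest.approx(20.0)
        assert r.n_pulses == 10
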
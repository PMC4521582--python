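"""Generator tests: determinism, intrinsic firing, clamp consistency, and an
independent fine-step integration oracle."""

import dataclasses
import math

import numpy as np
import pytest
from numba import njit

from dgfilter import (
    FieldModelParams,
    StimulationProtocol,
    simulate_cell,
    simulate_field,
    simulate_voltage_clamp,
)
from dgfilter.circuit import (
    _draw_events,
    _dualexp_peak_norm,
    _stp_weights,
    population_spike_probability,
)
from dgfilter.params import DT_MS


def _no_noise(cell):
    return dataclasses.replace(
        cell,
        noise=dataclasses.replace(cell.noise, amp_cv=0.0, latency_sd=0.0, v_noise_sd=0.0),
    )


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_traces(self, mature):
        proto = StimulationProtocol(frequency=20.0, n_trains=3)
        a = simulate_cell(mature, proto)
        b = simulate_cell(mature, proto)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_different_trains_differ(self, mature):
        proto = StimulationProtocol(frequency=20.0, n_trains=2)
        a, b = simulate_cell(mature, proto)
        assert not np.array_equal(a.y, b.y)

    def test_conditions_share_feedforward_substream(self, mature):
        """Control and DCG4 voltage-clamp sweeps are exactly paired: their
        difference is the feedback component alone."""
        proto = lambda c: StimulationProtocol(
            frequency=20.0, n_trains=1, condition=c, mode="vclamp_inh"
        )
        tot = simulate_voltage_clamp(mature, proto("control"))[0]
        ff = simulate_voltage_clamp(mature, proto("DCG4"))[0]
        np.testing.assert_array_equal(tot.meta["g_ff"], ff.meta["g_ff"])
        np.testing.assert_allclose(
            tot.y - ff.y, tot.meta["g_fb"] * (0.0 - mature.E_inh), atol=1e-9
        )


class TestIntrinsicFiring:
    @pytest.mark.parametrize("freq", [20.0, 40.0])
    def test_ten_pulses_give_ten_spikes(self, mature, immature, freq):
        for cell in (mature, immature):
            proto = StimulationProtocol(
                frequency=freq, n_trains=3, mode="intrinsic_iclamp"
            )
            for tr in simulate_cell(cell, proto):
                assert len(tr.meta["spike_times"]) == 10

    def test_no_drive_stays_at_rest(self, mature):
        cell = _no_noise(mature)
        proto = StimulationProtocol(
            frequency=10.0, n_trains=1, input_strength=0.0, mode="loose_patch"
        )
        tr = simulate_cell(cell, proto)[0]
        assert len(tr.meta["spike_times"]) == 0
        np.testing.assert_allclose(tr.meta["v"], cell.E_L, atol=1e-6)


class TestVoltageClamp:
    def test_exc_isolation_nulls_inhibition(self, mature):
        """At the inhibitory reversal a KYN sweep (inhibition-only drive in
        current terms) is flat apart from artifacts/noise."""
        cell = _no_noise(dataclasses.replace(mature, vclamp_noise_sd=0.0))
        proto = StimulationProtocol(
            frequency=10.0, n_trains=1, condition="KYN", mode="vclamp_exc"
        )
        tr = simulate_voltage_clamp(cell, proto)[0]
        mask = np.ones(tr.y.size, bool)
        for s in tr.stim_times:
            i0 = int(s / DT_MS)
            mask[i0: i0 + 20] = False
        assert np.abs(tr.y[mask]).max() == 0.0

    def test_wrong_holding_potential_rejected(self, mature):
        proto = StimulationProtocol(frequency=10.0, mode="vclamp_exc")
        with pytest.raises(ValueError, match="holding"):
            simulate_voltage_clamp(mature, proto, holding_potential=-30.0)

    def test_clamp_current_matches_internal_conductance(self, mature):
        """Linear-clamp consistency: I = g_syn * (V_hold - E_rev) exactly."""
        cell = dataclasses.replace(mature, vclamp_noise_sd=0.0)
        proto = StimulationProtocol(frequency=20.0, n_trains=1, mode="vclamp_inh")
        tr = simulate_voltage_clamp(cell, proto)[0]
        expected = tr.meta["g_syn"] * (0.0 - cell.E_inh)
        mask = np.ones(tr.y.size, bool)
        for s in tr.stim_times:
            mask[int(s / DT_MS): int(s / DT_MS) + 20] = False
        np.testing.assert_allclose(tr.y[mask], expected[mask], atol=1e-9)

    def test_ptx_inh_clamp_is_silent(self, mature):
        cell = dataclasses.replace(mature, vclamp_noise_sd=0.0)
        proto = StimulationProtocol(
            frequency=10.0, n_trains=1, condition="PTX", mode="vclamp_inh"
        )
        tr = simulate_voltage_clamp(cell, proto)[0]
        assert tr.meta["g_syn"].max() == 0.0


class TestShortTermDynamics:
    def test_first_event_weight_is_unity(self):
        from dgfilter.params import SynapseParams

        syn = SynapseParams(g_peak=1.0, tau_rise=0.5, tau_decay=5.0, latency=1.0,
                            stp_u=0.3, stp_tau_fac=300.0)
        w = _stp_weights(np.array([0.0, 25.0, 50.0]), syn)
        assert w[0] == 1.0
        assert np.all(np.diff(w) > 0)  # facilitating

    def test_depression_reduces_weights(self):
        from dgfilter.params import SynapseParams

        syn = SynapseParams(g_peak=1.0, tau_rise=0.5, tau_decay=5.0, latency=1.0,
                            stp_u=0.2, stp_tau_rec=200.0)
        w = _stp_weights(np.arange(10) * 25.0, syn)
        assert np.all(np.diff(w) < 0)

    def test_dualexp_norm_matches_peak(self):
        tau_r, tau_d = 0.7, 9.0
        t = np.linspace(0, 60, 200001)
        wave = np.exp(-t / tau_d) - np.exp(-t / tau_r)
        assert math.isclose(wave.max(), _dualexp_peak_norm(tau_r, tau_d), rel_tol=1e-6)


class TestPopulationSurrogate:
    def test_probability_declines_along_train_faster_at_high_freq(self):
        p40 = population_spike_probability(40.0, 10)
        p1 = population_spike_probability(1.0, 10)
        assert np.all(np.diff(p40) < 0)
        assert p40[-1] < p1[-1]
        assert np.all((p40 > 0) & (p40 < 1))


@njit(cache=True)
def _euler_fine(dt, n, v0, g_l, c_m, e_l, e_exc, v_th, v_reset, ref_steps, g_e):
    v = v0
    ref = 0
    count = 0
    for i in range(n):
        dv = (-g_l * (v - e_l) - g_e[i] * (v - e_exc)) * dt / c_m
        v = v + dv
        if ref > 0:
            ref -= 1
            v = v_reset
        elif v >= v_th:
            count += 1
            v = v_reset
            ref = ref_steps
    return count


class TestIntegrationOracle:
    def test_spike_counts_match_fine_step_euler(self, mature):
        """Forward-Euler integration at 10x finer steps, driven by the same
        synaptic events evaluated in closed form, reproduces the generator's
        mean spike count (PTX condition, noise-free voltage) within 2%."""
        cell = dataclasses.replace(
            mature, noise=dataclasses.replace(mature.noise, v_noise_sd=0.0)
        )
        proto = StimulationProtocol(
            frequency=10.0, n_trains=20, condition="PTX", input_strength=0.5
        )
        traces = simulate_cell(cell, proto)
        coarse = np.array([len(tr.meta["spike_times"]) for tr in traces])

        fine = []
        refine = 10
        dt_f = DT_MS / refine
        n_f = traces[0].t.size * refine
        tt = np.arange(n_f) * dt_f
        norm = _dualexp_peak_norm(cell.exc.tau_rise, cell.exc.tau_decay)
        from dgfilter.circuit import _substream

        stim = proto.stim_times()
        for k in range(proto.n_trains):
            rng = _substream(cell.noise.seed, proto.frequency, k, "exc")
            times, weights = _draw_events(
                cell.exc, stim, proto.input_strength, rng,
                cell.noise.amp_cv, cell.noise.latency_sd,
            )
            g = np.zeros(n_f)
            for t0, w in zip(times, weights):
                m = tt >= t0
                g[m] += (
                    w
                    * (np.exp(-(tt[m] - t0) / cell.exc.tau_decay)
                       - np.exp(-(tt[m] - t0) / cell.exc.tau_rise))
                    / norm
                )
            fine.append(
                _euler_fine(
                    dt_f, n_f, cell.E_L, cell.g_L, cell.C_m, cell.E_L, cell.E_exc,
                    cell.V_th, cell.V_reset, int(round(cell.t_ref / dt_f)), g,
                )
            )
        fine = np.array(fine)
        assert abs(coarse.mean() - fine.mean()) <= 0.02 * max(fine.mean(), 1.0)


class TestFieldGenerator:
    def test_zero_intensity_is_flat(self):
        fp = FieldModelParams(noise_sd_mv=0.0, seed=1)
        tr = simulate_field(fp, [0.0, 10.0, 50.0, 90.0])[0]
        assert np.abs(tr.y).max() == 0.0

    def test_slope_amplitudes_monotone_with_intensity(self):
        fp = FieldModelParams(seed=3)
        traces = simulate_field(fp, np.linspace(5, 95, 10))
        amps = [tr.meta["fepsp_amp"] for tr in traces]
        assert np.all(np.diff(amps) > 0)

    def test_pop_spike_saturates(self):
        fp = FieldModelParams(seed=3)
        traces = simulate_field(fp, np.linspace(5, 95, 10))
        ps = np.array([tr.meta["ps_amp"] for tr in traces])
        assert ps[-1] / fp.ps_max_mv > 0.99

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            simulate_field(FieldModelParams(), [1.0, 2.0, 3.0])

    def test_decreasing_intensities_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_field(FieldModelParams(), [1.0, 5.0, 4.0, 9.0])
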
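"""Conductance extraction: driving-force arithmetic, peak/rise timing against
closed forms, and recovery of generator ground truth."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from dgfilter import StimulationProtocol, simulate_voltage_clamp
from dgfilter.conductance import (
    conductances_at_spike_time,
    current_to_conductance,
    epsc_peak_time,
    residual_recruited,
    rise20_latency,
)
from dgfilter.params import DT_MS
from conftest import make_trace


def _vc_trace(y, stim=(100.0,), hold=-60.0, mode="vclamp_exc", **kw):
    return make_trace(y, stim_times=stim, mode=mode, holding_potential=hold, **kw)


def _dualexp(t, onset, tau_r, tau_d):
    out = np.zeros_like(t)
    m = t >= onset
    tpk = tau_d * tau_r / (tau_d - tau_r) * math.log(tau_d / tau_r)
    norm = math.exp(-tpk / tau_d) - math.exp(-tpk / tau_r)
    out[m] = (np.exp(-(t[m] - onset) / tau_d) - np.exp(-(t[m] - onset) / tau_r)) / norm
    return out


class TestCurrentToConductance:
    def test_driving_force_division(self):
        """100 pA over a 60 mV driving force is 1.667 nS."""
        n = int(200 / DT_MS)
        y = np.zeros(n)
        y[int(110 / DT_MS):] = -100.0  # inward current at V_hold = -60, E_rev = 0
        tr = _vc_trace(y)
        g = current_to_conductance(tr, reversal=0.0)
        assert g[-1] == pytest.approx(100.0 / 60.0, rel=1e-9)

    def test_zero_current_gives_zero_conductance(self):
        tr = _vc_trace(np.zeros(int(200 / DT_MS)))
        assert current_to_conductance(tr, reversal=0.0).max() == 0.0

    def test_baseline_subtracted(self):
        y = np.full(int(200 / DT_MS), -40.0)
        tr = _vc_trace(y)
        assert current_to_conductance(tr, reversal=0.0).max() == 0.0

    def test_holding_at_reversal_rejected(self):
        tr = _vc_trace(np.zeros(int(200 / DT_MS)), hold=0.5)
        with pytest.raises(ValueError, match="too close"):
            current_to_conductance(tr, reversal=0.0)

    def test_missing_baseline_window_rejected(self):
        tr = make_trace(np.zeros(2000), stim_times=[1.0], mode="vclamp_exc",
                        holding_potential=-60.0)
        with pytest.raises(ValueError, match="baseline"):
            current_to_conductance(tr, reversal=0.0)

    def test_recovers_generator_conductance_within_2pct(self, mature):
        proto = StimulationProtocol(frequency=20.0, n_trains=1, mode="vclamp_inh")
        tr = simulate_voltage_clamp(mature, proto)[0]
        g = current_to_conductance(tr, reversal=mature.E_inh)
        truth = tr.meta["g_syn"]
        mask = np.ones(g.size, bool)
        for s in tr.stim_times:
            i0 = int((s - 0.1) / DT_MS)
            mask[i0: i0 + int(1.2 / DT_MS)] = False
        assert np.abs(g - truth)[mask].max() <= 0.02 * truth.max()


class TestEpscPeakTime:
    def test_matches_closed_form_peak_of_dual_exponential(self):
        tau_r, tau_d, onset = 0.4, 6.0, 101.8
        t = np.arange(int(400 / DT_MS)) * DT_MS
        y = -80.0 * _dualexp(t, onset, tau_r, tau_d)
        tr = _vc_trace(y)
        tpk_analytic = (onset - 100.0) + tau_d * tau_r / (tau_d - tau_r) * math.log(tau_d / tau_r)
        assert epsc_peak_time(tr, 100.0) == pytest.approx(tpk_analytic, abs=DT_MS)

    def test_flat_trace_reports_missing(self):
        rng = np.random.default_rng(0)
        tr = _vc_trace(rng.normal(0, 1.0, int(400 / DT_MS)))
        assert np.isnan(epsc_peak_time(tr, 100.0))

    def test_peak_close_to_spike_latency_on_defaults(self, mature, study):
        """EPSC peak and action potential occur close in time (< 2 ms apart)."""
        ctrl = study.conductances[
            (study.conductances.phenotype == "mature")
            & (study.conductances.frequency == 1.0)
        ]
        tim = study.timing[
            (study.timing.phenotype == "mature") & (study.timing.condition == "control")
        ]
        gap = abs(ctrl["epsc_peak_ms"].mean() - tim["mean_latency_ms"].mean())
        assert gap < 2.0


class TestRise20:
    def test_matches_analytic_crossing(self):
        tau_r, tau_d, onset_rel = 2.0, 40.0, 3.0
        t = np.arange(int(600 / DT_MS)) * DT_MS
        y = 120.0 * _dualexp(t, 100.0 + onset_rel, tau_r, tau_d)
        tr = _vc_trace(y, hold=0.0, mode="vclamp_inh")

        tpk = tau_d * tau_r / (tau_d - tau_r) * math.log(tau_d / tau_r)
        norm = math.exp(-tpk / tau_d) - math.exp(-tpk / tau_r)
        f = lambda x: (math.exp(-x / tau_d) - math.exp(-x / tau_r)) / norm - 0.2
        x20 = brentq(f, 1e-6, tpk)
        assert rise20_latency(tr, 100.0) == pytest.approx(onset_rel + x20, abs=DT_MS)

    def test_step_current_latency_is_step_onset(self):
        t = np.arange(int(400 / DT_MS)) * DT_MS
        y = np.where(t >= 105.0, 90.0, 0.0)
        tr = _vc_trace(y, hold=0.0, mode="vclamp_inh")
        assert rise20_latency(tr, 100.0) == pytest.approx(5.0, abs=DT_MS)

    def test_noise_floor_reports_missing(self):
        rng = np.random.default_rng(1)
        tr = _vc_trace(rng.normal(0, 1.0, int(400 / DT_MS)), hold=0.0, mode="vclamp_inh")
        assert np.isnan(rise20_latency(tr, 100.0))


class TestConductancesAtSpikeTime:
    def test_zero_inhibition_flags_ratios_undefined(self):
        t = np.arange(int(400 / DT_MS)) * DT_MS
        exc = _vc_trace(-80.0 * _dualexp(t, 102.0, 0.4, 6.0))
        inh = _vc_trace(np.zeros(t.size), hold=0.0, mode="vclamp_inh")
        tab = conductances_at_spike_time(exc, inh)
        assert tab.ipsg_at_peak.max() == 0.0
        assert np.isnan(tab.mean_ei_ratio)
        assert np.all(np.isnan(tab.ei_ratio_per_pulse))

    def test_epsg_read_at_own_peak(self):
        t = np.arange(int(400 / DT_MS)) * DT_MS
        exc = _vc_trace(-60.0 * _dualexp(t, 102.0, 0.4, 6.0))
        inh = _vc_trace(30.0 * _dualexp(t, 102.0, 0.5, 40.0), hold=0.0, mode="vclamp_inh")
        tab = conductances_at_spike_time(exc, inh)
        assert tab.epsg_at_peak[0] == pytest.approx(1.0, rel=0.01)  # 60 pA / 60 mV


class TestResidualRecruited:
    def _inh_1hz(self, tau_d=60.0, n_pulses=3):
        stim = 100.0 + 1000.0 * np.arange(n_pulses)
        t = np.arange(int((stim[-1] + 500) / DT_MS)) * DT_MS
        y = np.zeros(t.size)
        for s in stim:
            y += 90.0 * _dualexp(t, s + 3.0, 1.0, tau_d)
        return _vc_trace(y, stim=stim, hold=0.0, mode="vclamp_inh")

    def test_residual_monotone_in_lag(self):
        summ = residual_recruited(self._inh_1hz())
        r = summ.residual_ipsg
        assert r[25.0] > r[50.0] > r[100.0] >= r[1000.0]

    def test_fast_decay_leaves_no_residual_at_one_second(self):
        summ = residual_recruited(self._inh_1hz(tau_d=30.0))
        assert summ.residual_ipsg[1000.0] == pytest.approx(0.0, abs=1e-3)

    def test_requires_1hz_protocol(self):
        t = np.arange(int(800 / DT_MS)) * DT_MS
        stim = 100.0 + 100.0 * np.arange(3)
        tr = _vc_trace(np.zeros(t.size), stim=stim, hold=0.0, mode="vclamp_inh")
        with pytest.raises(ValueError, match="1 Hz"):
            residual_recruited(tr)

    def test_mature_sustained_inhibition_exceeds_excitation_at_100ms(self, study):
        """Residual + recruited inhibition outweighs excitation at a 100 ms
        lag in mature cells but not in immature cells."""
        c = study.conductances
        one = c[c.frequency == 1.0]
        for phen, expected in (("mature", True), ("immature", False)):
            sub = one[one.phenotype == phen]
            total = (sub["residual_100ms"] + sub["recruited_ipsg"]).mean()
            epsg = sub["mean_epsg"].mean()
            assert (total > epsg) == expected, (phen, total, epsg)
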
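"""Conductance-based granule-cell microcircuit generator.

One granule cell is modelled as a leaky integrate-and-fire unit with
conductance synapses:

    C_m dV/dt = -g_L (V - E_L) - g_E(t) (V - E_exc) - g_I(t) (V - E_inh) + I_inj

Excitation (``exc``) and feedforward inhibition (``inh_ff``) are driven by each
stimulus pulse; feedback inhibition (``inh_fb``) is recruited by granule-cell
spiking — by the simulated cell's own spikes in current clamp, and by a
surrogate population-spike process in voltage clamp, where the recorded cell is
clamped and cannot spike.  A small direct (monosynaptic) inhibitory pathway
survives glutamatergic block and is what remains under KYN.

Pharmacology:

=========  =================================================================
control    exc + FF + FB + monosynaptic inhibition
PTX        all inhibition removed (GABA-A block)
DCG4       feedback inhibition removed (mossy-fibre release suppressed)
KYN        glutamatergic drive removed: only monosynaptic inhibition remains
=========  =================================================================

Integration is fixed-step exponential Euler at the acquisition interval
(0.05 ms, 20 kHz).  All randomness flows from ``params.noise.seed`` through
named substreams keyed by (frequency, train, component) — but never by
condition, so that condition contrasts (control vs DCG4, control vs KYN) are
exactly paired and pharmacological subtraction is meaningful sweep by sweep.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .params import (
    DT_MS,
    CellModelParams,
    StimulationProtocol,
    SynapseParams,
    TraceRecording,
)

__all__ = [
    "simulate_cell",
    "simulate_voltage_clamp",
    "simulate_field",
    "FieldModelParams",
    "population_spike_probability",
    "intrinsic_pulse_amplitude",
    "ARTIFACT_MS",
    "MONO_LATENCY_MS",
]

#: stimulus-artifact duration (ms); analysis modules blank 1.0 ms
ARTIFACT_MS = 0.5
#: onset latency of the direct (monosynaptic) inhibitory pathway
MONO_LATENCY_MS = 1.2
#: latency from a stimulus to the surrogate population spike in voltage clamp
POP_SPIKE_LATENCY_MS = 4.0


# ---------------------------------------------------------------------------
# RNG plumbing

def _substream(seed: int, frequency: float, train_index: int, component: str) -> np.random.Generator:
    """Deterministic named substream; independent of pharmacological condition."""
    key = (
        int(seed) & 0x7FFFFFFF,
        int(round(frequency * 1000)),
        int(train_index),
        zlib.crc32(component.encode()),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Synaptic event machinery

def _dualexp_peak_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak of exp(-t/tau_decay) - exp(-t/tau_rise); used to normalise to g_peak."""
    t_pk = (tau_decay * tau_rise) / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise)


def _stp_weights(event_times: np.ndarray, syn: SynapseParams) -> np.ndarray:
    """Relative release amplitudes (first event = 1) under resource/utilisation
    dynamics.  Facilitation: utilisation u relaxes to stp_u with stp_tau_fac and
    jumps by stp_u*(1-u) after each event.  Depression: resources x relax to 1
    with stp_tau_rec and are depleted by the released fraction."""
    n = len(event_times)
    out = np.ones(n)
    if n == 0:
        return out
    u_prev = syn.stp_u
    x_prev = 1.0
    last_t = None
    for k, t in enumerate(event_times):
        if last_t is None:
            u_k, x_k = syn.stp_u, 1.0
        else:
            dt = t - last_t
            if syn.stp_tau_fac > 0:
                u_k = syn.stp_u + (u_prev - syn.stp_u) * math.exp(-dt / syn.stp_tau_fac)
            else:
                u_k = syn.stp_u
            if syn.stp_tau_rec > 0:
                x_k = 1.0 + (x_prev - 1.0) * math.exp(-dt / syn.stp_tau_rec)
            else:
                x_k = 1.0
        out[k] = u_k * x_k / syn.stp_u
        x_prev = x_k * (1.0 - u_k)
        u_prev = u_k + syn.stp_u * (1.0 - u_k) if syn.stp_tau_fac > 0 else syn.stp_u
        last_t = t
    return out


def _draw_events(
    syn: SynapseParams,
    trigger_times: np.ndarray,
    scale: float,
    rng: np.random.Generator,
    amp_cv: float,
    latency_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Event onset times and absolute conductance weights for one pathway."""
    trigger_times = np.asarray(trigger_times, dtype=float)
    n = trigger_times.size
    if n == 0 or scale <= 0 or syn.g_peak <= 0:
        return np.empty(0), np.empty(0)
    rel = _stp_weights(trigger_times, syn)
    if amp_cv > 0:
        sigma = math.sqrt(math.log(1.0 + amp_cv**2))
        mult = np.exp(rng.normal(0.0, sigma, n) - 0.5 * sigma**2)
    else:
        mult = np.ones(n)
    if latency_sd > 0:
        jit = rng.normal(0.0, latency_sd, n)
    else:
        jit = np.zeros(n)
    times = trigger_times + syn.latency + jit
    times = np.maximum(times, trigger_times + 0.1)  # causality floor
    weights = syn.g_peak * scale * rel * mult
    return times, weights


def _event_conductance(
    n: int, dt: float, times: np.ndarray, weights: np.ndarray,
    tau_rise: float, tau_decay: float,
) -> np.ndarray:
    """Sum of peak-normalised dual-exponential transients on a uniform grid.

    Implemented as two one-pole IIR filters over an impulse train, which is
    exact for exponentials sampled on the grid.
    """
    g = np.zeros(n)
    if times.size == 0:
        return g
    imp = np.zeros(n)
    idx = np.round(times / dt).astype(int)
    keep = (idx >= 0) & (idx < n)
    np.add.at(imp, idx[keep], weights[keep])
    if not np.any(imp):
        return g
    a = lfilter([1.0], [1.0, -math.exp(-dt / tau_rise)], imp)
    b = lfilter([1.0], [1.0, -math.exp(-dt / tau_decay)], imp)
    norm = _dualexp_peak_norm(tau_rise, tau_decay)
    g = (b - a) / norm
    return np.maximum(g, 0.0)


# ---------------------------------------------------------------------------
# Integrate-and-fire kernel (numba)

@njit(cache=True)
def _lif_kernel(
    dt, v0, g_l, c_m, e_l, e_exc, e_inh, v_th, v_reset, ref_steps,
    g_e, g_i_stim, i_inj, v_noise,
    fb_on, fb_delay_steps, fb_g_peak, fb_tau_rise, fb_tau_decay, fb_norm,
    fb_u, fb_tau_fac, fb_lat_jit_steps,
):  # pragma: no cover - exercised via simulate_cell
    n = g_e.shape[0]
    v_out = np.empty(n)
    g_fb_out = np.zeros(n)
    spike_steps = np.empty(n, dtype=np.int64)
    n_spikes = 0
    fb_imp = np.zeros(n)
    dr = math.exp(-dt / fb_tau_rise)
    dd = math.exp(-dt / fb_tau_decay)
    a = 0.0
    b = 0.0
    u_state = fb_u
    last_trig = -1.0e18
    v = v0
    ref = 0
    for i in range(n):
        a = a * dr + fb_imp[i]
        b = b * dd + fb_imp[i]
        g_fb = (b - a) / fb_norm
        if g_fb < 0.0:
            g_fb = 0.0
        g_fb_out[i] = g_fb
        g_i = g_i_stim[i] + g_fb
        g_tot = g_l + g_e[i] + g_i
        v_inf = (g_l * e_l + g_e[i] * e_exc + g_i * e_inh + i_inj[i]) / g_tot
        v = v_inf + (v - v_inf) * math.exp(-g_tot * dt / c_m)
        v = v + v_noise[i]
        if ref > 0:
            ref -= 1
            v = v_reset
        elif v >= v_th:
            spike_steps[n_spikes] = i
            v = v_reset
            ref = ref_steps
            if fb_on:
                t_now = i * dt
                if fb_tau_fac > 0.0 and last_trig > -1.0e17:
                    u_k = fb_u + (u_state - fb_u) * math.exp(-(t_now - last_trig) / fb_tau_fac)
                else:
                    u_k = fb_u
                w = fb_g_peak * (u_k / fb_u)
                if fb_tau_fac > 0.0:
                    u_state = u_k + fb_u * (1.0 - u_k)
                last_trig = t_now
                j = i + fb_delay_steps + fb_lat_jit_steps[n_spikes % fb_lat_jit_steps.shape[0]]
                if 0 <= j < n:
                    fb_imp[j] += w
            n_spikes += 1
        v_out[i] = v
        if not math.isfinite(v):
            return v_out, g_fb_out, spike_steps[:n_spikes], i
    return v_out, g_fb_out, spike_steps[:n_spikes], -1


# ---------------------------------------------------------------------------
# Trace assembly helpers

def _time_grid(protocol: StimulationProtocol, dt: float = DT_MS) -> np.ndarray:
    n = int(round(protocol.sweep_ms / dt)) + 1
    return np.arange(n) * dt


def _add_artifacts(y: np.ndarray, dt: float, stim_times: np.ndarray, amp: float) -> None:
    w = max(1, int(round(ARTIFACT_MS / dt)))
    for s in stim_times:
        i0 = int(round(s / dt))
        y[i0: i0 + w] += amp


def _spike_waveform(dt: float, amp: float) -> tuple[np.ndarray, int]:
    """Stereotyped biphasic loose-patch spike; returns (waveform, index of the
    negative extremum within the waveform)."""
    tt = np.arange(-1.0, 2.0 + dt / 2, dt)
    w = amp * (-np.exp(-((tt / 0.15) ** 2)) + 0.45 * np.exp(-(((tt - 0.55) / 0.35) ** 2)))
    return w, int(np.argmin(w))


def _mono_synapse(params: CellModelParams) -> SynapseParams:
    """Direct (monosynaptic) inhibitory pathway: FF-like kinetics, short
    latency, amplitude a configurable fraction of the FF peak."""
    ff = params.inh_ff
    return SynapseParams(
        g_peak=params.mono_fraction * ff.g_peak,
        tau_rise=ff.tau_rise, tau_decay=ff.tau_decay,
        latency=MONO_LATENCY_MS,
        stp_u=ff.stp_u, stp_tau_fac=ff.stp_tau_fac, stp_tau_rec=ff.stp_tau_rec,
    )


def population_spike_probability(frequency: float, n_pulses: int) -> np.ndarray:
    """Stylised per-pulse probability that the surrounding granule-cell
    population emits a spike, used to drive feedback inhibition when the
    recorded cell is voltage clamped.  Anchored at ~0.55 on the first pulse
    (the calibrated 50% operating point) and declining along the train faster
    at higher frequency, mirroring the low-pass behaviour of the population.
    Phenotype-independent: feedback reflects the (mostly mature) population,
    not the recorded cell.
    """
    k = np.arange(n_pulses)
    return 0.55 * np.exp(-k * frequency / 250.0)


def intrinsic_pulse_amplitude(params: CellModelParams, width_ms: float = 2.0) -> float:
    """Current-pulse amplitude (pA) that reliably evokes one spike per pulse:
    1.5x the amplitude that just reaches threshold by the end of the pulse."""
    charge = 1.0 - math.exp(-width_ms / params.tau_m)
    return 1.5 * params.g_L * (params.V_th - params.E_L) / charge


def _check_finite_params(params: CellModelParams) -> None:
    # dataclass validation already rejects non-finite values; keep a cheap
    # defensive check for mutated instances
    for v in (params.C_m, params.g_L, params.E_L, params.V_th):
        if not math.isfinite(v):
            raise ValueError("non-finite cell parameter")


# ---------------------------------------------------------------------------
# Public simulators

def _stimulus_conductances(
    params: CellModelParams,
    protocol: StimulationProtocol,
    n: int,
    dt: float,
    train_index: int,
    include: dict,
) -> dict:
    """Per-pathway stimulus-driven conductance arrays for one sweep.

    Substreams are keyed by pathway, not condition, so paired conditions share
    event noise and differ only in which pathways are present.
    """
    stim = protocol.stim_times()
    noise = params.noise
    seed = noise.seed
    freq = protocol.frequency
    out = {}
    specs = {
        "exc": (params.exc, protocol.input_strength),
        "ff": (params.inh_ff, protocol.input_strength),
        "mono": (_mono_synapse(params), protocol.input_strength),
    }
    for name, (syn, scale) in specs.items():
        if not include.get(name, False):
            out[name] = np.zeros(n)
            continue
        rng = _substream(seed, freq, train_index, name)
        times, weights = _draw_events(
            syn, stim, scale, rng, noise.amp_cv, noise.latency_sd
        )
        out[name] = _event_conductance(n, dt, times, weights, syn.tau_rise, syn.tau_decay)
    return out


def simulate_cell(
    params: CellModelParams,
    protocol: StimulationProtocol,
    i_pulse_amp: float | None = None,
    i_pulse_width: float = 2.0,
) -> list[TraceRecording]:
    """Simulate spiking sweeps: loose-patch (synaptically driven) or
    intrinsic current-clamp (square current pulses, synapses off).

    Returns ``protocol.n_trains`` sweeps.  Loose-patch sweeps contain baseline
    noise, stimulus artifacts and a stereotyped biphasic waveform at each spike
    time; ground-truth spike times and internal conductances are stored in
    ``trace.meta``.
    """
    _check_finite_params(params)
    if protocol.mode not in ("loose_patch", "intrinsic_iclamp"):
        raise ValueError("simulate_cell handles loose_patch or intrinsic_iclamp modes")
    dt = DT_MS
    t = _time_grid(protocol, dt)
    n = t.size
    stim = protocol.stim_times()
    cond = protocol.condition
    intrinsic = protocol.mode == "intrinsic_iclamp"

    if intrinsic:
        include = dict(exc=False, ff=False, mono=False)
        fb_on = False
        if i_pulse_amp is None:
            i_pulse_amp = intrinsic_pulse_amplitude(params, i_pulse_width)
    else:
        include = dict(
            exc=cond not in ("KYN",),
            ff=cond in ("control", "DCG4"),
            mono=cond in ("control", "DCG4", "KYN"),
        )
        fb_on = cond == "control"

    fb = params.inh_fb
    fb_norm = _dualexp_peak_norm(fb.tau_rise, fb.tau_decay)
    ref_steps = max(1, int(round(params.t_ref / dt)))
    fb_delay_steps = int(round(fb.latency / dt))

    traces = []
    for k in range(protocol.n_trains):
        g = _stimulus_conductances(params, protocol, n, dt, k, include)
        g_e = g["exc"]
        g_i_stim = g["ff"] + g["mono"]

        i_inj = np.zeros(n)
        if intrinsic:
            w = int(round(i_pulse_width / dt))
            for s in stim:
                i0 = int(round(s / dt))
                i_inj[i0: i0 + w] = i_pulse_amp

        rng_v = _substream(params.noise.seed, protocol.frequency, k, "vnoise")
        if params.noise.v_noise_sd > 0:
            v_noise = params.noise.v_noise_sd * math.sqrt(2.0 * dt / params.tau_m) * rng_v.standard_normal(n)
        else:
            v_noise = np.zeros(n)
        rng_fb = _substream(params.noise.seed, protocol.frequency, k, "fb")
        fb_jit = np.round(
            rng_fb.normal(0.0, params.noise.latency_sd, 64) / dt
        ).astype(np.int64)

        v, g_fb, spike_steps, bad = _lif_kernel(
            dt, params.E_L, params.g_L, params.C_m, params.E_L,
            params.E_exc, params.E_inh, params.V_th, params.V_reset, ref_steps,
            g_e, g_i_stim, i_inj, v_noise,
            fb_on, fb_delay_steps, fb.g_peak, fb.tau_rise, fb.tau_decay, fb_norm,
            fb.stp_u, fb.stp_tau_fac, fb_jit,
        )
        if bad >= 0:
            raise FloatingPointError(
                f"integration produced a non-finite voltage at t = {bad * dt:.3f} ms"
            )
        spike_times = spike_steps * dt

        if intrinsic:
            y = v.copy()
            # render a stereotyped action potential peak so threshold crossings
            # are visible in the voltage trace
            y[spike_steps] = 30.0
        else:
            rng_b = _substream(params.noise.seed, protocol.frequency, k, "lp_noise")
            y = (
                params.loose_patch_noise_sd * rng_b.standard_normal(n)
                if params.loose_patch_noise_sd > 0
                else np.zeros(n)
            )
            wave, pk = _spike_waveform(dt, params.spike_waveform_amp)
            for s in spike_steps:
                i0 = s - pk
                lo, hi = max(i0, 0), min(i0 + wave.size, n)
                y[lo:hi] += wave[lo - i0: hi - i0]
            _add_artifacts(y, dt, stim, amp=150.0)

        traces.append(
            TraceRecording(
                t=t, y=y, stim_times=stim, mode=protocol.mode,
                condition=cond, phenotype=params.phenotype, train_index=k,
                meta=dict(
                    spike_times=spike_times,
                    v=v,
                    g_exc=g_e,
                    g_inh=g_i_stim + g_fb,
                    g_fb=g_fb,
                ),
            )
        )
    return traces


def simulate_voltage_clamp(
    params: CellModelParams,
    protocol: StimulationProtocol,
    holding_potential: float | None = None,
) -> list[TraceRecording]:
    """Simulate voltage-clamp current sweeps.

    ``vclamp_exc`` holds at the inhibitory reversal (isolating the EPSC);
    ``vclamp_inh`` holds at the excitatory reversal (isolating the IPSC).
    Feedback inhibition in voltage clamp is driven by a surrogate
    population-spike process (Bernoulli per pulse, see
    :func:`population_spike_probability`), because the clamped cell cannot
    spike while the surrounding population still does.
    """
    _check_finite_params(params)
    if protocol.mode not in ("vclamp_exc", "vclamp_inh"):
        raise ValueError("simulate_voltage_clamp handles vclamp_exc or vclamp_inh modes")
    exc_mode = protocol.mode == "vclamp_exc"
    target = params.E_inh if exc_mode else params.E_exc
    if holding_potential is None:
        holding_potential = target
    if abs(holding_potential - target) > 1.0:
        raise ValueError(
            f"holding potential {holding_potential} mV does not match the "
            f"required reversal ({target} mV) for mode {protocol.mode}"
        )
    dt = DT_MS
    t = _time_grid(protocol, dt)
    n = t.size
    stim = protocol.stim_times()
    cond = protocol.condition
    noise = params.noise

    if exc_mode:
        include = dict(exc=cond != "KYN", ff=False, mono=False)
    else:
        include = dict(
            exc=False,
            ff=cond in ("control", "DCG4"),
            mono=cond in ("control", "DCG4", "KYN"),
        )
    fb = params.inh_fb
    traces = []
    for k in range(protocol.n_trains):
        g = _stimulus_conductances(params, protocol, n, dt, k, include)
        g_fb = np.zeros(n)
        if (not exc_mode) and cond == "control" and fb.g_peak > 0:
            rng_fb = _substream(noise.seed, protocol.frequency, k, "fb")
            p = population_spike_probability(protocol.frequency, protocol.n_pulses)
            trig = stim + POP_SPIKE_LATENCY_MS
            # the population spike is a compound event of many granule cells:
            # a graded conductance scaled by the population spiking probability,
            # with timing scatter (0.3 ms SD) set by the network, not by the
            # recorded phenotype
            times, weights = _draw_events(fb, trig, 1.0, rng_fb, noise.amp_cv, 0.3)
            weights = weights * p
            g_fb = _event_conductance(n, dt, times, weights, fb.tau_rise, fb.tau_decay)

        if exc_mode:
            g_syn = g["exc"]
            i_syn = g_syn * (holding_potential - params.E_exc)
        else:
            g_syn = g["ff"] + g["mono"] + g_fb
            i_syn = g_syn * (holding_potential - params.E_inh)

        rng_b = _substream(noise.seed, protocol.frequency, k, "vclamp_noise")
        y = (
            params.vclamp_noise_sd * rng_b.standard_normal(n)
            if params.vclamp_noise_sd > 0
            else np.zeros(n)
        )
        y += i_syn
        _add_artifacts(y, dt, stim, amp=300.0)
        traces.append(
            TraceRecording(
                t=t, y=y, stim_times=stim, mode=protocol.mode,
                condition=cond, phenotype=params.phenotype, train_index=k,
                holding_potential=holding_potential,
                meta=dict(
                    g_syn=g_syn,
                    g_ff=g["ff"],
                    g_fb=g_fb,
                    g_mono=g["mono"],
                    g_exc=g["exc"],
                ),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Field recordings

@dataclass(frozen=True)
class FieldModelParams:
    """Generative model of the granule-cell-layer field response.

    The fEPSP is a negative dual-exponential deflection whose amplitude (and
    hence initial slope) grows sigmoidally with stimulus intensity; a biphasic
    population-spike wavelet rides on it with its own, right-shifted sigmoid
    that saturates at high intensity.
    """

    fepsp_max_mv: float = 1.2
    midpoint: float = 30.0  # intensity at half-maximal fEPSP (a.u.)
    scale: float = 8.0  # sigmoid slope scale (a.u.)
    ps_max_mv: float = 2.0
    ps_midpoint: float = 55.0
    ps_scale: float = 6.0
    noise_sd_mv: float = 0.01
    seed: int = 0

    def fepsp_amplitude(self, intensity: np.ndarray) -> np.ndarray:
        return self.fepsp_max_mv / (1.0 + np.exp(-(np.asarray(intensity, float) - self.midpoint) / self.scale))

    def pop_spike_amplitude(self, intensity: np.ndarray) -> np.ndarray:
        return self.ps_max_mv / (1.0 + np.exp(-(np.asarray(intensity, float) - self.ps_midpoint) / self.ps_scale))


def simulate_field(
    params_population: FieldModelParams,
    intensities: "np.ndarray | list[float]",
    sweep_ms: float = 60.0,
    stim_ms: float = 10.0,
) -> list[TraceRecording]:
    """Synthetic field sweeps at increasing stimulus intensities.

    The initial fEPSP slope grows sigmoidally with intensity; the
    population-spike deflection saturates, and the intensity at which it is
    maximal defines the 100% input-strength reference downstream.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < 4:
        raise ValueError("need at least 4 intensities for the downstream sigmoid fit")
    if np.any(intensities < 0):
        raise ValueError("intensities must be non-negative")
    if np.any(np.diff(intensities) <= 0):
        raise ValueError("intensities must be strictly increasing")
    dt = DT_MS
    t = np.arange(int(round(sweep_ms / dt)) + 1) * dt
    onset = stim_ms + 1.2  # fEPSP onset, after the artifact blank window
    tau_r, tau_d = 2.0, 10.0
    rel = np.where(
        t >= onset,
        np.exp(-(t - onset) / tau_d) - np.exp(-(t - onset) / tau_r),
        0.0,
    ) / _dualexp_peak_norm(tau_r, tau_d)
    ps_t = stim_ms + 6.0
    ps_wave = 0.5 * np.exp(-(((t - (ps_t - 0.8)) / 0.5) ** 2)) - np.exp(
        -(((t - ps_t) / 0.6) ** 2)
    )

    rng = np.random.default_rng(np.random.SeedSequence((int(params_population.seed) & 0x7FFFFFFF, zlib.crc32(b"field"))))
    amps = params_population.fepsp_amplitude(intensities)
    ps_amps = params_population.pop_spike_amplitude(intensities)
    traces = []
    for k, (inten, a, pa) in enumerate(zip(intensities, amps, ps_amps)):
        y = rng.normal(0.0, params_population.noise_sd_mv, t.size) if params_population.noise_sd_mv > 0 else np.zeros(t.size)
        if inten > 0:
            y -= a * rel
            y += pa * ps_wave
            _add_artifacts(y, dt, np.array([stim_ms]), amp=2.0)
        traces.append(
            TraceRecording(
                t=t, y=y, stim_times=np.array([stim_ms]) if inten > 0 else np.empty(0),
                mode="field", condition="control", phenotype="mature",
                train_index=k,
                meta=dict(intensity=float(inten), fepsp_amp=float(a), ps_amp=float(pa)),
            )
        )
    return traces
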
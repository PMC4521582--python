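"""Excitation/inhibition conductance analysis of voltage-clamp recordings.

Synaptic conductance is the recorded current divided by the driving force at
the holding potential: g(t) = (I(t) - baseline) / (V_hold - E_rev).  Per pulse,
the excitatory conductance (EPSG) is read at its own peak and the inhibitory
conductance (IPSG) at the EPSC-peak time of the same pulse — inhibition is
measured where it matters for spike generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TraceRecording

__all__ = [
    "ConductanceTable",
    "InhibitionTimingSummary",
    "current_to_conductance",
    "epsc_peak_time",
    "conductances_at_spike_time",
    "rise20_latency",
    "residual_recruited",
    "RESIDUAL_LAGS_MS",
]

log = logging.getLogger(__name__)

#: post-stimulus artifact blank excluded from every measurement (ms)
BLANK_MS = 1.0
#: pre-stimulus window used for the baseline estimate (ms)
BASELINE_MS = 50.0
#: lags at which residual inhibition is read out (ms)
RESIDUAL_LAGS_MS = (25.0, 50.0, 100.0, 1000.0)


@dataclass
class ConductanceTable:
    """Per-pulse EPSG/IPSG readout for one cell x condition x frequency."""

    cell_id: str
    phenotype: str
    condition: str
    frequency: float
    epsc_peak_times: np.ndarray  # ms from each stimulus (NaN = missing pulse)
    epsg_at_peak: np.ndarray  # nS
    ipsg_at_peak: np.ndarray  # nS
    mean_epsg: float = field(init=False)
    mean_ipsg: float = field(init=False)
    ei_ratio_per_pulse: np.ndarray = field(init=False)
    mean_ei_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.epsc_peak_times = np.asarray(self.epsc_peak_times, float)
        self.epsg_at_peak = np.asarray(self.epsg_at_peak, float)
        self.ipsg_at_peak = np.asarray(self.ipsg_at_peak, float)
        self.mean_epsg = float(np.nanmean(self.epsg_at_peak))
        self.mean_ipsg = float(np.nanmean(self.ipsg_at_peak))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ei_ratio_per_pulse = np.where(
                self.ipsg_at_peak > 0, self.epsg_at_peak / self.ipsg_at_peak, np.nan
            )
        self.mean_ei_ratio = (
            self.mean_epsg / self.mean_ipsg if self.mean_ipsg > 0 else np.nan
        )

    def to_frame(self) -> pd.DataFrame:
        n = self.epsg_at_peak.size
        return pd.DataFrame(
            dict(
                cell_id=self.cell_id,
                phenotype=self.phenotype,
                condition=self.condition,
                frequency=self.frequency,
                pulse=np.arange(1, n + 1),
                epsc_peak_time_ms=self.epsc_peak_times,
                epsg_nS=self.epsg_at_peak,
                ipsg_nS=self.ipsg_at_peak,
                ei_ratio=self.ei_ratio_per_pulse,
            )
        )


@dataclass
class InhibitionTimingSummary:
    """First-pulse inhibition kinetics and sustained-inhibition readout."""

    rise20_latency: float  # ms
    residual_ipsg: dict  # lag (ms) -> nS (NaN if lag beyond sweep)
    recruited_ipsg: float  # nS, mean IPSG at the EPSC-peak time at 1 Hz
    residual_plus_recruited: dict = field(init=False)

    def __post_init__(self) -> None:
        self.residual_plus_recruited = {
            lag: v + self.recruited_ipsg for lag, v in self.residual_ipsg.items()
        }


# ---------------------------------------------------------------------------

def _baseline(trace: TraceRecording) -> float:
    """Median of the 50 ms window before the first stimulus."""
    if trace.stim_times.size == 0:
        raise ValueError("trace has no stimulus; baseline window undefined")
    t0 = trace.stim_times[0]
    mask = (trace.t >= t0 - BASELINE_MS) & (trace.t < t0 - 0.5)
    # require at least 5 ms of baseline for a usable median
    if np.count_nonzero(mask) < int(5.0 / trace.dt):
        raise ValueError("no pre-stimulus baseline window available")
    return float(np.median(trace.y[mask]))


def current_to_conductance(trace: TraceRecording, reversal: float) -> np.ndarray:
    """Convert a voltage-clamp current sweep to a conductance trace (nS).

    g(t) = (I(t) - baseline) / (V_hold - E_rev); the baseline is the median of
    the 50 ms pre-stimulus (pre-train) window.  Small negative excursions are
    clipped to zero and the clipped fraction is logged.
    """
    if trace.holding_potential is None:
        raise ValueError("trace has no holding potential")
    dv = trace.holding_potential - reversal
    if abs(dv) <= 1.0:
        raise ValueError(
            f"holding ({trace.holding_potential} mV) too close to reversal "
            f"({reversal} mV); conductance undefined"
        )
    g = (trace.y - _baseline(trace)) / dv
    clipped = np.count_nonzero(g < 0) / g.size
    if clipped > 0.6:
        log.warning("conductance clip fraction %.2f — check sign conventions", clipped)
    elif clipped > 0:
        log.debug("clipped %.3f of conductance samples to zero", clipped)
    return np.maximum(g, 0.0)


def _pulse_window(trace: TraceRecording, stim_time: float) -> tuple[int, int]:
    """Sample range (artifact-blank end, next stimulus]."""
    dt = trace.dt
    later = trace.stim_times[trace.stim_times > stim_time + 1e-9]
    t_end = later[0] if later.size else trace.t[-1]
    i0 = int(np.ceil((stim_time + BLANK_MS) / dt))
    i1 = int(np.floor(t_end / dt))
    return i0, max(i1, i0 + 1)


def epsc_peak_time(
    exc_trace: TraceRecording, stim_time: float, noise_k: float = 4.0
) -> float:
    """Time of the EPSC peak relative to ``stim_time`` (ms); NaN if the pulse
    evoked no deflection above the noise floor."""
    base = _baseline(exc_trace)
    i0, i1 = _pulse_window(exc_trace, stim_time)
    seg = exc_trace.y[i0:i1] - base
    pre = exc_trace.y[
        (exc_trace.t >= exc_trace.stim_times[0] - BASELINE_MS)
        & (exc_trace.t < exc_trace.stim_times[0] - 0.5)
    ] - base
    noise_sd = float(pre.std()) if pre.size else 0.0
    j = int(np.argmax(np.abs(seg)))
    if np.abs(seg[j]) <= noise_k * noise_sd:
        return np.nan
    return (i0 + j) * exc_trace.dt - stim_time


def conductances_at_spike_time(
    exc_trace: TraceRecording,
    inh_trace: TraceRecording,
    stim_times: np.ndarray | None = None,
    cell_id: str | None = None,
    e_exc: float = 0.0,
    e_inh: float = -60.0,
) -> ConductanceTable:
    """Per-pulse EPSG (at its own peak) and IPSG (at the EPSC-peak time).

    The two traces must come from the same cell and protocol.  Pulses whose
    EPSC is missing are read at the median peak latency of the remaining
    pulses (logged).
    """
    if stim_times is None:
        stim_times = exc_trace.stim_times
    if exc_trace.stim_times.size != inh_trace.stim_times.size:
        raise ValueError("excitation and inhibition traces have different protocols")
    # each trace is recorded at one component's reversal and reports the other:
    # the EPSC trace divides by (E_inh - E_exc), the IPSC trace by (E_exc - E_inh)
    g_e = current_to_conductance(exc_trace, reversal=e_exc)
    g_i = current_to_conductance(inh_trace, reversal=e_inh)
    dt = exc_trace.dt

    peak_rel = np.array([epsc_peak_time(exc_trace, s) for s in stim_times])
    missing = ~np.isfinite(peak_rel)
    if missing.any():
        if missing.all():
            raise ValueError("no pulse evoked a measurable EPSC")
        fill = float(np.nanmedian(peak_rel))
        log.info(
            "cell %s: %d pulses without measurable EPSC; using median peak latency %.2f ms",
            cell_id, int(missing.sum()), fill,
        )
        peak_rel = np.where(missing, fill, peak_rel)

    epsg = np.empty(stim_times.size)
    ipsg = np.empty(stim_times.size)
    for k, s in enumerate(stim_times):
        idx = int(round((s + peak_rel[k]) / dt))
        idx = min(idx, g_e.size - 1)
        epsg[k] = g_e[idx]
        ipsg[k] = g_i[idx]
    return ConductanceTable(
        cell_id=cell_id or exc_trace.cell_id,
        phenotype=exc_trace.phenotype,
        condition=inh_trace.condition,
        frequency=(
            1000.0 / float(np.diff(stim_times).mean()) if stim_times.size > 1 else np.nan
        ),
        epsc_peak_times=np.where(missing, np.nan, peak_rel),
        epsg_at_peak=epsg,
        ipsg_at_peak=ipsg,
    )


def rise20_latency(
    inh_trace: TraceRecording, stim_time: float | None = None, noise_k: float = 4.0
) -> float:
    """Latency (ms from the stimulus) at which the IPSC first reaches 20% of
    its first-pulse peak, linearly interpolated between samples."""
    if stim_time is None:
        stim_time = inh_trace.stim_times[0]
    base = _baseline(inh_trace)
    i0, i1 = _pulse_window(inh_trace, stim_time)
    seg = np.abs(inh_trace.y[i0:i1] - base)
    pre = inh_trace.y[
        (inh_trace.t >= inh_trace.stim_times[0] - BASELINE_MS)
        & (inh_trace.t < inh_trace.stim_times[0] - 0.5)
    ] - base
    noise_sd = float(pre.std()) if pre.size else 0.0
    jpk = int(np.argmax(seg))
    peak = seg[jpk]
    if peak <= noise_k * noise_sd:
        return np.nan
    target = 0.2 * peak
    above = np.flatnonzero(seg[: jpk + 1] >= target)
    if above.size == 0:
        return np.nan
    j = above[0]
    dt = inh_trace.dt
    if j == 0:
        t_cross = i0 * dt
    else:
        y0, y1 = seg[j - 1], seg[j]
        frac = (target - y0) / (y1 - y0) if y1 != y0 else 0.0
        t_cross = (i0 + j - 1 + frac) * dt
    return t_cross - stim_time


def residual_recruited(
    inh_trace_1hz: TraceRecording,
    exc_trace_1hz: TraceRecording | None = None,
    lags_ms: tuple = RESIDUAL_LAGS_MS,
    spike_latency_ms: float | None = None,
) -> InhibitionTimingSummary:
    """Sustained-inhibition readout from a 1 Hz inhibition recording.

    Residual inhibition is the conductance remaining ``lag`` ms after the first
    pulse; recruited inhibition is the inhibition newly evoked by a pulse, read
    at the spike time.  Pass the cell's measured action-potential latency as
    ``spike_latency_ms`` (from loose-patch recordings); without it the readout
    falls back to the EPSC-peak time (spikes and EPSC peaks occur close in
    time, though inhibition is still rising steeply between them).
    """
    stim = inh_trace_1hz.stim_times
    if stim.size > 1:
        ipi = float(np.diff(stim).mean())
        if abs(ipi - 1000.0) > 50.0:
            raise ValueError("residual/recruited analysis expects a 1 Hz recording")
    g_i = current_to_conductance(inh_trace_1hz, reversal=-60.0)
    dt = inh_trace_1hz.dt
    t_max = inh_trace_1hz.t[-1]
    residual = {}
    s0 = stim[0]
    for lag in lags_ms:
        # read 0.1 ms early so a lag landing exactly on the next stimulus
        # (1000 ms at 1 Hz) is not contaminated by its artifact
        t_read = s0 + lag - 0.1
        if t_read > t_max:
            residual[lag] = np.nan
        else:
            residual[lag] = float(g_i[int(round(t_read / dt))])

    if spike_latency_ms is not None:
        read_at = float(spike_latency_ms)
        idxs = [int(round((s + read_at) / dt)) for s in stim]
        recruited = float(np.mean([g_i[min(i, g_i.size - 1)] for i in idxs]))
    elif exc_trace_1hz is not None:
        table = conductances_at_spike_time(exc_trace_1hz, inh_trace_1hz)
        recruited = table.mean_ipsg
    else:
        # nominal readout 3.5 ms after each stimulus
        idxs = [int(round((s + 3.5) / dt)) for s in stim]
        recruited = float(np.mean([g_i[min(i, g_i.size - 1)] for i in idxs]))
    rise = rise20_latency(inh_trace_1hz)
    return InhibitionTimingSummary(
        rise20_latency=rise, residual_ipsg=residual, recruited_ipsg=recruited
    )
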
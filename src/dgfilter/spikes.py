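"""Spike detection and spike-train statistics for loose-patch recordings.

Covers the full activation analysis: per-pulse spike probability, mean spikes
per train, efficacy of frequency transmission, the frequency-following test,
and first-pulse latency/jitter with the variance-ratio comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .params import TraceRecording
from .stats import TestResult, variance_ratio_test, wilcoxon_signed_rank

__all__ = [
    "SpikeRaster",
    "ActivationSummary",
    "TimingSummary",
    "detect_spikes",
    "build_raster",
    "assign_spikes",
    "per_pulse_probability",
    "mean_total_spikes",
    "efficacy",
    "frequency_following_test",
    "latency_and_jitter",
    "variance_ratio_test",
]

#: post-stimulus window blanked around each artifact (ms)
BLANK_MS = 1.0
#: minimum separation between detected events (ms)
MERGE_MS = 1.0
#: spike-to-pulse assignment window cap for the last pulse (ms), keeping 1 Hz
#: comparable to 10 Hz
LAST_PULSE_CAP_MS = 100.0


# ---------------------------------------------------------------------------
# Detection

def detect_spikes(trace: TraceRecording, k: float = 5.0) -> np.ndarray:
    """Detect spike times (ms) in a loose-patch sweep.

    Stimulus-artifact windows are blanked, the signal is high-pass filtered
    (300 Hz), and events are found where the rectified signal exceeds
    ``k`` times a robust (MAD-based) noise SD.  Events closer than 1 ms are
    merged; each event is localised at its absolute extremum.
    """
    if trace.mode != "loose_patch":
        raise ValueError("detect_spikes expects a loose_patch trace")
    y = trace.y.astype(float).copy()
    dt = trace.dt
    n = y.size
    finite_span = np.ptp(y)
    if finite_span == 0:
        return np.empty(0)
    # saturation check: a long contiguous run pinned at an extreme means the
    # amplifier clipped (stimulus artifacts are brief, ~0.5 ms, and spikes
    # never plateau)
    for extreme in (y.max(), y.min()):
        pinned = np.flatnonzero(y == extreme)
        if pinned.size > 40:
            runs = np.split(pinned, np.flatnonzero(np.diff(pinned) > 1) + 1)
            if max(len(r) for r in runs) > int(2.0 / dt):
                raise ValueError("trace appears saturated/clipped")

    blank = np.zeros(n, dtype=bool)
    w = int(round(BLANK_MS / dt))
    for s in trace.stim_times:
        i0 = max(int(np.floor((s - 0.1) / dt)), 0)
        blank[i0: i0 + w + 2] = True
    y[blank] = 0.0

    nyq = 0.5 / (dt * 1e-3)  # Hz
    sos = butter(2, 300.0 / nyq, btype="highpass", output="sos")
    hp = sosfiltfilt(sos, y)
    hp[blank] = 0.0

    mad = np.median(np.abs(hp - np.median(hp)))
    sd = 1.4826 * mad
    if sd <= 1e-9 * max(np.abs(hp).max(), 1e-30):  # numerically noiseless
        # noiseless trace: threshold at half the largest deflection, above any
        # filter ringing but below every rendered spike
        sd = np.abs(hp).max() / (2.0 * k) if np.abs(hp).max() > 0 else 0.0
        if sd == 0:
            return np.empty(0)
    above = np.abs(hp) > k * sd
    if not np.any(above):
        return np.empty(0)
    idx = np.flatnonzero(above)
    # split into events separated by > MERGE_MS
    gaps = np.flatnonzero(np.diff(idx) * dt > MERGE_MS)
    starts = np.r_[0, gaps + 1]
    ends = np.r_[gaps, idx.size - 1]
    times = []
    merge_steps = int(round(MERGE_MS / dt))
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e]
        # single-sample threshold excursions are noise tails, not spikes: a
        # real spike waveform stays above threshold for >= 3 samples
        if e - s + 1 < 3:
            continue
        seg = hp[max(lo - merge_steps, 0): hi + merge_steps]
        off = max(lo - merge_steps, 0)
        peak = off + int(np.argmax(np.abs(seg)))
        times.append(peak * dt)
    times = np.array(sorted(times))
    if times.size > 1:
        keep = np.r_[True, np.diff(times) >= MERGE_MS]
        times = times[keep]
    return times


# ---------------------------------------------------------------------------
# Raster container

@dataclass
class SpikeRaster:
    """Detected spike times organised per train for one cell/condition/frequency."""

    cell_id: str
    phenotype: str
    condition: str
    frequency: float
    spike_times: list  # list of per-train sorted arrays (ms)
    stim_times: list  # list of per-train arrays (ms)
    n_pulses: int
    n_trains: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.spike_times) != len(self.stim_times) or not self.spike_times:
            raise ValueError("need matching, non-empty per-train spike and stim lists")
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]
        self.stim_times = [np.asarray(s, dtype=float) for s in self.stim_times]
        for s in self.spike_times:
            if s.size > 1 and np.any(np.diff(s) < MERGE_MS - 1e-9):
                raise ValueError("spikes violate the 1 ms refractory floor")
        self.n_trains = len(self.spike_times)


def build_raster(traces: list[TraceRecording], cell_id: str | None = None) -> SpikeRaster:
    """Detect spikes in a set of loose-patch sweeps and build a raster."""
    if not traces:
        raise ValueError("no traces given")
    first = traces[0]
    freq = 1000.0 / np.diff(first.stim_times).mean() if first.stim_times.size > 1 else np.nan
    return SpikeRaster(
        cell_id=cell_id or first.cell_id,
        phenotype=first.phenotype,
        condition=first.condition,
        frequency=float(freq),
        spike_times=[detect_spikes(tr) for tr in traces],
        stim_times=[tr.stim_times for tr in traces],
        n_pulses=int(first.stim_times.size),
    )


# ---------------------------------------------------------------------------
# Activation statistics

def assign_spikes(raster: SpikeRaster) -> tuple[np.ndarray, int]:
    """Assign spikes to stimulus pulses.

    A spike belongs to the most recent preceding stimulus if it falls within
    that stimulus's inter-pulse interval (for the last pulse: within one
    interval, capped at 100 ms).  Multiple spikes in one window count once.

    Returns ``(hits, spontaneous)`` where ``hits`` is an
    (n_trains, n_pulses) boolean array and ``spontaneous`` counts spikes
    preceding the first stimulus or falling outside every window.
    """
    hits = np.zeros((raster.n_trains, raster.n_pulses), dtype=bool)
    spont = 0
    for k, (spk, stim) in enumerate(zip(raster.spike_times, raster.stim_times)):
        if stim.size != raster.n_pulses:
            raise ValueError("train with unexpected pulse count")
        ipi = np.diff(stim).mean() if stim.size > 1 else LAST_PULSE_CAP_MS
        for s in spk:
            j = int(np.searchsorted(stim, s, side="right")) - 1
            if j < 0:
                spont += 1
                continue
            window = ipi if j < raster.n_pulses - 1 else min(ipi, LAST_PULSE_CAP_MS)
            if s - stim[j] <= window:
                hits[k, j] = True
            else:
                spont += 1
    return hits, spont


def per_pulse_probability(raster: SpikeRaster) -> np.ndarray:
    """Fraction of trains with at least one assigned spike, per pulse."""
    hits, _ = assign_spikes(raster)
    return hits.mean(axis=0)


def train_counts(raster: SpikeRaster) -> np.ndarray:
    """Answered pulses per train (one spike max per pulse)."""
    hits, _ = assign_spikes(raster)
    return hits.sum(axis=1)


def mean_total_spikes(raster: SpikeRaster) -> float:
    """Mean number of answered pulses per train (one spike max per pulse)."""
    return float(train_counts(raster).mean())


def efficacy(raster: SpikeRaster) -> float:
    """Efficacy of frequency transmission.

    Per train, the fraction of adjacent pulse pairs in which both pulses carry
    an assigned spike, out of the n_pulses - 1 intervals in the train; averaged
    across trains.  A train answering 5 consecutive pulses of 10 scores 4/9; 5
    non-adjacent pulses score 0; all 10 pulses score 1.
    """
    if raster.n_pulses < 2:
        raise ValueError("efficacy requires at least 2 pulses")
    hits, _ = assign_spikes(raster)
    pairs = hits[:, :-1] & hits[:, 1:]
    return float(pairs.sum(axis=1).mean() / (raster.n_pulses - 1))


def frequency_following_test(
    per_cell_counts: np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Is the population's mean spikes-per-train different from 1?

    One-sample Wilcoxon signed-rank test against 1 over per-cell mean total
    spike counts (exact null for n <= 25).
    """
    counts = np.asarray(per_cell_counts, dtype=float)
    if counts.size < 5:
        raise ValueError("need at least 5 cells/trains for the signed-rank test")
    return wilcoxon_signed_rank(counts, mu=1.0, alpha=alpha)


# ---------------------------------------------------------------------------
# Timing

@dataclass
class TimingSummary:
    """First-pulse spike latencies and their jitter, pooled across cells."""

    latencies: np.ndarray  # ms, all first-pulse spike latencies
    jitter_values: np.ndarray  # ms, deviations from each cell's mean latency
    jitter_sd: float  # ms
    n_cells: int
    excluded_cells: list


def pulse_response_latencies(raster: SpikeRaster, pulses: str = "first") -> np.ndarray:
    """Latency of the first spike after each stimulated pulse (NaN if none).

    ``pulses="first"`` uses only pulse 1 of each train (one trial per train);
    ``pulses="all"`` treats every pulse of the train as a repeated trial, as in
    low-frequency protocols where pulses are far enough apart to be
    independent trials.
    """
    out = []
    for spk, stim in zip(raster.spike_times, raster.stim_times):
        ipi = np.diff(stim).mean() if stim.size > 1 else LAST_PULSE_CAP_MS
        window = min(ipi, LAST_PULSE_CAP_MS)
        use = stim[:1] if pulses == "first" else stim
        for s in use:
            cand = spk[(spk > s) & (spk - s <= window)]
            out.append(cand[0] - s if cand.size else np.nan)
    return np.asarray(out)


def latency_and_jitter(
    rasters: list[SpikeRaster], min_trials: int = 3, pulses: str = "first"
) -> TimingSummary:
    """Pool per-trial spike latencies and jitter across cells.

    Jitter per trial is the deviation of that trial's latency from the cell's
    own mean latency; cells with fewer than ``min_trials`` spiking trials are
    excluded and logged.  With ``pulses="all"`` every answered pulse counts as
    a trial (appropriate for 1 Hz trains).
    """
    lat_all, jit_all, excluded = [], [], []
    n_used = 0
    for r in rasters:
        lat = pulse_response_latencies(r, pulses=pulses)
        lat = lat[np.isfinite(lat)]
        if lat.size < min_trials:
            excluded.append(r.cell_id)
            continue
        n_used += 1
        lat_all.append(lat)
        jit_all.append(lat - lat.mean())
    if not lat_all:
        return TimingSummary(np.empty(0), np.empty(0), np.nan, 0, excluded)
    lat_all = np.concatenate(lat_all)
    jit_all = np.concatenate(jit_all)
    sd = float(jit_all.std(ddof=1)) if jit_all.size > 1 else 0.0
    return TimingSummary(lat_all, jit_all, sd, n_used, excluded)
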
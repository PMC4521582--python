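"""Feedforward/feedback separation of inhibition and KYN quality control.

DCG4 (a group II mGluR agonist) silences mossy-fibre release and thereby
feedback inhibition, leaving the feedforward IPSC; the feedback IPSC is the
pointwise difference between the control (total) and DCG4 recordings.
Kynurenic acid (KYN) blocks all glutamatergic transmission; whatever IPSC
survives is directly (monosynaptically) stimulated inhibition.  A recording
qualifies for analysis only if KYN blocks more than 70% of the IPSC, and the
monosynaptic remainder (always below 30% of the peak) is subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import TraceRecording

__all__ = ["DecompositionResult", "KynFilterResult", "decompose_ff_fb", "kyn_quality_filter"]

log = logging.getLogger(__name__)

#: maximum tolerated stimulus misalignment between paired sweeps (ms)
MAX_SHIFT_MS = 1.0


@dataclass
class DecompositionResult:
    """Total, feedforward and feedback IPSC arrays for one paired sweep."""

    total_ipsc: np.ndarray  # pA, baseline-subtracted
    ff_ipsc: np.ndarray  # pA
    fb_ipsc: np.ndarray  # pA, total - ff with negative excursions clipped
    ff_fraction_peak: float
    clipped_fraction: float
    shift_samples: int


@dataclass
class KynFilterResult:
    kyn_block_fraction: float
    monosynaptic_fraction: float
    included: bool
    corrected_ipsc: np.ndarray | None  # pA; None when the cell is excluded


def _baseline_subtract(trace: TraceRecording) -> np.ndarray:
    t0 = trace.stim_times[0]
    mask = (trace.t >= t0 - 50.0) & (trace.t < t0 - 0.5)
    if not np.any(mask):
        raise ValueError("no pre-stimulus baseline window")
    return trace.y - np.median(trace.y[mask])


def _artifact_shift(a: TraceRecording, b: TraceRecording) -> int:
    """Relative shift (samples) between the two sweeps' first stimulus
    artifacts, from cross-correlation of short artifact windows."""
    dt = a.dt
    w = int(round(2.0 / dt))
    ia = int(round(a.stim_times[0] / dt))
    ib = int(round(b.stim_times[0] / dt))
    seg_a = a.y[ia: ia + w] - np.median(a.y[ia: ia + w])
    seg_b = b.y[ib: ib + w] - np.median(b.y[ib: ib + w])
    if seg_a.size != seg_b.size or seg_a.size == 0:
        raise ValueError("cannot window the stimulus artifacts")
    xc = np.correlate(seg_a, seg_b, mode="full")
    lag = int(np.argmax(xc)) - (seg_b.size - 1)
    return (ia - ib) + lag


def decompose_ff_fb(
    total: TraceRecording, dcg4: TraceRecording
) -> DecompositionResult:
    """Split the total IPSC into feedforward and feedback components.

    ``total`` is a control inhibition sweep and ``dcg4`` its DCG4-paired
    sweep (same cell, same protocol).  After baseline alignment and an
    artifact cross-correlation alignment check (max 1 ms), the feedback
    current is the pointwise difference; negative excursions (FF exceeding
    total, from noise) are clipped to zero and the clipped fraction reported.
    """
    if total.stim_times.size != dcg4.stim_times.size:
        raise ValueError("protocol mismatch: different pulse counts")
    if total.stim_times.size > 1:
        ipi_t = np.diff(total.stim_times).mean()
        ipi_d = np.diff(dcg4.stim_times).mean()
        if abs(ipi_t - ipi_d) > 1e-6 * ipi_t:
            raise ValueError("protocol mismatch: different frequencies")
    shift = _artifact_shift(total, dcg4)
    if abs(shift) * total.dt > MAX_SHIFT_MS:
        raise ValueError(
            f"sweeps misaligned by {abs(shift) * total.dt:.2f} ms (> {MAX_SHIFT_MS} ms)"
        )
    tot = _baseline_subtract(total)
    ff = _baseline_subtract(dcg4)
    if shift > 0:
        ff = np.r_[np.zeros(shift), ff[:-shift]] if shift else ff
    elif shift < 0:
        ff = np.r_[ff[-shift:], np.zeros(-shift)]
    fb = tot - ff
    neg = fb < 0
    clipped = float(np.count_nonzero(neg) / fb.size)
    fb = np.maximum(fb, 0.0)
    peak_tot = float(np.abs(tot).max())
    ff_frac = float(np.clip(np.abs(ff).max() / peak_tot, 0.0, 1.0)) if peak_tot > 0 else np.nan
    if clipped > 0:
        log.debug("clipped %.3f of FB samples (FF exceeded total)", clipped)
    return DecompositionResult(
        total_ipsc=tot, ff_ipsc=ff, fb_ipsc=fb,
        ff_fraction_peak=ff_frac, clipped_fraction=clipped, shift_samples=shift,
    )


def _pulse1_peak(trace_y: np.ndarray, trace: TraceRecording) -> float:
    dt = trace.dt
    s = trace.stim_times[0]
    later = trace.stim_times[trace.stim_times > s + 1e-9]
    t_end = min(later[0] if later.size else trace.t[-1], s + 100.0)
    i0 = int(np.ceil((s + 1.0) / dt))
    i1 = int(np.floor(t_end / dt))
    return float(np.abs(trace_y[i0:i1]).max())


def kyn_quality_filter(
    control_ipsc: TraceRecording, kyn_ipsc: TraceRecording
) -> KynFilterResult:
    """Apply the KYN inclusion filter and monosynaptic subtraction.

    Block fraction = 1 - peak(KYN)/peak(control) on the first pulse; the cell
    is included only if KYN blocked more than 70% of the IPSC.  When the
    monosynaptic remainder is below 30% of the peak it is subtracted pointwise
    from the control IPSC; otherwise the cell is excluded.
    """
    ctrl = _baseline_subtract(control_ipsc)
    kyn = _baseline_subtract(kyn_ipsc)
    peak_c = _pulse1_peak(ctrl, control_ipsc)
    peak_k = _pulse1_peak(kyn, kyn_ipsc)
    if peak_c <= 0:
        raise ValueError("control IPSC has no measurable peak")
    if peak_k > peak_c:
        raise ValueError("KYN IPSC exceeds control IPSC; invalid recording")
    mono_frac = peak_k / peak_c
    block_frac = 1.0 - mono_frac
    included = block_frac > 0.7 and mono_frac < 0.3
    if not included:
        log.info(
            "cell %s excluded: KYN block %.2f, monosynaptic fraction %.2f",
            control_ipsc.cell_id, block_frac, mono_frac,
        )
        return KynFilterResult(block_frac, mono_frac, False, None)
    if ctrl.size != kyn.size:
        raise ValueError("paired sweeps differ in length")
    return KynFilterResult(block_frac, mono_frac, True, ctrl - kyn)
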
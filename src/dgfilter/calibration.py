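"""Input-strength calibration from field recordings.

Stimulation intensity is an arbitrary, slice-dependent quantity; input
strength is made comparable across slices by normalising the fEPSP slope at
each intensity to the slope at the intensity that evokes the maximal
population spike (the 100% reference).  All train experiments run at the 50%
operating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .params import TraceRecording

__all__ = [
    "InputStrengthCurve",
    "measure_fepsp_slope",
    "pop_spike_amplitude",
    "fit_input_curve",
    "calibrate_from_traces",
]

log = logging.getLogger(__name__)

#: artifact blank after each stimulus (ms)
BLANK_MS = 1.0
#: search window for the fEPSP trough after the blank (ms); kept short so the
#: population-spike deflection (~5-8 ms post stimulus) never enters the fit
FEPSP_WINDOW_MS = 3.8
#: search window for the population-spike deflection (ms post stimulus)
PS_WINDOW_MS = (4.5, 8.5)


def _sigmoid(x, top, midpoint, scale):
    return top / (1.0 + np.exp(-(x - midpoint) / scale))


@dataclass
class InputStrengthCurve:
    """Fitted intensity -> fEPSP-slope relation and the derived operating points."""

    intensities: np.ndarray
    fepsp_slopes: np.ndarray  # mV/ms
    sigmoid_params: tuple  # (top, midpoint, scale)
    ref_intensity: float  # smallest intensity with a near-maximal pop spike
    ref_slope_100pct: float  # mV/ms, measured slope at ref_intensity
    target_intensity_50pct: float

    def normalized_strength(self, intensity: float) -> float:
        """Normalised input strength at an intensity (1.0 at the reference)."""
        intensity = float(intensity)
        if np.any(np.isclose(self.intensities, intensity)):
            i = int(np.argmin(np.abs(self.intensities - intensity)))
            return float(self.fepsp_slopes[i] / self.ref_slope_100pct)
        return float(_sigmoid(intensity, *self.sigmoid_params) / self.ref_slope_100pct)


def measure_fepsp_slope(trace: TraceRecording, stim_index: int = 0) -> float:
    """Initial slope of the fEPSP (mV/ms, positive magnitude).

    Linear fit over the 20-80% span of the rising phase of the post-artifact
    negative deflection.  Returns 0 (with a warning) when no deflection rises
    above the noise floor.
    """
    if trace.mode != "field":
        raise ValueError("measure_fepsp_slope expects a field trace")
    if trace.stim_times.size == 0:
        warnings.warn("trace has no stimulus; returning slope 0")
        return 0.0
    s = trace.stim_times[stim_index]
    dt = trace.dt
    i0 = int(np.ceil((s + BLANK_MS) / dt))
    i1 = int(round((s + BLANK_MS + FEPSP_WINDOW_MS) / dt))
    seg = trace.y[i0:i1]
    pre = trace.y[trace.t < s - 0.5]
    base = float(np.median(pre)) if pre.size else 0.0
    noise_sd = float(pre.std()) if pre.size else 0.0
    seg = seg - base
    jpk = int(np.argmin(seg))
    trough = seg[jpk]
    if trough >= -4.0 * noise_sd or trough >= 0:
        warnings.warn("no fEPSP deflection above the noise floor; slope = 0")
        return 0.0
    lo, hi = 0.2 * trough, 0.8 * trough  # note: negative numbers
    mask = np.flatnonzero((seg[: jpk + 1] <= lo) & (seg[: jpk + 1] >= hi))
    if mask.size < 2:
        warnings.warn("rising phase too short to fit; slope = 0")
        return 0.0
    tt = (i0 + mask) * dt
    coef = np.polyfit(tt, seg[mask], 1)
    return float(abs(coef[0]))


def pop_spike_amplitude(trace: TraceRecording, stim_index: int = 0) -> float:
    """Peak-to-trough amplitude (mV) of the population-spike deflection."""
    if trace.stim_times.size == 0:
        return 0.0
    s = trace.stim_times[stim_index]
    mask = (trace.t >= s + PS_WINDOW_MS[0]) & (trace.t <= s + PS_WINDOW_MS[1])
    seg = trace.y[mask]
    if seg.size == 0:
        return 0.0
    return float(seg.max() - seg.min())


def fit_input_curve(
    intensities: np.ndarray,
    slopes: np.ndarray,
    pop_spike_amplitudes: np.ndarray,
) -> InputStrengthCurve:
    """Fit the 3-parameter sigmoid and locate the 100% and 50% operating points.

    The 100% reference is the smallest intensity whose pop-spike amplitude is
    within 1% of the maximum observed; the 50% target solves
    sigmoid(intensity) = 0.5 * reference slope and must lie inside the sampled
    intensity range (extrapolation is refused).
    """
    intensities = np.asarray(intensities, float)
    slopes = np.asarray(slopes, float)
    ps = np.asarray(pop_spike_amplitudes, float)
    if not (intensities.size == slopes.size == ps.size):
        raise ValueError("intensities, slopes and pop-spike amplitudes must align")
    if intensities.size < 4:
        raise ValueError("need at least 4 points for the sigmoid fit")
    if np.ptp(slopes) <= 1e-12 * max(1.0, np.abs(slopes).max()):
        raise ValueError("slopes carry no dynamic range; degenerate fit")

    p0 = (slopes.max(), float(np.median(intensities)), np.ptp(intensities) / 8.0)
    try:
        popt, pcov = curve_fit(
            _sigmoid, intensities, slopes, p0=p0,
            bounds=([0, intensities.min() - np.ptp(intensities), 1e-6],
                    [10 * max(slopes.max(), 1e-9), intensities.max() + np.ptp(intensities), np.ptp(intensities)]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = slopes - _sigmoid(intensities, *p0)
        raise RuntimeError(f"sigmoid fit did not converge; residuals {resid}") from err
    resid = slopes - _sigmoid(intensities, *popt)
    if np.sqrt(np.mean(resid**2)) > 0.5 * np.ptp(slopes):
        raise RuntimeError(f"sigmoid fit failed to describe the data; residuals {resid}")

    ps_max = ps.max()
    qual = np.flatnonzero(ps >= 0.99 * ps_max)
    ref_i = int(qual[0])  # tie-break: smallest qualifying intensity
    ref_intensity = float(intensities[ref_i])
    ref_slope = float(slopes[ref_i])
    if ref_slope <= 0:
        raise ValueError("reference slope is not positive")

    top, mid, scale = popt
    half = 0.5 * ref_slope
    if not 0 < half < top:
        raise ValueError("half-reference slope outside the sigmoid's range")
    target = mid - scale * np.log(top / half - 1.0)
    if not intensities.min() <= target <= intensities.max():
        raise ValueError(
            f"50% target intensity {target:.2f} outside the sampled range; "
            "extrapolation refused"
        )
    return InputStrengthCurve(
        intensities=intensities,
        fepsp_slopes=slopes,
        sigmoid_params=(float(top), float(mid), float(scale)),
        ref_intensity=ref_intensity,
        ref_slope_100pct=ref_slope,
        target_intensity_50pct=float(target),
    )


def calibrate_from_traces(traces: list[TraceRecording]) -> InputStrengthCurve:
    """Measure slopes and pop spikes on a generated intensity family and fit."""
    intensities = np.array([tr.meta.get("intensity", np.nan) for tr in traces])
    if np.any(~np.isfinite(intensities)):
        raise ValueError("field traces lack intensity metadata")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        slopes = np.array([measure_fepsp_slope(tr) for tr in traces])
    ps = np.array([pop_spike_amplitude(tr) for tr in traces])
    return fit_input_curve(intensities, slopes, ps)
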
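"""Domain types: cell/synapse parameters, stimulation protocols, trace records.

Units used throughout the package: time in ms, voltage in mV, current in pA,
conductance in nS, capacitance in pF.  With these units the membrane equation
``C dV/dt = -g (V - E) + I`` is dimensionally consistent without conversion
factors (nS * mV = pA, pA / pF = mV/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SynapseParams",
    "NoiseParams",
    "CellModelParams",
    "StimulationProtocol",
    "TraceRecording",
    "mature_cell",
    "immature_cell",
    "CONDITIONS",
    "MODES",
    "PHENOTYPES",
]

CONDITIONS = ("control", "PTX", "DCG4", "KYN")
MODES = ("loose_patch", "vclamp_exc", "vclamp_inh", "intrinsic_iclamp", "field")
PHENOTYPES = ("mature", "immature")

#: default acquisition rate (kHz) — 20 kHz sampling, i.e. dt = 0.05 ms
SAMPLE_RATE_KHZ = 20.0
DT_MS = 1.0 / SAMPLE_RATE_KHZ


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics and short-term dynamics of one effective synaptic pathway.

    The conductance waveform per activation is a difference of exponentials
    normalised to peak ``g_peak``.  Short-term dynamics follow the standard
    resource/utilisation (Tsodyks–Markram) update; ``stp_tau_fac <= 0``
    disables facilitation and ``stp_tau_rec <= 0`` disables depression.
    """

    g_peak: float  # nS, peak conductance of a single activation at full strength
    tau_rise: float  # ms
    tau_decay: float  # ms
    latency: float  # ms, delay from the triggering event to conductance onset
    stp_u: float = 1.0  # baseline utilisation (release fraction)
    stp_tau_fac: float = 0.0  # ms, facilitation recovery (<=0: off)
    stp_tau_rec: float = 0.0  # ms, depression recovery (<=0: off)

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.g_peak, self.tau_rise, self.tau_decay, self.latency)
        ):
            raise ValueError("synapse parameters must be finite")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if self.g_peak < 0:
            raise ValueError("g_peak must be non-negative")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")
        if not 0 < self.stp_u <= 1:
            raise ValueError("stp_u must lie in (0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Trial-to-trial variability knobs and the RNG seed.

    ``amp_cv`` is a multiplicative (lognormal) coefficient of variation applied
    per synaptic event; ``latency_sd`` jitters each event's onset;
    ``v_noise_sd`` sets the stationary SD of Ornstein–Uhlenbeck-like membrane
    voltage noise.  Identical parameters and seed give bit-identical traces.
    """

    amp_cv: float = 0.2
    latency_sd: float = 0.15  # ms
    v_noise_sd: float = 1.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amp_cv, self.latency_sd, self.v_noise_sd) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class CellModelParams:
    """Full parameter set of one synthetic granule-cell phenotype.

    The cell is a conductance-based leaky integrate-and-fire unit receiving
    three effective synaptic pathways: monosynaptic perforant-path excitation
    (``exc``), disynaptic feedforward inhibition (``inh_ff``, driven by the
    stimulus) and feedback inhibition (``inh_fb``, recruited by granule-cell
    spiking).  A small direct (monosynaptic) inhibitory pathway, expressed as a
    fraction of the feedforward peak, survives glutamatergic block and is what
    the KYN quality filter measures.
    """

    phenotype: str
    C_m: float  # pF
    g_L: float  # nS
    E_L: float  # mV
    V_th: float  # mV
    V_reset: float  # mV
    t_ref: float  # ms
    E_exc: float  # mV
    E_inh: float  # mV
    exc: SynapseParams
    inh_ff: SynapseParams
    inh_fb: SynapseParams
    noise: NoiseParams = field(default_factory=NoiseParams)
    mono_fraction: float = 0.10  # direct IPSC peak as a fraction of the FF peak
    spike_waveform_amp: float = 60.0  # pA, loose-patch spike rendering
    loose_patch_noise_sd: float = 3.0  # pA
    vclamp_noise_sd: float = 2.0  # pA

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        scalars = (
            self.C_m, self.g_L, self.E_L, self.V_th, self.V_reset,
            self.t_ref, self.E_exc, self.E_inh, self.mono_fraction,
        )
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("cell parameters must be finite")
        if self.g_L <= 0 or self.C_m <= 0:
            raise ValueError("g_L and C_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if not (self.E_inh < self.V_th < self.E_exc):
            raise ValueError("require E_inh < V_th < E_exc")
        if not 0 <= self.mono_fraction < 1:
            raise ValueError("mono_fraction must lie in [0, 1)")

    @property
    def input_resistance(self) -> float:
        """Input resistance in GΩ (1/g_L with g_L in nS)."""
        return 1.0 / self.g_L

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return self.C_m / self.g_L

    def with_seed(self, seed: int) -> "CellModelParams":
        return replace(self, noise=replace(self.noise, seed=int(seed)))


@dataclass(frozen=True)
class StimulationProtocol:
    """Train structure of one stimulation experiment.

    Default protocol: trains of 10 pulses repeated 5 times, at 1, 10, 20 or
    40 Hz, delivered at 50% of the calibrated maximal input strength.
    """

    frequency: float  # Hz
    n_pulses: int = 10
    n_trains: int = 5
    input_strength: float = 0.5  # fraction of the calibrated 100% reference
    condition: str = "control"
    mode: str = "loose_patch"
    pre_ms: float = 100.0  # silent baseline before the first pulse
    post_ms: float = 200.0  # tail after the last pulse

    def __post_init__(self) -> None:
        if not (math.isfinite(self.frequency) and self.frequency > 0):
            raise ValueError("frequency must be positive and finite")
        if self.n_pulses < 1 or self.n_trains < 1:
            raise ValueError("n_pulses and n_trains must be >= 1")
        if not 0 <= self.input_strength <= 1:
            raise ValueError("input_strength must lie in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def ipi_ms(self) -> float:
        """Inter-pulse interval in ms."""
        return 1000.0 / self.frequency

    def stim_times(self) -> np.ndarray:
        """Stimulus onset times (ms from sweep start)."""
        return self.pre_ms + self.ipi_ms * np.arange(self.n_pulses)

    @property
    def sweep_ms(self) -> float:
        return self.pre_ms + self.ipi_ms * (self.n_pulses - 1) + self.post_ms


@dataclass
class TraceRecording:
    """One sweep of a uniformly sampled signal plus stimulus metadata.

    ``y`` carries mV for voltage/field sweeps and pA for current sweeps.
    ``meta`` holds generator ground truth (spike times, internal conductance
    arrays) when the sweep is synthetic; analysis code never reads it.
    """

    t: np.ndarray  # ms
    y: np.ndarray
    stim_times: np.ndarray  # ms
    mode: str
    condition: str = "control"
    phenotype: str = "mature"
    train_index: int = 0
    holding_potential: Optional[float] = None  # mV (voltage clamp only)
    cell_id: str = "cell0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same length")
        if self.t.size < 2:
            raise ValueError("trace must contain at least two samples")
        dts = np.diff(self.t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling interval must be constant")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValueError("stim_times must be strictly increasing")
            if self.stim_times[0] < self.t[0] or self.stim_times[-1] > self.t[-1]:
                raise ValueError("stim_times must fall within the sweep")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return self.t.size


def _mature_synapses() -> dict:
    # Excitation: fast, strong, mildly depressing over a 40 Hz train.
    # Feedforward inhibition: fast-rising, large, facilitating, slow-decaying
    # so that residual inhibition summates at 20/40 Hz.
    return dict(
        exc=SynapseParams(
            g_peak=23.0, tau_rise=0.4, tau_decay=6.0, latency=1.8,
            stp_u=0.06, stp_tau_fac=0.0, stp_tau_rec=150.0,
        ),
        inh_ff=SynapseParams(
            g_peak=36.0, tau_rise=0.5, tau_decay=45.0, latency=3.2,
            stp_u=0.5, stp_tau_fac=200.0, stp_tau_rec=0.0,
        ),
        inh_fb=_FB_SYNAPSE,
    )


#: feedback inhibition is a property of the local interneuron network and is
#: identical for the two granule-cell phenotypes.
_FB_SYNAPSE = SynapseParams(
    g_peak=2.5, tau_rise=1.0, tau_decay=80.0, latency=5.0,
    stp_u=0.35, stp_tau_fac=400.0, stp_tau_rec=0.0,
)


def mature_cell(seed: int = 0) -> CellModelParams:
    """Default mature granule-cell phenotype.

    Low input resistance (~200 MΩ) matched to a strong excitatory drive;
    fast, large feedforward inhibition.
    """
    return CellModelParams(
        phenotype="mature",
        C_m=30.0, g_L=5.0, E_L=-75.0, V_th=-45.0, V_reset=-60.0, t_ref=2.0,
        E_exc=0.0, E_inh=-60.0,
        noise=NoiseParams(amp_cv=0.2, latency_sd=0.15, v_noise_sd=1.0, seed=seed),
        **_mature_synapses(),
    )


def immature_cell(seed: int = 0) -> CellModelParams:
    """Default immature (4-week-old) granule-cell phenotype.

    High input resistance (~1 GΩ) matched to a weak excitatory drive; small,
    slow feedforward inhibition; feedback inhibition identical to the mature
    phenotype.
    """
    return CellModelParams(
        phenotype="immature",
        C_m=12.0, g_L=1.0, E_L=-75.0, V_th=-45.0, V_reset=-60.0, t_ref=2.0,
        E_exc=0.0, E_inh=-60.0,
        exc=SynapseParams(
            g_peak=5.3, tau_rise=1.2, tau_decay=7.0, latency=2.2,
            stp_u=0.08, stp_tau_fac=0.0, stp_tau_rec=100.0,
        ),
        inh_ff=SynapseParams(
            g_peak=9.0, tau_rise=1.5, tau_decay=30.0, latency=5.8,
            stp_u=0.75, stp_tau_fac=200.0, stp_tau_rec=0.0,
        ),
        inh_fb=_FB_SYNAPSE,
        noise=NoiseParams(amp_cv=0.2, latency_sd=0.5, v_noise_sd=1.0, seed=seed),
        mono_fraction=0.03,
    )
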
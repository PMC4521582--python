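# Methods

## Model

Each granule cell (GC) is a single-compartment conductance-based leaky
integrate-and-fire neuron,

    C_m dV/dt = −g_L (V − E_L) − g_E(t) (V − E_exc) − g_I(t) (V − E_inh) + I_inj(t),

integrated by fixed-step exponential Euler at the acquisition interval
(dt = 0.05 ms, 20 kHz). A spike is a threshold crossing (V ≥ V_th) followed by
reset to V_reset and an absolute refractory period t_ref. Units throughout:
ms, mV, pA, nS, pF (so nS·mV = pA and pA/pF = mV/ms with no conversion
factors).

Synaptic pathways are peak-normalised differences of exponentials with
Tsodyks–Markram short-term dynamics (utilisation u relaxing to its baseline
with τ_fac, resources x recovering with τ_rec; weights normalised so the first
event of a train has amplitude `g_peak`):

| pathway | driven by | role |
|---|---|---|
| `exc` | each stimulus pulse | monosynaptic perforant-path excitation, mildly depressing |
| `inh_ff` | each stimulus pulse (disynaptic latency) | feedforward inhibition, facilitating, slow-decaying |
| `inh_fb` | GC spiking | feedback inhibition via the mossy-fibre→interneuron loop |
| mono | each stimulus pulse (short latency) | direct stimulation of inhibitory axons; survives KYN |

Pharmacology is implemented as pathway gating: PTX removes all inhibitory
pathways; DCG4 removes only `inh_fb`; KYN removes the glutamatergic pathways
(`exc`, and with them FF and FB, which require glutamatergic drive), leaving
only the monosynaptic inhibitory component.

In current clamp (loose patch) feedback is triggered by the simulated cell's
own spikes after the FB latency. In voltage clamp the recorded cell cannot
spike while the surrounding population still does, so the FB drive is a
surrogate **population event**: one graded conductance per pulse, scaled by a
stylised population spiking probability (0.55 on pulse 1, declining along the
train faster at higher frequency) with 0.3 ms timing scatter. Treating the
population spike as graded rather than all-or-none reflects that it is the
compound activity of many granule cells; it also keeps the FB component's
trial-to-trial variance realistic rather than dominated by single Bernoulli
draws. The surrogate is deliberately phenotype-independent: feedback sampled
by one cell reflects the (overwhelmingly mature) population, not the recorded
cell — this is why FB conductances are statistically indistinguishable between
phenotypes while FF conductances differ.

## Phenotype parameters and why

No absolute synaptic conductances are available to constrain the generator;
they are free parameters bounded by ordinal relations and one calibration
(below). The defaults were designed once, before the analysis-level tests were
written, to encode the known physiology:

| parameter | mature | immature | rationale |
|---|---|---|---|
| g_L (nS) / R_in | 5 / 200 MΩ | 1 / 1 GΩ | immature cells are high-impedance |
| C_m (pF), τ_m | 30, 6 ms | 12, 12 ms | slower immature membrane |
| E_L, V_th, V_reset (mV) | −75, −45, −60 | same | shared spike mechanism |
| E_exc, E_inh (mV) | 0, −60 | same | reversals; clamp targets |
| exc g_peak (nS, full strength) | 23 | 5.3 | strong drive matched to low R_in vs weak drive matched to high R_in — the pairing that makes the two phenotypes indistinguishable once inhibition is blocked |
| exc STP | u=0.06, τ_rec=150 ms | u=0.08, τ_rec=100 ms | mild depression (~15–20% by pulse 10 at 40 Hz) |
| FF g_peak (nS) | 36 | 9 | feedforward inhibition much weaker onto immature cells |
| FF latency / τ_rise (ms) | 3.2 / 0.5 | 5.8 / 1.5 | immature FF IPSC is later and slower-rising |
| FF τ_decay (ms) | 45 | 30 | slow decay → residual inhibition summates at 20/40 Hz |
| FF STP | u=0.5, τ_fac=200 ms | u=0.75, τ_fac=200 ms | inhibition grows along the train |
| FB (both) | g 2.5 nS, latency 5 ms, τ_rise 1 ms, τ_decay 80 ms, u=0.35, τ_fac=400 ms | identical | feedback is a property of the shared interneuron network |
| mono fraction of FF peak | 0.10 | 0.03 | sparser direct GABAergic innervation of immature cells; keeps the KYN block fraction > 0.7 in both |
| noise | amp CV 0.2, latency SD 0.15 ms (mature) / 0.5 ms (immature), V-noise 1 mV | | trial-to-trial variability; immature events are less precisely timed |

Two structural features carry most of the behaviour:

1. **Feedforward veto.** Mature FF is strong enough to pull the steady-state
   voltage below threshold once active, and it arrives ~1.5 ms after the EPSC
   peak. Control spikes are therefore confined to a brief window between the
   EPSC onset and the FF veto; removing inhibition (PTX) re-opens the late,
   noise-driven part of the EPSP tail, which raises both spike counts and
   spike-time jitter. The same mechanism, scaled down and slowed, applies to
   the immature cell.
2. **Inhibition outlasting excitation.** With τ_decay ≫ EPSC decay and
   facilitation, FF inhibition summates across pulses at 20/40 Hz and
   throttles the train; the mature cell's residual-plus-recruited inhibition
   exceeds its excitation already at a 100 ms inter-stimulus lag, the immature
   cell's does not — which is why only the immature cell follows 10 Hz trains
   well.

**Calibration.** `input_strength` scales the stimulus-driven pathways (exc,
FF, mono). The excitation scale was chosen so that, at the calibrated 50%
operating point, the mature phenotype's control spiking probability at 1 Hz
is ≈0.5 (≈5 spikes per 10-pulse train); this anchors the model's single
stated operating point. The measured value with the default seed family is
5.2–5.7 spikes/train.

## Analysis conventions

- **Artifacts.** Stimulus artifacts are 0.5 ms square deflections; every
  measurement blanks 1.0 ms after each stimulus.
- **Spike detection.** High-pass (2nd-order Butterworth, 300 Hz, zero-phase),
  threshold k = 5 robust (MAD-based) SDs on the rectified signal, events
  merged within 1 ms and localised at the extremum. Events spanning fewer
  than 3 samples are rejected as noise tails — at 5σ over ~2·10⁵ samples per
  sweep, single-sample excursions would otherwise contribute ~0.1 false
  events per sweep and corrupt the jitter statistic.
- **Spike-to-pulse assignment.** A spike belongs to the most recent preceding
  stimulus if it falls within that stimulus's inter-pulse interval; the last
  pulse's window is capped at 100 ms so 1 Hz trains are comparable to 10 Hz.
  Multiple spikes in one window count once (train maxima of 10 imply
  one-per-pulse accounting).
- **Efficacy** = fraction of the (n_pulses − 1) adjacent pulse pairs with
  spikes on both pulses, averaged over trains.
- **Conductances.** g(t) = (I(t) − baseline)/(V_hold − E_rev), baseline =
  median of the 50 ms pre-train window (inter-pulse baselines are contaminated
  at 20/40 Hz); small negative excursions are clipped to zero and the clipped
  fraction logged. EPSG is read at its own per-pulse peak, IPSG at the
  EPSC-peak time of the same pulse; missing EPSC peaks fall back to the median
  peak latency of the remaining pulses.
- **Recruited inhibition** is read at the cell's measured spike latency (from
  its loose-patch recording); residual inhibition at fixed lags after pulse 1
  of the 1 Hz train, 0.1 ms early at the 1000 ms lag to avoid the next
  artifact.
- **Decomposition.** FB = control − DCG4, per averaged sweep, after baseline
  alignment and an artifact cross-correlation alignment check (max 1 ms);
  negative FB excursions are clipped with a logged fraction. Paired conditions
  share RNG substreams per pathway (never keyed by condition), so the
  subtraction is exact on synthetic data — mirroring that control and DCG4
  sweeps in a real experiment come from the same cell.
- **Jitter.** Every answered pulse of the lowest-frequency (1 Hz) protocol is
  a timing trial; jitter is the deviation of each trial's first-spike latency
  from the cell's mean, pooled across cells (pooled counts of ~100+ spikes
  from 8 cells match how the source distributions were built). Variances are
  compared with a two-sided F-test, larger variance in the numerator.
- **Statistics.** Frequency following: one-sample Wilcoxon signed-rank test
  against 1, zeros dropped, midranks for ties; the null distribution is exact
  (dynamic programming over the positive-rank sum, equivalent to enumerating
  all 2ⁿ sign assignments) for n ≤ 25, normal approximation with tie and
  continuity corrections above. Phenotype-equality claims (PTX spike counts,
  FB conductance) use per-frequency Mann–Whitney tests with Holm correction
  across the four-frequency family; the FB test is skipped at frequencies
  where FB is not expressed (at 1 Hz it would compare baseline noise).

## What the generator does and does not emulate

It emulates: train protocols (5 × 10 pulses, 1–40 Hz) at a calibrated
operating point; loose-patch spike waveforms over baseline noise with stimulus
artifacts; voltage-clamp isolation at either reversal; pharmacological
condition contrasts with paired noise; field sweeps whose fEPSP slope grows
sigmoidally with intensity and whose population spike saturates; per-cell
heterogeneity (lognormal, CV 0.08 on synaptic peaks).

It does not emulate: dendritic filtering or multi-compartment effects, NMDA
currents, series-resistance errors, explicit interneuron spiking (FF/FB are
effective conductances; the DCG4-invariance of interneuron recruitment is a
built-in assumption), mossy-cell pathways, or slow forms of plasticity. A
green ordinal test therefore establishes that the analysis chain recovers the
contrasts a circuit with these mechanisms produces — not that the mechanisms
are uniquely identified from data.

## Numerical choices and degenerate inputs

- Exponential Euler is exact for piecewise-constant conductances over a step
  and unconditionally stable for this conductance LIF; the test suite checks
  mean spike counts against a 10×-finer forward-Euler oracle (2% tolerance).
- Event conductances are generated by exact one-pole recursions
  (`scipy.signal.lfilter`) over impulse trains.
- Detection on numerically noiseless traces (MAD ≈ 0) falls back to a
  threshold at half the largest deflection.
- Saturated sweeps (a contiguous run > 2 ms pinned at an extreme) are
  rejected; zero-variance sweeps return no spikes.
- The sigmoid fit refuses targets outside the sampled intensity range
  (no extrapolation) and degenerate (flat-slope) inputs.
- All randomness flows from one master seed through named `SeedSequence`
  substreams keyed by (cell seed, frequency, train, pathway) — never by
  condition — making every run bit-reproducible and every condition contrast
  exactly paired.

## Known limitations

- Absolute conductance magnitudes are stylised; only their ordinal structure
  and the 50% calibration are constrained.
- The population-spike surrogate in voltage clamp is stationary within a
  frequency and does not adapt to the pharmacological condition (except that
  PTX/DCG4/KYN remove it outright).
- Rank tests on 8 cells/phenotype have limited power; equality checks are
  supported by construction (shared FB parameters) rather than by the tests
  alone.
- The loose-patch spike waveform is stereotyped; the detector is not designed
  for bursting or multi-unit recordings.
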
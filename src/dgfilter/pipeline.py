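"""End-to-end study driver: generate -> calibrate -> analyse -> compare.

Runs the full protocol grid (phenotypes x conditions x frequencies, five
10-pulse trains each) on a population of synthetic cells, applies every
analysis stage through its public interface (spike detection on rendered
loose-patch sweeps, conductance extraction from voltage-clamp sweeps,
feedforward/feedback decomposition, KYN quality control), and aggregates
figure-level summary tables plus the headline ordinal checks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, circuit, conductance, decompose, spikes, stats
from .params import (
    CellModelParams,
    StimulationProtocol,
    TraceRecording,
    immature_cell,
    mature_cell,
)

__all__ = ["PipelineConfig", "StudySummary", "run_study", "average_traces", "make_cells"]

log = logging.getLogger(__name__)

_KNOWN_OVERRIDES = {"exc", "inh_ff", "inh_fb", "noise"} | {
    f.name for f in dataclasses.fields(CellModelParams)
}


@dataclass
class PipelineConfig:
    """Declarative configuration of one study run."""

    master_seed: int = 0
    n_cells: int = 8
    frequencies: tuple = (1.0, 10.0, 20.0, 40.0)
    conditions: tuple = ("control", "PTX", "DCG4", "KYN")
    phenotypes: tuple = ("mature", "immature")
    n_trains: int = 5
    input_strength: float | None = None  # None: calibrate from field sweeps
    cell_cv: float = 0.08  # per-cell lognormal scatter of synaptic peaks
    overrides: dict = field(default_factory=dict)  # phenotype -> {field: value}
    output_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        for phen, over in self.overrides.items():
            if phen not in ("mature", "immature"):
                raise ValueError(f"override for unknown phenotype {phen!r}")
            bad = set(over) - _KNOWN_OVERRIDES
            if bad:
                raise ValueError(f"unknown override keys {sorted(bad)}")


@dataclass
class StudySummary:
    """Aggregated study output.

    ``activation``, ``conductances``, ``decomposition`` and ``timing`` are tidy
    per-cell tables; ``summary`` is the mean +/- SEM roll-up keyed by
    (phenotype, condition, frequency); ``tests`` holds the gating statistics
    and ``checks`` the machine-checked ordinal reproduction flags.
    """

    input_strength: float
    calibration_curve: calibration.InputStrengthCurve | None
    activation: pd.DataFrame
    conductances: pd.DataFrame
    decomposition: pd.DataFrame
    timing: pd.DataFrame
    summary: pd.DataFrame
    tests: dict
    checks: dict
    exclusions: list

    @property
    def all_checks_pass(self) -> bool:
        return all(self.checks.values())


# ---------------------------------------------------------------------------
# helpers

def average_traces(traces: list[TraceRecording]) -> TraceRecording:
    """Pointwise mean sweep (trial average) preserving metadata."""
    t0 = traces[0]
    return TraceRecording(
        t=t0.t,
        y=np.mean([tr.y for tr in traces], axis=0),
        stim_times=t0.stim_times,
        mode=t0.mode,
        condition=t0.condition,
        phenotype=t0.phenotype,
        train_index=-1,
        holding_potential=t0.holding_potential,
        cell_id=t0.cell_id,
    )


def _cell_seed(master_seed: int, phenotype: str, index: int) -> int:
    ss = np.random.SeedSequence((int(master_seed) & 0x7FFFFFFF,
                                 0 if phenotype == "mature" else 1, int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def _apply_overrides(params: CellModelParams, over: dict) -> CellModelParams:
    for key, val in over.items():
        if key in ("exc", "inh_ff", "inh_fb", "noise") and isinstance(val, dict):
            params = dataclasses.replace(
                params, **{key: dataclasses.replace(getattr(params, key), **val)}
            )
        else:
            params = dataclasses.replace(params, **{key: val})
    return params


def make_cells(config: PipelineConfig, phenotype: str) -> list[CellModelParams]:
    """Population of cells with mild per-cell scatter of synaptic peaks."""
    base = mature_cell() if phenotype == "mature" else immature_cell()
    base = _apply_overrides(base, config.overrides.get(phenotype, {}))
    out = []
    for i in range(config.n_cells):
        seed = _cell_seed(config.master_seed, phenotype, i)
        rng = np.random.default_rng(seed)
        cell = base.with_seed(seed)
        if config.cell_cv > 0:
            sigma = np.sqrt(np.log(1 + config.cell_cv**2))
            factors = np.exp(rng.normal(0.0, sigma, 3) - sigma**2 / 2)
            cell = dataclasses.replace(
                cell,
                exc=dataclasses.replace(cell.exc, g_peak=cell.exc.g_peak * factors[0]),
                inh_ff=dataclasses.replace(cell.inh_ff, g_peak=cell.inh_ff.g_peak * factors[1]),
                inh_fb=dataclasses.replace(cell.inh_fb, g_peak=cell.inh_fb.g_peak * factors[2]),
            )
        out.append(cell)
    return out


def _component_table(
    exc_mean: TraceRecording,
    comp_y: np.ndarray,
    template: TraceRecording,
    condition_label: str,
) -> conductance.ConductanceTable:
    tr = TraceRecording(
        t=template.t, y=comp_y, stim_times=template.stim_times,
        mode="vclamp_inh", condition=condition_label,
        phenotype=template.phenotype, holding_potential=template.holding_potential,
        cell_id=template.cell_id,
    )
    return conductance.conductances_at_spike_time(exc_mean, tr, cell_id=template.cell_id)


# ---------------------------------------------------------------------------

def calibrate_input_strength(
    master_seed: int, intensities: np.ndarray | None = None
) -> tuple[float, calibration.InputStrengthCurve]:
    """Field-recording calibration: return the normalised strength at the 50%
    operating point together with the fitted curve."""
    if intensities is None:
        intensities = np.linspace(5.0, 95.0, 12)
    fp = circuit.FieldModelParams(seed=int(master_seed) & 0x7FFFFFFF)
    traces = circuit.simulate_field(fp, intensities)
    curve = calibration.calibrate_from_traces(traces)
    strength = curve.normalized_strength(curve.target_intensity_50pct)
    return float(strength), curve


def run_study(config: PipelineConfig) -> StudySummary:
    """Run the complete study grid and aggregate all summaries.

    Deterministic given ``config.master_seed``.  Writes tidy CSV tables, a
    JSON summary and an exclusion log to ``config.output_dir`` when set.
    """
    if config.input_strength is None:
        strength, curve = calibrate_input_strength(config.master_seed)
    else:
        strength, curve = float(config.input_strength), None

    act_rows, cond_rows, dec_rows, tim_rows = [], [], [], []
    exclusions: list = []
    jitter_pools: dict = {}

    spike_conditions = [c for c in config.conditions if c in ("control", "PTX")]
    do_conductance = "control" in config.conditions

    for phenotype in config.phenotypes:
        cells = make_cells(config, phenotype)
        for ci, cell in enumerate(cells):
            cell_id = f"{phenotype}{ci:02d}"
            ap_latencies = {}
            for cond in spike_conditions:
                for freq in config.frequencies:
                    proto = StimulationProtocol(
                        frequency=freq, n_trains=config.n_trains,
                        input_strength=strength, condition=cond, mode="loose_patch",
                    )
                    traces = circuit.simulate_cell(cell, proto)
                    raster = spikes.build_raster(traces, cell_id=cell_id)
                    counts = spikes.train_counts(raster)
                    act_rows.append(
                        dict(
                            phenotype=phenotype, condition=cond, frequency=freq,
                            cell_id=cell_id,
                            mean_total_spikes=float(counts.mean()),
                            train_counts=counts.tolist(),
                            efficacy=spikes.efficacy(raster),
                            p_first_pulse=float(spikes.per_pulse_probability(raster)[0]),
                            p_last_pulse=float(spikes.per_pulse_probability(raster)[-1]),
                        )
                    )
                    if freq == min(config.frequencies):
                        # low-frequency trains double as repeated timing trials
                        lats = spikes.pulse_response_latencies(raster, pulses="all")
                        lats = lats[np.isfinite(lats)]
                        if lats.size >= 3:
                            jitter_pools.setdefault((phenotype, cond), []).append(
                                lats - lats.mean()
                            )
                            tim_rows.append(
                                dict(
                                    phenotype=phenotype, condition=cond,
                                    cell_id=cell_id, n_trials=int(lats.size),
                                    mean_latency_ms=float(lats.mean()),
                                    jitter_sd_ms=float(lats.std(ddof=1)),
                                )
                            )
                            if cond == "control":
                                ap_latencies[freq] = float(lats.mean())
                        else:
                            exclusions.append(
                                f"{cell_id} {cond}: <3 spiking trials, excluded from jitter"
                            )

            if not do_conductance:
                continue
            for freq in config.frequencies:
                exc_m = average_traces(
                    circuit.simulate_voltage_clamp(
                        cell,
                        StimulationProtocol(
                            frequency=freq, n_trains=config.n_trains,
                            input_strength=strength, condition="control",
                            mode="vclamp_exc",
                        ),
                    )
                )
                inh_tot = circuit.simulate_voltage_clamp(
                    cell,
                    StimulationProtocol(
                        frequency=freq, n_trains=config.n_trains,
                        input_strength=strength, condition="control",
                        mode="vclamp_inh",
                    ),
                )
                inh_m = average_traces(inh_tot)
                for tr_ in (exc_m, inh_m):
                    tr_.cell_id = cell_id
                table = conductance.conductances_at_spike_time(
                    exc_m, inh_m, cell_id=cell_id
                )
                row = dict(
                    phenotype=phenotype, condition="control", frequency=freq,
                    cell_id=cell_id, mean_epsg=table.mean_epsg,
                    mean_ipsg=table.mean_ipsg, mean_ei_ratio=table.mean_ei_ratio,
                    late_ei_ratio=float(np.nanmean(table.ei_ratio_per_pulse[-3:])),
                    rise20_ms=conductance.rise20_latency(inh_m),
                    epsc_peak_ms=float(np.nanmean(table.epsc_peak_times)),
                )
                if freq == min(config.frequencies) and abs(freq - 1.0) <= 0.05:
                    summ = conductance.residual_recruited(
                        inh_m, exc_m,
                        spike_latency_ms=ap_latencies.get(freq),
                    )
                    row["recruited_ipsg"] = summ.recruited_ipsg
                    for lag, v in summ.residual_ipsg.items():
                        row[f"residual_{int(lag)}ms"] = v
                cond_rows.append(row)

                if "DCG4" in config.conditions:
                    inh_ff = circuit.simulate_voltage_clamp(
                        cell,
                        StimulationProtocol(
                            frequency=freq, n_trains=config.n_trains,
                            input_strength=strength, condition="DCG4",
                            mode="vclamp_inh",
                        ),
                    )
                    ff_m = average_traces(inh_ff)
                    ff_m.cell_id = cell_id
                    dec = decompose.decompose_ff_fb(inh_m, ff_m)
                    tab_ff = _component_table(exc_m, dec.ff_ipsc, inh_m, "DCG4")
                    tab_fb = _component_table(exc_m, dec.fb_ipsc, inh_m, "control")
                    fb_tr = TraceRecording(
                        t=inh_m.t, y=dec.fb_ipsc, stim_times=inh_m.stim_times,
                        mode="vclamp_inh", condition="control",
                        phenotype=phenotype, holding_potential=inh_m.holding_potential,
                        cell_id=cell_id,
                    )
                    dec_rows.append(
                        dict(
                            phenotype=phenotype, frequency=freq, cell_id=cell_id,
                            ff_ipsg=tab_ff.mean_ipsg, fb_ipsg=tab_fb.mean_ipsg,
                            total_ipsg=table.mean_ipsg,
                            ff_rise20_ms=conductance.rise20_latency(ff_m),
                            fb_rise20_ms=conductance.rise20_latency(fb_tr),
                            clipped_fraction=dec.clipped_fraction,
                        )
                    )

            if "KYN" in config.conditions and do_conductance:
                freq0 = min(config.frequencies)
                kyn_m = average_traces(
                    circuit.simulate_voltage_clamp(
                        cell,
                        StimulationProtocol(
                            frequency=freq0, n_trains=config.n_trains,
                            input_strength=strength, condition="KYN",
                            mode="vclamp_inh",
                        ),
                    )
                )
                ctrl_m = average_traces(
                    circuit.simulate_voltage_clamp(
                        cell,
                        StimulationProtocol(
                            frequency=freq0, n_trains=config.n_trains,
                            input_strength=strength, condition="control",
                            mode="vclamp_inh",
                        ),
                    )
                )
                ctrl_m.cell_id = kyn_m.cell_id = cell_id
                kf = decompose.kyn_quality_filter(ctrl_m, kyn_m)
                if not kf.included:
                    exclusions.append(
                        f"{cell_id}: KYN filter failed "
                        f"(block {kf.kyn_block_fraction:.2f}, mono {kf.monosynaptic_fraction:.2f})"
                    )
                for r in cond_rows:
                    if r["cell_id"] == cell_id:
                        r["kyn_block_fraction"] = kf.kyn_block_fraction
                        r["monosynaptic_fraction"] = kf.monosynaptic_fraction
                        r["included"] = kf.included

    activation = pd.DataFrame(act_rows)
    conductances = pd.DataFrame(cond_rows)
    decomposition = pd.DataFrame(dec_rows)
    timing = pd.DataFrame(tim_rows)

    tests = _run_tests(config, activation, decomposition, jitter_pools)
    checks = _run_checks(config, activation, conductances, decomposition, tests)
    summary = _summarize(activation, conductances, decomposition, timing)

    result = StudySummary(
        input_strength=strength, calibration_curve=curve,
        activation=activation, conductances=conductances,
        decomposition=decomposition, timing=timing, summary=summary,
        tests=tests, checks=checks, exclusions=exclusions,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _pooled_jitter(pools: dict, key: tuple) -> np.ndarray:
    vals = pools.get(key, [])
    return np.concatenate(vals) if vals else np.empty(0)


def _run_tests(config, activation, decomposition, jitter_pools) -> dict:
    tests: dict = {}
    if activation.empty:
        return tests
    ctrl = activation[activation.condition == "control"]
    for phenotype in config.phenotypes:
        for freq in config.frequencies:
            counts = ctrl[(ctrl.phenotype == phenotype) & (ctrl.frequency == freq)][
                "mean_total_spikes"
            ].to_numpy()
            if counts.size >= 5:
                res = spikes.frequency_following_test(counts)
                tests[f"wilcoxon_vs1_{phenotype}_{freq:g}Hz"] = dataclasses.asdict(res)
    for phenotype in config.phenotypes:
        jc = _pooled_jitter(jitter_pools, (phenotype, "control"))
        jp = _pooled_jitter(jitter_pools, (phenotype, "PTX"))
        if jc.size >= 3 and jp.size >= 3:
            res = stats.variance_ratio_test(jp, jc)
            tests[f"ftest_jitter_PTX_{phenotype}"] = dict(
                dataclasses.asdict(res),
                sd_control=float(jc.std(ddof=1)), sd_ptx=float(jp.std(ddof=1)),
                ptx_wider=bool(jp.std(ddof=1) > jc.std(ddof=1)),
            )
    jm = _pooled_jitter(jitter_pools, ("mature", "control"))
    ji = _pooled_jitter(jitter_pools, ("immature", "control"))
    if jm.size >= 3 and ji.size >= 3:
        res = stats.variance_ratio_test(ji, jm)
        tests["ftest_jitter_immature_vs_mature"] = dict(
            dataclasses.asdict(res),
            sd_mature=float(jm.std(ddof=1)), sd_immature=float(ji.std(ddof=1)),
            immature_wider=bool(ji.std(ddof=1) > jm.std(ddof=1)),
        )
    # PTX equalisation of the two phenotypes: rank test on per-train spike
    # counts at each frequency, Holm-corrected across the frequency family
    # (mirroring the per-frequency post-tests of the source protocol)
    ptx = activation[activation.condition == "PTX"]
    if not ptx.empty and {"mature", "immature"} <= set(config.phenotypes):
        from scipy.stats import mannwhitneyu

        raw = {}
        for freq in config.frequencies:
            a = np.concatenate(
                ptx[(ptx.phenotype == "mature") & (ptx.frequency == freq)][
                    "train_counts"
                ].to_list() or [[]]
            )
            b = np.concatenate(
                ptx[(ptx.phenotype == "immature") & (ptx.frequency == freq)][
                    "train_counts"
                ].to_list() or [[]]
            )
            if a.size and b.size:
                if np.ptp(np.r_[a, b]) == 0:
                    raw[freq] = (np.nan, 1.0)
                else:
                    stat, p = mannwhitneyu(a, b, alternative="two-sided")
                    raw[freq] = (float(stat), float(p))
        sig = _holm(dict((f, p) for f, (s, p) in raw.items()))
        for freq, (stat, p) in raw.items():
            tests[f"ranktest_PTX_phenotypes_{freq:g}Hz"] = dict(
                statistic=stat, p_value=p, significant=bool(sig[freq])
            )
    # FB indistinguishable between phenotypes: rank test per frequency, only
    # where feedback is actually expressed (it is absent at 1 Hz, where the
    # readout would compare baseline noise), Holm-corrected
    if not decomposition.empty and {"mature", "immature"} <= set(config.phenotypes):
        from scipy.stats import mannwhitneyu

        raw = {}
        for freq in config.frequencies:
            a = decomposition[
                (decomposition.phenotype == "mature") & (decomposition.frequency == freq)
            ]["fb_ipsg"].to_numpy()
            b = decomposition[
                (decomposition.phenotype == "immature") & (decomposition.frequency == freq)
            ]["fb_ipsg"].to_numpy()
            if (
                a.size and b.size
                and max(a.mean(), b.mean()) > 0.1
                and (a.std() > 0 or b.std() > 0)
            ):
                stat, p = mannwhitneyu(a, b, alternative="two-sided")
                raw[freq] = (float(stat), float(p))
        sig = _holm(dict((f, p) for f, (s, p) in raw.items()))
        for freq, (stat, p) in raw.items():
            tests[f"ranktest_FB_phenotypes_{freq:g}Hz"] = dict(
                statistic=stat, p_value=p, significant=bool(sig[freq])
            )
    return tests


def _holm(pvals: dict, alpha: float = 0.05) -> dict:
    """Holm-Bonferroni step-down significance flags for a family of p-values."""
    if not pvals:
        return {}
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    out = {}
    blocked = False
    for rank, (key, p) in enumerate(items):
        if blocked or p > alpha / (m - rank):
            blocked = True
            out[key] = False
        else:
            out[key] = True
    return out


def _run_checks(config, activation, conductances, decomposition, tests) -> dict:
    """Machine-checked ordinal reproduction of the headline contrasts."""
    checks: dict = {}
    freqs = sorted(config.frequencies)
    both = {"mature", "immature"} <= set(config.phenotypes)

    def mean_counts(phenotype, cond):
        sub = activation[(activation.phenotype == phenotype) & (activation.condition == cond)]
        return sub.groupby("frequency")["mean_total_spikes"].mean().reindex(freqs)

    if not activation.empty and both and "control" in set(activation.condition):
        mat, imm = mean_counts("mature", "control"), mean_counts("immature", "control")
        checks["immature_spikes_above_mature_all_freqs"] = bool((imm > mat).all())
        checks["counts_decrease_with_frequency"] = bool(
            (mat.diff().dropna() <= 1e-9).all() and (imm.diff().dropna() <= 1e-9).all()
        )
        if "PTX" in set(activation.condition):
            mat_p = mean_counts("mature", "PTX")
            checks["ptx_raises_mature_counts_all_freqs"] = bool((mat_p > mat).all())
            eq = [
                not tests[k]["significant"]
                for k in tests
                if k.startswith("ranktest_PTX_phenotypes_")
            ]
            checks["ptx_equalizes_phenotypes"] = bool(eq and all(eq))

    if not conductances.empty and both:
        g = conductances.groupby(["phenotype", "frequency"])
        epsg = g["mean_epsg"].mean().unstack(0)
        ipsg = g["mean_ipsg"].mean().unstack(0)
        ratio = g["mean_ei_ratio"].mean().unstack(0)
        checks["epsg_larger_in_mature"] = bool((epsg["mature"] > epsg["immature"]).all())
        checks["ipsg_larger_in_mature"] = bool((ipsg["mature"] > ipsg["immature"]).all())
        low = [f for f in freqs if f <= 10]
        checks["ei_ratio_larger_in_immature_low_freq"] = bool(
            (ratio.loc[low, "immature"] > ratio.loc[low, "mature"]).all()
        )
        checks["ipsg_increases_with_frequency"] = bool(
            (ipsg.diff().dropna() >= -1e-9).all().all()
        )
        checks["epsg_decreases_with_frequency"] = bool(
            (epsg.diff().dropna() <= 1e-9).all().all()
        )

    if not decomposition.empty and both:
        g = decomposition.groupby(["phenotype", "frequency"])
        ff = g["ff_ipsg"].mean().unstack(0)
        fb = g["fb_ipsg"].mean().unstack(0)
        r20 = g["ff_rise20_ms"].mean().unstack(0)
        checks["ff_ipsg_larger_in_mature"] = bool((ff["mature"] > ff["immature"]).all())
        checks["ff_rise20_slower_in_immature"] = bool(
            (r20["immature"] > r20["mature"]).all()
        )
        checks["fb_ipsg_increases_with_frequency"] = bool(
            (fb.diff().dropna() >= -1e-9).all().all()
        )
        checks["ff_ipsg_increases_with_frequency"] = bool(
            (ff.diff().dropna() >= -1e-9).all().all()
        )
        fb_eq = [
            not tests[k]["significant"]
            for k in tests
            if k.startswith("ranktest_FB_phenotypes_")
        ]
        checks["fb_indistinguishable_between_phenotypes"] = bool(fb_eq and all(fb_eq))

    for phen in config.phenotypes:
        key = f"ftest_jitter_PTX_{phen}"
        if key in tests:
            checks[f"ptx_widens_jitter_{phen}"] = bool(
                tests[key]["significant"] and tests[key]["ptx_wider"]
            )
    if "ftest_jitter_immature_vs_mature" in tests:
        t = tests["ftest_jitter_immature_vs_mature"]
        checks["jitter_wider_in_immature"] = bool(t["significant"] and t["immature_wider"])
    return checks


def _summarize(activation, conductances, decomposition, timing) -> pd.DataFrame:
    frames = []

    def agg(df, keys, cols):
        if df.empty:
            return
        g = df.groupby(keys)[cols]
        mean = g.mean().add_suffix("_mean")
        sem = g.sem().add_suffix("_sem")
        frames.append(mean.join(sem).reset_index())

    agg(activation, ["phenotype", "condition", "frequency"],
        ["mean_total_spikes", "efficacy"])
    agg(conductances, ["phenotype", "condition", "frequency"],
        ["mean_epsg", "mean_ipsg", "mean_ei_ratio", "rise20_ms"])
    agg(decomposition, ["phenotype", "frequency"],
        ["ff_ipsg", "fb_ipsg", "ff_rise20_ms", "fb_rise20_ms"])
    agg(timing, ["phenotype", "condition"], ["mean_latency_ms", "jitter_sd_ms"])
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _write_outputs(result: StudySummary, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.activation.to_csv(out / "activation.csv", index=False)
    result.conductances.to_csv(out / "conductances.csv", index=False)
    result.decomposition.to_csv(out / "decomposition.csv", index=False)
    result.timing.to_csv(out / "timing.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    doc = dict(
        master_seed=config.master_seed,
        n_cells=config.n_cells,
        input_strength=result.input_strength,
        tests=result.tests,
        checks=result.checks,
        exclusions=result.exclusions,
    )
    (out / "report.json").write_text(json.dumps(doc, indent=2, default=float))
    log.info("study outputs written to %s", out)
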
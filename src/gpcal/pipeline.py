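"""End-to-end orchestration: simulate or load -> correct -> kinetics -> stats.

All numeric work lives in the sibling modules; this module sequences them,
fixes the output table schemas and writes a manifest sufficient to reproduce
every number bit-identically (config + seed + package version).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .background import BackgroundFit, correct
from .core import RecordingMovie, RoiSet, Stimulus, Trace
from .kinetics import (
    ResponseKinetics,
    average_epoch,
    detect_spontaneous,
    measure_epoch,
    measure_response,
    percent_remaining,
)
from .preprocess import extract_traces, motion_correct
from .stats import compare_unpaired, ecdf_compare, factorial_compare, normality_gate
from .synthetic import Cohort, CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

MAX_RECORDING_MIN = 12.0  # photo-damage guard: warn past this recording length

SCHEMA_VERSION = "1"
SCHEMAS = {
    "kinetics": ["cell_id", "genotype", "epoch", "amplitude", "duration_half_max",
                 "rise_10_90", "decay_90_10", "peak_time", "n_responses", "n_duration"],
    "block": ["cell_id", "genotype", "pct_amplitude_remaining", "pct_duration_remaining",
              "included_in_duration"],
    "spontaneous": ["roi_id", "n_events", "duration_s", "frequency_hz",
                    "frequency_per_min", "mean_amplitude"],
    "comparisons": ["metric", "test", "group_a", "group_b", "n_a", "n_b", "statistic",
                    "p_value", "median_a", "ci_low_a", "ci_high_a", "median_b",
                    "ci_low_b", "ci_high_b", "p25_a", "p75_a", "p25_b", "p75_b"],
}


@dataclass
class AnalysisParams:
    """Tunable analysis parameters, with the pipeline defaults."""

    window_frames: int = 200  # moving-average window (frames)
    threshold_k: float = 3.0  # signal threshold (multiples of noise SD)
    reentry_fraction: float = 0.5  # mask-extension re-entry level (x SD)
    sd_estimator: str = "mad"
    response_window_s: float = 10.0  # post-stimulus analysis window
    baseline_window_s: float = 1.0
    upsample: int = 100  # sub-frame interpolation factor
    epoch_method: str = "waveform"  # waveform: average aligned traces, then
    # measure; metrics: measure each stimulation, then average the metrics
    alpha: float = 0.05


@dataclass
class RunConfig:
    """One pipeline run: exactly one input mode plus all analysis parameters."""

    mode: str = "simulate"  # movie | traces | simulate
    movie_path: str | None = None
    mask_path: str | None = None
    roi_meta_path: str | None = None
    traces_path: str | None = None
    stimuli_path: str | None = None
    frame_rate: float = 10.0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    outdir: str = "gpcal_run"
    qc_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("movie", "traces", "simulate"):
            raise ValueError("mode must be one of movie | traces | simulate")
        if self.mode == "movie" and not (self.movie_path and self.mask_path):
            raise ValueError("movie mode needs movie_path and mask_path")
        if self.mode == "traces" and not self.traces_path:
            raise ValueError("traces mode needs traces_path")


def _check_length(trace: Trace) -> None:
    if trace.duration_s > MAX_RECORDING_MIN * 60.0:
        log.warning(
            "trace %s lasts %.1f min (> %g min photo-damage guard)",
            trace.roi_id, trace.duration_s / 60.0, MAX_RECORDING_MIN,
        )


def analyze_trace(
    trace: Trace,
    stimuli: list[Stimulus],
    params: AnalysisParams | None = None,
) -> tuple[BackgroundFit, dict[str, ResponseKinetics], list[ResponseKinetics]]:
    """Correct one trace and measure every stimulus, averaged per epoch."""
    params = params or AnalysisParams()
    _check_length(trace)
    fit = correct(
        trace,
        window_frames=params.window_frames,
        threshold_k=params.threshold_k,
        reentry_fraction=params.reentry_fraction,
        sd_estimator=params.sd_estimator,
    )
    per_stim: list[ResponseKinetics] = []
    by_epoch: dict[str, list] = {}
    for idx, stim in enumerate(stimuli):
        r = measure_response(
            fit.corrected,
            stim.time_s,
            window=params.response_window_s,
            baseline_window=params.baseline_window_s,
            upsample=params.upsample,
            stimulus_index=idx,
            epoch=stim.epoch,
        )
        per_stim.append(r)
        by_epoch.setdefault(stim.epoch, []).append((stim.time_s, r))
    if params.epoch_method == "waveform":
        epoch_means = {}
        # measure the baseline epoch first: its peak latency (a cell
        # property) then confines the peak search for the weaker epochs
        latency = None
        order = sorted(by_epoch, key=lambda e: e != "baseline")
        for epoch in order:
            pairs = by_epoch[epoch]
            r = measure_epoch(
                fit.corrected,
                [t for t, _ in pairs],
                epoch=epoch,
                window=params.response_window_s,
                baseline_window=params.baseline_window_s,
                upsample=params.upsample,
                peak_latency=latency if epoch != "baseline" else None,
            )
            epoch_means[epoch] = r
            if epoch == "baseline" and r.amplitude > 0 and np.isfinite(r.peak_time):
                latency = r.peak_time - params.baseline_window_s
    else:
        epoch_means = {
            epoch: average_epoch([r for _, r in pairs]) for epoch, pairs in by_epoch.items()
        }
    return fit, epoch_means, per_stim


def analyze_cohort(
    cohort: Cohort, params: AnalysisParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[BackgroundFit]]:
    """Run the full measurement pipeline over a simulated cohort.

    Returns the per-cell-per-epoch kinetics table, the per-cell block table
    (when the cohort includes an antagonist epoch), and the background fits
    for QC.
    """
    params = params or AnalysisParams()
    genotype = dict(zip(cohort.cells["cell_id"], cohort.cells["genotype"]))
    kin_rows = []
    block_rows = []
    fits = []
    for trace in cohort.traces:
        fit, epoch_means, _ = analyze_trace(trace, cohort.stimuli, params)
        fits.append(fit)
        for epoch, r in epoch_means.items():
            kin_rows.append(
                {
                    "cell_id": trace.roi_id,
                    "genotype": genotype[trace.roi_id],
                    "epoch": epoch,
                    "amplitude": r.amplitude,
                    "duration_half_max": r.duration_half_max,
                    "rise_10_90": r.rise_10_90,
                    "decay_90_10": r.decay_90_10,
                    "peak_time": r.peak_time,
                    "n_responses": r.n_responses,
                    "n_duration": r.n_duration,
                }
            )
        if "baseline" in epoch_means and "antagonist" in epoch_means:
            before, during = epoch_means["baseline"], epoch_means["antagonist"]
            if before.amplitude > 0:
                blk = percent_remaining(before, during)
                block_rows.append(
                    {
                        "cell_id": trace.roi_id,
                        "genotype": genotype[trace.roi_id],
                        "pct_amplitude_remaining": blk.pct_amplitude_remaining,
                        "pct_duration_remaining": blk.pct_duration_remaining,
                        "included_in_duration": blk.included_in_duration,
                    }
                )
    kinetics = pd.DataFrame(kin_rows, columns=SCHEMAS["kinetics"])
    block = pd.DataFrame(block_rows, columns=SCHEMAS["block"])
    return kinetics, block, fits


def compare_genotypes(
    kinetics: pd.DataFrame, epoch: str = "baseline", alpha: float = 0.05
) -> pd.DataFrame:
    """Genotype comparisons of the epoch-averaged kinetics (tidy table).

    Every metric is compared with Mann-Whitney (the normality gate is run and
    logged; these right-skewed metrics select the nonparametric branch) and
    the amplitude additionally with Kolmogorov-Smirnov on its cumulative
    distribution.
    """
    sub = kinetics[kinetics["epoch"] == epoch]
    groups = sorted(sub["genotype"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 genotypes, found {groups}")
    ga, gb = groups
    rows = []
    metrics = ["amplitude", "duration_half_max", "rise_10_90", "decay_90_10"]
    for metric in metrics:
        a = sub.loc[sub["genotype"] == ga, metric].to_numpy()
        b = sub.loc[sub["genotype"] == gb, metric].to_numpy()
        decision, _ = normality_gate({ga: a, gb: b}, alpha=alpha)
        log.info("normality gate for %s: %s", metric, decision)
        comp = compare_unpaired(a, b, labels=(ga, gb), metric=metric)
        rows.append(_comparison_row(comp, ga, gb))
    comp = ecdf_compare(
        sub.loc[sub["genotype"] == ga, "amplitude"].to_numpy(),
        sub.loc[sub["genotype"] == gb, "amplitude"].to_numpy(),
        labels=(ga, gb),
        metric="amplitude_ecdf",
    )
    rows.append(_comparison_row(comp, ga, gb))
    return pd.DataFrame(rows, columns=SCHEMAS["comparisons"])


def _comparison_row(comp, ga: str, gb: str) -> dict:
    sa, sb = comp.summaries[ga], comp.summaries[gb]
    pa, pb = comp.percentiles_25_75[ga], comp.percentiles_25_75[gb]
    return {
        "metric": comp.metric,
        "test": comp.test,
        "group_a": ga,
        "group_b": gb,
        "n_a": comp.n[ga],
        "n_b": comp.n[gb],
        "statistic": comp.statistic,
        "p_value": comp.p_value,
        "median_a": sa["median"], "ci_low_a": sa["ci_low"], "ci_high_a": sa["ci_high"],
        "median_b": sb["median"], "ci_low_b": sb["ci_low"], "ci_high_b": sb["ci_high"],
        "p25_a": pa[0], "p75_a": pa[1], "p25_b": pb[0], "p75_b": pb[1],
    }


def factorial_block_table(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA (genotype x epoch) on amplitude and duration."""
    rows = []
    for metric in ("amplitude", "duration_half_max"):
        comp = factorial_compare(
            kinetics[metric].to_numpy(),
            kinetics["genotype"].to_numpy(),
            kinetics["epoch"].to_numpy(),
            metric=metric,
        )
        for effect in comp.effects.index:
            if effect == "Residual":
                continue
            rows.append(
                {
                    "metric": metric,
                    "effect": effect,
                    "F": float(comp.effects.loc[effect, "F"]),
                    "p_value": float(comp.effects.loc[effect, "PR(>F)"]),
                }
            )
    return pd.DataFrame(rows, columns=["metric", "effect", "F", "p_value"])


def _qc_plots(fits: list[BackgroundFit], outdir: Path, max_rois: int = 4) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for fit in fits[:max_rois]:
        t = fit.corrected.times_s
        figure, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        axes[0].plot(t, fit.raw, lw=0.7, label="raw F")
        axes[0].plot(t, fit.background, lw=1.2, label="background F0")
        masked = np.where(fit.signal_mask, fit.raw, np.nan)
        axes[0].plot(t, masked, lw=0.7, color="crimson", label="signal mask")
        axes[0].set_ylabel("F (a.u.)")
        axes[0].legend(loc="upper right", fontsize=8)
        axes[1].plot(t, fit.corrected.values, lw=0.7)
        axes[1].set_ylabel("dF/F0")
        axes[1].set_xlabel("time (s)")
        figure.suptitle(f"ROI {fit.roi_id}: background fit (mask {fit.mask_fraction:.1%})")
        figure.tight_layout()
        figure.savefig(outdir / f"qc_background_roi{fit.roi_id}.png", dpi=110)
        plt.close(figure)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute one configured pipeline run and write the result bundle.

    Outputs: kinetics.csv, block.csv, spontaneous.csv, comparisons.csv (when
    two genotypes are present), QC plots and manifest.json. Reruns with the
    same config and seed are bit-identical; on failure partial outputs are
    removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        return _run_inner(config, outdir, written)
    except Exception:
        for path in written.values():
            if path.exists():
                path.unlink()
        raise


def _run_inner(config: RunConfig, outdir: Path, written: dict[str, Path]) -> dict[str, Path]:
    params = config.params
    shift_table = None
    cohort = None

    if config.mode == "simulate":
        cohort = simulate_cohort(config.cohort, seed=config.seed)
        traces, stimuli = cohort.traces, cohort.stimuli
        genotype = dict(zip(cohort.cells["cell_id"], cohort.cells["genotype"]))
        classes = {t.roi_id: "neuron" for t in traces}
    elif config.mode == "movie":
        movie = io.read_movie(config.movie_path, config.frame_rate)
        rois = io.read_roi_set(config.mask_path, config.roi_meta_path)
        stimuli = io.read_stimuli(config.stimuli_path) if config.stimuli_path else []
        movie, shift_table = motion_correct(movie)
        traces = extract_traces(movie, rois)
        genotype = {t.roi_id: "NA" for t in traces}
        classes = {t.roi_id: rois.roi_class(t.roi_id) for t in traces}
    else:
        traces = io.read_traces(config.traces_path, config.frame_rate)
        stimuli = io.read_stimuli(config.stimuli_path) if config.stimuli_path else []
        genotype = {t.roi_id: "NA" for t in traces}
        classes = {t.roi_id: "neuron" for t in traces}

    kin_rows, block_rows, spont_rows, fits = [], [], [], []
    evoked_windows = [(s.time_s, s.time_s + params.response_window_s) for s in stimuli]
    for trace in traces:
        fit, epoch_means, _ = analyze_trace(trace, stimuli, params)
        fits.append(fit)
        log.info(
            "ROI %s: noise SD %.4g, mask fraction %.3f",
            trace.roi_id, fit.noise_sd, fit.mask_fraction,
        )
        for epoch, r in epoch_means.items():
            kin_rows.append(
                {
                    "cell_id": trace.roi_id, "genotype": genotype[trace.roi_id],
                    "epoch": epoch, "amplitude": r.amplitude,
                    "duration_half_max": r.duration_half_max,
                    "rise_10_90": r.rise_10_90, "decay_90_10": r.decay_90_10,
                    "peak_time": r.peak_time, "n_responses": r.n_responses,
                    "n_duration": r.n_duration,
                }
            )
        if {"baseline", "antagonist"} <= set(epoch_means):
            before, during = epoch_means["baseline"], epoch_means["antagonist"]
            if before.amplitude > 0:
                blk = percent_remaining(before, during)
                block_rows.append(
                    {
                        "cell_id": trace.roi_id, "genotype": genotype[trace.roi_id],
                        "pct_amplitude_remaining": blk.pct_amplitude_remaining,
                        "pct_duration_remaining": blk.pct_duration_remaining,
                        "included_in_duration": blk.included_in_duration,
                    }
                )
        if classes.get(trace.roi_id) == "glia" and trace.duration_s >= 10.0:
            summ = detect_spontaneous(
                fit.corrected, threshold_k=params.threshold_k, exclude_windows=evoked_windows
            )
            spont_rows.append(
                {
                    "roi_id": trace.roi_id, "n_events": summ.n_events,
                    "duration_s": summ.duration_s, "frequency_hz": summ.frequency_hz,
                    "frequency_per_min": summ.frequency_per_min,
                    "mean_amplitude": summ.mean_amplitude,
                }
            )

    kinetics = pd.DataFrame(kin_rows, columns=SCHEMAS["kinetics"])
    block = pd.DataFrame(block_rows, columns=SCHEMAS["block"])
    spont = pd.DataFrame(spont_rows, columns=SCHEMAS["spontaneous"])

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=io.FLOAT_FORMAT)
        written[name] = path

    save("kinetics", kinetics)
    save("block", block)
    save("spontaneous", spont)
    if kinetics["genotype"].nunique() == 2:
        save("comparisons", compare_genotypes(kinetics, alpha=params.alpha))
    if shift_table is not None:
        save("shifts", shift_table)
    if cohort is not None:
        save("ground_truth_cells", cohort.cells)
        save("ground_truth_epochs", cohort.epoch_truth)

    if config.qc_plots:
        _qc_plots(fits, outdir)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "gpcal_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "params": asdict(params),
        "tables": {name: _sha256(path) for name, path in written.items()},
        "schemas": SCHEMAS,
    }
    io.write_json(outdir / "manifest.json", manifest)
    written["manifest"] = outdir / "manifest.json"
    return written


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
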
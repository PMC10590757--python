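"""End-to-end pipeline wiring: simulate -> track -> quantify -> ph -> size-control.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages to
run and their parameters. One global seed is fanned out to every
stochastic stage through a counter-based derivation, so a config + seed
pair fully determines every output byte. Each run writes its stage
tables as CSV plus a JSON run report with versions, derived seeds and
per-stage record counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import child_seed
from . import imaging, io, oscillometry, ph_dynamics, size_control, synthetic

STAGES = ("simulate", "track", "quantify", "ph", "size_control")
# stable per-stage offsets for seed derivation
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


class ConfigError(ValueError):
    exit_code = 2


class InputError(FileNotFoundError):
    exit_code = 3


class StageError(RuntimeError):
    exit_code = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "vacuoscope_run"
    stages: tuple = STAGES
    reporter_channel: str = "vsep"
    reference_channel: str = "ref"
    simulate: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    ph: dict = field(default_factory=dict)
    size_control: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        if not Path(path).exists():
            raise InputError(f"config file not found: {path}")
        raw = io.read_yaml(path) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def stage_seed(self, stage: str) -> int:
        return child_seed(self.seed, _STAGE_INDEX[stage])


def _cohort_config_from(params: dict, seed: int) -> synthetic.SynthCohortConfig:
    params = dict(params)
    medium = params.pop("medium", "SDC")
    profile_over = params.pop("profile", {})
    cfg = synthetic.cohort_config(medium)
    if profile_over:
        cfg = replace(cfg, profile=replace(cfg.profile, **profile_over))
    if params:
        cfg = replace(cfg, **params)
    return replace(cfg, seed=seed)


def _stage_simulate(config: PipelineConfig, out: Path) -> dict:
    seed = config.stage_seed("simulate")
    params = config.simulate
    cohort_cfg = _cohort_config_from(params.get("cohort", {}), seed)
    traces, truths = synthetic.make_cohort(cohort_cfg)
    io.write_traces_csv(traces, out / "traces.csv")
    io.write_annotations_csv(traces, out / "annotations.csv")
    io.write_json([t.to_jsonable() for t in truths], out / "ground_truth.json")

    cal_models = (cohort_cfg.channels[config.reporter_channel], cohort_cfg.channels[config.reference_channel])
    cal = synthetic.make_calibration_series(
        cal_models,
        noise_sd=params.get("calibration_noise_sd", 0.005),
        seed=child_seed(seed, 1000),
    )
    io.write_calibration_csv(cal, out / "calibration.csv")

    n_sizes = {}
    for j, (label, size_params) in enumerate(sorted(params.get("sizes", {}).items())):
        size_cfg = synthetic.SizeCohortConfig(**size_params, seed=child_seed(seed, 2000 + j))
        records = synthetic.make_size_cohort(size_cfg)
        io.write_sizes_csv(records, out / f"sizes_{label}.csv")
        n_sizes[label] = len(records)

    rendered = []
    if params.get("render", False):
        scene = synthetic.ImageSceneConfig(**params.get("scene", {}))
        stacks, truth = synthetic.render_image_stack(traces, scene, seed=child_seed(seed, 3000))
        for name, stack in stacks.items():
            io.write_stack_tiff(stack, out / f"stack_{name}.tif")
            rendered.append(name)
        io.write_json(truth.to_jsonable(), out / "render_truth.json")
    return {
        "seed": seed,
        "n_cells": len(traces),
        "n_samples": traces[0].n if traces else 0,
        "size_cohorts": n_sizes,
        "rendered_channels": rendered,
    }


def _stage_track(config: PipelineConfig, out: Path) -> dict:
    params = config.track
    channels = params.get("channels")
    if channels is None:
        channels = sorted(p.stem[len("stack_") :] for p in out.glob("stack_*.tif"))
    if not channels:
        raise InputError("track stage: no stack_<channel>.tif inputs found")
    dt = float(params.get("dt", 2.0))
    stacks = {}
    for name in channels:
        path = out / f"stack_{name}.tif"
        if not path.exists():
            raise InputError(f"track stage: missing {path}")
        stacks[name] = imaging.Stack(io.read_stack_tiff(path), dt=dt, channel=name)
    detect_on = params.get("detect_channel", config.reporter_channel)
    if detect_on not in stacks:
        detect_on = channels[0]
    work = stacks[detect_on]
    if params.get("background_radius"):
        work = imaging.subtract_background(work, radius=int(params["background_radius"]))
    if params.get("register", False):
        work, _ = imaging.register_stack(work)
    detections = imaging.detect_stack(
        work,
        diameter=float(params.get("diameter", 27.0)),
        threshold=float(params.get("threshold", 0.3)),
    )
    tracks = imaging.link_tracks(
        detections,
        initial_radius=float(params.get("initial_radius", 25.0)),
        radius=float(params.get("radius", 20.0)),
    )
    io.write_tracks_csv(tracks, out / "tracks.csv")
    traces = imaging.extract_traces(tracks, stacks, aperture=params.get("aperture"))
    io.write_traces_csv(traces, out / "traces_tracked.csv")
    return {
        "n_detections": int(sum(len(d) for d in detections)),
        "n_tracks": len(tracks),
        "n_traces": len(traces),
    }


def _stage_quantify(config: PipelineConfig, out: Path) -> dict:
    params = config.quantify
    source = out / params.get("traces", "traces.csv")
    if not source.exists():
        raise InputError(f"quantify stage: missing {source}")
    traces = io.read_traces_csv(source)
    channel = params.get("channel", config.reporter_channel)
    min_span = float(params.get("min_span", 500.0))
    kept = oscillometry.select_traces(traces, min_span)
    components = [oscillometry.analyze_trace(t, channel) for t in kept]
    pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in kept],
            "amplitude_au2": [c.amplitude for c in components],
            "period_min": [c.period for c in components],
        }
    ).to_csv(out / "components.csv", index=False, float_format=io.FLOAT_FMT)
    summary = oscillometry.cohort_summary(
        components,
        label=params.get("label", channel),
        n_boot=int(params.get("n_boot", 2000)),
        seed=config.stage_seed("quantify"),
    )
    pd.DataFrame(
        [
            {
                "label": summary.label,
                "n_cells": summary.n_cells,
                "median_amplitude_au2": summary.median_amplitude,
                "amplitude_ci_lo": summary.amplitude_ci[0],
                "amplitude_ci_hi": summary.amplitude_ci[1],
                "median_period_min": summary.median_period,
                "period_ci_lo": summary.period_ci[0],
                "period_ci_hi": summary.period_ci[1],
            }
        ]
    ).to_csv(out / "cohort_summary.csv", index=False, float_format=io.FLOAT_FMT)
    return {"n_selected": len(kept), "median_period_min": summary.median_period}


def _stage_ph(config: PipelineConfig, out: Path) -> dict:
    params = config.ph
    cal_path = out / params.get("calibration", "calibration.csv")
    traces_path = out / params.get("traces", "traces.csv")
    for p in (cal_path, traces_path):
        if not p.exists():
            raise InputError(f"ph stage: missing {p}")
    cal = io.read_calibration_csv(cal_path)
    fit = ph_dynamics.fit_calibration(cal, mode=params.get("calibration_mode", "sigmoid"))
    traces = io.read_traces_csv(traces_path, annotations_path=out / "annotations.csv")
    num = params.get("numerator", config.reporter_channel)
    den = params.get("denominator", config.reference_channel)
    peak_kwargs = dict(
        min_prominence_frac=float(params.get("min_prominence_frac", 0.25)),
        min_separation=float(params.get("min_separation", 20.0)),
        smooth_window=int(params.get("smooth_window", 5)),
    )
    metric_rows, peak_rows, peaks_per_trace = [], [], []
    for tr in traces:
        ph, _ = ph_dynamics.ratio_to_ph(fit, tr.ratio(num, den))
        peaks = ph_dynamics.detect_peaks(ph, tr.times, **peak_kwargs)
        peaks_per_trace.append(peaks)
        for p in peaks:
            peak_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "time_min": p.time,
                    "peak_ph": p.height,
                    "prominence": p.prominence,
                    "half_width_min": p.half_width,
                }
            )
        if peaks:
            cm = ph_dynamics.cycle_metrics(ph, tr.times, peaks, peak_kwargs["smooth_window"])
            for i in range(cm.n_cycles):
                metric_rows.append(
                    {
                        "cell_id": tr.cell_id,
                        "peak_time_min": cm.peak_time[i],
                        "peak_ph": cm.peak_ph[i],
                        "min_ph": cm.min_ph[i],
                        "delta_ph": cm.delta_ph[i],
                    }
                )
    pd.DataFrame(peak_rows).to_csv(out / "peaks.csv", index=False, float_format=io.FLOAT_FMT)
    pd.DataFrame(metric_rows).to_csv(
        out / "cycle_metrics.csv", index=False, float_format=io.FLOAT_FMT
    )
    intervals = ph_dynamics.event_intervals(traces, peaks_per_trace)
    pd.DataFrame(
        [
            {
                "n_cycles": len(intervals.bud_to_peak),
                "mean_bud_to_peak_min": intervals.mean_bud_to_peak,
                "sem_bud_to_peak_min": intervals.sem_bud_to_peak,
                "sd_bud_to_peak_min": intervals.sd_bud_to_peak,
                "mean_peak_to_sep_min": intervals.mean_peak_to_sep,
                "sem_peak_to_sep_min": intervals.sem_peak_to_sep,
                "sd_peak_to_sep_min": intervals.sd_peak_to_sep,
                "n_unmatched": intervals.n_unmatched,
            }
        ]
    ).to_csv(out / "event_intervals.csv", index=False, float_format=io.FLOAT_FMT)
    return {
        "n_cycles": len(metric_rows),
        "mean_delta_ph": float(np.mean([r["delta_ph"] for r in metric_rows])) if metric_rows else float("nan"),
    }


def _stage_size_control(config: PipelineConfig, out: Path) -> dict:
    params = config.size_control
    paths = sorted(out.glob("sizes_*.csv"))
    named = params.get("inputs")
    if named:
        paths = [out / p for p in named]
    if not paths:
        raise InputError("size_control stage: no sizes_*.csv inputs found")
    for p in paths:
        if not p.exists():
            raise InputError(f"size_control stage: missing {p}")
    use_pi = bool(params.get("use_pi", False))
    cohorts = {p.stem[len("sizes_") :] or p.stem: io.read_sizes_csv(p, use_pi=use_pi) for p in paths}
    fits = {}
    rows = []
    for label, records in cohorts.items():
        fit = size_control.fit_size_control(records)
        fits[label] = fit
        rows.append(
            {
                "cohort": label,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "stderr": fit.stderr,
                "pvalue": fit.pvalue,
                "r_squared": fit.r_squared,
            }
        )
    pd.DataFrame(rows).to_csv(out / "size_fits.csv", index=False, float_format=io.FLOAT_FMT)
    comp_rows = []
    labels = list(cohorts)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            cmp_ = size_control.compare_slopes(cohorts[labels[i]], cohorts[labels[j]])
            comp_rows.append(
                {
                    "cohort_a": labels[i],
                    "cohort_b": labels[j],
                    "f_statistic": cmp_.f_statistic,
                    "df_num": cmp_.df_num,
                    "df_den": cmp_.df_den,
                    "pvalue": cmp_.pvalue,
                }
            )
    pd.DataFrame(comp_rows).to_csv(
        out / "slope_comparisons.csv", index=False, float_format=io.FLOAT_FMT
    )
    return {"slopes": {r["cohort"]: r["slope"] for r in rows}}


_RUNNERS = {
    "simulate": _stage_simulate,
    "track": _stage_track,
    "quantify": _stage_quantify,
    "ph": _stage_ph,
    "size_control": _stage_size_control,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a run report.

    Raises ConfigError / InputError / StageError; stage outputs land in
    ``config.out_dir`` and the report in ``report.json`` there.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "vacuoscope_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in config.stages:
        runner = _RUNNERS[stage]
        try:
            report["stages"][stage] = runner(config, out)
        except (ConfigError, InputError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    io.write_json(report, out / "report.json")
    return report
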
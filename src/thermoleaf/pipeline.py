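"""End-to-end orchestration: simulate/load -> extract -> angles -> indices -> fit.

Every stage writes a plain CSV or JSON artifact into the output directory so
each step is auditable and individually re-runnable; the final ``report.json``
echoes the fully resolved configuration (including every defaulted threshold)
so a run can be reproduced from its own report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, InsufficientDataError, PipelineError
from .geometry import CONTRAST_THRESHOLD_C, measure_angles
from .indices import IndexReferences, compute_indices, demo_references
from .kinetics import (
    DEFAULT_HORIZON_H,
    AsymptoticStressModel,
    detect_wilting_onset,
)
from .scene import FrameSequence, load_roi_config, read_manifest
from .synthetic import ScenarioConfig, generate_sequence
from .thermometry import (
    HYSTERESIS_MIN,
    SWITCH_MARGIN_C,
    build_time_series,
    extract_readings,
    hourly_aggregate,
)

log = logging.getLogger("thermoleaf")

CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation XOR manifest input)."""

    scenario: ScenarioConfig | None = None
    manifest: str | Path | None = None
    roi_config: str | Path | None = None
    references: IndexReferences | None = None
    onset: str | float = "auto"
    out_dir: str | Path = "thermoleaf_run"
    seed: int | None = None
    resample_min: float = 30.0
    horizon_h: float = DEFAULT_HORIZON_H
    day_night_schedule: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.manifest is None):
            raise ConfigurationError(
                "exactly one of scenario / manifest must be supplied")


@dataclass
class RunReport:
    """Artifact paths plus the fitted kinetics for each plant."""

    out_dir: Path
    series_path: Path
    angles_path: Path
    hourly_path: Path
    indices_path: Path
    fits: dict                 # plant -> fit dict
    onsets: dict               # plant -> minutes or None
    anchor_min: float | None
    version: str
    config_echo: dict


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def _config_echo(cfg: RunConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, tuple):
            return list(v)
        return v

    echo = {k: enc(v) for k, v in dataclasses.asdict(cfg).items()}
    echo["defaults"] = {
        "switch_margin_c": SWITCH_MARGIN_C,
        "switch_hysteresis_min": HYSTERESIS_MIN,
        "segmentation_contrast_c": CONTRAST_THRESHOLD_C,
        "onset_rate_threshold_pct_per_h": 15.0,
        "onset_sustain_min": 30.0,
        "lowess_span": 0.5,
        "resample_min": cfg.resample_min,
        "horizon_h": cfg.horizon_h,
    }
    return echo


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; identical config + seed gives identical files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, out: Path) -> RunReport:
    # --- stage: input ---------------------------------------------------
    stage = "input"
    try:
        if cfg.scenario is not None:
            scenario = cfg.scenario
            if cfg.seed is not None:
                scenario = dataclasses.replace(scenario, seed=cfg.seed)
            log.info("simulating scenario (seed=%s)", scenario.seed)
            sequence, truth = generate_sequence(scenario)
        else:
            rois = load_roi_config(cfg.roi_config) if cfg.roi_config else None
            log.info("loading manifest %s", cfg.manifest)
            sequence = read_manifest(cfg.manifest, rois=rois,
                                     day_night_schedule=cfg.day_night_schedule)
            truth = None
    except (OSError, FileNotFoundError, ConfigurationError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    treatments = {r.name: (r.treatment or r.name) for r in sequence.plant_rois()}

    # --- stage: extract -------------------------------------------------
    stage = "extract"
    log.info("extracting ROI temperatures (%d frames)", len(sequence.frames))
    try:
        readings = extract_readings(sequence)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: angles --------------------------------------------------
    stage = "angles"
    log.info("segmenting plants and measuring leaf angles")
    try:
        air_series = readings[["time_min", "air_temp"]]
        angles = measure_angles(sequence, air_series)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    series = build_time_series(readings, angles, treatments, sequence)
    series_path = _write_csv(series, out / "series.csv")
    angles_path = _write_csv(angles, out / "angles.csv")
    hourly = hourly_aggregate(series, sequence.day_night_schedule,
                              cadence_min=sequence.cadence_min)
    hourly_path = _write_csv(hourly, out / "hourly.csv")

    # --- stage: indices -------------------------------------------------
    stage = "indices"
    refs = cfg.references or demo_references(series)
    log.info("computing indices (t_dry=%.2f, t_wet=%.2f)", refs.t_dry, refs.t_wet)
    try:
        idx = compute_indices(series, refs)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    indices_path = _write_csv(idx, out / "indices.csv")

    # --- stage: onset + fit ---------------------------------------------
    stage = "fit"
    onsets: dict = {}
    fits: dict = {}
    try:
        for plant, grp in series.groupby("plant"):
            if cfg.onset == "auto":
                res = detect_wilting_onset(grp)
                onsets[plant] = res.onset_min
            else:
                onsets[plant] = float(cfg.onset)
        detected = [v for v in onsets.values() if v is not None]
        anchor = min(detected) if detected else None
        if anchor is not None:
            for plant, grp in series.groupby("plant"):
                day = grp[grp["is_day"]] if "is_day" in grp.columns else grp
                try:
                    model = AsymptoticStressModel.from_time_series(
                        day, anchor, horizon_h=cfg.horizon_h,
                        resample_min=cfg.resample_min)
                except InsufficientDataError as exc:
                    log.warning("plant %s: %s", plant, exc)
                    continue
                fit = model.fit()
                fits[plant] = fit.to_dict()
                log.info("plant %s: theta=%s shape=%s", plant,
                         fit.theta.round(4).tolist(), fit.shape_class)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        out_dir=out, series_path=series_path, angles_path=angles_path,
        hourly_path=hourly_path, indices_path=indices_path,
        fits=fits, onsets=onsets, anchor_min=anchor,
        version=__version__, config_echo=_config_echo(cfg))
    payload = {
        "version": report.version,
        "onsets_min": report.onsets,
        "anchor_min": report.anchor_min,
        "fits": report.fits,
        "artifacts": {
            "series": series_path.name, "angles": angles_path.name,
            "hourly": hourly_path.name, "indices": indices_path.name,
        },
        "config": report.config_echo,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    log.info("report written to %s", out / "report.json")
    return report
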
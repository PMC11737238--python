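"""End-to-end orchestration: simulate -> clean -> track -> segment ->
covariates -> resample -> train -> report.

A single :class:`PipelineConfig` (strict keys, all stage parameters with
their standard defaults, one master seed) drives the whole run; the manifest
records row counts at every filter so a run can be audited like a field
study's data accounting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    balanced_resampler,
    covariates,
    phase_classifier,
    phase_segmentation,
    synthetic_telemetry,
    track_builder,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters.  Unknown keys are rejected on load."""

    # data source: simulate when telemetry_csv is None
    telemetry_csv: str | None = None
    raster_dir: str | None = None
    seed: int = 0
    scenario: synthetic_telemetry.SimScenario = field(
        default_factory=synthetic_telemetry.SimScenario
    )
    # cleaning / tracks
    max_speed: float = 8.0            # m/s outlier threshold
    capture_window_hours: float = 24.0
    dt_min: float = 10.0              # minutes
    dt_max: float = 60.0
    # segmentation
    min_residency_days: float = 7.0
    min_separation: float = 2_000.0
    core_radius_factor: float = 4.0
    q_lo: float = 0.015
    q_hi: float = 0.985
    s2_window_days: float = 28.0
    min_envelope_fixes: int = 50
    trap_radius: float = 1_000.0
    # covariates
    latlon: tuple[float, float] = covariates.DEFAULT_LATLON
    # resampling
    n_select: int = 10
    n_boot: int = 120
    # forest
    n_trees: int = 300
    n_forests: int = 5
    mtry: int | str = "auto"
    pdp_variables: tuple[str, ...] = ("pv", "sl", "ta", "season")
    pdp_sample: int = 500

    def __post_init__(self) -> None:
        if self.dt_max < self.dt_min:
            raise ValueError("dt_max must be >= dt_min")
        if not (0 <= self.q_lo < self.q_hi <= 1):
            raise ValueError("need 0 <= q_lo < q_hi <= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = synthetic_telemetry.SimScenario(**d["scenario"])
        return cls(**d)


@dataclass
class RunResult:
    config: PipelineConfig
    manifest: dict
    features: pd.DataFrame
    resampled: pd.DataFrame
    model: phase_classifier.ForestModel
    oob: phase_classifier.OobReport
    importance: pd.DataFrame
    segmentations: dict
    population: list | None
    landscape: object


def _load_telemetry(cfg: PipelineConfig):
    fixes = pd.read_csv(cfg.telemetry_csv, parse_dates=["timestamp"])
    fixes = fixes.rename(columns={"timestamp": "t"})
    stack = covariates.LandscapeStack.read(cfg.raster_dir)
    traps = {
        ind: (float(g["x"].iloc[0]), float(g["y"].iloc[0]))
        for ind, g in fixes.groupby("individual_id")
    }
    return fixes[["individual_id", "t", "x", "y"]], stack, traps, None


def _simulate(cfg: PipelineConfig):
    scenario = replace(cfg.scenario, seed=cfg.seed)
    population, stack = synthetic_telemetry.simulate_population(scenario)
    fixes = pd.concat([s.fixes for s in population], ignore_index=True)
    traps = {
        s.fixes["individual_id"].iloc[0]: s.trap_location for s in population
    }
    return fixes, stack, traps, population


def run(cfg: PipelineConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write all stage outputs.

    Stage order and row accounting: raw fixes -> spatial-outlier filter ->
    24 h capture-window exclusion -> burst building (dt window) -> step
    metrics -> phase labels -> feature rows -> balanced resample ->
    five-forest ensemble with OOB validation, minimal depth and PDPs.
    """
    manifest: dict = {"seed": cfg.seed}
    ss = np.random.SeedSequence(cfg.seed)
    forest_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_forests)
    ]

    if cfg.telemetry_csv is None:
        fixes, stack, traps, population = _simulate(cfg)
    else:
        fixes, stack, traps, population = _load_telemetry(cfg)
    manifest["n_individuals"] = fixes["individual_id"].nunique()
    manifest["rows_raw"] = len(fixes)

    fixes = track_builder.remove_spatial_outliers(fixes, cfg.max_speed)
    manifest["rows_post_outlier"] = len(fixes)
    fixes = track_builder.drop_capture_window(
        fixes, window_hours=cfg.capture_window_hours
    )
    manifest["rows_post_capture_window"] = len(fixes)
    tracks = track_builder.build_tracks(fixes, cfg.dt_min, cfg.dt_max)
    manifest["rows_post_track"] = len(tracks)
    steps = track_builder.step_metrics(tracks)
    manifest["n_steps"] = len(steps)

    segmentations = {}
    excluded = {}
    for ind, g in fixes.groupby("individual_id", sort=True):
        try:
            segmentations[ind] = phase_segmentation.segment_track(
                g.reset_index(drop=True),
                trap_location=traps[ind],
                min_residency_days=cfg.min_residency_days,
                min_separation=cfg.min_separation,
                core_radius_factor=cfg.core_radius_factor,
                q_lo=cfg.q_lo,
                q_hi=cfg.q_hi,
                s2_window_days=cfg.s2_window_days,
                min_envelope_fixes=cfg.min_envelope_fixes,
                trap_radius=cfg.trap_radius,
            )
        except phase_segmentation.SegmentationError as err:
            excluded[ind] = str(err)
            log.warning("individual %s excluded: %s", ind, err)
    if not segmentations:
        raise RuntimeError("segmentation: no individual could be segmented")
    manifest["individuals_segmented"] = len(segmentations)
    manifest["individuals_excluded"] = excluded

    features = covariates.build_feature_table(
        steps, segmentations, stack, latlon=cfg.latlon
    )
    manifest["feature_rows"] = len(features)
    screen = covariates.screen_collinearity(features)
    manifest["collinearity_flags"] = [
        f"{a}~{b}:{r:.2f}" for a, b, r in screen.flagged
    ]

    rcfg = balanced_resampler.ResampleConfig(
        n_select=cfg.n_select, n_boot=cfg.n_boot, seed=cfg.seed
    )
    resampled = balanced_resampler.resample(features, rcfg)
    manifest["resampled_rows"] = len(resampled)
    cell_sizes = resampled.groupby(["individual_id", "phase"]).size()
    manifest["balanced_cells"] = int(len(cell_sizes))
    manifest["cell_size"] = (
        int(cell_sizes.iloc[0]) if cell_sizes.nunique() == 1 else "UNBALANCED"
    )

    models = [
        phase_classifier.fit_forest(
            resampled, n_trees=cfg.n_trees, mtry=cfg.mtry, seed=s
        )
        for s in forest_seeds
    ]
    model = phase_classifier.combine_forests(models)
    manifest["n_trees_combined"] = model.n_trees
    manifest["mtry"] = model.mtry
    oob = phase_classifier.oob_confusion(model)
    manifest["oob_error_pct"] = round(oob.overall_error, 3)
    manifest["oob_accuracy_pct"] = round(oob.accuracy, 3)
    manifest["oob_per_class_error_pct"] = {
        k: round(v, 3) for k, v in oob.per_class_error.items()
    }
    importance = phase_classifier.minimal_depth(model)
    manifest["top_variable"] = importance["variable"].iloc[0]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if population is not None:
            synthetic_telemetry.telemetry_to_csv(
                population, outdir / "telemetry.csv"
            )
            stack.write(outdir / "landscape")
        phase_segmentation.segmentation_to_csv(
            segmentations, outdir / "segmentation.csv"
        )
        phase_segmentation.segmentation_summary(segmentations).to_csv(
            outdir / "segmentation_summary.csv", index=False,
            float_format="%.2f",
        )
        covariates.feature_table_to_csv(features, outdir / "features.csv")
        resampled_out = resampled.copy()
        resampled_out.to_csv(outdir / "resampled.csv", index=False)
        oob.to_frame().to_csv(outdir / "oob_confusion.csv")
        importance.to_csv(outdir / "minimal_depth.csv", index=False)
        screen.rho.to_csv(outdir / "collinearity.csv")
        for var in cfg.pdp_variables:
            pdp = phase_classifier.partial_dependence(
                model, var, sample=cfg.pdp_sample, seed=cfg.seed
            )
            pdp.to_frame().to_csv(outdir / f"pdp_{var}.csv", index=False)
        cfg_echo = asdict(cfg)
        cfg_echo["scenario"] = asdict(cfg.scenario)
        (outdir / "config.json").write_text(json.dumps(cfg_echo, indent=1, default=str))
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str)
        )

    return RunResult(
        cfg, manifest, features, resampled, model, oob, importance,
        segmentations, population, stack,
    )
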
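"""End-to-end orchestration: simulate → quantify → calibrate → map → analyze.

One :func:`run_pipeline` call executes the full chain deterministically for a
given (config, seed), writing every artifact plus a manifest with the config
hash and per-file checksums. Each stage is also callable on its own, so a run
can be resumed or a single stage re-executed on the previous stage's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import calibrate as cal
from . import idw, quantify, temporal
from . import scene as scene_mod

logger = logging.getLogger("microph")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``field_kind``/``field_params`` select the simulated ground truth;
    ``images_dir`` (if set) skips simulation and reads an existing scene.
    ``calibration_csv`` (if set) replaces the synthetic calibration source.
    """

    scene: scene_mod.SceneConfig = dc_field(default_factory=scene_mod.SceneConfig)
    phys: scene_mod.Photophysics = dc_field(default_factory=scene_mod.Photophysics)
    segmentation: quantify.SegmentationParams = dc_field(
        default_factory=quantify.SegmentationParams
    )
    idw_params: idw.IDWParams = dc_field(default_factory=idw.IDWParams)
    field_kind: str = "ramp"
    field_params: dict[str, Any] = dc_field(default_factory=dict)
    images_dir: str | None = None
    calibration_csv: str | None = None
    control_summary_csv: str | None = None
    resolutions_um: tuple[float, ...] = idw.DEFAULT_RESOLUTIONS
    r2_min: float = 0.79
    err_max_pct: float = 4.5
    cv_frame: int = -1
    window_um: float = 20.0
    top_fraction: float = 0.1
    onset_k: float = 3.0
    link_radius_um: float = 2.0
    max_gap: int = 2
    write_images: bool = True
    write_heatmaps: bool = True
    out_dir: str = "runs/out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r2_min <= 0 or self.err_max_pct <= 0:
            raise ValueError("CV thresholds must be positive")
        if list(self.resolutions_um) != sorted(self.resolutions_um):
            raise ValueError("candidate resolutions must be sorted ascending")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    field: scene_mod.GroundTruthField | None
    layout: scene_mod.CellLayout | None
    observations_by_frame: list[list[quantify.CellObservation]]
    tracks: quantify.TrackTable
    curve: cal.CalibrationCurve
    cv_report: idw.CVReport | None
    maps: dict[int, idw.InterpolatedMap]
    summaries: list[temporal.FrameSummary]
    gradients: list[temporal.GradientReport]
    manifest: dict[str, Any]


def _config_to_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["resolutions_um"] = list(config.resolutions_um)
    # the output location is not part of the scientific configuration:
    # identical runs in different directories must hash identically
    d.pop("out_dir")
    return d


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of (possibly partial) sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    if "scene" in raw:
        kwargs["scene"] = scene_mod.SceneConfig(**raw.pop("scene"))
    if "phys" in raw:
        kwargs["phys"] = scene_mod.Photophysics(**raw.pop("phys"))
    if "segmentation" in raw:
        kwargs["segmentation"] = quantify.SegmentationParams(**raw.pop("segmentation"))
    if "idw_params" in raw:
        kwargs["idw_params"] = idw.IDWParams(**raw.pop("idw_params"))
    if "resolutions_um" in raw:
        raw["resolutions_um"] = tuple(raw["resolutions_um"])
    kwargs.update(raw)
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages

def stage_simulate(
    config: RunConfig,
) -> tuple[scene_mod.GroundTruthField, scene_mod.CellLayout, list[scene_mod.ImagePair]]:
    field = scene_mod.generate_field(config.scene, config.field_kind, config.field_params)
    layout = scene_mod.place_cells(config.scene, seed=config.seed)
    images = scene_mod.render_stack(field, layout, config.phys, config.scene, seed=config.seed)
    return field, layout, images


def stage_quantify(
    config: RunConfig, images: list[scene_mod.ImagePair]
) -> tuple[list[list[quantify.CellObservation]], quantify.TrackTable]:
    obs_by_frame = []
    for pair in images:
        t = pair.frame * config.scene.frame_interval_h
        obs_by_frame.append(quantify.quantify_frame(pair, t, config.segmentation))
        logger.debug("frame %d: %d cells", pair.frame, len(obs_by_frame[-1]))
    tracks = quantify.link_tracks(obs_by_frame, config.link_radius_um, config.max_gap)
    return obs_by_frame, tracks


def stage_calibrate(
    config: RunConfig, obs_by_frame: list[list[quantify.CellObservation]]
) -> cal.CalibrationCurve:
    if config.calibration_csv:
        points = cal.read_calibration_csv(config.calibration_csv)
        points = [p for p in points if p.medium is cal.Medium.UNBUFFERED] or points
    else:
        points = cal.synthetic_calibration_points(
            slope=config.phys.alpha, intercept=config.phys.beta,
            seed=config.seed + 1,
        )
    curve = cal.fit_calibration(points)
    for obs_list in obs_by_frame:
        cal.apply_calibration(obs_list, curve)
    return curve


def stage_map(
    config: RunConfig, obs_by_frame: list[list[quantify.CellObservation]]
) -> tuple[idw.CVReport, dict[int, idw.InterpolatedMap]]:
    cv_obs = obs_by_frame[config.cv_frame]
    report = idw.cross_validate_resolutions(
        cv_obs, config.resolutions_um, config.idw_params,
        config.r2_min, config.err_max_pct,
    )
    maps: dict[int, idw.InterpolatedMap] = {}
    if report.selected_resolution_um is not None:
        for f, obs_list in enumerate(obs_by_frame):
            ok = [o for o in obs_list if o.qc_flag is quantify.QCFlag.OK]
            if len(ok) >= 2:
                maps[f] = idw.build_map(
                    obs_list, report.selected_resolution_um, config.idw_params, f
                )
    return report, maps


def stage_analyze(
    config: RunConfig,
    obs_by_frame: list[list[quantify.CellObservation]],
    maps: dict[int, idw.InterpolatedMap],
) -> tuple[list[temporal.FrameSummary], list[temporal.GradientReport]]:
    summaries = [temporal.frame_stats(obs) for obs in obs_by_frame]
    gradients: list[temporal.GradientReport] = []
    prev = None
    for f in sorted(maps):
        rep = temporal.gradient_metric(maps[f], config.window_um)
        if prev is not None and prev.grid == maps[f].grid:
            jac = temporal.gradient_stability(prev, maps[f], config.top_fraction)
            rep = dataclasses.replace(rep, stability_jaccard=jac)
        gradients.append(rep)
        prev = maps[f]
    return summaries, gradients


# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in order and write all artifacts + manifest.

    Deterministic for a fixed (config, seed). When no candidate resolution
    passes cross-validation, heatmaps are skipped and the manifest records the
    diagnostic; the temporal summary (which needs no maps) is still produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _config_to_dict(config)
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "files": {},
    }
    (out / "config.yaml").write_text(cfg_yaml)

    # -- simulate (or load) ------------------------------------------------
    field = layout = None
    if config.images_dir is None:
        logger.info("simulate: %s field, %d frames", config.field_kind,
                    config.scene.n_frames)
        field, layout, images = stage_simulate(config)
        if config.write_images:
            scene_mod.write_scene(out / "images", config.scene, field, layout, images)
        manifest["stages"]["simulate"] = {"n_cells": len(layout)}
    else:
        src = Path(config.images_dir)
        with open(src / "scene.json") as fh:
            meta = json.load(fh)
        images = [
            scene_mod.read_image_pair(p, f, meta["pixel_size_um"])
            for f, p in enumerate(sorted(src.glob("frame_*.tif")))
        ]
        manifest["stages"]["simulate"] = {"loaded_from": str(src)}

    # -- quantify ----------------------------------------------------------
    logger.info("quantify: %d frames", len(images))
    obs_by_frame, tracks = stage_quantify(config, images)
    manifest["stages"]["quantify"] = {
        "n_observations": sum(len(o) for o in obs_by_frame),
        "n_tracks": len(tracks),
    }

    # -- calibrate ---------------------------------------------------------
    curve = stage_calibrate(config, obs_by_frame)
    cal.write_curve_json(curve, out / "calibration_curve.json")
    manifest["stages"]["calibrate"] = {
        "slope": curve.slope, "intercept": curve.intercept,
        "r_squared": curve.r_squared,
    }
    all_obs = [o for obs in obs_by_frame for o in obs]
    quantify.observations_to_frame(all_obs).to_csv(
        out / "observations.csv", index=False, float_format="%.6g"
    )

    # -- map ---------------------------------------------------------------
    cv_report, maps = stage_map(config, obs_by_frame)
    with open(out / "cv_report.csv", "w") as fh:
        fh.write("r_um,cv_r_squared,prediction_error_pct,n\n")
        for r in cv_report.resolutions_um:
            fh.write(
                f"{r:g},{cv_report.cv_r_squared[r]:.6f},"
                f"{cv_report.prediction_error_pct[r]:.6f},{cv_report.n}\n"
            )
    manifest["stages"]["map"] = {
        "selected_resolution_um": cv_report.selected_resolution_um,
        "diagnostic": cv_report.diagnostic,
        "n_maps": len(maps),
    }
    if cv_report.selected_resolution_um is None:
        logger.warning("map: %s", cv_report.diagnostic)
        manifest["warnings"].append(cv_report.diagnostic)
    else:
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        for f, m in maps.items():
            idw.save_map(m, map_dir / f"map_{f:03d}.csv")
            if config.write_heatmaps:
                idw.plot_map(m, map_dir / f"map_{f:03d}.png")

    # -- analyze -----------------------------------------------------------
    summaries, gradients = stage_analyze(config, obs_by_frame, maps)
    with open(out / "summary.csv", "w") as fh:
        fh.write("frame,time_h,n_cells,mean_ph,sd_ph\n")
        for s in summaries:
            fh.write(
                f"{s.frame},{s.time_h:g},{s.n_cells},{s.mean_ph:.6f},{s.sd_ph:.6f}\n"
            )
    with open(out / "gradients.csv", "w") as fh:
        fh.write("frame,max_delta_ph,window_um,jaccard_vs_prev\n")
        for g in gradients:
            fh.write(
                f"{g.frame},{g.max_delta_ph:.6f},{g.window_um:g},"
                f"{g.stability_jaccard:.6f}\n"
            )
    onset_frame = None
    if config.control_summary_csv:
        control = _read_summary_csv(config.control_summary_csv)
        onset_frame = temporal.onset_time(summaries, control, config.onset_k)
    report = {
        "onset_frame": onset_frame,
        "selected_resolution_um": cv_report.selected_resolution_um,
        "final_mean_ph": summaries[-1].mean_ph if summaries else None,
        "max_gradient_ph": max((g.max_delta_ph for g in gradients), default=None),
        "influence_zone_um": temporal.influence_zone_width(18.0, 100.0),
        "diffusion_time_s_20um": temporal.diffusion_time(20.0),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_np_default)
    manifest["stages"]["analyze"] = {"n_summaries": len(summaries)}

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_np_default)

    return PipelineResult(
        config=config, field=field, layout=layout,
        observations_by_frame=obs_by_frame, tracks=tracks, curve=curve,
        cv_report=cv_report, maps=maps, summaries=summaries,
        gradients=gradients, manifest=manifest,
    )


def _read_summary_csv(path: str | Path) -> list[temporal.FrameSummary]:
    """Read a summary.csv written by a previous (control) run."""
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.strip().split(",")
            out.append(
                temporal.FrameSummary(
                    frame=int(parts[idx["frame"]]),
                    time_h=float(parts[idx["time_h"]]),
                    n_cells=int(parts[idx["n_cells"]]),
                    mean_ph=float(parts[idx["mean_ph"]]),
                    sd_ph=float(parts[idx["sd_ph"]]),
                )
            )
    return out


def _np_default(v: Any) -> Any:
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON-serialisable: {type(v)}")
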
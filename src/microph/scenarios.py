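"""Canonical study-condition scenarios for validation and benchmarking.

Each function builds one of the reference synthetic experiments the package
is validated against — the conditions mirror the emulated study: a
0.4 × 0.8 mm observation area seeded at ≈2200 cells/mm² with the default
photophysics — runs the relevant pipeline stages, and returns the recovered
quantity together with the problem size. They are deliberately thin
compositions of public API calls so the same definitions back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import calibrate as cal
from . import idw, quantify, temporal
from . import scene as scene_mod

__all__ = [
    "cv_accuracy_at_resolution",
    "gradient_recovery",
    "acidification_trajectory_endpoint",
]


def cv_accuracy_at_resolution(
    seed: int,
    resolution_um: float = 3.0,
    correlation_length_um: float = 50.0,
    noise_sd_ph: float = 0.15,
    n_replicates: int = 3,
) -> tuple[float, float, int]:
    """LOO-CV accuracy of IDW mapping on heterogeneous late-stage-like fields.

    Each replicate draws a Gaussian-random pH field (defaults anchored to the
    observed late-stage heterogeneity), samples it at a fresh Poisson cell
    layout, perturbs each per-cell pH by ``noise_sd_ph`` (the sensor's
    worst-case single-cell precision), and scores leave-one-out IDW at
    ``resolution_um``. Returns (mean CV R², mean error %, cells per scene).
    """
    config = scene_mod.SceneConfig(n_frames=1)
    r2s, errs, ns = [], [], []
    for rep in range(n_replicates):
        s = seed + rep
        field = scene_mod.generate_field(
            config, "grf",
            {"mean_ph": 5.1, "sd_ph": 0.35,
             "correlation_length_um": correlation_length_um, "seed": s},
        )
        layout = scene_mod.place_cells(config, seed=s + 1)
        rng = np.random.default_rng(s + 2)
        ph = field.sample(0, layout.x_um, layout.y_um)
        ph = ph + rng.normal(0.0, noise_sd_ph, len(layout))
        obs = np.column_stack([layout.x_um, layout.y_um, ph])
        r2, err = idw.loo_cv(obs, resolution_um)
        r2s.append(r2)
        errs.append(err)
        ns.append(len(layout))
    return float(np.mean(r2s)), float(np.mean(errs)), int(np.mean(ns))


def _image_to_observations(
    config: scene_mod.SceneConfig,
    field: scene_mod.GroundTruthField,
    layout: scene_mod.CellLayout,
    phys: scene_mod.Photophysics,
    frame: int,
    seed: int,
) -> list[quantify.CellObservation]:
    img = scene_mod.render_frame(field, layout, phys, config, frame, seed=seed)
    obs = quantify.quantify_frame(img, frame * config.frame_interval_h)
    curve = cal.fit_calibration(cal.synthetic_calibration_points(
        slope=phys.alpha, intercept=phys.beta, seed=seed + 1
    ))
    return cal.apply_calibration(obs, curve)


def gradient_recovery(
    seed: int,
    amplitude: float = 1.4,
    length_scale_um: float = 20.0,
    resolution_um: float = 3.0,
    n_replicates: int = 3,
) -> tuple[float, int]:
    """Planted-gradient recovery through the full image → map pipeline.

    Each replicate plants a static sigmoidal pH step (``amplitude`` units
    across ``length_scale_um``) mid-field, renders a noisy frame, segments
    and calibrates the cells, builds the IDW map at ``resolution_um``, and
    reads off the maximum pH contrast within a window equal to the step's
    length scale. Returns (mean recovered contrast, cells per scene).
    """
    deltas, ns = [], []
    for rep in range(n_replicates):
        s = seed + rep
        config = scene_mod.SceneConfig(n_frames=1, seed=s)
        phys = scene_mod.Photophysics()
        field = scene_mod.generate_field(
            config, "gradient_patch",
            {"baseline": 5.8, "amplitude": amplitude,
             "length_scale_um": length_scale_um,
             "anchors_x_um": [config.field_width_um / 2.0]},
        )
        layout = scene_mod.place_cells(config, seed=s)
        obs = _image_to_observations(config, field, layout, phys, 0, 10_000 + s)
        phmap = idw.build_map(obs, resolution_um, frame=0)
        report = temporal.gradient_metric(phmap, length_scale_um)
        deltas.append(report.max_delta_ph)
        ns.append(len(layout))
    return float(np.mean(deltas)), int(np.mean(ns))


def acidification_trajectory_endpoint(
    seed: int,
    ph_start: float = 6.9,
    ph_end: float = 5.0,
    n_frames: int = 49,
) -> tuple[float, temporal.FrameSummary, int]:
    """Full 48 h acidification run; recovered final-frame area-average pH.

    Simulates the hourly-imaged ramp scene (area mean drifting linearly from
    ``ph_start`` to ``ph_end``), runs segmentation, tracking-free per-frame
    quantification and calibration, and returns (final mean pH, final frame
    summary, number of planted cells).
    """
    config = scene_mod.SceneConfig(n_frames=n_frames, seed=seed)
    phys = scene_mod.Photophysics()
    field = scene_mod.generate_field(
        config, "ramp", {"ph_start": ph_start, "ph_end": ph_end}
    )
    layout = scene_mod.place_cells(config, seed=seed)
    curve = cal.fit_calibration(cal.synthetic_calibration_points(
        slope=phys.alpha, intercept=phys.beta, seed=seed + 1
    ))
    last = None
    for frame in range(n_frames):
        img = scene_mod.render_frame(
            field, layout, phys, config, frame, seed=seed + 10_000 + frame
        )
        obs = quantify.quantify_frame(img, frame * config.frame_interval_h)
        cal.apply_calibration(obs, curve)
        last = temporal.frame_stats(obs)
    return float(last.mean_ph), last, len(layout)
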
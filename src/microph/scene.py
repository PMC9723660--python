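"""Synthetic microcosm scenes: ground-truth pH fields, cell layouts, image rendering.

The generator emulates a time-lapse ratiometric biosensing experiment: ~2 µm
reporter cells immobilised at ≈2200 cells/mm² on a 0.4 × 0.8 mm agarose field,
imaged hourly in two excitation channels (475 nm and 395 nm, both read out at
510 nm emission). Each cell reports the pH at its position through the
excitation ratio R = I475/I395, which responds linearly (negative slope) to pH.

Every downstream stage of the pipeline (segmentation, calibration, IDW mapping,
temporal analytics) can therefore be tested against a known latent truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "Photophysics",
    "GroundTruthField",
    "CellLayout",
    "ImagePair",
    "FIELD_KINDS",
    "generate_field",
    "place_cells",
    "render_frame",
    "render_stack",
    "write_scene",
    "read_image_pair",
]

PH_MIN, PH_MAX = 3.0, 9.0

FIELD_KINDS = ("uniform", "ramp", "gradient_patch", "grf", "hyphal_front")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and acquisition parameters of the synthetic microcosm.

    Defaults mirror the reference experiment: a 0.8 × 0.4 mm observation area,
    hourly frames for 48 h, ≈2200 cells/mm² surface coverage of ~1 µm-radius
    cells, sampled at 0.5 µm/pixel.
    """

    field_width_um: float = 800.0
    field_height_um: float = 400.0
    pixel_size_um: float = 0.5
    n_frames: int = 49
    frame_interval_h: float = 1.0
    cell_density_per_mm2: float = 2200.0
    cell_radius_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if self.cell_density_per_mm2 < 0:
            raise ValueError("cell density must be >= 0")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be positive")

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of the rendered image."""
        return (
            int(round(self.field_height_um / self.pixel_size_um)),
            int(round(self.field_width_um / self.pixel_size_um)),
        )

    @property
    def area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um * 1e-6

    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


@dataclass(frozen=True)
class Photophysics:
    """Linear excitation-ratio response plus a simple camera model.

    ``alpha`` and ``beta`` define the ratio response R(pH) = alpha·pH + beta
    (alpha < 0: the ratio rises as the environment acidifies). Defaults are the
    two-point line through the unbuffered calibration endpoints R = 0.45 at
    pH 7.4 and R = 1.59 at pH 5.0, i.e. alpha = −0.475, beta = 3.965.

    ``total_signal`` A is the in-focus per-pixel amplitude of ch475 + ch395 for
    a cell; the split I475 = A·R/(1+R), I395 = A/(1+R) keeps total brightness
    independent of pH so segmentation cannot be pH-biased. Photobleaching acts
    as a geometric per-frame decay on A only; the ratio is invariant to it.
    """

    alpha: float = -0.475
    beta: float = 3.965
    total_signal: float = 1500.0
    background_475: float = 100.0
    background_395: float = 100.0
    read_noise_sd: float = 3.0
    bleach_per_frame: float = 0.005
    psf_sd_um: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("alpha must be negative (ratio rises as pH drops)")
        if self.total_signal <= 0:
            raise ValueError("total_signal must be positive")
        if not (0.0 <= self.bleach_per_frame < 1.0):
            raise ValueError("bleach_per_frame must be in [0, 1)")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    def ratio(self, ph: float | np.ndarray) -> float | np.ndarray:
        """Noise-free excitation ratio at a given pH."""
        return self.alpha * np.asarray(ph, dtype=float) + self.beta

    def ph_of_ratio(self, ratio: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ratio, dtype=float) - self.beta) / self.alpha


@dataclass
class GroundTruthField:
    """Latent time-resolved pH landscape on a regular grid.

    ``values`` has shape (n_frames, n_rows, n_cols); node (i, j) is centred at
    ((j + 0.5)·dx, (i + 0.5)·dx) in µm, origin at the top-left of the field.
    """

    values: np.ndarray
    node_spacing_um: float
    field_kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("field values must be (frame, row, col)")
        if self.node_spacing_um <= 0:
            raise ValueError("node_spacing_um must be positive")
        if np.any(self.values < PH_MIN) or np.any(self.values > PH_MAX):
            raise ValueError(f"pH values outside [{PH_MIN}, {PH_MAX}]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def sample(self, frame: int, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Bilinear pH at arbitrary positions for one frame (edge-clamped)."""
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        col = x / self.node_spacing_um - 0.5
        row = y / self.node_spacing_um - 0.5
        return ndimage.map_coordinates(
            self.values[frame], np.vstack([row.ravel(), col.ravel()]),
            order=1, mode="nearest",
        ).reshape(x.shape)

    def frame_mean(self, frame: int) -> float:
        return float(self.values[frame].mean())


@dataclass
class CellLayout:
    """Immobilised cell centres in µm; ``cell_id`` is 0..n-1."""

    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.shape != self.y_um.shape or self.x_um.ndim != 1:
            raise ValueError("x_um and y_um must be matching 1-d arrays")

    def __len__(self) -> int:
        return self.x_um.size

    @property
    def cell_id(self) -> np.ndarray:
        return np.arange(len(self))


@dataclass
class ImagePair:
    """One frame's two-channel 16-bit acquisition (510 nm emission)."""

    ch475: np.ndarray
    ch395: np.ndarray
    frame: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.ch475.shape != self.ch395.shape:
            raise ValueError("channel shapes differ")
        for ch in (self.ch475, self.ch395):
            if ch.dtype != np.uint16:
                raise ValueError("channels must be uint16")


# ---------------------------------------------------------------------------
# ground-truth field generators

def _field_grid(config: SceneConfig, node_spacing_um: float) -> tuple[np.ndarray, np.ndarray]:
    n_rows = max(1, int(round(config.field_height_um / node_spacing_um)))
    n_cols = max(1, int(round(config.field_width_um / node_spacing_um)))
    x = (np.arange(n_cols) + 0.5) * node_spacing_um
    y = (np.arange(n_rows) + 0.5) * node_spacing_um
    return np.meshgrid(x, y)


def _clip_field(values: np.ndarray) -> np.ndarray:
    if np.any(values < PH_MIN) or np.any(values > PH_MAX):
        warnings.warn(
            f"field parameters produce pH outside [{PH_MIN}, {PH_MAX}]; clipping",
            stacklevel=3,
        )
        values = np.clip(values, PH_MIN, PH_MAX)
    return values


def generate_field(
    config: SceneConfig,
    kind: str,
    params: dict[str, Any] | None = None,
    node_spacing_um: float = 2.0,
) -> GroundTruthField:
    """Generate a latent pH field of one of five kinds.

    uniform
        constant ``ph`` everywhere (control scene).
    ramp
        spatially constant; the mean drifts linearly from ``ph_start`` at
        frame 0 to ``ph_end`` at the last frame (bulk acidification).
    gradient_patch
        ``baseline`` minus sigmoidal steps of ``amplitude`` with full
        transition width ``length_scale_um`` centred at ``anchors_x_um``
        (list of x positions); flat baseline before ``onset_frame``, static
        afterwards. Emulates stable microscale gradient fronts.
    grf
        static Gaussian random field: mean ``mean_ph``, point sd ``sd_ph``,
        Gaussian correlation length ``correlation_length_um``; clipped to the
        valid pH range. Emulates late-stage spatial heterogeneity.
    hyphal_front
        a pH depression travelling from the left edge at
        ``extension_rate_um_per_h`` whose acidified halo (ΔpH > 0.05) leads
        the tip by ``lead_time_h`` hours of travel; depth ``depth`` below
        ``baseline`` behind the tip, exponential decay ahead of it.
    """
    params = dict(params or {})
    if kind not in FIELD_KINDS:
        raise ValueError(f"unknown field kind {kind!r}; expected one of {FIELD_KINDS}")
    xx, yy = _field_grid(config, node_spacing_um)
    n_rows, n_cols = xx.shape
    frames = np.empty((config.n_frames, n_rows, n_cols), dtype=float)
    times = config.times_h()

    if kind == "uniform":
        frames[:] = float(params.get("ph", 6.9))

    elif kind == "ramp":
        ph_start = float(params.get("ph_start", 6.9))
        ph_end = float(params.get("ph_end", 5.0))
        if config.n_frames == 1:
            means = np.array([ph_start])
        else:
            means = np.linspace(ph_start, ph_end, config.n_frames)
        frames[:] = means[:, None, None]

    elif kind == "gradient_patch":
        baseline = float(params.get("baseline", 5.8))
        amplitude = float(params.get("amplitude", 1.4))
        length = float(params.get("length_scale_um", 20.0))
        anchors = params.get("anchors_x_um", [config.field_width_um / 2.0])
        onset = int(params.get("onset_frame", 0))
        # logistic scale = length/10: >98% of the amplitude falls within the
        # stated transition width, so the step is recoverable at that scale
        s = length / 10.0
        patch = np.zeros_like(xx)
        for xa in np.atleast_1d(anchors):
            step = 1.0 / (1.0 + np.exp(-(xx - float(xa)) / s))
            patch = np.maximum(patch, step)
        static = baseline - amplitude * patch
        for f in range(config.n_frames):
            frames[f] = baseline if f < onset else static

    elif kind == "grf":
        mean_ph = float(params.get("mean_ph", 5.1))
        sd_ph = float(params.get("sd_ph", 0.35))
        corr = float(params.get("correlation_length_um", 50.0))
        seed = int(params.get("seed", config.seed))
        rng = np.random.default_rng(seed)
        sigma_nodes = corr / node_spacing_um
        # pad so smoothing is stationary, then normalise empirically to the
        # requested point sd (the filter shrinks white-noise variance)
        pad = int(np.ceil(4 * sigma_nodes))
        white = rng.standard_normal((n_rows + 2 * pad, n_cols + 2 * pad))
        smooth = ndimage.gaussian_filter(white, sigma_nodes)[pad:-pad or None, pad:-pad or None]
        smooth = (smooth - smooth.mean()) / smooth.std()
        frames[:] = mean_ph + sd_ph * smooth

    elif kind == "hyphal_front":
        baseline = float(params.get("baseline", 6.9))
        depth = float(params.get("depth", 1.9))
        rate = float(params.get("extension_rate_um_per_h", 100.0))
        lead = float(params.get("lead_time_h", 18.0))
        source_x = float(params.get("source_x_um", 0.0))
        threshold = 0.05  # halo edge definition (ΔpH > threshold)
        if depth <= threshold:
            raise ValueError("depth must exceed the 0.05 halo threshold")
        lam = lead * rate / np.log(depth / threshold)
        for f, t in enumerate(times):
            tip = source_x + rate * t
            ahead = np.clip(xx - tip, 0.0, None)
            frames[f] = baseline - depth * np.exp(-ahead / lam)

    frames = _clip_field(frames)
    return GroundTruthField(frames, node_spacing_um, kind, params)


def place_cells(config: SceneConfig, seed: int | None = None) -> CellLayout:
    """Homogeneous Poisson placement of cell centres over the field.

    The count is Poisson(density × area); at the default geometry the mean is
    2200 mm⁻² × 0.32 mm² = 704 cells.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = rng.poisson(config.cell_density_per_mm2 * config.area_mm2)
    x = rng.uniform(0.0, config.field_width_um, size=n)
    y = rng.uniform(0.0, config.field_height_um, size=n)
    return CellLayout(x, y)


# ---------------------------------------------------------------------------
# rendering

def _disk_profile(
    shape: tuple[int, int],
    x_um: float,
    y_um: float,
    radius_um: float,
    pixel_size_um: float,
) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased disk coverage on a local window; returns (rows, cols, prof)."""
    r_px = radius_um / pixel_size_um
    cx = x_um / pixel_size_um - 0.5  # pixel-centre coordinates
    cy = y_um / pixel_size_um - 0.5
    half = int(np.ceil(r_px)) + 2
    i0 = max(0, int(np.floor(cy)) - half)
    i1 = min(shape[0], int(np.floor(cy)) + half + 1)
    j0 = max(0, int(np.floor(cx)) - half)
    j1 = min(shape[1], int(np.floor(cx)) + half + 1)
    if i0 >= i1 or j0 >= j1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    d = np.hypot(jj - cx, ii - cy)
    prof = np.clip(r_px - d + 0.5, 0.0, 1.0)
    return slice(i0, i1), slice(j0, j1), prof


def render_frame(
    field: GroundTruthField,
    layout: CellLayout,
    phys: Photophysics,
    config: SceneConfig,
    frame: int,
    seed: int | None = None,
    noise: bool = True,
) -> ImagePair:
    """Render one two-channel frame of the scene.

    Each cell senses the latent pH at its centre; its noise-free channel
    amplitudes are I475 = A·R/(1+R) and I395 = A/(1+R) so that the pixelwise
    ratio equals R exactly and total brightness is pH-independent. The frame
    is blurred by a Gaussian point spread, offset by per-channel backgrounds,
    and (optionally) degraded by Poisson shot noise plus Gaussian read noise,
    then quantised to 16 bits.
    """
    shape = config.shape_px
    ph = field.sample(frame, layout.x_um, layout.y_um) if len(layout) else np.empty(0)
    ratios = phys.ratio(ph)
    if len(layout) and np.any(ratios <= 0):
        bad = float(np.asarray(ph)[np.argmin(ratios)])
        raise ValueError(
            f"configured response gives non-positive ratio at pH {bad:.2f}; "
            "photophysics incompatible with the field's pH range"
        )
    amp = phys.total_signal * (1.0 - phys.bleach_per_frame) ** frame
    im475 = np.zeros(shape, dtype=float)
    im395 = np.zeros(shape, dtype=float)
    for k in range(len(layout)):
        rows, cols, prof = _disk_profile(
            shape, layout.x_um[k], layout.y_um[k], config.cell_radius_um,
            config.pixel_size_um,
        )
        if prof.size == 0:
            continue
        r = ratios[k]
        im475[rows, cols] += amp * r / (1.0 + r) * prof
        im395[rows, cols] += amp / (1.0 + r) * prof
    if phys.psf_sd_um > 0:
        sigma_px = phys.psf_sd_um / config.pixel_size_um
        im475 = ndimage.gaussian_filter(im475, sigma_px)
        im395 = ndimage.gaussian_filter(im395, sigma_px)
    im475 += phys.background_475
    im395 += phys.background_395
    if noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        im475 = rng.poisson(im475).astype(float)
        im395 = rng.poisson(im395).astype(float)
        if phys.read_noise_sd > 0:
            im475 += rng.normal(0.0, phys.read_noise_sd, shape)
            im395 += rng.normal(0.0, phys.read_noise_sd, shape)
    out475 = np.clip(np.rint(im475), 0, 65535).astype(np.uint16)
    out395 = np.clip(np.rint(im395), 0, 65535).astype(np.uint16)
    return ImagePair(out475, out395, frame, config.pixel_size_um)


def render_stack(
    field: GroundTruthField,
    layout: CellLayout,
    phys: Photophysics,
    config: SceneConfig,
    seed: int | None = None,
    noise: bool = True,
) -> list[ImagePair]:
    """Render all frames; per-frame noise streams derive from the base seed."""
    base = config.seed if seed is None else seed
    return [
        render_frame(field, layout, phys, config, f, seed=base + 10_000 + f, noise=noise)
        for f in range(config.n_frames)
    ]


# ---------------------------------------------------------------------------
# on-disk scene dialect

def write_scene(
    out_dir: str | Path,
    config: SceneConfig,
    field: GroundTruthField,
    layout: CellLayout,
    images: list[ImagePair],
) -> None:
    """Write a scene: per-frame two-page TIFFs, layout CSV, truth CSV, sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in images:
        tifffile.imwrite(
            out / f"frame_{pair.frame:03d}.tif",
            np.stack([pair.ch475, pair.ch395]),
            metadata=None,
        )
    with open(out / "layout.csv", "w") as fh:
        fh.write("cell_id,x_um,y_um\n")
        for k in range(len(layout)):
            fh.write(f"{k},{layout.x_um[k]:.4f},{layout.y_um[k]:.4f}\n")
    nf, nr, nc = field.values.shape
    idx_f, idx_r, idx_c = np.meshgrid(
        np.arange(nf), np.arange(nr), np.arange(nc), indexing="ij"
    )
    table = np.column_stack(
        [idx_f.ravel(), idx_r.ravel(), idx_c.ravel(), field.values.ravel()]
    )
    np.savetxt(
        out / "ground_truth.csv", table, fmt=("%d", "%d", "%d", "%.5f"),
        delimiter=",", header="frame,row,col,ph", comments="",
    )
    sidecar = {
        "config": dataclasses.asdict(config),
        "field_kind": field.field_kind,
        "field_params": {k: _jsonable(v) for k, v in field.params.items()},
        "node_spacing_um": field.node_spacing_um,
        "pixel_size_um": config.pixel_size_um,
        "n_frames": config.n_frames,
        "frame_interval_h": config.frame_interval_h,
    }
    with open(out / "scene.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def _jsonable(v: Any) -> Any:
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def read_image_pair(path: str | Path, frame: int, pixel_size_um: float) -> ImagePair:
    """Read one two-page TIFF written by :func:`write_scene`."""
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page TIFF (ch475, ch395)")
    return ImagePair(
        stack[0].astype(np.uint16), stack[1].astype(np.uint16), frame, pixel_size_um
    )
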
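"""Single-cell detection, background-corrected intensity extraction, tracking.

Replaces an interactive ImageJ per-cell fluorescence protocol with an
automated equivalent: Otsu segmentation of the summed two-channel frame,
per-channel background correction against the median of cell-free pixels, and
greedy nearest-neighbour linking of the immobilised cells across frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import filters, measure

from .scene import ImagePair

__all__ = [
    "QCFlag",
    "SegmentationParams",
    "ROI",
    "CellObservation",
    "TrackTable",
    "segment_cells",
    "measure_cell",
    "estimate_background",
    "quantify_frame",
    "link_tracks",
    "observations_to_frame",
]


class QCFlag(str, Enum):
    OK = "ok"
    LOW_SIGNAL = "low_signal"
    NEGATIVE_AFTER_CORRECTION = "negative_after_correction"
    OUT_OF_CALIBRATION_RANGE = "out_of_calibration_range"


@dataclass(frozen=True)
class SegmentationParams:
    """Settings for cell detection.

    ``min_area_um2``/``max_area_um2`` bound accepted component areas (the
    defaults pass single ~1 µm-radius cells and reject debris and merged
    clumps of several cells); ``smooth_sd_px`` is the pre-threshold Gaussian
    smoothing; ``low_signal_k`` flags cells whose corrected I395 falls below
    k × read-noise.
    """

    min_area_um2: float = 1.0
    max_area_um2: float = 20.0
    smooth_sd_px: float = 1.0
    low_signal_k: float = 3.0
    read_noise_sd: float = 3.0


@dataclass
class ROI:
    """One segmented cell in one frame: its pixels and centroid (µm)."""

    cell_id: int
    frame: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    x_um: float
    y_um: float
    area_um2: float


@dataclass
class CellObservation:
    """One cell at one frame, after intensity extraction.

    ``ratio = i475_corr / i395_corr`` holds whenever ``qc_flag`` is ``ok``;
    ``ph`` is filled later by the calibration stage (NaN until then).
    """

    cell_id: int
    frame: int
    time_h: float
    x_um: float
    y_um: float
    i475_corr: float
    i395_corr: float
    ratio: float
    ph: float = float("nan")
    qc_flag: QCFlag = QCFlag.OK
    track_id: int = -1


@dataclass
class TrackTable:
    """track_id → frame-ordered observations of one immobilised cell."""

    tracks: dict[int, list[CellObservation]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def lengths(self) -> dict[int, int]:
        return {tid: len(obs) for tid, obs in self.tracks.items()}


def segment_cells(images: ImagePair, params: SegmentationParams | None = None) -> list[ROI]:
    """Detect cells on the summed frame: smooth, Otsu, label, area-filter.

    Returns ROIs with centroids in µm. A constant (blank, noise-free) frame
    yields no ROIs; a frame with >1% saturated pixels triggers a warning.
    """
    params = params or SegmentationParams()
    total = images.ch475.astype(float) + images.ch395.astype(float)
    n_sat = int(np.count_nonzero((images.ch475 == 65535) | (images.ch395 == 65535)))
    if n_sat > 0.01 * total.size:
        warnings.warn(
            f"frame {images.frame}: {n_sat} saturated pixels (>1%)", stacklevel=2
        )
    if params.smooth_sd_px > 0:
        total = filters.gaussian(total, params.smooth_sd_px, preserve_range=True)
    if total.max() == total.min():
        return []
    thr = filters.threshold_otsu(total)
    labels = measure.label(total > thr, connectivity=2)
    px2 = images.pixel_size_um**2
    rois: list[ROI] = []
    for region in measure.regionprops(labels):
        area = region.area * px2
        if not (params.min_area_um2 <= area <= params.max_area_um2):
            continue
        cy, cx = region.centroid  # row, col in pixel-index space
        coords = region.coords
        rois.append(
            ROI(
                cell_id=len(rois),
                frame=images.frame,
                pixels=(coords[:, 0], coords[:, 1]),
                x_um=(cx + 0.5) * images.pixel_size_um,
                y_um=(cy + 0.5) * images.pixel_size_um,
                area_um2=area,
            )
        )
    return rois


def estimate_background(
    images: ImagePair, rois: list[ROI]
) -> tuple[float, float]:
    """Per-channel background: median over pixels belonging to no ROI."""
    mask = np.ones(images.ch475.shape, dtype=bool)
    for roi in rois:
        mask[roi.pixels] = False
    if not mask.any():
        raise ValueError("no background pixels left after masking ROIs")
    return (
        float(np.median(images.ch475[mask])),
        float(np.median(images.ch395[mask])),
    )


def measure_cell(
    roi: ROI,
    images: ImagePair,
    background: tuple[float, float],
    time_h: float = 0.0,
    params: SegmentationParams | None = None,
) -> CellObservation:
    """Background-corrected mean intensities and their ratio for one ROI."""
    params = params or SegmentationParams()
    rows, cols = roi.pixels
    shape = images.ch475.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("ROI pixels outside the image")
    i475 = float(images.ch475[rows, cols].mean()) - background[0]
    i395 = float(images.ch395[rows, cols].mean()) - background[1]
    if i475 <= 0 or i395 <= 0:
        flag, ratio = QCFlag.NEGATIVE_AFTER_CORRECTION, float("nan")
    elif i395 < params.low_signal_k * params.read_noise_sd:
        flag, ratio = QCFlag.LOW_SIGNAL, i475 / i395
    else:
        flag, ratio = QCFlag.OK, i475 / i395
    return CellObservation(
        cell_id=roi.cell_id,
        frame=roi.frame,
        time_h=time_h,
        x_um=roi.x_um,
        y_um=roi.y_um,
        i475_corr=i475,
        i395_corr=i395,
        ratio=ratio,
        qc_flag=flag,
    )


def quantify_frame(
    images: ImagePair,
    time_h: float = 0.0,
    params: SegmentationParams | None = None,
) -> list[CellObservation]:
    """Segment one frame and measure every detected cell."""
    params = params or SegmentationParams()
    rois = segment_cells(images, params)
    if not rois:
        return []
    background = estimate_background(images, rois)
    return [measure_cell(r, images, background, time_h, params) for r in rois]


def link_tracks(
    observations_by_frame: list[list[CellObservation]],
    link_radius_um: float = 2.0,
    max_gap: int = 2,
) -> TrackTable:
    """Greedy nearest-neighbour linking of per-frame observations into tracks.

    Within each new frame, candidate (track, observation) pairs closer than
    ``link_radius_um`` are matched in ascending distance order (ties by lower
    cell_id), each side at most once. Tracks not extended for more than
    ``max_gap`` frames are closed; unmatched observations open new tracks.
    Adequate for immobilised cells; not a motile-cell tracker.
    """
    table = TrackTable()
    next_id = 0
    # active track state: track_id -> (x, y, last_frame)
    active: dict[int, tuple[float, float, int]] = {}
    for obs_list in observations_by_frame:
        if not obs_list:
            continue
        frame = obs_list[0].frame
        active = {
            tid: st for tid, st in active.items() if frame - st[2] <= max_gap + 1
        }
        matched_obs: set[int] = set()
        matched_trk: set[int] = set()
        if active and obs_list:
            tids = sorted(active)
            tpos = np.array([[active[t][0], active[t][1]] for t in tids])
            opos = np.array([[o.x_um, o.y_um] for o in obs_list])
            dist = cdist(tpos, opos)
            cand = [
                (dist[a, b], obs_list[b].cell_id, a, b)
                for a in range(len(tids))
                for b in range(len(obs_list))
                if dist[a, b] <= link_radius_um
            ]
            for d, _, a, b in sorted(cand):
                if a in matched_trk or b in matched_obs:
                    continue
                tid = tids[a]
                obs = obs_list[b]
                obs.track_id = tid
                table.tracks[tid].append(obs)
                active[tid] = (obs.x_um, obs.y_um, frame)
                matched_trk.add(a)
                matched_obs.add(b)
        for b, obs in enumerate(obs_list):
            if b in matched_obs:
                continue
            obs.track_id = next_id
            table.tracks[next_id] = [obs]
            active[next_id] = (obs.x_um, obs.y_um, frame)
            next_id += 1
    return table


def observations_to_frame(observations: list[CellObservation]) -> pd.DataFrame:
    """Flatten observations into the pipeline's tabular dialect."""
    return pd.DataFrame(
        {
            "cell_id": [o.cell_id for o in observations],
            "track_id": [o.track_id for o in observations],
            "frame": [o.frame for o in observations],
            "time_h": [o.time_h for o in observations],
            "x_um": [o.x_um for o in observations],
            "y_um": [o.y_um for o in observations],
            "i475_corr": [o.i475_corr for o in observations],
            "i395_corr": [o.i395_corr for o in observations],
            "ratio": [o.ratio for o in observations],
            "ph": [o.ph for o in observations],
            "qc_flag": [o.qc_flag.value for o in observations],
        }
    )
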
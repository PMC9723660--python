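"""Cell segmentation, intensity measurement and track linking."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import microph as m
from microph.quantify import estimate_background

from conftest import render_uniform


def _pair(ch475, ch395, pixel_size=0.5):
    return m.ImagePair(
        np.asarray(ch475, dtype=np.uint16), np.asarray(ch395, dtype=np.uint16),
        frame=0, pixel_size_um=pixel_size,
    )


class TestSegmentCells:
    def test_well_separated_disks_found_with_subpixel_centroids(self, phys):
        cfg = m.SceneConfig(field_width_um=200, field_height_um=200, n_frames=1)
        x, y = np.meshgrid(np.arange(30.0, 200, 60), np.arange(30.0, 200, 60))
        lay = m.CellLayout(x.ravel(), y.ravel())  # 16 cells, 60 um apart
        _, _, img = render_uniform(cfg, phys, 6.5, layout=lay, noise=False)
        rois = m.segment_cells(img)
        assert len(rois) == len(lay)
        found = np.array([[r.x_um, r.y_um] for r in rois])
        truth = np.column_stack([lay.x_um, lay.y_um])
        assert cdist(truth, found).min(axis=1).max() < 0.5

    def test_blank_frame_yields_no_rois(self, phys):
        img = _pair(np.full((64, 64), 100), np.full((64, 64), 100))
        assert m.segment_cells(img) == []

    def test_subresolution_specks_filtered_by_min_area(self):
        im = np.full((64, 64), 100.0)
        im[32, 32] = 5000  # 0.25 um^2 at 0.5 um/px, below the 1 um^2 floor
        rois = m.segment_cells(
            _pair(im, im), m.SegmentationParams(smooth_sd_px=0)
        )
        assert rois == []

    def test_saturated_frame_warns(self):
        im = np.full((64, 64), 65535)
        im[:40] = 100
        with pytest.warns(UserWarning, match="saturated"):
            m.segment_cells(_pair(im, im))


class TestMeasureCell:
    def test_background_corrected_ratio_arithmetic(self):
        im475 = np.full((16, 16), 100.0)
        im395 = np.full((16, 16), 100.0)
        im475[4:8, 4:8] = 300
        im395[4:8, 4:8] = 500
        rows, cols = np.meshgrid(range(4, 8), range(4, 8), indexing="ij")
        roi = m.ROI(0, 0, (rows.ravel(), cols.ravel()), 3.0, 3.0, 4.0)
        obs = m.measure_cell(roi, _pair(im475, im395), (100.0, 100.0))
        assert obs.i475_corr == pytest.approx(200.0)
        assert obs.i395_corr == pytest.approx(400.0)
        assert obs.ratio == pytest.approx(0.5)
        assert obs.qc_flag is m.QCFlag.OK

    def test_negative_after_correction_flagged(self):
        im = np.full((16, 16), 90.0)
        roi = m.ROI(0, 0, (np.array([5]), np.array([5])), 2.75, 2.75, 0.25)
        obs = m.measure_cell(roi, _pair(im, im), (100.0, 100.0))
        assert obs.qc_flag is m.QCFlag.NEGATIVE_AFTER_CORRECTION
        assert np.isnan(obs.ratio)

    def test_noise_free_cell_at_ph74_measures_unbuffered_endpoint(
        self, small_scene, phys
    ):
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        _, _, img = render_uniform(small_scene, phys, 7.4, layout=lay, noise=False)
        obs = m.quantify_frame(img)
        assert obs[0].ratio == pytest.approx(0.45, abs=0.01)

    def test_roi_outside_image_rejected(self):
        im = np.full((16, 16), 100.0)
        roi = m.ROI(0, 0, (np.array([20]), np.array([5])), 2.75, 10.25, 0.25)
        with pytest.raises(ValueError, match="outside"):
            m.measure_cell(roi, _pair(im, im), (100.0, 100.0))

    def test_background_is_median_of_non_roi_pixels(self):
        im = np.full((32, 32), 100.0)
        im[10:12, 10:12] = 900
        pair = _pair(im, im)
        rois = m.segment_cells(pair, m.SegmentationParams(smooth_sd_px=0))
        assert estimate_background(pair, rois) == (100.0, 100.0)


def _obs(cell_id, frame, x, y):
    return m.CellObservation(
        cell_id=cell_id, frame=frame, time_h=float(frame), x_um=x, y_um=y,
        i475_corr=1.0, i395_corr=1.0, ratio=1.0,
    )


class TestLinkTracks:
    def test_static_centroids_give_one_full_track_per_cell(self):
        frames = [[_obs(i, f, 10.0 * i, 5.0) for i in range(4)] for f in range(6)]
        table = m.link_tracks(frames)
        assert len(table) == 4
        assert all(n == 6 for n in table.lengths().values())

    def test_small_jitter_preserves_tracks(self):
        rng = np.random.default_rng(0)
        frames = [
            [_obs(i, f, 10.0 * i + rng.uniform(-0.5, 0.5), 5.0 + rng.uniform(-0.5, 0.5))
             for i in range(4)]
            for f in range(6)
        ]
        table = m.link_tracks(frames)
        assert len(table) == 4
        assert all(n == 6 for n in table.lengths().values())

    def test_large_displacement_breaks_track(self):
        frames = [[_obs(0, f, 10.0 + (5.0 if f >= 3 else 0.0), 5.0)] for f in range(6)]
        table = m.link_tracks(frames, link_radius_um=2.0, max_gap=2)
        lengths = sorted(table.lengths().values())
        assert lengths == [3, 3]

    def test_gap_tolerance_bridges_missing_frames(self):
        frames = [[_obs(0, f, 10.0, 5.0)] if f != 2 else [] for f in range(5)]
        table = m.link_tracks(frames, max_gap=2)
        assert len(table) == 1
        assert list(table.lengths().values()) == [4]

    def test_every_observation_lands_in_exactly_one_track(self, phys):
        cfg = m.SceneConfig(field_width_um=150, field_height_um=150, n_frames=4, seed=9)
        field = m.generate_field(cfg, "uniform", {"ph": 6.0})
        lay = m.place_cells(cfg, seed=9)
        images = m.render_stack(field, lay, phys, cfg, seed=9)
        obs_by_frame = [m.quantify_frame(img, float(f)) for f, img in enumerate(images)]
        table = m.link_tracks(obs_by_frame)
        n_obs = sum(len(o) for o in obs_by_frame)
        assert sum(table.lengths().values()) == n_obs
        ids = [id(o) for track in table.tracks.values() for o in track]
        assert len(ids) == len(set(ids))


class TestRecovery:
    def test_planted_cells_recovered_and_tracked_at_default_snr(self, phys):
        # >=95% of planted cells must be segmented in every frame and linked
        cfg = m.SceneConfig(field_width_um=300, field_height_um=300, n_frames=5, seed=21)
        field = m.generate_field(cfg, "uniform", {"ph": 6.0})
        lay = m.place_cells(cfg, seed=21)
        images = m.render_stack(field, lay, phys, cfg, seed=21)
        obs_by_frame = [m.quantify_frame(img, float(f)) for f, img in enumerate(images)]
        table = m.link_tracks(obs_by_frame)
        full = [t for t in table.tracks.values() if len(t) == cfg.n_frames]
        truth = np.column_stack([lay.x_um, lay.y_um])
        starts = np.array([[t[0].x_um, t[0].y_um] for t in full])
        recovered = cdist(truth, starts).min(axis=1) < 2.5
        assert recovered.mean() >= 0.95

    def test_ratio_error_consistent_with_configured_noise(self, phys):
        # Monte-Carlo oracle: noise sd from paired noisy renders bounds the
        # error of noisy vs noise-free measurements of the same scene
        cfg = m.SceneConfig(field_width_um=200, field_height_um=200, n_frames=1, seed=5)
        field = m.generate_field(cfg, "uniform", {"ph": 5.5})
        lay = m.place_cells(cfg, seed=5)

        def ratios(seed, noise):
            img = m.render_frame(field, lay, phys, cfg, 0, seed=seed, noise=noise)
            obs = [o for o in m.quantify_frame(img) if o.qc_flag is m.QCFlag.OK]
            pos = np.array([[o.x_um, o.y_um] for o in obs])
            val = np.array([o.ratio for o in obs])
            return pos, val

        pos0, clean = ratios(0, noise=False)
        out = {}
        for s in (101, 102):
            pos, val = ratios(s, noise=True)
            match = cdist(pos0, pos).argmin(axis=1)
            out[s] = val[match]
        noise_sd = np.std(out[101] - out[102]) / np.sqrt(2)
        err = np.abs(out[101] - clean)
        assert err.mean() < 3 * noise_sd
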
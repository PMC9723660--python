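"""Synthetic scene generator: fields, layouts, rendering physics."""

import numpy as np
import pytest

import microph as m
from microph.scene import PH_MAX, PH_MIN

from conftest import render_uniform


class TestGenerateField:
    def test_uniform_is_constant_everywhere(self):
        cfg = m.SceneConfig(n_frames=3)
        f = m.generate_field(cfg, "uniform", {"ph": 6.9})
        assert np.all(f.values == 6.9)

    def test_ramp_means_are_linear_between_endpoints(self):
        cfg = m.SceneConfig(n_frames=49)
        f = m.generate_field(cfg, "ramp", {"ph_start": 6.9, "ph_end": 5.0})
        means = [f.frame_mean(i) for i in range(49)]
        assert means[0] == pytest.approx(6.9)
        assert means[48] == pytest.approx(5.0)
        np.testing.assert_allclose(means, np.linspace(6.9, 5.0, 49), atol=1e-12)

    def test_gradient_patch_amplitude_realised_across_length_scale(self):
        cfg = m.SceneConfig(n_frames=2)
        f = m.generate_field(
            cfg,
            "gradient_patch",
            {"baseline": 5.8, "amplitude": 1.4, "length_scale_um": 20.0,
             "anchors_x_um": [400.0], "onset_frame": 1},
        )
        assert np.all(f.values[0] == 5.8)  # flat before onset
        row = f.values[1][f.values.shape[1] // 2]
        # >98% of the step falls within +-10 um of the anchor
        lo = f.sample(1, np.array([390.0]), np.array([200.0]))[0]
        hi = f.sample(1, np.array([410.0]), np.array([200.0]))[0]
        assert lo - hi > 0.98 * 1.4
        assert row.min() >= 5.8 - 1.4 - 1e-9 and row.max() <= 5.8 + 1e-9

    def test_hyphal_front_halo_edge_advances_at_rate_plus_lead(self):
        # acidified (dpH > 0.05) leading edge at t equals rate*t + lead*rate
        cfg = m.SceneConfig(field_width_um=4000, field_height_um=100, n_frames=25)
        f = m.generate_field(
            cfg, "hyphal_front",
            {"baseline": 6.9, "depth": 1.9, "extension_rate_um_per_h": 100.0,
             "lead_time_h": 18.0, "source_x_um": 0.0},
        )
        x = (np.arange(f.values.shape[2]) + 0.5) * f.node_spacing_um
        for t in (0, 5, 10, 20):
            acid = 6.9 - f.values[t][0] > 0.05
            expected = min(100.0 * t + 1800.0, cfg.field_width_um)
            measured = x[acid].max()
            assert abs(measured - expected) <= f.node_spacing_um

    def test_grf_matches_requested_moments_and_stays_in_range(self):
        cfg = m.SceneConfig(n_frames=2)
        f = m.generate_field(
            cfg, "grf",
            {"mean_ph": 5.1, "sd_ph": 0.35, "correlation_length_um": 50.0, "seed": 3},
        )
        assert f.values[0].mean() == pytest.approx(5.1, abs=1e-6)
        assert f.values[0].std() == pytest.approx(0.35, abs=1e-6)
        assert np.array_equal(f.values[0], f.values[1])  # static field
        assert f.values.min() >= PH_MIN and f.values.max() <= PH_MAX

    def test_unknown_kind_rejected_and_out_of_range_clipped(self):
        cfg = m.SceneConfig(n_frames=1)
        with pytest.raises(ValueError, match="unknown field kind"):
            m.generate_field(cfg, "vortex", {})
        with pytest.warns(UserWarning, match="clipping"):
            f = m.generate_field(cfg, "uniform", {"ph": 2.0})
        assert np.all(f.values == PH_MIN)


class TestPlaceCells:
    def test_poisson_count_mean_matches_density_times_area(self):
        # 2200 / mm^2 * 0.32 mm^2 = 704 expected cells
        cfg = m.SceneConfig()
        counts = [len(m.place_cells(cfg, seed=s)) for s in range(200)]
        se = np.sqrt(704 / 200)
        assert abs(np.mean(counts) - 704) < 3 * se

    def test_zero_density_gives_empty_layout(self):
        cfg = m.SceneConfig(cell_density_per_mm2=0)
        assert len(m.place_cells(cfg, seed=1)) == 0

    def test_same_seed_reproduces_layout_exactly(self):
        cfg = m.SceneConfig()
        a, b = m.place_cells(cfg, seed=5), m.place_cells(cfg, seed=5)
        assert np.array_equal(a.x_um, b.x_um) and np.array_equal(a.y_um, b.y_um)

    def test_cells_inside_field_bounds(self):
        cfg = m.SceneConfig()
        lay = m.place_cells(cfg, seed=2)
        assert lay.x_um.min() >= 0 and lay.x_um.max() <= cfg.field_width_um
        assert lay.y_um.min() >= 0 and lay.y_um.max() <= cfg.field_height_um


class TestRenderFrame:
    def test_isolated_cell_at_ph5_measures_unbuffered_endpoint_ratio(
        self, small_scene, phys
    ):
        # R(5.0) on the unbuffered curve is 1.59
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        _, _, img = render_uniform(small_scene, phys, 5.0, layout=lay, noise=False)
        obs = m.quantify_frame(img)
        assert len(obs) == 1
        assert obs[0].ratio == pytest.approx(1.59, abs=0.01)

    def test_empty_layout_noise_free_renders_pure_background(self, small_scene, phys):
        lay = m.CellLayout(np.array([]), np.array([]))
        _, _, img = render_uniform(small_scene, phys, 6.9, layout=lay, noise=False)
        assert np.all(img.ch475 == phys.background_475)
        assert np.all(img.ch395 == phys.background_395)

    def test_ratio_invariant_to_total_signal_scale(self, small_scene):
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        ratios = []
        for a in (1500.0, 3000.0):
            p = m.Photophysics(total_signal=a)
            _, _, img = render_uniform(small_scene, p, 6.0, layout=lay, noise=False)
            ratios.append(m.quantify_frame(img)[0].ratio)
        assert ratios[0] == pytest.approx(ratios[1], abs=2e-3)

    def test_ratio_invariant_to_bleaching(self, phys):
        cfg = m.SceneConfig(field_width_um=100, field_height_um=100, n_frames=10, seed=7)
        bleached = m.Photophysics(bleach_per_frame=0.05)
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        field = m.generate_field(cfg, "uniform", {"ph": 6.0})
        r = []
        for ph_model in (phys, bleached):
            img = m.render_frame(field, lay, ph_model, cfg, frame=9, noise=False)
            r.append(m.quantify_frame(img)[0].ratio)
        assert r[0] == pytest.approx(r[1], abs=2e-3)

    def test_channel_monotonicity_in_ph(self, small_scene, phys):
        # acidification raises I475 and lowers I395 at fixed total signal
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        peaks = []
        for ph in (7.4, 6.0, 5.0):
            _, _, img = render_uniform(small_scene, phys, ph, layout=lay, noise=False)
            peaks.append((int(img.ch475.max()), int(img.ch395.max())))
        i475, i395 = zip(*peaks)
        assert i475[0] < i475[1] < i475[2]
        assert i395[0] > i395[1] > i395[2]

    def test_nonpositive_ratio_aborts(self, small_scene, phys):
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        field = m.generate_field(small_scene, "uniform", {"ph": 8.9})
        with pytest.raises(ValueError, match="non-positive ratio"):
            m.render_frame(field, lay, phys, small_scene, 0, noise=False)

    def test_rendering_is_deterministic_under_fixed_seed(self, small_scene, phys):
        field = m.generate_field(small_scene, "uniform", {"ph": 6.0})
        lay = m.place_cells(small_scene, seed=4)
        a = m.render_frame(field, lay, phys, small_scene, 0, seed=11)
        b = m.render_frame(field, lay, phys, small_scene, 0, seed=11)
        assert np.array_equal(a.ch475, b.ch475) and np.array_equal(a.ch395, b.ch395)


class TestRatioFidelity:
    @pytest.mark.parametrize("ph", [4.6, 5.0, 5.8, 6.9, 7.6])
    def test_noise_free_roundtrip_recovers_ph_within_hundredth(
        self, small_scene, phys, ph
    ):
        lay = m.CellLayout(np.array([50.0]), np.array([50.0]))
        _, _, img = render_uniform(small_scene, phys, ph, layout=lay, noise=False)
        obs = m.quantify_frame(img)
        measured = (obs[0].ratio - phys.beta) / phys.alpha
        assert measured == pytest.approx(ph, abs=0.01)


class TestSceneIO:
    def test_write_scene_roundtrip(self, tmp_path, small_scene, phys):
        field = m.generate_field(small_scene, "uniform", {"ph": 6.5})
        lay = m.place_cells(small_scene, seed=3)
        images = m.render_stack(field, lay, phys, small_scene, seed=3)
        from microph.scene import read_image_pair, write_scene

        write_scene(tmp_path, small_scene, field, lay, images)
        back = read_image_pair(
            tmp_path / "frame_000.tif", 0, small_scene.pixel_size_um
        )
        assert np.array_equal(back.ch475, images[0].ch475)
        assert np.array_equal(back.ch395, images[0].ch395)
        assert (tmp_path / "scene.json").exists()
        layout_lines = (tmp_path / "layout.csv").read_text().splitlines()
        assert len(layout_lines) == len(lay) + 1
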
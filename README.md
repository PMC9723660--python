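# microph

Microscale pH mapping from ratiometric whole-cell biosensor imaging.

Filamentous fungi acidify their surroundings (the *mycosphere*) through
organic-acid excretion, shaping microbial habitats at scales far below what
bulk pH measurements or planar optodes (>150 µm resolution) can resolve.
One way to see this is to immobilise thousands of bacterial reporter cells
expressing a pH-sensitive GFP variant (pHluorin2) in their periplasm on an
agarose pad, image them for two days at hourly intervals, and interpolate
the per-cell readouts into micrometre-scale pH maps. `microph` implements
that analysis chain end to end, together with a synthetic-scene generator
that provides ground-truth test data for every stage:

1. **Simulation** (`microph.scene`) — latent pH fields (uniform controls,
   acidification ramps, sigmoidal gradient fronts, Gaussian random fields,
   travelling hyphal fronts), Poisson cell layouts at ≈2200 cells/mm² on a
   0.4 × 0.8 mm field, and two-channel 16-bit frames with Poisson + read
   noise.
2. **Quantification** (`microph.quantify`) — Otsu segmentation of the summed
   channels, background-corrected per-cell intensities, the excitation
   ratio R = I₄₇₅/I₃₉₅, and nearest-neighbour track linking.
3. **Calibration** (`microph.calibrate`) — ordinary least squares of the
   per-level mean ratio on pH, R(pH) = α·pH + β with α < 0; inversion
   pH = (R − β)/α with range flagging; precision propagation
   σ_pH = σ_R/|α|.
4. **Mapping** (`microph.idw`) — inverse distance weighting,
   ẑ(s) = Σᵢ zᵢ d(s,sᵢ)⁻ᵖ / Σᵢ d(s,sᵢ)⁻ᵖ (p = 2, 12-nearest neighbours),
   on regular r × r µm grids, with leave-one-out cross-validation per
   candidate resolution (r ∈ {1,2,3,4,5} µm) and selection of the finest
   resolution with CV R² ≥ 0.79 and mean absolute prediction error < 4.5 %.
5. **Temporal analytics** (`microph.temporal`) — per-frame mean ± sd pH,
   maximum pH contrast within a distance window, gradient-persistence
   (Jaccard of top-decile gradient nodes), acidification-onset detection
   against a control series, and the zone-of-influence (lead time ×
   hyphal extension rate) and proton diffusion-time (t = x²/(g·D))
   estimates.
6. **Orchestration** (`microph.pipeline`, `microph.cli`) — one reproducible
   run with a YAML config, per-stage artifacts and a checksummed manifest.

## Worked example

Simulate a scene containing a planted 1.4-unit pH step with a 20 µm length
scale, recover it through the full image → map chain, and measure it:

```python
from microph import (
    SceneConfig, Photophysics, generate_field, place_cells, render_frame,
    quantify_frame, fit_calibration, build_map, gradient_metric,
    cross_validate_resolutions,
)
from microph.calibrate import apply_calibration, synthetic_calibration_points

cfg = SceneConfig(n_frames=1, seed=0)          # 0.8 x 0.4 mm, 2200 cells/mm^2
phys = Photophysics()                          # R(pH) = -0.475 pH + 3.965
field = generate_field(cfg, "gradient_patch",
                       {"baseline": 5.8, "amplitude": 1.4,
                        "length_scale_um": 20.0, "anchors_x_um": [400.0]})
layout = place_cells(cfg, seed=0)
image = render_frame(field, layout, phys, cfg, frame=0, seed=10_000)

observations = quantify_frame(image)
curve = fit_calibration(synthetic_calibration_points(seed=1))
apply_calibration(observations, curve)

report = cross_validate_resolutions(observations)
phmap = build_map(observations, report.selected_resolution_um)
grad = gradient_metric(phmap, window_um=20.0)
```

Output:

```
cells planted/measured: 714/667
calibration: slope=-0.4724, R^2=1.0000
  1 um: CV R^2=0.961, error=1.19%
  2 um: CV R^2=0.961, error=1.19%
  3 um: CV R^2=0.960, error=1.20%
  4 um: CV R^2=0.961, error=1.20%
  5 um: CV R^2=0.960, error=1.19%
selected resolution: 1 um
max pH contrast within 20 um: 1.32
```

714 cells were planted, 667 segmented and calibrated (cells that merge into
one blob or fall below the QC thresholds are excluded, not imputed). The
fitted calibration recovers the configured response line (α = −0.475) from
~300 noisy per-cell ratios at each of nine pH levels. Cross-validation
scores every candidate grid resolution; on this strongly structured scene
all resolutions predict held-out cells well, so the finest (1 µm) is
selected. The planted 1.4-unit contrast is read back from the map as 1.32 —
inverse-distance smoothing between cells ~10 µm apart slightly erodes the
extremes.

The same pipeline is available from the shell:

```
microph all --config examples/demo.yaml --out runs/demo --seed 0
```

which writes per-frame TIFFs, an observations CSV, the calibration curve,
the CV report, per-frame pH maps (CSV + PNG heatmaps), frame summaries and
a manifest with checksums.

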
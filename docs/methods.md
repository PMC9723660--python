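# Methods

## Sensor model and calibration

The reporter's readout is the ratio R = I₄₇₅/I₃₉₅ of background-corrected
510 nm emission intensities under 475 nm and 395 nm excitation. Over the
sensor's useful range (roughly pH 4.6–7.6 in unbuffered medium) the response
is treated as linear,

    R(pH) = α·pH + β,      α < 0,

and the package's default parameters are the two-point line through the
unbuffered endpoints R(7.4) = 0.45 and R(5.0) = 1.59, i.e. α = −0.475,
β = 3.965. Calibration fits ordinary least squares on the *per-level mean*
ratios with every pH level weighted equally — the natural model when each
level is an independent experiment summarised by its population mean — with
per-cell pooled regression available as a manual alternative. Inversion is
pH = (R − β)/α; values falling more than 0.2 pH units outside the fitted
range are flagged `out_of_calibration_range` and excluded from mapping
rather than clamped, because extrapolating a saturating fluorescent sensor
past its calibrated response is not defensible. Precision propagates
linearly, σ_pH = σ_R/|α|.

A caveat worth stating: single-cell studies of this sensor report ratio
scatter of ±0.01 near pH 7.4 translating to ±0.05 pH units, but ±0.10 near
pH 5.4 translating to ±0.15 pH units. Those pairs imply a locally varying
slope (≈0.2 and ≈0.67 ratio units per pH unit respectively), which a single
global line cannot reproduce — with α = −0.475 a ratio sd of 0.10 propagates
to 0.21 pH units, not 0.15. The linear model is retained because the
response is reported as linear to R² ≈ 0.99 over the full range; the
per-level sd table (`sd_by_level`) carries the empirical scatter so users
can propagate level-specific precision if they need it.

## Synthetic scenes

The generator emulates the reference experiment: a 0.8 × 0.4 mm observation
area sampled at 0.5 µm/pixel, 49 hourly frames, ~1 µm-radius cells placed by
a homogeneous Poisson process at 2200 cells/mm² (≈704 cells per field).
Five latent-field kinds cover the behaviours the analytics must recover:
uniform controls; spatially flat ramps (mean drifting linearly, default
6.9 → 5.0 over 48 h); static sigmoidal gradient patches; stationary
Gaussian random fields; and a travelling acidification front.

Field-kind specifics:

- **gradient_patch** uses a logistic step with scale = length_scale/10, so
  that >98 % of the configured amplitude is realised across the stated
  length scale. A shallower step would spread the amplitude beyond the
  window used to measure it and make the planted value unrecoverable by
  construction; the steep choice keeps "amplitude A over distance L" an
  operationally testable statement.
- **grf** draws white noise on the field grid, smooths it with a Gaussian
  kernel of sd `correlation_length_um` (autocorrelation exp(−d²/(4L²)),
  reaching 1/e at 2L) and renormalises each realisation to the requested
  point sd exactly. Defaults (mean 5.1, sd 0.35) are anchored to the
  late-stage heterogeneity the pipeline is meant to map: fields spanning
  roughly pH 4.4–5.8, read as a ±2σ interval.
- **hyphal_front** places the tip at source_x + rate·t and lets the
  acidification halo decay exponentially ahead of it with decay length
  λ = lead_time·rate / ln(depth/0.05), so the ΔpH > 0.05 contour leads the
  tip by exactly lead_time hours of travel — the zone-of-influence
  arithmetic (lead × rate) is then exact by construction.

Rendering gives each cell the pH at its centre (bilinear sample of the
latent grid), splits a pH-independent total amplitude A as
I₄₇₅ = A·R/(1+R), I₃₉₅ = A/(1+R) — so the pixelwise ratio equals R exactly
and segmentation cannot be brightness-biased by pH — blurs with a Gaussian
point spread (sd 0.5 µm), adds per-channel backgrounds, then Poisson shot
noise and Gaussian read noise, and quantises to 16 bits. Photobleaching is
a geometric per-frame decay applied to A only; the ratio is invariant to it
by construction, and tests assert exactly that. Defaults (A = 1500,
backgrounds 100, read noise 3) put the weaker channel near SNR 20,
yielding single-cell pH noise of ≈0.05 at mid-range pH. Absolute counts
and camera gain are free parameters: the simulator emulates a generic
sCMOS-class acquisition, not a specific instrument.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: optical aberrations and depth-dependent focus,
autofluorescence and hyphal shading, cell growth/division and reporter
expression drift, spatially correlated illumination error, and any real
coupling between fungal physiology and the pH field. Recovery results
certify the analysis chain, not the biology.

## Quantification

Cells are segmented on the *sum* of the two channels (Gaussian smooth,
sd 1 px; global Otsu threshold; 8-connected components; area filter
1–20 µm²). Background is the per-channel median of all non-ROI pixels —
robust at ~1.5 % areal cell coverage and reproducible, unlike a hand-drawn
background region. Intensities are background-corrected ROI means; the
ratio of means equals the ratio of integrated densities over a shared ROI,
and means are insensitive to ROI-area differences between channels. QC
flags (`negative_after_correction`, `low_signal`,
`out_of_calibration_range`) exclude cells from mapping; nothing is imputed.
Tracking is greedy nearest-neighbour linking (radius 2 µm, gap tolerance
2 frames), which is adequate for physically immobilised cells and
explicitly not a motile-cell tracker. Touching cells are not split by
watershed; at the default density ~3–4 % of cells merge pairwise and are
measured as one blob with a mid-point centroid.

## IDW mapping and resolution selection

Interpolation is inverse distance weighting with power p = 2 over the
k = 12 nearest observations, exact at data points (coincident targets
return the observation mean) and bounded by the data range. p = 2 is the
standard geostatistical default. The neighbourhood default deserves a
note: with *all* points as neighbours in 2D, the number of observations at
distance d grows as d while their weights fall as d⁻², so the far field
contributes a log-divergent share of the total weight and every estimate is
pulled toward the global mean. At realistic densities this measurably
degrades held-out accuracy (CV R² drops by ~0.08 on the reference
heterogeneous scenes), which is why the bounded 12-point neighbourhood —
the convention of mainstream GIS implementations — is the default and the
global neighbourhood (`k_nearest=None`) an option.

Cross-validation is leave-one-out with a resolution-dependent target: each
observation is predicted at the centre of the r × r µm grid cell containing
it, from all other observations. Plain LOO at the observation's own
location would score identically at every resolution; predicting at the
cell centre ties the score to the grid actually produced. This is one
consistent construction, documented as a choice, not the only possible
one. Reported metrics are CV R² (1 − SSE/SStot, undefined at zero
variance) and mean absolute percentage error. Selection takes the finest
candidate resolution with CV R² ≥ 0.79 and error < 4.5 %; if none passes,
the pipeline completes without maps and reports a per-resolution
diagnostic.

On the reference heterogeneous validation scene (stationary GRF,
correlation length 50 µm, field sd 0.35, per-cell pH noise sd 0.15,
~700 cells), LOO-CV at 3 µm measures R² ≈ 0.78 and error ≈ 2.8 %. The R²
ceiling here is set by the observation noise itself: the held-out value
carries variance σ_n² and the prediction ~σ_n²·Σw², so with SStot ≈ 0.145
the attainable R² is ≈0.80 even for a perfect field interpolant. Fields
with stronger structure (fronts, trends — as in the worked example) score
far higher because SStot grows while the noise floor does not. CV R² on a
stationary GRF should therefore be read as a conservative lower bound on
mapping quality.

## Temporal analytics

Frame summaries are the mean and sample sd of ok-flagged per-cell pH.
The gradient metric is the maximum |ΔpH| over all node pairs within a
window (default 20 µm) of centre distance; ties resolve to the first pair
in offset order then row-major node order, and the result is verified
against a brute-force all-pairs oracle in the tests. Gradient persistence
is the Jaccard overlap of the top decile of nodes ranked by local gradient
magnitude (max 8-neighbour |ΔpH|/distance) in consecutive frames: 1.0 for
frozen structure, ≈0.053 for unrelated maps, with ≥0.5 used as the working
notion of "temporally stable". Acidification onset is the first frame
whose mean drops more than k·σ (default k = 3) below the control
baseline, with σ the sd of the control's frame means — a deliberately
simple automated change-point rule standing in for formal per-frame
hypothesis testing.

Two back-of-envelope physical quantities round out the report. The
zone-of-influence width is lead_time × extension_rate (18 h × 100 µm/h =
1800 µm with the defaults). The proton diffusion time across a gradient is
t = x²/(g·D) with D = 9.3 × 10⁻⁵ cm²/s and g = 2 by default (the 1-D
mean-squared-displacement convention ⟨x²⟩ = 2Dt); for x = 20 µm this gives
0.0215 s. Published estimates of this quantity vary by severalfold
depending on the distance and geometry convention used — hence the exposed
`geometry_factor` — but every convention yields sub-second times, which is
the scientifically relevant point: persistent micro-gradients require
continuous proton production against diffusion.

## Numerical and reproducibility choices

Coordinates: origin at the top-left, x rightward, y downward, in µm; pixel
(i, j) covers [j·s, (j+1)·s) × [i·s, (i+1)·s), so a pixel's centre is at
(j+0.5)·s. Grid node (i, j) of an r-grid is centred at (x0+(j+0.5)·r,
y0+(i+0.5)·r). IDW distances below 10⁻⁹ µm trigger the exact-value policy.
All randomness flows through `numpy.random.default_rng` seeded from the
run seed (per-frame noise streams at seed + 10000 + frame), making
re-runs bit-identical; the pipeline manifest records the config hash and
per-file SHA-256 checksums, with the output directory excluded from the
hash so identical runs in different locations compare equal. Validation
scenes in the test-suite run at reduced field sizes and frame counts
(e.g. 300 × 300 µm, 3–6 frames) where the claim under test does not depend
on the full geometry; the end-to-end trajectory check runs the full
0.32 mm², 49-frame scene.

## Known limitations

- The linear sensor model ignores the sigmoidal saturation of the real
  fluorophore outside its calibrated range; out-of-range flags, not model
  extensions, handle this.
- Merged neighbouring cells are measured as single blobs; at much higher
  densities than 2200 mm⁻² a watershed split would be needed.
- IDW with a 12-point neighbourhood produces plateau artefacts around
  isolated observations and cannot extrapolate trends; kriging with a
  fitted variogram would, but is out of scope.
- The CV-selected resolution is a property of one reference frame (default:
  the last); strongly non-stationary series may warrant per-frame
  selection.
- Greedy nearest-neighbour tracking assumes immobilised cells and will
  fragment tracks under drift larger than the link radius.
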
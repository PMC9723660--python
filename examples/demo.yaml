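# Demo run: a static acidification front with a 1.4-unit step over 20 um,
# imaged twice, mapped at the CV-selected resolution.
scene:
  field_width_um: 800
  field_height_um: 400
  pixel_size_um: 0.5
  n_frames: 2
  frame_interval_h: 1
  cell_density_per_mm2: 2200
  cell_radius_um: 1.0
  seed: 0
field_kind: gradient_patch
field_params:
  baseline: 5.8
  amplitude: 1.4
  length_scale_um: 20.0
  anchors_x_um: [400.0]
window_um: 20.0
write_images: true
write_heatmaps: true
seed: 0
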
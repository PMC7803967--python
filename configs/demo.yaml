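# Desk-scale demo: every stage enabled, small sizes so the run finishes in
# well under a minute of CPU beyond the compositing stage.
seed: 7
out_dir: run_demo

synthetic:
  n_days: 4
  frame_interval_s: 120

compositor:
  n_images: 12
  frame_width: 512
  frame_height: 320
  paste_mode: mix
  n_poses: 3

detection_eval:
  iou_threshold: 0.5
  jitter_px: 2.0

behavior:
  score_threshold: 0.5

heatmap:
  beta: 0.01
  lambda: 0.1
  cell_size: 200

weather:
  n_days: 62
  noise_sd: 0.15
  intercept: false

featuremap:
  height: 16
  width: 16
  dim: 8
  out_dim: 3
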
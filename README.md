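# egretwatch

Domain-randomized scene compositing and post-detector behavioural analysis
for long-term camera monitoring of roosting egrets.

The package has two halves:

1. **Training-data synthesis** — procedural bird sprites and backgrounds are
   composited into annotated detection datasets with three paste operators
   (direct alpha copy, Gaussian-feathered blend, and gradient-domain
   Poisson blend), with on-screen size, lighting and 2D pose drawn from
   uniform randomization distributions (area fraction U(0.04%, 0.56%) of
   the frame, light factor U(0.6, 1.0)).
2. **Post-detector analysis** — everything downstream of a bird detector:
   AP/mAP evaluation with precision–recall curves (IoU matching), daily
   maximum counts and backward 1-h moving-average departure/return
   schedules with paired hypothesis tests, spatio-temporally smoothed
   occupancy heatmaps on a 200-px cell grid, detrended multivariable
   regression of log-counts on 12 weather factors, and row/null-space
   feature-map visualization.

Because the original monitoring video is not available, a first-class
`synthetic` module generates detection streams, weather tables and feature
stacks with *planted* ground truth (recorded in a JSON ledger), so every
estimator in the package has a parameter-recovery test surface.

## CLI

Each stage has a subcommand; `run` drives the whole pipeline from a YAML
config:

```bash
# 1000-image domain-randomized dataset with COCO annotations
egretwatch compose --n 1000 --seed 7 --paste mix --out dataset/

# score detections against ground truth (COCO JSON in, AP/mAP out)
egretwatch evaluate --gt dataset/annotations.json --dets dets.json --iou 0.5

# daily counts + departure/return schedules from a detection-record CSV
egretwatch behavior --records records.csv --out out/

# smoothed occupancy heatmap (spatial kernel beta, temporal constant lambda)
egretwatch heatmap --records records.csv --beta 0.01 --lambda 0.1 --out out/

# detrended count-weather regression report
egretwatch weather --weather weather.csv --out report.md

# row-space feature visualization overlay
egretwatch featuremap --stack stack.npz --image frame.png --out viz.png

# everything, from one config
egretwatch run --config configs/demo.yaml
```

Detection records are CSV with columns
`timestamp_iso,species,x_min,y_min,x_max,y_max,score` (0-based half-open
pixel boxes); weather tables are one row per day with the 12 factor
columns plus `count_all`; annotations are COCO JSON.

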
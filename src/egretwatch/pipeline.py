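"""End-to-end orchestration of the synthetic-to-report pipeline.

A single YAML/dict config drives the stages in dependency order:

    synthetic -> compositor -> detection_eval -> behavior -> heatmap
              -> weather -> featuremap

Each stage writes its artifacts into the run directory; a manifest records
the seed, the config hash and every stage's outputs so that a rerun with
the same config reproduces all deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import behavior, compositor, detection_eval, featuremap, heatmap, io, synthetic
from . import weather_stats

logger = logging.getLogger("egretwatch")

_STAGES = ("synthetic", "compositor", "detection_eval", "behavior", "heatmap",
           "weather", "featuremap")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "run",
    "stages": {name: True for name in _STAGES},
    "synthetic": {"n_days": 4, "frame_interval_s": 120},
    "compositor": {
        "n_images": 12, "frame_width": 512, "frame_height": 320,
        "paste_mode": "mix", "n_poses": 3,
    },
    "detection_eval": {"iou_threshold": 0.5, "jitter_px": 2.0},
    "behavior": {"score_threshold": 0.5},
    "heatmap": {"beta": heatmap.DEFAULT_BETA, "lambda": heatmap.DEFAULT_LAMBDA,
                "cell_size": 200},
    "weather": {"n_days": 62, "noise_sd": 0.15, "intercept": False},
    "featuremap": {"height": 16, "width": 16, "dim": 8, "out_dim": 3},
}


class ConfigError(ValueError):
    """Raised on unknown keys or malformed stage blocks."""


@dataclasses.dataclass
class RunConfig:
    seed: int
    out_dir: Path
    stages: dict
    params: dict

    @classmethod
    def from_dict(cls, raw: dict | None) -> "RunConfig":
        raw = dict(raw or {})
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, value in raw.items():
            if key not in merged:
                raise ConfigError(f"unknown config key: {key!r}")
            if isinstance(merged[key], dict):
                if not isinstance(value, dict):
                    raise ConfigError(f"config block {key!r} must be a mapping")
                for sub in value:
                    if sub not in merged[key]:
                        raise ConfigError(f"unknown config key: {key}.{sub}")
                merged[key].update(value)
            else:
                merged[key] = value
        stages = {k: bool(v) for k, v in merged["stages"].items()}
        params = {k: merged[k] for k in _STAGES if k in merged}
        return cls(int(merged["seed"]), Path(merged["out_dir"]), stages, params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sha256(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "stages": self.stages, "params": self.params},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; return (and write) the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_sha256": config.sha256(),
                      "stages": {}}
    records = weather_table = None
    ann_path = None

    try:
        if config.stages.get("synthetic", True):
            p = config.params["synthetic"]
            sim = synthetic.SimulationConfig(
                days=[synthetic.dt.date(2019, 9, 23) + synthetic.dt.timedelta(d)
                      for d in range(int(p["n_days"]))],
                frame_interval_s=int(p["frame_interval_s"]),
                rng_seed=config.seed,
            )
            records, ledger = synthetic.simulate_detections(sim)
            io.write_detections_csv(records, out / "detections.csv")
            io.write_ledger(ledger, out / "detections_ledger.json")
            manifest["stages"]["synthetic"] = ["detections.csv", "detections_ledger.json"]
            logger.info("synthetic: %d detection records", len(records))

        if config.stages.get("weather", True) or config.stages.get("synthetic", True):
            p = config.params["weather"]
            weather_table, wledger = synthetic.simulate_weather(
                n_days=int(p["n_days"]), seed=config.seed, noise_sd=float(p["noise_sd"])
            )
            io.write_weather_csv(weather_table, out / "weather.csv")
            io.write_ledger(wledger, out / "weather_ledger.json")
            manifest["stages"].setdefault("synthetic", []).extend(
                ["weather.csv", "weather_ledger.json"]
            )

        if config.stages.get("compositor", True):
            p = config.params["compositor"]
            sprites = synthetic.generate_sprites(config.seed, int(p["n_poses"]))
            backgrounds = [
                synthetic.generate_background(int(p["frame_width"]),
                                              int(p["frame_height"]), config.seed + k)
                for k in range(3)
            ]
            compositor.generate_dataset(
                out / "dataset", sprites, backgrounds,
                n_images=int(p["n_images"]), seed=config.seed,
                paste_mode=p["paste_mode"],
            )
            ann_path = out / "dataset" / "annotations.json"
            manifest["stages"]["compositor"] = ["dataset/annotations.json",
                                                "dataset/manifest.json"]
            logger.info("compositor: %d images", int(p["n_images"]))

        if config.stages.get("detection_eval", True) and ann_path is not None:
            p = config.params["detection_eval"]
            gts = detection_eval.load_coco_ground_truth(ann_path)
            rng = np.random.default_rng(config.seed + 1)
            names = {v: k for k, v in compositor.CATEGORY_IDS.items()}
            dets = {
                img: [
                    detection_eval.ScoredDetection(
                        lbl,
                        tuple(np.array(box) + rng.normal(0, p["jitter_px"], 4)),
                        float(rng.uniform(0.3, 1.0)),
                    )
                    for lbl, box in gts_img
                ]
                for img, gts_img in gts.items()
            }
            report = detection_eval.evaluate(dets, gts, float(p["iou_threshold"]))
            with open(out / "eval_report.json", "w") as fh:
                json.dump({"mAP": report["mAP"], "per_class_ap": report["per_class_ap"]},
                          fh, indent=2)
            rows = [
                {"class": cls, "recall": r, "precision": pr}
                for cls, curve in report["curves"].items()
                for r, pr in curve
            ]
            pd.DataFrame(rows).to_csv(out / "pr_curve.csv", index=False)
            manifest["stages"]["detection_eval"] = ["eval_report.json", "pr_curve.csv"]

        if config.stages.get("behavior", True) and records is not None:
            thr = float(config.params["behavior"]["score_threshold"])
            counts = pd.DataFrame(
                {
                    sp: behavior.daily_count(records, sp, thr)
                    for sp in synthetic.SPECIES
                }
            )
            counts["all"] = behavior.daily_count(records, None, thr)
            counts.to_csv(out / "daily_counts.csv", index_label="date")
            sched = {
                sp: behavior.daily_schedule(records, sp, thr)
                for sp in ("great_egret", "little_egret")
            }
            merged = sched["great_egret"].join(
                sched["little_egret"], lsuffix="_great", rsuffix="_little", how="inner"
            )
            merged.to_csv(out / "schedule.csv", index_label="date")
            if len(merged) >= 3:
                rep = behavior.schedule_tests(
                    merged["departure_great"], merged["departure_little"],
                    merged["return_great"], merged["return_little"],
                )
                with open(out / "schedule_tests.json", "w") as fh:
                    json.dump(dataclasses.asdict(rep), fh, indent=2)
            manifest["stages"]["behavior"] = ["daily_counts.csv", "schedule.csv"]

        if config.stages.get("heatmap", True) and records is not None:
            p = config.params["heatmap"]
            grid = heatmap.CellGrid(2139, 1281, int(p["cell_size"]))
            fields = {}
            for sp in ("great_egret", "little_egret"):
                stack, times = heatmap.counts_over_time(records, grid, sp)
                x = heatmap.spatial_smooth(stack, grid, float(p["beta"]))
                s = heatmap.temporal_smooth(x, float(p["lambda"]))
                fields[sp] = heatmap.period_heatmap(s, times)
            table = pd.concat(
                [heatmap.field_table(fields[sp], sp) for sp in fields],
                ignore_index=True,
            )
            table.to_csv(out / "heatmap_fields.csv", index=False)
            img = heatmap.render(fields["great_egret"], fields["little_egret"])
            Image.fromarray(img).save(out / "heatmap.png")
            manifest["stages"]["heatmap"] = ["heatmap_fields.csv", "heatmap.png"]

        if config.stages.get("weather", True) and weather_table is not None:
            p = config.params["weather"]
            result = weather_stats.analyze(weather_table, intercept=bool(p["intercept"]))
            md = weather_stats.report_markdown(result["regression"], result["ht3"])
            (out / "weather_report.md").write_text(md)
            manifest["stages"]["weather"] = ["weather_report.md"]

        if config.stages.get("featuremap", True):
            p = config.params["featuremap"]
            stack_data = synthetic.generate_feature_stack(
                config.seed, int(p["height"]), int(p["width"]),
                int(p["dim"]), int(p["out_dim"]),
            )
            stack = featuremap.FeatureStack(stack_data["x"], stack_data["A"])
            image = synthetic.generate_background(256, 256, config.seed)
            viz = featuremap.visualize(stack, image)
            Image.fromarray(viz["rendered"]).save(out / "featuremap.png")
            manifest["stages"]["featuremap"] = ["featuremap.png"]
    except Exception as exc:  # annotate failures with the stage context
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
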
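"""End-to-end pipeline: simulate → preprocess → split → train →
evaluate → activation maps, driven by one config and one seed.

All stage outputs (resolved config, manifest, split assignment, per-eye
predictions, metrics with confidence intervals, example CAM overlays)
land in the output directory, so a run is reproducible from the config
plus its seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import evaluate as ev
from .cam import compute_cams, save_overlays
from .errors import ConfigError
from .model import BackboneSpec, build_cam_model, build_prognostic_model
from .preprocess import grouped_split, preprocess_image, select_eligible
from .synthetic import SyntheticConfig, generate_cohort, write_cohort
from .train import SequenceDataset, TrainSchedule, train

__all__ = ["RunConfig", "run_pipeline", "load_dataset", "load_run_config"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    manifest: str | None = None      # existing manifest; None -> simulate
    image_root: str | None = None
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    # schedule tuned for from-scratch training of the small backbone on a
    # synthetic cohort; pass TrainSchedule() for the plain defaults
    schedule: TrainSchedule = field(default_factory=lambda: TrainSchedule(
        initial_lr=3e-3, max_epochs=60, min_epochs=60, batch_size=8,
        lr_patience=30))
    T: int = 3
    use_interval_scaling: bool = True
    target_side: int = 48
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    model_kind: str = "cam"          # "plain" (GRU of size 1) or "cam"
    n_cam_examples: int = 3
    bootstrap_B: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    kwargs = dict(raw)
    for key, cls in (("simulate", SyntheticConfig), ("backbone", BackboneSpec),
                     ("schedule", TrainSchedule)):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            for tup in ("visit_gap_range", "drusen_count_range",
                        "background_color"):
                if tup in sub and isinstance(sub[tup], list):
                    sub[tup] = tuple(sub[tup])
            kwargs[key] = cls(**sub)
    if "split_fractions" in kwargs:
        kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
    return RunConfig(**kwargs)


def load_dataset(eligible: pd.DataFrame, image_root: str | Path,
                 target_side: int, T: int) -> SequenceDataset:
    """Read, preprocess and stack the input images of eligible eyes.

    Uses the last ``T`` input visits of each eye (T <= 3 for the
    standard 3-input window).
    """
    root = Path(image_root)
    imgs, times, pred, labels, ids = [], [], [], [], []
    for _, row in eligible.iterrows():
        paths = row["input_paths"][-T:]
        ts = row["input_times"][-T:]
        seq = []
        for p in paths:
            arr = np.asarray(Image.open(root / p).convert("RGB"))
            seq.append(preprocess_image(arr, row["laterality"],
                                        target_side=target_side))
        imgs.append(np.stack(seq))
        times.append(ts)
        pred.append(row["prediction_time"])
        labels.append(row["outcome"])
        ids.append(row["eye_id"])
    return SequenceDataset(np.stack(imgs), np.asarray(times, float),
                           np.asarray(pred, float),
                           np.asarray(labels, int), ids)


def _metrics_block(labels, scores, B: int, seed: int) -> dict:
    roc = ev.roc_analysis(labels, scores)
    auc_ci = ev.delong_ci(labels, scores)
    sens_ci = ev.bootstrap_ci(labels, scores, "sens_at_youden", B=B, seed=seed)
    spec_ci = ev.bootstrap_ci(labels, scores, "spec_at_youden", B=B, seed=seed + 1)
    return {
        "auc": roc.auc,
        "auc_ci": [auc_ci.lower, auc_ci.upper],
        "youden_threshold": roc.youden_threshold,
        "sensitivity": roc.youden_sens,
        "sensitivity_ci": [sens_ci.lower, sens_ci.upper],
        "specificity": roc.youden_spec,
        "specificity_ci": [spec_ci.lower, spec_ci.upper],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the metrics dict written to metrics.json."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f)

    # -- data ----------------------------------------------------------
    if config.manifest is None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        sequences, manifest = generate_cohort(sim)
        write_cohort(sequences, manifest, out / "data")
        manifest_path = out / "data" / "manifest.csv"
        image_root = out / "data"
        manifest = pd.read_csv(manifest_path)
    else:
        manifest_path = Path(config.manifest)
        if not manifest_path.exists():
            raise ConfigError(f"manifest not found: {manifest_path}")
        manifest = pd.read_csv(manifest_path)
        image_root = Path(config.image_root or manifest_path.parent)

    eligible = select_eligible(manifest)
    split = grouped_split(eligible, config.split_fractions, seed=config.seed)
    with open(out / "splits.json", "w") as f:
        json.dump(split.assignment, f, indent=1)

    ds = load_dataset(eligible, image_root, config.target_side, config.T)
    idx = {name: [i for i, e in enumerate(ds.eye_ids)
                  if split.assignment[e] == name]
           for name in ("train", "val", "test")}
    train_set, val_set, test_set = (ds.subset(idx[k])
                                    for k in ("train", "val", "test"))

    # -- model ---------------------------------------------------------
    spec = dataclasses.replace(config.backbone, input_side=config.target_side)
    builder = build_cam_model if config.model_kind == "cam" \
        else build_prognostic_model
    model = builder(config.T, spec, config.use_interval_scaling,
                    seed=config.seed)
    schedule = dataclasses.replace(config.schedule, seed=config.seed)
    model, history = train(model, train_set, val_set, schedule)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    model.save(out / "model.npz")

    # -- evaluation ----------------------------------------------------
    scores = model.predict_proba(test_set.images, test_set.times,
                                 test_set.prediction_time)
    preds = pd.DataFrame({"eye_id": test_set.eye_ids,
                          "label": test_set.labels, "score": scores})
    preds.to_csv(out / "preds.csv", index=False)
    metrics = {"test": _metrics_block(test_set.labels, scores,
                                      config.bootstrap_B, config.seed),
               "n_test": int(len(test_set)),
               "n_train": int(len(train_set)),
               "elapsed_s": round(time.time() - t0, 1)}

    # -- example activation maps --------------------------------------
    if config.model_kind == "cam" and config.n_cam_examples:
        order = np.argsort(-scores)
        for i in order[:config.n_cam_examples]:
            cams = compute_cams(model, test_set.images[i], test_set.times[i],
                                float(test_set.prediction_time[i]),
                                eye_id=test_set.eye_ids[i])
            save_overlays(test_set.images[i], cams, out / "cams")

    with open(out / "metrics.json", "w") as f:
        json.dump(metrics, f, indent=1)
    return metrics
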
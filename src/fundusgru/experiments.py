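"""Reproducible study workflows on synthetic cohorts.

These functions bundle the package's stages into the studies reported in
the README: the longitudinal-versus-single-visit comparison (with and
without interval scaling), Monte-Carlo checks of the De Long interval
and test, and the activation-map localization rate.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from . import evaluate as ev
from .cam import compute_cams, lesion_localization
from .model import BackboneSpec, build_cam_model
from .pipeline import load_dataset
from .preprocess import grouped_split, preprocess_mask, select_eligible
from .synthetic import SyntheticConfig, generate_cohort, write_cohort
from .train import SequenceDataset, TrainSchedule, train

__all__ = [
    "ComparisonResult",
    "run_comparison_study",
    "delong_coverage_study",
    "delong_type1_study",
]

# schedule used by the synthetic comparison study (from-scratch training
# of the small batch-normalized backbone)
STUDY_SCHEDULE = TrainSchedule(initial_lr=3e-3, max_epochs=60, min_epochs=60,
                               batch_size=8, lr_patience=30)


@dataclass
class ComparisonResult:
    """Test-set results of the three study arms plus CAM localization."""

    labels: np.ndarray
    scores: dict[str, np.ndarray]          # arm -> test scores
    aucs: dict[str, float]
    metrics: dict[str, dict]               # arm -> auc/sens/spec with CIs
    delong_p: dict[str, float]             # scaled vs each ablation
    cam_localized: int
    cam_total: int
    n_eyes: int

    @property
    def cam_rate(self) -> float:
        return self.cam_localized / self.cam_total if self.cam_total else float("nan")


def _arm_metrics(labels, scores, B, seed) -> dict:
    roc = ev.roc_analysis(labels, scores)
    auc_ci = ev.delong_ci(labels, scores)
    sens = ev.bootstrap_ci(labels, scores, "sens_at_youden", B=B, seed=seed)
    spec = ev.bootstrap_ci(labels, scores, "spec_at_youden", B=B, seed=seed + 1)
    return {
        "auc": roc.auc, "auc_ci": (auc_ci.lower, auc_ci.upper),
        "sensitivity": roc.youden_sens,
        "sensitivity_ci": (sens.lower, sens.upper),
        "specificity": roc.youden_spec,
        "specificity_ci": (spec.lower, spec.upper),
        "youden_threshold": roc.youden_threshold,
    }


def run_comparison_study(seed: int, work_dir: str | Path,
                         n_patients: int = 280, target_side: int = 48,
                         schedule: TrainSchedule | None = None,
                         bootstrap_B: int = 2000) -> ComparisonResult:
    """Train the three arms on one synthetic cohort and evaluate them.

    Arms: the interval-scaled three-visit model, the same model without
    interval scaling, and a single-visit (last image) baseline.  All use
    the small CNN backbone with the CAM-capable head.  The activation
    maps of the scaled model are scored against the generator's known
    drusen masks on correctly classified progressing test eyes.
    """
    work_dir = Path(work_dir)
    schedule = schedule or STUDY_SCHEDULE
    sim = SyntheticConfig(n_patients=n_patients, seed=seed)
    sequences, manifest = generate_cohort(sim)
    write_cohort(sequences, manifest, work_dir)
    import pandas as pd

    manifest = pd.read_csv(work_dir / "manifest.csv")
    eligible = select_eligible(manifest)
    split = grouped_split(eligible, (0.6, 0.2, 0.2), seed=seed)

    spec = BackboneSpec(name="tiny_cnn", input_side=target_side, feature_len=64)
    arms = {"scaled_t3": (3, True), "unscaled_t3": (3, False),
            "single_visit": (1, False)}
    scores: dict[str, np.ndarray] = {}
    models = {}
    labels = None
    test_sets = {}
    for name, (T, scaling) in arms.items():
        ds = load_dataset(eligible, work_dir, target_side, T)
        idx = {k: [i for i, e in enumerate(ds.eye_ids)
                   if split.assignment[e] == k]
               for k in ("train", "val", "test")}
        tr, va, te = (ds.subset(idx[k]) for k in ("train", "val", "test"))
        model = build_cam_model(T, spec, use_interval_scaling=scaling,
                                seed=seed)
        model, _ = train(model, tr, va,
                         dataclasses.replace(schedule, seed=seed))
        scores[name] = model.predict_proba(te.images, te.times,
                                           te.prediction_time)
        models[name] = model
        test_sets[name] = te
        labels = te.labels

    aucs = {k: ev.auc(labels, s) for k, s in scores.items()}
    metrics = {k: _arm_metrics(labels, s, bootstrap_B, seed)
               for k, s in scores.items()}
    delong_p = {k: ev.delong_test(labels, scores["scaled_t3"], scores[k])[1]
                for k in ("unscaled_t3", "single_visit")}

    localized, total = _cam_localization(
        models["scaled_t3"], test_sets["scaled_t3"], sequences, sim,
        metrics["scaled_t3"]["youden_threshold"], target_side)

    return ComparisonResult(labels=labels, scores=scores, aucs=aucs,
                            metrics=metrics, delong_p=delong_p,
                            cam_localized=localized, cam_total=total,
                            n_eyes=len(eligible))


def _cam_localization(model, test_set: SequenceDataset, sequences, sim,
                      threshold: float, target_side: int) -> tuple[int, int]:
    """Count correctly classified progressing test eyes whose activation
    map is denser inside the known drusen region than outside."""
    seq_by_eye = {s.eye_id: s for s in sequences}
    scores = model.predict_proba(test_set.images, test_set.times,
                                 test_set.prediction_time)
    localized = total = 0
    for i, eye in enumerate(test_set.eye_ids):
        if test_set.labels[i] != 1 or scores[i] < threshold:
            continue
        seq = seq_by_eye[eye]
        mask96 = seq.lesion_masks[-1]
        img96 = (np.clip(seq.images[-1], 0, 1) * 255).round().astype(np.uint8)
        mask = preprocess_mask(mask96, img96, seq.laterality,
                               target_side=target_side, threshold=0.25)
        if not mask.any() or mask.all():
            continue
        cams = compute_cams(model, test_set.images[i], test_set.times[i],
                            float(test_set.prediction_time[i]), eye_id=eye)
        inside, outside = lesion_localization(cams[-1], mask)
        total += 1
        localized += inside > outside
    return localized, total


# -- Monte-Carlo checks of the De Long machinery ----------------------

def delong_coverage_study(seed: int, true_auc: float = 0.8, n: int = 1000,
                          replicates: int = 500, level: float = 0.95) -> float:
    """Empirical coverage of the De Long CI on equal-variance binormal
    scores with known AUC.  Returns the fraction of replicates whose CI
    contains the true value."""
    rng = np.random.default_rng(seed)
    mu = np.sqrt(2.0) * norm.ppf(true_auc)
    m = n // 2
    hits = 0
    for _ in range(replicates):
        y = np.r_[np.ones(m, int), np.zeros(n - m, int)]
        s = np.r_[rng.normal(mu, 1, m), rng.normal(0, 1, n - m)]
        ci = ev.delong_ci(y, s, level=level)
        hits += ci.lower <= true_auc <= ci.upper
    return hits / replicates


def delong_type1_study(seed: int, n: int = 200, replicates: int = 500,
                       alpha: float = 0.05) -> float:
    """Rejection rate of the paired De Long test when both score vectors
    are pure noise (the null of equal AUCs holds)."""
    rng = np.random.default_rng(seed)
    m = n // 2
    rejections = 0
    for _ in range(replicates):
        y = np.r_[np.ones(m, int), np.zeros(n - m, int)]
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        _, p = ev.delong_test(y, a, b)
        rejections += p < alpha
    return rejections / replicates
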
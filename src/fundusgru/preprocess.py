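"""Image preprocessing, cohort eligibility and grouped splitting.

Preprocessing follows a fully automated recipe: find the bounding box of
everything that differs from the background colour by more than a small
offset, crop to it, rescale 8-bit values to [0, 1], resize to a square
target, and mirror right eyes so the optic disc sits on the left in
every image.

Eligibility reduces a per-visit manifest to eyes with a window of four
consecutive visits whose first three are pre-advanced; the outcome is
whether the fourth visit shows advanced disease.  Splitting is grouped
by patient so fellow eyes never straddle the train/validation/test
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import BlankImageError, EmptyCohortError, SchemaError
from .synthetic import MANIFEST_COLUMNS

__all__ = [
    "CropBox",
    "SplitAssignment",
    "compute_crop",
    "preprocess_image",
    "select_eligible",
    "grouped_split",
    "estimate_background",
]

DEFAULT_OFFSET = 10.0 / 255.0


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned crop, half-open on the max side (numpy convention)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("crop box must have positive extent")

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_min:self.row_max, self.col_min:self.col_max]


def _to_unit_float(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def estimate_background(image: np.ndarray, patch: int = 5) -> np.ndarray:
    """Median colour of the four corner patches (fundus corners are dark)."""
    img = _to_unit_float(image)
    corners = np.concatenate([
        img[:patch, :patch].reshape(-1, 3),
        img[:patch, -patch:].reshape(-1, 3),
        img[-patch:, :patch].reshape(-1, 3),
        img[-patch:, -patch:].reshape(-1, 3),
    ])
    return np.median(corners, axis=0)


def compute_crop(image: np.ndarray, background_color=None,
                 offset: float = DEFAULT_OFFSET) -> CropBox:
    """Tightest box holding all pixels that differ from the background.

    A pixel counts as foreground when the maximum over channels of its
    absolute difference from the background colour exceeds ``offset``
    (both on the [0, 1] scale).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    img = _to_unit_float(image)
    bg = (estimate_background(image) if background_color is None
          else np.asarray(background_color, dtype=float))
    diff = np.abs(img - bg).max(axis=2)
    mask = diff > offset
    if not mask.any():
        raise BlankImageError(
            "no pixel differs from the background by more than the offset")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return CropBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def preprocess_image(image: np.ndarray, laterality: str, target_side: int = 256,
                     background_color=None, offset: float = DEFAULT_OFFSET
                     ) -> np.ndarray:
    """Crop, rescale to [0, 1], resize, and mirror right eyes.

    The input must be 8-bit RGB; passing float data raises, which guards
    against accidentally dividing by 255 twice.
    """
    if image.dtype != np.uint8:
        raise TypeError("preprocess_image expects 8-bit RGB input "
                        f"(got dtype {image.dtype})")
    if laterality not in ("left", "right"):
        raise ValueError("laterality must be 'left' or 'right'")
    box = compute_crop(image, background_color, offset)
    cropped = box.apply(image).astype(np.float64) / 255.0
    out = resize(cropped, (target_side, target_side), order=1,
                 preserve_range=True, anti_aliasing=True)
    if laterality == "right":
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def preprocess_mask(mask: np.ndarray, image: np.ndarray, laterality: str,
                    target_side: int = 256, background_color=None,
                    offset: float = DEFAULT_OFFSET,
                    threshold: float = 0.5) -> np.ndarray:
    """Carry a boolean pixel mask through the same crop/resize/flip as
    ``preprocess_image`` applied to ``image`` (used to map lesion
    annotations into model space).

    ``threshold`` binarizes the bilinearly resized mask; lower it when
    downsampling so small lesions survive the resize.
    """
    if mask.shape != image.shape[:2]:
        raise ValueError("mask must match the image's spatial shape")
    box = compute_crop(image, background_color, offset)
    m = resize(box.apply(mask).astype(float), (target_side, target_side),
               order=1, preserve_range=True)
    if laterality == "right":
        m = m[:, ::-1]
    return m > threshold


# -- eligibility -------------------------------------------------------

def select_eligible(manifest: pd.DataFrame, window: int = 4) -> pd.DataFrame:
    """Pick each eye's most recent eligible 4-visit window.

    An eye qualifies if it has ``window`` consecutive recorded visits
    whose first ``window - 1`` are not advanced-stage; among qualifying
    windows the most recent is used.  The outcome is 1 iff the final
    visit of the window is advanced.  Eyes without a qualifying window
    are dropped.

    Returns one row per eligible eye with columns ``patient_id, eye_id,
    laterality, input_times, input_paths, prediction_time, outcome``
    (times/paths are lists in visit order).
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest is missing columns: {missing}")
    out_rows = []
    for eye_id, grp in manifest.groupby("eye_id", sort=True):
        grp = grp.sort_values("visit_index")
        t = grp["time_months"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SchemaError(f"eye {eye_id}: visit times not strictly increasing")
        stages = grp["stage"].to_numpy()
        advanced = stages == "advanced"
        n = len(grp)
        chosen = None
        for start in range(n - window, -1, -1):  # most recent window first
            if not advanced[start:start + window - 1].any():
                chosen = start
                break
        if chosen is None:
            continue
        win = grp.iloc[chosen:chosen + window]
        out_rows.append({
            "patient_id": win["patient_id"].iloc[0],
            "eye_id": eye_id,
            "laterality": win["laterality"].iloc[0],
            "input_times": win["time_months"].iloc[:-1].tolist(),
            "input_paths": win["image_path"].iloc[:-1].tolist(),
            "prediction_time": float(win["time_months"].iloc[-1]),
            "outcome": int(win["stage"].iloc[-1] == "advanced"),
        })
    return pd.DataFrame(out_rows, columns=[
        "patient_id", "eye_id", "laterality", "input_times", "input_paths",
        "prediction_time", "outcome"])


# -- grouped splitting -------------------------------------------------

@dataclass(frozen=True)
class SplitAssignment:
    """eye_id -> split name; all eyes of a patient share one split."""

    assignment: dict[str, str]
    fractions: tuple[float, ...]
    seed: int

    def eyes(self, split: str) -> list[str]:
        return [e for e, s in self.assignment.items() if s == split]


def _largest_remainder(total: int, fractions) -> list[int]:
    raw = [total * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest frac part first
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def grouped_split(eyes: pd.DataFrame, fractions=(0.6, 0.2, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Patient-grouped train/val/test split.

    Patients are shuffled with ``seed`` and packed into the splits in
    order; eye-level targets come from largest-remainder apportionment of
    the requested fractions, and a patient goes to the current split
    while that leaves the eye count at least as close to target as
    stopping would.  Deterministic given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not len(eyes):
        raise EmptyCohortError("no eyes to split")
    eye_patient = eyes[["eye_id", "patient_id"]].drop_duplicates()
    patients = sorted(eye_patient["patient_id"].unique())
    if len(patients) < len(fractions):
        raise EmptyCohortError(
            f"need at least {len(fractions)} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    eyes_of = eye_patient.groupby("patient_id")["eye_id"].apply(list).to_dict()
    total_eyes = len(eye_patient)
    targets = _largest_remainder(total_eyes, fractions)
    names = ["train", "val", "test"][:len(fractions)]

    assignment: dict[str, str] = {}
    split_idx, count = 0, 0
    for k, pid in enumerate(order):
        n_eyes = len(eyes_of[pid])
        last_split = split_idx == len(names) - 1
        remaining_patients = len(order) - k
        if (not last_split
                and (count >= targets[split_idx]
                     or (count + n_eyes - targets[split_idx]
                         > targets[split_idx] - count))
                and remaining_patients >= len(names) - split_idx):
            split_idx += 1
            count = 0
        for e in eyes_of[pid]:
            assignment[e] = names[split_idx]
        count += n_eyes
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions),
                           seed=seed)
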
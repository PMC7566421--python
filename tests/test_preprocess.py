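"""Cropping, preprocessing, eligibility windows and grouped splits."""

import numpy as np
import pandas as pd
import pytest

from fundusgru import (BlankImageError, SchemaError, compute_crop,
                       grouped_split, preprocess_image, select_eligible)
from fundusgru.errors import EmptyCohortError

from conftest import make_manifest


# -- cropping ----------------------------------------------------------

def crop_bruteforce(img, bg, offset):
    """Per-pixel scan oracle for the crop box."""
    H, W, _ = img.shape
    rows, cols = [], []
    for r in range(H):
        for c in range(W):
            if np.abs(img[r, c] / 255.0 - bg).max() > offset:
                rows.append(r)
                cols.append(c)
    if not rows:
        return None
    return min(rows), max(rows) + 1, min(cols), max(cols) + 1


def test_crop_white_rectangle_on_black():
    img = np.zeros((100, 100, 3), np.uint8)
    img[10:30, 40:70] = 255
    box = compute_crop(img, background_color=(0, 0, 0), offset=10 / 255)
    assert (box.row_min, box.row_max, box.col_min, box.col_max) == (10, 30, 40, 70)


def test_crop_blank_and_full_frame():
    with pytest.raises(BlankImageError):
        compute_crop(np.zeros((20, 20, 3), np.uint8), background_color=(0, 0, 0))
    img = np.full((20, 30, 3), 200, np.uint8)
    box = compute_crop(img, background_color=(0, 0, 0))
    assert (box.row_min, box.row_max, box.col_min, box.col_max) == (0, 20, 0, 30)


def test_crop_matches_bruteforce_on_random_images():
    rng = np.random.default_rng(0)
    bg = np.zeros(3)
    for _ in range(100):
        img = (rng.random((50, 50, 3)) < 0.001).astype(np.uint8) * 255
        expected = crop_bruteforce(img, bg, 10 / 255)
        if expected is None:
            with pytest.raises(BlankImageError):
                compute_crop(img, background_color=bg)
            continue
        box = compute_crop(img, background_color=bg, offset=10 / 255)
        assert (box.row_min, box.row_max, box.col_min, box.col_max) == expected


def test_background_estimated_from_corners():
    img = np.full((40, 40, 3), 30, np.uint8)  # dark grey corners
    img[15:25, 15:25] = 220
    box = compute_crop(img)  # no explicit background
    assert (box.row_min, box.row_max, box.col_min, box.col_max) == (15, 25, 15, 25)


# -- preprocess_image --------------------------------------------------

def _fundus_like(side=80):
    rng = np.random.default_rng(4)
    img = np.zeros((side, side, 3), np.uint8)
    yy, xx = np.mgrid[0:side, 0:side]
    disc = ((yy - side / 2) ** 2 + (xx - side / 2) ** 2) < (0.4 * side) ** 2
    img[disc] = (rng.random((disc.sum(), 3)) * 200 + 30).astype(np.uint8)
    return img


def test_preprocess_output_contract():
    out = preprocess_image(_fundus_like(), "left", target_side=256)
    assert out.shape == (256, 256, 3)
    assert out.dtype == np.float32
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_preprocess_rejects_float_input():
    with pytest.raises(TypeError):
        preprocess_image(_fundus_like().astype(np.float64) / 255, "left")


def test_right_eye_flip_is_mirror_of_left():
    img = _fundus_like()
    left = preprocess_image(img, "left", target_side=64)
    right = preprocess_image(img, "right", target_side=64)
    np.testing.assert_array_equal(right, left[:, ::-1])
    # flipping twice recovers the unflipped rendering
    np.testing.assert_array_equal(right[:, ::-1], left)


def test_preprocess_deterministic():
    img = _fundus_like()
    a = preprocess_image(img, "left", target_side=64)
    b = preprocess_image(img, "left", target_side=64)
    np.testing.assert_array_equal(a, b)


# -- eligibility -------------------------------------------------------

def eligibility_oracle(stages, window=4):
    """Independent sliding-window scan, most recent window first."""
    n = len(stages)
    for start in range(n - window, -1, -1):
        if all(s != "a" for s in stages[start:start + window - 1]):
            return start, int(stages[start + window - 1] == "a")
    return None


def test_eligibility_hand_worked_cases():
    man = make_manifest({
        "A_L": list("eeea"),    # straightforward progressor
        "B_L": list("eeee"),    # non-progressor
        "C_L": list("eee"),     # too few visits -> dropped
        "D_L": list("eaeeee"),  # advanced mid-sequence; last-4 window works
        "E_L": list("eaeee"),   # no window with 3 clean leading visits
        "F_L": list("eeeee"),   # 5 visits -> most recent window
    })
    out = select_eligible(man).set_index("eye_id")
    assert set(out.index) == {"A_L", "B_L", "D_L", "F_L"}
    assert out.loc["A_L", "outcome"] == 1
    assert out.loc["B_L", "outcome"] == 0
    assert out.loc["D_L", "outcome"] == 0
    assert out.loc["D_L", "input_times"] == [20.0, 30.0, 40.0]  # visits 2-4
    assert out.loc["F_L", "input_times"] == [10.0, 20.0, 30.0]  # most recent
    assert out.loc["F_L", "prediction_time"] == 40.0


def test_eligibility_matches_oracle_on_random_sequences():
    rng = np.random.default_rng(2)
    stage_lists = {}
    expected = {}
    for i in range(200):
        n = int(rng.integers(3, 9))
        stages = ["a" if rng.random() < 0.25 else "e" for _ in range(n)]
        eye = f"R{i}_L"
        stage_lists[eye] = stages
        expected[eye] = eligibility_oracle(stages)
    out = select_eligible(make_manifest(stage_lists)).set_index("eye_id")
    for eye, exp in expected.items():
        if exp is None:
            assert eye not in out.index
        else:
            start, outcome = exp
            assert out.loc[eye, "outcome"] == outcome
            assert out.loc[eye, "input_times"][0] == start * 10.0


def test_eligibility_schema_errors():
    with pytest.raises(SchemaError):
        select_eligible(pd.DataFrame({"eye_id": ["x"]}))
    man = make_manifest({"A_L": list("eeee")}, times=[0, 10, 5, 20])
    with pytest.raises(SchemaError):
        select_eligible(man)


# -- grouped split -----------------------------------------------------

def _eyes_frame(n_single, n_double=0):
    rows = []
    for i in range(n_single):
        rows.append({"patient_id": f"S{i}", "eye_id": f"S{i}_L"})
    for i in range(n_double):
        rows.append({"patient_id": f"D{i}", "eye_id": f"D{i}_L"})
        rows.append({"patient_id": f"D{i}", "eye_id": f"D{i}_R"})
    return pd.DataFrame(rows)


def test_exact_fractions_for_single_eye_patients():
    split = grouped_split(_eyes_frame(10), (0.6, 0.2, 0.2), seed=0)
    sizes = {k: len(split.eyes(k)) for k in ("train", "val", "test")}
    assert sizes == {"train": 6, "val": 2, "test": 2}


def test_fellow_eyes_stay_together():
    eyes = _eyes_frame(20, n_double=10)
    for seed in range(5):
        split = grouped_split(eyes, seed=seed)
        df = eyes.assign(split=eyes.eye_id.map(split.assignment))
        per_patient = df.groupby("patient_id")["split"].nunique()
        assert (per_patient == 1).all()


def test_no_patient_leakage_across_splits():
    eyes = _eyes_frame(30, n_double=15)
    for seed in range(5):
        split = grouped_split(eyes, seed=seed)
        df = eyes.assign(split=eyes.eye_id.map(split.assignment))
        groups = df.groupby("split")["patient_id"].apply(set)
        names = list(groups.index)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not (groups[names[i]] & groups[names[j]])


def test_split_is_seeded_and_seed_sensitive():
    eyes = _eyes_frame(40, n_double=10)
    a = grouped_split(eyes, seed=1)
    b = grouped_split(eyes, seed=1)
    c = grouped_split(eyes, seed=2)
    assert a.assignment == b.assignment
    assert a.assignment != c.assignment
    for s in (a, c):
        assert sum(len(s.eyes(k)) for k in ("train", "val", "test")) == 60


def test_split_errors():
    with pytest.raises(EmptyCohortError):
        grouped_split(_eyes_frame(0))
    with pytest.raises(EmptyCohortError):
        grouped_split(_eyes_frame(2), (0.6, 0.2, 0.2))
    with pytest.raises(ValueError):
        grouped_split(_eyes_frame(10), (0.5, 0.2, 0.2))
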
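"""Synthetic cohort generator: determinism, progression signal,
structure, and validation."""

import dataclasses

import numpy as np
import pytest

from fundusgru import (ConfigError, EmptyCohortError, SyntheticConfig, auc,
                       crude_drusen_area, generate_cohort, generate_eye,
                       write_cohort)


CFG = SyntheticConfig(n_patients=4, seed=7)


def test_seeded_generation_is_bit_identical():
    a = generate_eye(CFG, "P1", "left", True, np.random.default_rng(7))
    b = generate_eye(CFG, "P1", "left", True, np.random.default_rng(7))
    assert a.times == b.times and a.outcome == b.outcome
    for x, y in zip(a.images, b.images):
        np.testing.assert_array_equal(x, y)


def test_progressor_drusen_area_grows_monotonically():
    cfg = dataclasses.replace(CFG, noise_sd=0.0)
    seq = generate_eye(cfg, "P1", "left", True, np.random.default_rng(7))
    areas = [crude_drusen_area(im) for im in seq.images]
    assert all(b >= a for a, b in zip(areas, areas[1:]))
    assert areas[-1] > areas[0]


def test_zero_growth_keeps_area_constant_up_to_noise():
    cfg = dataclasses.replace(CFG, drusen_growth_rate=0.0, noise_sd=0.0)
    seq = generate_eye(cfg, "P1", "left", True, np.random.default_rng(7))
    areas = [crude_drusen_area(im) for im in seq.images]
    assert max(areas) - min(areas) < 1e-9


def test_sequence_invariants():
    for progressor in (False, True):
        seq = generate_eye(CFG, "P2", "right", progressor,
                           np.random.default_rng(1))
        assert len(seq.images) == len(seq.times) == CFG.n_visits - 1
        assert np.all(np.diff(seq.times) > 0)
        assert seq.prediction_time > seq.times[-1]
        assert np.all(np.diff(seq.times) >= CFG.visit_gap_range[0])
        for im in seq.images:
            assert im.shape == (CFG.image_side, CFG.image_side, 3)
            assert im.min() >= 0 and im.max() <= 1
        assert seq.outcome == int(progressor)


def test_laterality_controls_disc_side():
    left = generate_eye(CFG, "P1", "left", False, np.random.default_rng(2))
    right = generate_eye(CFG, "P1", "right", False, np.random.default_rng(2))
    side = CFG.image_side
    half = side // 2
    # the optic disc is the brightest off-centre structure
    assert left.images[0][:, :half].sum() > left.images[0][:, half:].sum()
    assert right.images[0][:, half:].sum() > right.images[0][:, :half].sum()


def test_cohort_prevalence_within_binomial_bounds(small_cohort):
    cfg = SyntheticConfig(n_patients=150, seed=1)
    seqs, _ = generate_cohort(cfg)
    n = len(seqs)
    p = cfg.progression_prevalence
    frac = np.mean([s.outcome for s in seqs])
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * sd


def test_second_eye_probability_extremes():
    cfg0 = SyntheticConfig(n_patients=30, second_eye_prob=0.0, seed=2)
    assert len(generate_cohort(cfg0)[0]) == 30
    cfg1 = SyntheticConfig(n_patients=30, second_eye_prob=1.0, seed=2)
    seqs, manifest = generate_cohort(cfg1)
    assert len(seqs) == 60
    eyes_per_patient = manifest.groupby("patient_id")["eye_id"].nunique()
    assert (eyes_per_patient == 2).all()


def test_manifest_structure(small_cohort):
    _, seqs, manifest = small_cohort
    assert set(manifest.columns) == {
        "patient_id", "eye_id", "laterality", "visit_index", "time_months",
        "image_path", "stage"}
    # stage is pre-advanced at all input visits; advanced only at the
    # final visit of progressing eyes
    for seq in seqs:
        rows = manifest[manifest.eye_id == seq.eye_id].sort_values("visit_index")
        stages = rows["stage"].tolist()
        assert all(s == "early_intermediate" for s in stages[:-1])
        assert (stages[-1] == "advanced") == bool(seq.outcome)


def test_crude_area_statistic_separates_classes():
    """The simulated progression signal must be learnable: even a crude
    drusen-area statistic at the last input visit beats chance."""
    cfg = SyntheticConfig(n_patients=150, seed=5)
    seqs, _ = generate_cohort(cfg)
    y = np.array([s.outcome for s in seqs])
    a = np.array([crude_drusen_area(s.images[-1]) for s in seqs])
    assert auc(y, a) > 0.5


@pytest.mark.parametrize("field,value", [
    ("progression_prevalence", 0.0),
    ("progression_prevalence", 1.0),
    ("visit_gap_range", (0.2, 5.0)),
    ("visit_gap_range", (12.0, 6.0)),
    ("second_eye_prob", 1.5),
    ("n_visits", 1),
    ("drusen_count_range", (0, 4)),
    ("noise_sd", -0.1),
])
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(CFG, **{field: value})
    with pytest.raises(ConfigError) as exc:
        cfg.validate()
    assert field in str(exc.value)


def test_empty_cohort_errors():
    with pytest.raises(EmptyCohortError):
        generate_cohort(dataclasses.replace(CFG, n_patients=0))


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    import pandas as pd
    from PIL import Image

    _, seqs, manifest = small_cohort
    sub_ids = {s.eye_id for s in seqs[:3]}
    sub_seqs = [s for s in seqs if s.eye_id in sub_ids]
    sub_man = manifest[manifest.eye_id.isin(sub_ids)]
    path = write_cohort(sub_seqs, sub_man, tmp_path)
    df = pd.read_csv(path)
    assert len(df) == len(sub_man)
    first = df.iloc[0]
    img = np.asarray(Image.open(tmp_path / first["image_path"]))
    assert img.shape == (96, 96, 3) and img.dtype == np.uint8
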
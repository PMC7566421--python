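import numpy as np
import pandas as pd
import pytest

from fundusgru import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient synthetic cohort shared by read-only tests."""
    cfg = SyntheticConfig(n_patients=60, seed=3)
    sequences, manifest = generate_cohort(cfg)
    return cfg, sequences, manifest


def make_manifest(stage_lists, times=None):
    """Build a minimal manifest from per-eye stage sequences.

    ``stage_lists`` maps eye_id -> list of stages ('e' -> early,
    'a' -> advanced).  One patient per eye unless eye ids share a prefix
    before '_'.
    """
    rows = []
    for eye_id, stages in stage_lists.items():
        pid = eye_id.split("_")[0]
        for k, st in enumerate(stages):
            rows.append({
                "patient_id": pid,
                "eye_id": eye_id,
                "laterality": "left",
                "visit_index": k,
                "time_months": float(k * 10 if times is None else times[k]),
                "image_path": f"{eye_id}_v{k}.png",
                "stage": "advanced" if st == "a" else "early_intermediate",
            })
    return pd.DataFrame(rows)
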
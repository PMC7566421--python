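"""Preprocess images and build a leakage-free train/val/test split.

Cropping finds everything that differs from the background colour,
pixel values move to [0,1], images are resized square, and right eyes
are mirrored so the optic disc always sits on the left.  Splitting is
grouped by patient: fellow eyes never straddle the boundary.
"""

import numpy as np

from fundusgru import (SyntheticConfig, compute_crop, generate_cohort,
                       grouped_split, preprocess_image, select_eligible)

cfg = SyntheticConfig(n_patients=40, seed=0)
sequences, manifest = generate_cohort(cfg)

seq = sequences[0]
img8 = (seq.images[0] * 255).round().astype(np.uint8)
box = compute_crop(img8, background_color=cfg.background_color)
print(f"crop box rows [{box.row_min}, {box.row_max}) "
      f"cols [{box.col_min}, {box.col_max}) on a {img8.shape[0]}px frame")

out = preprocess_image(img8, seq.laterality, target_side=256,
                       background_color=cfg.background_color)
print(f"preprocessed: shape {out.shape}, range "
      f"[{out.min():.3f}, {out.max():.3f}] (laterality {seq.laterality})")

eligible = select_eligible(manifest)
print(f"\n{len(eligible)} eligible eyes "
      f"({int(eligible.outcome.sum())} progressing)")

split = grouped_split(eligible, (0.6, 0.2, 0.2), seed=0)
sizes = {k: len(split.eyes(k)) for k in ("train", "val", "test")}
print(f"split sizes: {sizes}")
leak = eligible.assign(split=eligible.eye_id.map(split.assignment)) \
    .groupby("patient_id")["split"].nunique()
print(f"patients spanning more than one split: {(leak > 1).sum()} "
      "(must be 0 — fellow eyes share information)")
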
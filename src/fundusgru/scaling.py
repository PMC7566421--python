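"""Interval scaling for unevenly spaced visit sequences.

Each input visit at time t_i receives the weight

    w_i = 1 / (t_pred - t_i),

where t_pred is the time at which the outcome is to be predicted.  Later
visits are closer to t_pred, so they receive strictly larger weights:
the prediction leans more on recent images.  The weights are a
deterministic function of the visit times — nothing is learned — and
they are applied by multiplying each visit's feature vector by its
weight.  No normalisation is applied by default (``normalize`` exists
for ablation experiments).

The formula is unit-dependent; this package uses months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntervalWeights", "interval_weights", "apply_scaling"]


@dataclass(frozen=True)
class IntervalWeights:
    """Per-visit scalars w_i = 1/(t_pred - t_i), in visit order."""

    weights: np.ndarray
    prediction_time: float

    def __len__(self) -> int:
        return len(self.weights)


def interval_weights(times, prediction_time: float) -> IntervalWeights:
    """Compute w_i = 1/(prediction_time - t_i) for every visit time.

    Raises ``ValueError`` if any visit time is at or past the prediction
    time (the gap must be strictly positive for the weight to be finite).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    gaps = float(prediction_time) - t
    if np.any(gaps <= 0):
        bad = t[gaps <= 0][0]
        raise ValueError(
            f"visit time {bad} is not strictly before prediction_time "
            f"{prediction_time}; interval weight undefined")
    return IntervalWeights(weights=1.0 / gaps, prediction_time=float(prediction_time))


def apply_scaling(features: np.ndarray, weights: IntervalWeights,
                  normalize: bool = False) -> np.ndarray:
    """Multiply row i of a T×F feature matrix by weight i.

    With ``normalize=True`` the weights are first divided by their sum
    (an ablation option; the default matches the plain formula).
    """
    feats = np.asarray(features)
    w = np.asarray(weights.weights, dtype=feats.dtype if feats.dtype.kind == "f"
                   else float)
    if feats.ndim != 2:
        raise ValueError("features must be a 2-D (visits x features) matrix")
    if feats.shape[0] != len(w):
        raise ValueError(
            f"feature matrix has {feats.shape[0]} rows but {len(w)} weights")
    if normalize:
        w = w / w.sum()
    return feats * w[:, None]
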
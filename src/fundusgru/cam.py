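"""Class activation maps, one per visit, for qualitative inspection.

The default recipe is the classic linear one: the final spatial feature
maps of each visit are combined with the effective weights linking the
pooled features to the positive logit, rectified, bilinearly upsampled
to the input size and min-max normalized.  A gradient-based variant
(``method="grad-cam"``) weights each channel by the spatially averaged
gradient of the logit instead, and works for any head.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .errors import FundusGruError
from .model import PrognosticModel

__all__ = ["ActivationMap", "compute_cams", "overlay_cam", "save_overlays"]


@dataclass(frozen=True)
class ActivationMap:
    """H×W map in [0, 1] for one visit of one eye."""

    values: np.ndarray
    time_index: int
    eye_id: str = ""

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("activation map values must lie in [0, 1]")


def _normalize(cam: np.ndarray) -> np.ndarray:
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:  # constant map (e.g. constant input) -> all zeros
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def compute_cams(cam_model: PrognosticModel, images: np.ndarray,
                 times, prediction_time: float, eye_id: str = "",
                 method: str = "cam") -> list[ActivationMap]:
    """Per-visit activation maps for one eye.

    ``images`` is (T, side, side, 3) preprocessed to [0, 1].  Returns T
    maps at image resolution.  ``method="cam"`` requires the CAM-capable
    model (dense layer after the GRU); ``method="grad-cam"`` works for
    the plain head too.
    """
    if method not in ("cam", "grad-cam"):
        raise ValueError(f"unknown CAM method {method!r}")
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError("expected (T, side, side, 3) images for one eye")
    if method == "cam" and not cam_model.has_cam_head:
        raise FundusGruError(
            "model has no dense layer after the GRU; build it with "
            "build_cam_model or use method='grad-cam'")
    T = cam_model.T
    side = images.shape[1]
    z, maps, w = cam_model.logits(images[None], np.asarray(times)[None],
                                  np.asarray([prediction_time]),
                                  keep_maps=True)
    if method == "grad-cam":
        z.backward()
    weights = None if method == "grad-cam" else cam_model.effective_class_weights()
    out = []
    for t in range(T):
        fmap = maps[t].data[0]  # (h, w, F)
        if method == "cam":
            cam = fmap @ weights
        else:
            g = maps[t].grad[0]  # d logit / d map
            cam = fmap @ g.mean(axis=(0, 1))
        # the recurrent head is a 1-D bottleneck, so the linear path to
        # the logit is defined only up to a global sign; rectify the
        # dominant-sign component rather than blindly keeping positives
        if -cam.clip(max=0).sum() > cam.clip(min=0).sum():
            cam = -cam
        cam = np.maximum(cam, 0.0)
        cam = resize(cam, (side, side), order=1, preserve_range=True)
        out.append(ActivationMap(values=_normalize(cam), time_index=t,
                                 eye_id=eye_id))
    return out


def lesion_localization(amap: ActivationMap, lesion_mask: np.ndarray
                        ) -> tuple[float, float]:
    """Mean activation inside vs outside a lesion mask.

    Returns ``(inside, outside)``; a map that attends to the lesion has
    inside > outside.  Raises if the mask is degenerate (all or none).
    """
    mask = np.asarray(lesion_mask, bool)
    if mask.shape != amap.values.shape:
        raise ValueError("mask and activation map shapes differ")
    if mask.all() or not mask.any():
        raise ValueError("lesion mask must be a proper subset of the image")
    return float(amap.values[mask].mean()), float(amap.values[~mask].mean())


def overlay_cam(image: np.ndarray, amap: ActivationMap,
                alpha: float = 0.4, cmap: str = "jet") -> np.ndarray:
    """Blend a heatmap over the fundus image; returns an RGB [0,1] array."""
    import matplotlib

    heat = matplotlib.colormaps[cmap](amap.values)[..., :3]
    return np.clip((1 - alpha) * image + alpha * heat, 0, 1)


def save_overlays(image_seq: np.ndarray, cams: list[ActivationMap],
                  out_dir: str | Path, prefix: str = "cam",
                  alpha: float = 0.4) -> list[Path]:
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, amap in zip(image_seq, cams):
        rgb = (overlay_cam(img, amap, alpha=alpha) * 255).round().astype(np.uint8)
        p = out_dir / f"{prefix}_{amap.eye_id}_t{amap.time_index}.png"
        Image.fromarray(rgb).save(p)
        paths.append(p)
    return paths
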
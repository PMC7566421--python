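"""Synthetic longitudinal fundus-like image cohorts.

Emulates the structure of a longitudinal colour-fundus study of
age-related macular degeneration: per-eye sequences of four visits at
uneven times, early/intermediate disease (drusen) at the first three
visits, and a binary progression outcome at the fourth.  Progressing
eyes carry drusen whose total area grows between visits; non-progressing
eyes keep a stable drusen load.  The rendering is deliberately toy —
a circular fundus field, an optic-disc blob on the nasal side and
Gaussian-profile drusen — but the progression signal is real, so every
downstream stage (preprocessing, training, evaluation, activation maps)
can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, EmptyCohortError

__all__ = [
    "SyntheticConfig",
    "VisitSequence",
    "generate_eye",
    "generate_cohort",
    "write_cohort",
    "crude_drusen_area",
]

MANIFEST_COLUMNS = [
    "patient_id", "eye_id", "laterality", "visit_index",
    "time_months", "image_path", "stage",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the simulator.

    Times are in months.  Visit gaps are drawn independently per interval
    (uniform on ``visit_gap_range``), so sequences are uneven by
    construction.  ``drusen_growth_rate`` is the relative drusen-area
    increase per month for progressing eyes; the defaults are calibrated
    so that the total drusen area at the last input visit is an
    informative but imperfect marker of progression.
    """

    n_patients: int = 100
    second_eye_prob: float = 0.4
    n_visits: int = 4
    image_side: int = 96
    visit_gap_range: tuple[float, float] = (6.0, 12.0)
    progression_prevalence: float = 0.092
    drusen_count_range: tuple[int, int] = (2, 12)
    drusen_growth_rate: float = 0.06
    noise_sd: float = 0.02
    background_color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not (0.0 <= self.second_eye_prob <= 1.0):
            raise ConfigError("second_eye_prob must lie in [0, 1]")
        if self.n_visits < 2:
            raise ConfigError("n_visits must be >= 2")
        if self.image_side < 16:
            raise ConfigError("image_side must be >= 16 pixels")
        lo, hi = self.visit_gap_range
        if lo < 1.0 or hi < lo:
            raise ConfigError(
                "visit_gap_range must satisfy 1 <= min <= max "
                "(a minimum one-month gap keeps interval weights finite)")
        if not (0.0 < self.progression_prevalence < 1.0):
            raise ConfigError("progression_prevalence must lie in (0, 1)")
        clo, chi = self.drusen_count_range
        if clo < 1 or chi < clo:
            raise ConfigError("drusen_count_range must satisfy 1 <= min <= max")
        if self.drusen_growth_rate < 0:
            raise ConfigError("drusen_growth_rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class VisitSequence:
    """One eye's ordered input images plus the prediction target.

    ``images`` and ``times`` cover the input visits only; the outcome is
    observed at ``prediction_time``.  ``outcome_image`` is the rendering
    of the outcome visit (used when writing a full manifest) and
    ``lesion_masks`` mark drusen pixels per input visit, for localization
    checks against activation maps.
    """

    patient_id: str
    eye_id: str
    laterality: str
    images: list[np.ndarray]
    times: list[float]
    prediction_time: float
    outcome: int
    outcome_image: np.ndarray | None = None
    lesion_masks: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.images) != len(self.times):
            raise ValueError("images and times must have equal length")
        t = np.asarray(self.times, float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("visit times must be strictly increasing")
        if len(t) and self.prediction_time <= t[-1]:
            raise ValueError("prediction_time must exceed the last visit time")
        for im in self.images:
            if im.min() < 0 or im.max() > 1:
                raise ValueError("pixel values must lie in [0, 1]")


# -- rendering ---------------------------------------------------------

_FUNDUS_RGB = np.array([0.72, 0.33, 0.10])
_DISC_RGB = np.array([0.98, 0.85, 0.55])
_DRUSEN_RGB = np.array([0.95, 0.88, 0.50])


def _fundus_canvas(side: int, background, laterality: str, tint: np.ndarray):
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cy = cx = (side - 1) / 2.0
    r = 0.48 * side
    fundus = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
    img = np.empty((side, side, 3))
    img[:] = np.asarray(background, float)
    img[fundus] = np.clip(_FUNDUS_RGB * tint, 0, 1)
    # optic disc on the nasal side: left half for left eyes, right for right
    dx = 0.22 * side if laterality == "left" else 0.78 * side
    disc = np.exp(-(((yy - cy) ** 2) / (2 * (0.055 * side) ** 2)
                    + ((xx - dx) ** 2) / (2 * (0.045 * side) ** 2)))
    img[fundus] += (disc[..., None] * _DISC_RGB)[fundus]
    return img, fundus, (cy, dx)


def _draw_drusen(img, fundus, centers, sigmas, angles, amps, scale):
    side = img.shape[0]
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    total = np.zeros((side, side))
    for (cy, cx), (sa, sb), th, amp in zip(centers, sigmas, angles, amps):
        sa, sb = sa * scale, sb * scale
        ca, sn = np.cos(th), np.sin(th)
        u = (xx - cx) * ca + (yy - cy) * sn
        v = -(xx - cx) * sn + (yy - cy) * ca
        total += amp * np.exp(-(u * u / (2 * sa * sa) + v * v / (2 * sb * sb)))
    total = np.clip(total, 0, 1) * fundus
    img = img + total[..., None] * _DRUSEN_RGB
    return img, total > 0.25


def _draw_atrophy(img, fundus, side, rng):
    # advanced stage: a large pale geographic-atrophy-like patch near the macula
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cy = (side - 1) / 2.0 + rng.uniform(-0.05, 0.05) * side
    cx = (side - 1) / 2.0 + rng.uniform(-0.08, 0.08) * side
    s = rng.uniform(0.10, 0.16) * side
    patch = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    return img + (patch[..., None] * np.array([0.9, 0.85, 0.7])) * fundus[..., None]


def generate_eye(config: SyntheticConfig, patient_id: str, laterality: str,
                 progressor: bool, rng: np.random.Generator) -> VisitSequence:
    """Render one eye's visit sequence.

    The deterministic component of total drusen area is non-decreasing in
    time for progressors (multiplied by ``1 + rate * months`` elapsed) and
    constant for non-progressors; pixel noise is added on top.
    """
    config.validate()
    if laterality not in ("left", "right"):
        raise ConfigError("laterality must be 'left' or 'right'")
    side = config.image_side
    eye_id = f"{patient_id}_{'L' if laterality == 'left' else 'R'}"

    gaps = rng.uniform(*config.visit_gap_range, size=config.n_visits - 1)
    times = np.concatenate([[0.0], np.cumsum(gaps)])

    tint = rng.uniform(0.88, 1.12, size=3)
    n_drusen = int(rng.integers(config.drusen_count_range[0],
                                config.drusen_count_range[1] + 1))
    cy = cx = (side - 1) / 2.0
    # drusen cluster in the central (macular) region, clear of the disc
    ang = rng.uniform(0, 2 * np.pi, n_drusen)
    rad = rng.uniform(0.03, 0.28, n_drusen) * side
    centers = [(cy + r * np.sin(a), cx + r * np.cos(a) * 0.6) for r, a in zip(rad, ang)]
    sigmas = [(rng.uniform(0.015, 0.032) * side, rng.uniform(0.015, 0.032) * side)
              for _ in range(n_drusen)]
    angles = rng.uniform(0, np.pi, n_drusen)
    amps = rng.uniform(0.45, 0.85, n_drusen)

    images, masks = [], []
    for t in times[:-1]:
        scale = np.sqrt(1.0 + config.drusen_growth_rate * t) if progressor else 1.0
        img, fundus, _ = _fundus_canvas(side, config.background_color, laterality, tint)
        img, mask = _draw_drusen(img, fundus, centers, sigmas, angles, amps, scale)
        img = img + rng.normal(0, config.noise_sd, img.shape)
        images.append(np.clip(img, 0, 1).astype(np.float32))
        masks.append(mask)

    img, fundus, _ = _fundus_canvas(side, config.background_color, laterality, tint)
    scale = (np.sqrt(1.0 + config.drusen_growth_rate * times[-1])
             if progressor else 1.0)
    img, _ = _draw_drusen(img, fundus, centers, sigmas, angles, amps, scale)
    if progressor:
        img = _draw_atrophy(img, fundus, side, rng)
    img = np.clip(img + rng.normal(0, config.noise_sd, img.shape), 0, 1)

    seq = VisitSequence(
        patient_id=patient_id,
        eye_id=eye_id,
        laterality=laterality,
        images=images,
        times=[float(t) for t in times[:-1]],
        prediction_time=float(times[-1]),
        outcome=int(progressor),
        outcome_image=img.astype(np.float32),
        lesion_masks=masks,
    )
    seq.validate()
    return seq


def crude_drusen_area(image: np.ndarray) -> float:
    """Fraction of pixels that look drusen-like (bright, yellowish).

    A deliberately crude burden statistic used to verify that the
    simulated progression signal is learnable at all.
    """
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    return float(np.mean((g > 0.55) & (r > 0.75) & (b < 0.75)))


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[list[VisitSequence], pd.DataFrame]:
    """Generate a cohort of eyes plus a per-visit manifest table.

    Each eye progresses with probability ``progression_prevalence``
    (independent Bernoulli draws, including between fellow eyes); a
    patient contributes a second eye with probability ``second_eye_prob``.
    Manifest stage labels are early/intermediate at every input visit and
    'advanced' at the final visit iff the eye progressed.
    """
    config.validate()
    if config.n_patients == 0:
        raise EmptyCohortError("cohort generation requires n_patients >= 1")
    rng = np.random.default_rng(config.seed)
    sequences: list[VisitSequence] = []
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        first = "left" if rng.random() < 0.5 else "right"
        lateralities = [first]
        if rng.random() < config.second_eye_prob:
            lateralities.append("right" if first == "left" else "left")
        for lat in lateralities:
            progressor = bool(rng.random() < config.progression_prevalence)
            seq = generate_eye(config, pid, lat, progressor, rng)
            sequences.append(seq)
            all_times = seq.times + [seq.prediction_time]
            for k, t in enumerate(all_times):
                stage = "advanced" if (k == len(all_times) - 1 and seq.outcome) \
                    else "early_intermediate"
                rows.append({
                    "patient_id": pid,
                    "eye_id": seq.eye_id,
                    "laterality": lat,
                    "visit_index": k,
                    "time_months": t,
                    "image_path": f"{seq.eye_id}_v{k}.png",
                    "stage": stage,
                })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return sequences, manifest


def write_cohort(sequences: list[VisitSequence], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write 8-bit PNGs and manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    manifest["image_path"] = manifest["image_path"].map(
        lambda p: str(Path("images") / p))
    for seq in sequences:
        frames = list(seq.images)
        if seq.outcome_image is not None:
            frames.append(seq.outcome_image)
        for k, img in enumerate(frames):
            arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(out_dir / "images" / f"{seq.eye_id}_v{k}.png")
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
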
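"""Deterministic synthetic wound-like image generator.

Stands in for the (non-public) clinical photograph collection so the full
pipeline is exercisable offline.  Each class is rendered as a skin-tone
background with a class-specific hue shift plus concentric darkened
elliptical "lesion rings" whose count and depth grow with stage severity
(he = 0 rings ... s4 = 4); the undetermined class draws a random ring
count with speckle occlusion.  This encodes the ordinal-severity
structure a stager must exploit and makes classes separable by a small
classifier; it makes no claim of clinical realism.

Pixel values are quantized to 8 bits so a PNG round-trip is lossless, and
the whole dataset regenerates bit-identically from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import LabeledImage, save_image, write_manifest
from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY

#: Training-split class counts of the reference clinical distribution.
TABLE2_TRAIN = {"he": 54, "s1": 60, "s2": 73, "s3": 39, "s4": 15, "un": 14}
#: Held-out test-split counts of the same distribution.
TABLE2_TEST = {"he": 7, "s1": 8, "s2": 9, "s3": 5, "s4": 2, "un": 2}

SKIN_TONE = np.array([0.76, 0.60, 0.50])

#: Per-class additive RGB shift — the photometric component of separability.
CLASS_TINT = {
    "he": np.array([0.03, 0.02, 0.00]),
    "s1": np.array([0.06, -0.03, -0.02]),
    "s2": np.array([0.00, 0.04, -0.04]),
    "s3": np.array([-0.05, 0.00, 0.04]),
    "s4": np.array([-0.09, -0.05, 0.00]),
    "un": np.array([0.00, -0.03, 0.06]),
}

#: Lesion ring count per class ("un" draws 1-4 at random).
RING_COUNT = {"he": 0, "s1": 1, "s2": 2, "s3": 3, "s4": 4}


@dataclass(frozen=True)
class SyntheticSpec:
    class_counts: dict[str, int] = field(default_factory=lambda: dict(TABLE2_TRAIN))
    image_size: int = 224
    noise_sd: float = 0.03
    seed: int = 0
    n_subjects: int = 50

    def __post_init__(self):
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError(f"counts must be >= 0, got {self.class_counts}")
        if self.image_size < 32:
            raise ValueError(f"image size must be >= 32, got {self.image_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.noise_sd}")
        if all(n == 0 for n in self.class_counts.values()):
            raise ValueError("at least one class count must be positive")


def _render(label: str, size: int, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    img = np.ones((size, size, 3)) * (SKIN_TONE + CLASS_TINT[label])
    if label == "un":
        n_rings = int(rng.integers(1, 5))
    else:
        n_rings = RING_COUNT[label]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size * rng.uniform(0.4, 0.6)
    cx = size * rng.uniform(0.4, 0.6)
    base_r = size * rng.uniform(0.22, 0.32)
    ecc = rng.uniform(0.7, 1.3)  # ellipse eccentricity
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    dist = np.sqrt((u / ecc) ** 2 + (v * ecc) ** 2)

    for k in range(n_rings):
        r = base_r * (1.0 - k / max(n_rings, 1) * 0.8)
        depth = 0.12 + 0.10 * k  # deeper rings darker: ordinal severity cue
        wobble = 1.0 + 0.08 * np.sin(np.arctan2(v, u) * rng.integers(2, 6) + rng.uniform(0, 2 * np.pi))
        mask = dist < r * wobble
        img[mask] *= (1.0 - depth)
        img[mask, 0] *= 1.05  # wound beds skew red

    if label == "un":  # speckle occlusion: ambiguous, partially obscured wound
        n_spots = int(rng.integers(20, 40))
        for _ in range(n_spots):
            sy, sx = rng.integers(0, size, 2)
            rad = max(1, int(size * 0.02))
            spot = (yy - sy) ** 2 + (xx - sx) ** 2 < rad ** 2
            img[spot] = rng.uniform(0.1, 0.9, 3)

    img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 255.0) / 255.0  # 8-bit quantized: PNG round-trip exact


def generate_dataset(spec: SyntheticSpec,
                     taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY,
                     ) -> tuple[list[LabeledImage], list[str]]:
    """Images plus their convention filenames, deterministic in the seed.

    Subject ids are assigned round-robin so subject-aware splitting can be
    exercised.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[LabeledImage] = []
    names: list[str] = []
    subject = 0
    for lab in taxonomy.labels:
        n = spec.class_counts.get(lab, 0)
        for i in range(n):
            pixels = _render(lab, spec.image_size, rng, spec.noise_sd)
            images.append(LabeledImage(pixels, lab,
                                       subject_id=f"subj{subject % spec.n_subjects:03d}",
                                       source="synthetic"))
            names.append(f"{lab}_{i:04d}.png")
            subject += 1
    return images, names


def write_dataset(spec: SyntheticSpec, out_dir,
                  taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> list[str]:
    """Render to PNGs under `out_dir` plus a manifest.csv; returns filenames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, names = generate_dataset(spec, taxonomy)
    for img, name in zip(images, names):
        save_image(img, out_dir / name)
    write_manifest(out_dir / "manifest.csv", images, names)
    return names


def simulate_splits(preset: str = "table2", seed: int = 0, image_size: int = 224,
                    ) -> dict[str, SyntheticSpec]:
    """Specs for the train and test splits of a named preset."""
    if preset == "table2":
        counts = {"train": TABLE2_TRAIN, "test": TABLE2_TEST}
    elif preset == "balanced":
        counts = {"train": {lab: 30 for lab in DEFAULT_TAXONOMY.labels},
                  "test": {lab: 6 for lab in DEFAULT_TAXONOMY.labels}}
    else:
        raise ValueError(f"unknown preset {preset!r} (use 'table2' or 'balanced')")
    # distinct child seeds per split so test images are not train re-renders
    return {split: SyntheticSpec(class_counts=dict(c), image_size=image_size,
                                 seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)))
            for i, (split, c) in enumerate(counts.items())}
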
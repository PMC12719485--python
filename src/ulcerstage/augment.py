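"""Class-adaptive augmentation and mixup.

Underrepresented stages (s3, s4, un by default) get an aggressive policy
— flips p=0.7/0.5, rotations to 30 deg, affine (translate 0.2, scale
0.8-1.2, shear 15 deg), color jitter 0.3, perspective p=0.3, autocontrast
p=0.5, random erasing p=0.3 — while well-represented classes get the same
pipeline with every probability and magnitude range halved.  Each class
is expanded to a target count (its original images plus seeded stochastic
transforms of them), producing a synthetically balanced training set.
Evaluation splits are never augmented.

Transform order is geometric before photometric: flip, rotate, affine,
color jitter, perspective, autocontrast, erasing.  Per-class random
streams are derived from one run seed plus the class index, so adding a
class does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import yaml
from PIL import Image, ImageEnhance, ImageOps

from .data_io import LabeledImage
from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY, MINORITY_LABELS

#: Training-set class counts of the reference clinical distribution...
TABLE_COUNTS_ORIGINAL = {"he": 54, "s1": 60, "s2": 73, "s3": 39, "s4": 15, "un": 14}
#: ...and the post-augmentation training targets that balance it.
TABLE_COUNTS_AUGMENTED = {"he": 392, "s1": 476, "s2": 589, "s3": 315, "s4": 129, "un": 126}

_PERSPECTIVE_MAG = 0.2  # corner displacement fraction at aggressive strength


@dataclass(frozen=True)
class ClassPolicy:
    """Stochastic transform parameters for one class."""

    hflip_p: float = 0.7
    vflip_p: float = 0.5
    max_rotation_deg: float = 30.0
    translate_frac: float = 0.2
    scale_min: float = 0.8
    scale_max: float = 1.2
    shear_deg: float = 15.0
    jitter: float = 0.3
    perspective_p: float = 0.3
    autocontrast_p: float = 0.5
    erasing_p: float = 0.3
    target_count: int = 0

    def __post_init__(self):
        for name in ("hflip_p", "vflip_p", "perspective_p", "autocontrast_p", "erasing_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.scale_min > self.scale_max:
            raise ValueError(f"scale range inverted: {self.scale_min} > {self.scale_max}")


AGGRESSIVE = ClassPolicy()
#: Conservative = aggressive with probabilities and magnitude ranges halved.
CONSERVATIVE = ClassPolicy(hflip_p=0.35, vflip_p=0.25, max_rotation_deg=15.0,
                           translate_frac=0.1, scale_min=0.9, scale_max=1.1,
                           shear_deg=7.5, jitter=0.15, perspective_p=0.15,
                           autocontrast_p=0.25, erasing_p=0.15)


@dataclass(frozen=True)
class MixupConfig:
    alpha: float = 0.2
    enabled: bool = True

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"mixup alpha must be > 0, got {self.alpha}")


@dataclass
class AugmentationPolicy:
    """Per-class policies keyed by taxonomy label."""

    per_class: dict[str, ClassPolicy]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({lab: asdict(p) for lab, p in self.per_class.items()}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AugmentationPolicy":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({lab: ClassPolicy(**params) for lab, params in raw.items()})


def default_targets(class_counts: dict[str, int]) -> dict[str, int]:
    """Reference targets when counts match the clinical training
    distribution exactly; otherwise every class is raised to the max count."""
    if class_counts == TABLE_COUNTS_ORIGINAL:
        return dict(TABLE_COUNTS_AUGMENTED)
    top = max(class_counts.values())
    return {lab: top for lab in class_counts}


def build_policy(class_counts: dict[str, int],
                 minority_labels: set[str] | frozenset[str] = MINORITY_LABELS,
                 targets: dict[str, int] | None = None,
                 taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> AugmentationPolicy:
    """Aggressive policy for minority classes, conservative for the rest."""
    unknown = set(minority_labels) - set(taxonomy.labels)
    if unknown:
        raise ValueError(f"unknown labels in minority set: {sorted(unknown)}")
    if any(n <= 0 for n in class_counts.values()):
        raise ValueError(f"all present classes need counts > 0, got {class_counts}")
    targets = targets if targets is not None else default_targets(class_counts)
    per_class = {}
    for lab, n in class_counts.items():
        base = AGGRESSIVE if lab in minority_labels else CONSERVATIVE
        tgt = max(targets.get(lab, n), n)
        per_class[lab] = replace(base, target_count=tgt)
    return AugmentationPolicy(per_class)


@dataclass
class BalanceReport:
    """Original vs augmented per-class counts and the minority expansion factor."""

    original: dict[str, int]
    augmented: dict[str, int]
    minority_labels: frozenset[str] = MINORITY_LABELS

    @property
    def minority_expansion_factor(self) -> float:
        num = sum(self.augmented[lab] for lab in self.minority_labels if lab in self.augmented)
        den = sum(self.original[lab] for lab in self.minority_labels if lab in self.original)
        if den == 0:
            raise ValueError("no minority-class images to expand")
        return num / den


# -- transform pipeline ----------------------------------------------------

def _to_pil(pixels: np.ndarray) -> Image.Image:
    return Image.fromarray(np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8))


def _find_perspective_coeffs(src, dst):
    """Solve the 8 projective coefficients mapping dst points onto src."""
    a = []
    b = []
    for (x, y), (u, v) in zip(dst, src):
        a.append([x, y, 1, 0, 0, 0, -u * x, -u * y])
        a.append([0, 0, 0, x, y, 1, -v * x, -v * y])
        b.extend([u, v])
    return np.linalg.lstsq(np.asarray(a, float), np.asarray(b, float), rcond=None)[0]


def apply_transforms(pixels: np.ndarray, policy: ClassPolicy,
                     rng: np.random.Generator,
                     fill: tuple[float, float, float] | None = None) -> np.ndarray:
    """One stochastic draw of the augmentation pipeline on an [0,1] image."""
    img = _to_pil(pixels)
    w, h = img.size
    mean_fill = tuple(int(round(c * 255)) for c in (
        fill if fill is not None else pixels.reshape(-1, 3).mean(axis=0)))

    if rng.random() < policy.hflip_p:
        img = img.transpose(Image.FLIP_LEFT_RIGHT)
    if rng.random() < policy.vflip_p:
        img = img.transpose(Image.FLIP_TOP_BOTTOM)
    angle = rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg)
    img = img.rotate(angle, resample=Image.BILINEAR, fillcolor=mean_fill)

    # affine: scale + shear about the center, then translate
    s = rng.uniform(policy.scale_min, policy.scale_max)
    shear = np.deg2rad(rng.uniform(-policy.shear_deg, policy.shear_deg))
    tx = rng.uniform(-policy.translate_frac, policy.translate_frac) * w
    ty = rng.uniform(-policy.translate_frac, policy.translate_frac) * h
    fwd = np.array([[s, s * np.tan(shear)], [0.0, s]])
    inv = np.linalg.inv(fwd)
    c = np.array([w / 2.0, h / 2.0])
    offset = c - inv @ (c + np.array([tx, ty]))
    img = img.transform((w, h), Image.AFFINE,
                        (inv[0, 0], inv[0, 1], offset[0], inv[1, 0], inv[1, 1], offset[1]),
                        resample=Image.BILINEAR, fillcolor=mean_fill)

    if policy.jitter > 0:
        img = ImageEnhance.Brightness(img).enhance(1.0 + rng.uniform(-policy.jitter, policy.jitter))
        img = ImageEnhance.Contrast(img).enhance(1.0 + rng.uniform(-policy.jitter, policy.jitter))

    if rng.random() < policy.perspective_p:
        mag = _PERSPECTIVE_MAG * (policy.shear_deg / AGGRESSIVE.shear_deg)
        src = [(0, 0), (w, 0), (w, h), (0, h)]
        dst = [(x + rng.uniform(-mag, mag) * w, y + rng.uniform(-mag, mag) * h)
               for x, y in src]
        coeffs = _find_perspective_coeffs(src, dst)
        img = img.transform((w, h), Image.PERSPECTIVE, tuple(coeffs),
                            resample=Image.BILINEAR, fillcolor=mean_fill)

    if rng.random() < policy.autocontrast_p:
        img = ImageOps.autocontrast(img)

    out = np.asarray(img, dtype=float) / 255.0
    if rng.random() < policy.erasing_p:
        area = rng.uniform(0.02, 0.15) * w * h
        aspect = rng.uniform(0.3, 3.3)
        eh = int(round(np.sqrt(area * aspect)))
        ew = int(round(np.sqrt(area / aspect)))
        if 0 < eh < h and 0 < ew < w:
            top = rng.integers(0, h - eh)
            left = rng.integers(0, w - ew)
            out[top:top + eh, left:left + ew] = (
                fill if fill is not None else out.reshape(-1, 3).mean(axis=0))
    return np.clip(out, 0.0, 1.0)


def class_stream(run_seed: int, class_index: int) -> np.random.Generator:
    """Per-class random stream derived from the run seed and class index."""
    return np.random.default_rng(np.random.SeedSequence([int(run_seed), int(class_index)]))


def augment_to_target(images: list[LabeledImage], policy: ClassPolicy, seed: int,
                      taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> list[LabeledImage]:
    """Expand one class to exactly ``policy.target_count`` images.

    Returns all originals followed by seeded stochastic transforms of
    uniformly re-sampled originals; deterministic for a fixed seed.
    """
    if not images:
        raise ValueError("cannot augment an empty class")
    labels = {img.label for img in images}
    if len(labels) != 1:
        raise ValueError(f"augment_to_target expects a single class, got {sorted(labels)}")
    label = images[0].label
    target = policy.target_count
    if target < len(images):
        raise ValueError(f"target {target} below original count {len(images)}")
    rng = class_stream(seed, taxonomy.index[label])
    fill = tuple(np.mean([im.pixels.reshape(-1, 3).mean(axis=0) for im in images], axis=0))
    out = list(images)
    for j in range(target - len(images)):
        src = images[int(rng.integers(0, len(images)))]
        pixels = apply_transforms(src.pixels, policy, rng, fill=fill)
        out.append(LabeledImage(pixels, label, subject_id=src.subject_id,
                                source=f"{src.source}#aug{j:03d}"))
    return out


def augment_training_set(images: list[LabeledImage],
                         policy: AugmentationPolicy | None = None,
                         seed: int = 0,
                         taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY,
                         ) -> tuple[list[LabeledImage], BalanceReport]:
    """Balance a whole training split; returns images plus a BalanceReport."""
    by_class: dict[str, list[LabeledImage]] = {}
    for img in images:
        by_class.setdefault(img.label, []).append(img)
    counts = {lab: len(v) for lab, v in by_class.items()}
    if policy is None:
        policy = build_policy(counts, taxonomy=taxonomy)
    out: list[LabeledImage] = []
    augmented_counts = {}
    for lab in taxonomy.labels:
        if lab not in by_class:
            continue
        expanded = augment_to_target(by_class[lab], policy.per_class[lab], seed, taxonomy)
        augmented_counts[lab] = len(expanded)
        out.extend(expanded)
    return out, BalanceReport(counts, augmented_counts)


def mixup_batch(x: np.ndarray, y: np.ndarray, cfg: MixupConfig,
                rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray, float]:
    """Blend the batch with a permuted copy: one lambda ~ Beta(alpha, alpha).

    `y` rows should be one-hot (or already-soft) label vectors; convexity
    keeps them on the simplex.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError(f"mixup needs a batch of >= 2, got {len(x)}")
    lam = float(rng.beta(cfg.alpha, cfg.alpha))
    perm = rng.permutation(len(x))
    return lam * x + (1 - lam) * x[perm], lam * y + (1 - lam) * y[perm], lam
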
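"""Dataset loading, labeling, preprocessing, and distribution summaries.

On-disk conventions
-------------------
* Images are PNG/JPEG; the class code is the filename's leading token
  before the first underscore (case-insensitive), e.g. ``s2_0143.jpg``.
* An optional CSV manifest with header ``path,label,subject_id`` overrides
  filename labels.
* A dataset root is either flat or has ``train/ val/ test/`` subdirectories.

Preprocessing resizes to ``target_size`` (bilinear, anti-aliased, no
center crop so wound margins are kept) and normalizes with the ImageNet
channel statistics on the [0, 1] pixel scale.  Color handling on load is
convert-to-RGB; the mean/std step is the only photometric correction.
Background segmentation / artifact-outlier hooks are deliberately no-ops
(`segment_background`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

SPLIT_DIRS = ("train", "val", "test")
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class LabeledImage:
    """One RGB image in [0, 1] with its class label and provenance."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    label: str
    subject_id: str = ""
    source: str = "synthetic"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {self.pixels.shape}")
        if min(self.pixels.shape[:2]) < 32:
            raise ValueError(f"image too small: {self.pixels.shape[:2]}, need >= 32 px")


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 224
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN
    channel_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if any(s <= 0 for s in self.channel_std):
            raise ValueError(f"channel std must be positive, got {self.channel_std}")


@dataclass
class DatasetSummary:
    """Per-class counts per split, with totals and proportions."""

    counts: dict[str, dict[str, int]]  # split -> label -> count
    taxonomy: ClassTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    @property
    def totals(self) -> dict[str, int]:
        return {split: sum(c.values()) for split, c in self.counts.items()}

    @property
    def proportions(self) -> dict[str, dict[str, float]]:
        out = {}
        for split, c in self.counts.items():
            tot = sum(c.values())
            out[split] = {lab: (c[lab] / tot if tot else 0.0) for lab in self.taxonomy.labels}
        return out

    def to_csv(self, path) -> None:
        """Rows = classes plus Total, columns = splits."""
        splits = list(self.counts)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", *splits])
            for lab in self.taxonomy.labels:
                w.writerow([lab, *(self.counts[s].get(lab, 0) for s in splits)])
            w.writerow(["Total", *(self.totals[s] for s in splits)])


def parse_label(filename, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> str:
    """Class code from the filename's leading token, case-insensitive."""
    name = Path(str(filename)).name
    if not name:
        raise ValueError("empty filename")
    token = name.split("_", 1)[0].split(".", 1)[0].lower()
    if token not in taxonomy:
        raise ValueError(
            f"cannot label {filename!r}: prefix {token!r} is not one of {taxonomy.labels}")
    return token


def load_image(path, label: str | None = None, subject_id: str = "",
               taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> LabeledImage:
    """Decode PNG/JPEG to an RGB [0, 1] LabeledImage."""
    img = Image.open(path).convert("RGB")
    pixels = np.asarray(img, dtype=float) / 255.0
    lab = label if label is not None else parse_label(path, taxonomy)
    return LabeledImage(pixels, lab, subject_id=subject_id, source=str(path))


def read_manifest(path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    required = {"path", "label", "subject_id"}
    if rows and not required <= set(rows[0]):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(rows[0])}")
    return rows


def write_manifest(path, images: list[LabeledImage], paths: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label", "subject_id"])
        for img, p in zip(images, paths):
            w.writerow([p, img.label, img.subject_id])


def load_dataset(root, manifest=None,
                 taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> dict[str, list[LabeledImage]]:
    """Load a dataset root into split -> images (flat roots map to 'train').

    A manifest CSV (columns path,label,subject_id) overrides filename labels.
    """
    root = Path(root)
    if manifest is not None:
        images = [
            load_image(root / r["path"] if not Path(r["path"]).is_absolute() else r["path"],
                       label=r["label"], subject_id=r["subject_id"], taxonomy=taxonomy)
            for r in read_manifest(manifest)
        ]
        return {"train": images}
    splits: dict[str, list[LabeledImage]] = {}
    subdirs = [d for d in SPLIT_DIRS if (root / d).is_dir()]
    if subdirs:
        for d in subdirs:
            splits[d] = [load_image(p, taxonomy=taxonomy)
                         for p in sorted((root / d).iterdir())
                         if p.suffix.lower() in IMAGE_SUFFIXES]
    else:
        splits["train"] = [load_image(p, taxonomy=taxonomy)
                           for p in sorted(root.iterdir())
                           if p.suffix.lower() in IMAGE_SUFFIXES]
    return splits


def save_image(img: LabeledImage, path) -> None:
    """Write as 8-bit PNG (lossless for uint8-quantized pixels)."""
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear anti-aliased resize of an (H, W, 3) array to (size, size, 3)."""
    if pixels.shape[:2] == (size, size):
        return np.asarray(pixels, dtype=float)
    return _sk_resize(np.asarray(pixels, dtype=float), (size, size),
                      order=1, anti_aliasing=True, preserve_range=True)


def preprocess_image(img: LabeledImage, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Resize and channel-normalize: output (3, S, S) with (x - mu_c) / sigma_c."""
    if img.pixels.ndim != 3 or img.pixels.shape[2] != 3:
        raise ValueError(f"expected 3-channel image, got shape {img.pixels.shape}")
    resized = resize_image(img.pixels, cfg.target_size)
    mean = np.asarray(cfg.channel_mean)
    std = np.asarray(cfg.channel_std)
    return np.transpose((resized - mean) / std, (2, 0, 1))


def preprocess_batch(images: list[LabeledImage],
                     cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    return np.stack([preprocess_image(img, cfg) for img in images])


def segment_background(img: LabeledImage) -> LabeledImage:
    """Hook for wound-region segmentation / artifact correction: identity.

    The upstream acquisition pipeline this package targets describes such
    steps without specifying algorithms, so this stays a no-op extension
    point rather than a guessed implementation.
    """
    return img


def class_distribution(splits: dict[str, list], taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY,
                       ) -> DatasetSummary:
    """Per-class counts per split; items may be LabeledImages or label strings."""
    counts: dict[str, dict[str, int]] = {}
    for split, items in splits.items():
        c = {lab: 0 for lab in taxonomy.labels}
        for it in items:
            lab = it if isinstance(it, str) else it.label
            if lab not in taxonomy:
                raise ValueError(f"item with unknown label {lab!r} in split {split!r}")
            c[lab] += 1
        counts[split] = c
    return DatasetSummary(counts, taxonomy)
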
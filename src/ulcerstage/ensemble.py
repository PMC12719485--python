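"""Two-tier probability ensembling.

Tier one averages class-probability matrices across checkpoint epochs
within a fold (``P_temporal = 1/|E| sum_e P_e``); tier two averages those
across folds (``P_final = 1/|K| sum_k P_temporal^k``).  Both tiers are
plain unweighted means over post-softmax probabilities, so the
composition equals one flat mean over all |E|x|K| members, rows stay on
the simplex, and averaging never sharpens a row beyond its sharpest
member.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY

ROW_SUM_TOL = 1e-6


@dataclass
class ProbabilityMatrix:
    """N x C class-probability rows tied to item ids, taxonomy class order."""

    probs: np.ndarray
    ids: list[str] = field(default_factory=list)
    taxonomy: ClassTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != self.taxonomy.n_classes:
            raise ValueError(f"expected N x {self.taxonomy.n_classes} matrix, "
                             f"got shape {self.probs.shape}")
        if not self.ids:
            self.ids = [str(i) for i in range(len(self.probs))]
        if len(self.ids) != len(self.probs):
            raise ValueError(f"{len(self.ids)} ids for {len(self.probs)} rows")
        if np.any(self.probs < -ROW_SUM_TOL) or np.any(self.probs > 1 + ROW_SUM_TOL):
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValueError(f"rows not on the simplex (first offender: id "
                             f"{self.ids[bad[0]]!r}, sum {sums[bad[0]]:.8f})")

    def to_csv(self, path, with_labels: bool = True) -> None:
        header = ["id"] + [f"p_{lab}" for lab in self.taxonomy.labels]
        rows = self.probs
        extra = []
        if with_labels:
            header += ["label", "confidence"]
            labels, conf = predict_labels(self)
            extra = list(zip(labels, conf))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for i, rid in enumerate(self.ids):
                row = [rid] + [f"{v:.10g}" for v in rows[i]]
                if with_labels:
                    row += [extra[i][0], f"{extra[i][1]:.10g}"]
                w.writerow(row)

    @classmethod
    def from_csv(cls, path, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY) -> "ProbabilityMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        cols = [f"p_{lab}" for lab in taxonomy.labels]
        missing = [c for c in cols if rows and c not in rows[0]]
        if missing:
            raise ValueError(f"{path}: missing probability columns {missing}")
        probs = np.array([[float(r[c]) for c in cols] for r in rows])
        return cls(probs, [r["id"] for r in rows], taxonomy)


@dataclass(frozen=True)
class EnsembleSpec:
    """Checkpoint-epoch set E and fold set K with unweighted averaging."""

    epochs: tuple[int, ...] = (15, 20, 25, 30)
    folds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self):
        if not self.epochs or not self.folds:
            raise ValueError("epoch set and fold set must be non-empty")


def _mean_members(members: list[ProbabilityMatrix], what: str) -> ProbabilityMatrix:
    if not members:
        raise ValueError(f"no {what} members to average")
    ref = members[0]
    for i, m in enumerate(members[1:], start=1):
        if m.probs.shape != ref.probs.shape:
            raise ValueError(f"{what} member {i} has shape {m.probs.shape}, "
                             f"expected {ref.probs.shape}")
        if m.ids != ref.ids:
            raise ValueError(f"{what} member {i} row ids do not match member 0")
    mean = np.mean([m.probs for m in members], axis=0)
    return ProbabilityMatrix(mean, list(ref.ids), ref.taxonomy)


def temporal_ensemble(members: list[ProbabilityMatrix]) -> ProbabilityMatrix:
    """Unweighted mean over checkpoint-epoch members of one fold."""
    return _mean_members(members, "temporal")


def spatial_ensemble(fold_members: list[ProbabilityMatrix]) -> ProbabilityMatrix:
    """Unweighted mean of per-fold temporal ensembles on shared test items."""
    return _mean_members(fold_members, "spatial")


def two_tier_ensemble(per_fold_members: list[list[ProbabilityMatrix]]) -> ProbabilityMatrix:
    """Temporal tier within each fold, then the spatial tier across folds."""
    return spatial_ensemble([temporal_ensemble(m) for m in per_fold_members])


def predict_labels(p: ProbabilityMatrix) -> tuple[list[str], np.ndarray]:
    """Argmax decoding: label and row-max confidence per item.

    Ties break toward the lower class index (taxonomy order), deterministically.
    """
    if np.isnan(p.probs).any():
        bad = int(np.flatnonzero(np.isnan(p.probs).any(axis=1))[0])
        raise ValueError(f"NaN probabilities in row id {p.ids[bad]!r}")
    idx = p.probs.argmax(axis=1)  # argmax returns the first (lowest) index on ties
    labels = [p.taxonomy.labels[i] for i in idx]
    return labels, p.probs[np.arange(len(idx)), idx]
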
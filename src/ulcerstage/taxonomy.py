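"""The six-class wound-stage taxonomy.

Classes follow the NPIAP-style ordinal staging used throughout the
package: healthy tissue (``he``), Stage 1-4 pressure ulcers
(``s1``..``s4``), and undetermined cases (``un``).  Index order is fixed
(he=0 ... un=5) for every probability matrix, confusion matrix and report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CLASS_LABELS: tuple[str, ...] = ("he", "s1", "s2", "s3", "s4", "un")

#: Labels the augmentation engine treats as underrepresented by default.
MINORITY_LABELS: frozenset[str] = frozenset({"s3", "s4", "un"})


@dataclass(frozen=True)
class ClassTaxonomy:
    """Ordered label set with a label -> index map.

    Invariants: exactly six unique labels; index order is the listed order.
    """

    labels: tuple[str, ...] = CLASS_LABELS
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.labels) != 6 or len(set(self.labels)) != 6:
            raise ValueError(f"taxonomy needs exactly six unique labels, got {self.labels!r}")
        object.__setattr__(self, "index", {lab: i for i, lab in enumerate(self.labels)})

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def to_indices(self, labels) -> list[int]:
        return [self.index[lab] for lab in labels]


DEFAULT_TAXONOMY = ClassTaxonomy()
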
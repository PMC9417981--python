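"""Aggregation of event labels into main populations and subpopulations.

The 8 main myP/M populations are the CD34/CD117/HLA-DR backbone
combinations; crossing them with the 4 aberrant categories yields the 32
monitored subpopulations.  A subpopulation is *immature* when its backbone
expresses CD34 and/or CD117 (24 of the 32).  All percentages are fractions
of CD45+ events; they are kept at full precision and rounded only when a
report is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .gating import CATEGORIES, EventLabels, NonEvaluableSampleError

#: Backbone combinations (CD34, CD117, HLA-DR) in canonical order,
#: all-positive first.
BACKBONES: tuple[tuple[bool, bool, bool], ...] = tuple(
    product((True, False), repeat=3)
)


def _sign(flag: bool) -> str:
    return "+" if flag else "-"


def backbone_label(backbone: tuple[bool, bool, bool]) -> str:
    cd34, cd117, hladr = backbone
    return f"CD34{_sign(cd34)}CD117{_sign(cd117)}HLA-DR{_sign(hladr)}"


_CATEGORY_LABELS = {
    "CD13neg": "CD13-", "CD33neg": "CD33-", "CD7pos": "CD7+", "CD56pos": "CD56+",
}
_CATEGORY_FROM_LABEL = {v: k for k, v in _CATEGORY_LABELS.items()}


@dataclass(frozen=True, order=True)
class SubpopulationID:
    """One of the 32 aberrant subpopulations: backbone + aberrant category."""

    cd34: bool
    cd117: bool
    hladr: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown aberrant category {self.category!r}")

    @property
    def backbone(self) -> tuple[bool, bool, bool]:
        return (self.cd34, self.cd117, self.hladr)

    @property
    def immature(self) -> bool:
        """Carries a marker of immaturity (CD34+ and/or CD117+)."""
        return self.cd34 or self.cd117

    @property
    def label(self) -> str:
        return backbone_label(self.backbone) + _CATEGORY_LABELS[self.category]

    @classmethod
    def from_label(cls, label: str) -> "SubpopulationID":
        for cat_label, category in _CATEGORY_FROM_LABEL.items():
            if label.endswith(cat_label):
                head = label[: -len(cat_label)]
                break
        else:
            raise ValueError(f"cannot parse subpopulation label {label!r}")
        for backbone in BACKBONES:
            if backbone_label(backbone) == head:
                return cls(*backbone, category)
        raise ValueError(f"cannot parse subpopulation label {label!r}")


def enumerate_main_populations() -> list[tuple[bool, bool, bool]]:
    """The 8 backbone main populations."""
    return list(BACKBONES)


def enumerate_subpopulations(immature_only: bool = False) -> list[SubpopulationID]:
    """All 32 subpopulations, or the 24 with a marker of immaturity."""
    ids = [
        SubpopulationID(*backbone, category)
        for backbone in BACKBONES
        for category in CATEGORIES
    ]
    if immature_only:
        ids = [i for i in ids if i.immature]
    return ids


ALL_SUBPOPULATIONS: tuple[SubpopulationID, ...] = tuple(enumerate_subpopulations())


@dataclass
class SubpopulationTable:
    """Counts and %CD45+ for 8 main populations and 32 subpopulations."""

    n_cd45: int
    n_mypm: int
    main_counts: dict[tuple[bool, bool, bool], int]
    subpop_counts: dict[SubpopulationID, int]
    sample_id: str = "sample"
    cohort_label: str | None = None

    def __post_init__(self) -> None:
        for backbone in BACKBONES:
            self.main_counts.setdefault(backbone, 0)
        for sid in ALL_SUBPOPULATIONS:
            self.subpop_counts.setdefault(sid, 0)
        if sum(self.main_counts.values()) != self.n_mypm:
            raise ValueError("main-population counts must sum to the myP/M count")

    def pct(self, sid: SubpopulationID) -> float:
        """Subpopulation frequency as % of CD45+ events (full precision)."""
        return 100.0 * self.subpop_counts[sid] / self.n_cd45

    def main_pct(self, backbone: tuple[bool, bool, bool]) -> float:
        return 100.0 * self.main_counts[backbone] / self.n_cd45

    def category_count(self, category: str) -> int:
        """myP/M events carrying the category (summed over backbones)."""
        return sum(
            c for sid, c in self.subpop_counts.items() if sid.category == category
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "subpopulation": sid.label,
                "cd34": sid.cd34,
                "cd117": sid.cd117,
                "hladr": sid.hladr,
                "category": sid.category,
                "immature": sid.immature,
                "count": self.subpop_counts[sid],
                "pct_cd45": self.pct(sid),
            }
            for sid in ALL_SUBPOPULATIONS
        ]
        return pd.DataFrame(rows)


def tabulate(
    labels: EventLabels,
    sample_id: str = "sample",
    cohort_label: str | None = None,
) -> SubpopulationTable:
    """Aggregate per-event labels into the population tables.

    An event carrying several aberrant categories contributes to one
    subpopulation per category (all under its unique backbone), so the
    backbone main populations partition myP/M while subpopulation counts may
    overlap across categories.
    """
    if labels.n_cd45 == 0:
        raise NonEvaluableSampleError("no CD45+ events: sample is non-evaluable")
    mypm = labels.mypm
    codes = labels.backbone[mypm]
    code_counts = np.bincount(codes, minlength=8)
    main_counts = {
        (bool(c & 4), bool(c & 2), bool(c & 1)): int(code_counts[c])
        for c in range(8)
    }
    subpop_counts: dict[SubpopulationID, int] = {}
    for category in CATEGORIES:
        cat_codes = labels.backbone[mypm & labels.categories[category]]
        counts = np.bincount(cat_codes, minlength=8)
        for c in range(8):
            sid = SubpopulationID(bool(c & 4), bool(c & 2), bool(c & 1), category)
            subpop_counts[sid] = int(counts[c])
    return SubpopulationTable(
        n_cd45=labels.n_cd45,
        n_mypm=int(mypm.sum()),
        main_counts=main_counts,
        subpop_counts=subpop_counts,
        sample_id=sample_id,
        cohort_label=cohort_label,
    )
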
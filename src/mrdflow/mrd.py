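"""Diagnosis LAIP detection and follow-up MRD calling.

At diagnosis, an aberrant category is a LAIP (aLAIP) when it affects at
least 10% of myP/M events (the threshold is configurable; 10, 5, 2.5 and
1% are the studied settings).  At follow-up:

* only subpopulations with >= 20 events are analyzed (minimum population
  size; configurable);
* the sample is MRD positive when at least one aberrant subpopulation
  *exceeds* its reference value (strict inequality);
* the excess over the reference (in percentage points of CD45+) is the
  disease burden of that subpopulation; burdens of subpopulations sharing
  an aberrant category are summed, and the category with the highest sum
  quantifies the MRD load;
* each positive category is classified by origin: aLAIP when the category
  was a LAIP at diagnosis, post-treatment DfN (ptDfN) when it appeared
  de novo.

Alternative schemes: the ELN-style call restricts the analysis to the 24
subpopulations with a marker of immaturity at a flat 0.1% cutoff; the
ImmOnly call applies the reference scheme to those same 24; the Lo/Hi split
divides positives at a maximum single-subpopulation excess of 0.1 (>= 0.1
is Hi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .gating import CATEGORIES, NonEvaluableSampleError
from .populations import (
    ALL_SUBPOPULATIONS,
    SubpopulationID,
    SubpopulationTable,
    enumerate_subpopulations,
)
from .reference import ReferencePanel

DEFAULT_MIN_EVENTS = 20
DEFAULT_ALAIP_THRESHOLD = 10.0
SUPPORTED_ALAIP_THRESHOLDS = (10.0, 5.0, 2.5, 1.0)
ELN_CUTOFF_PCT = 0.1
LOAD_SPLIT = 0.1


@dataclass
class DiagnosisProfile:
    """Per-category involvement of the diagnostic myP/M compartment."""

    pct_of_mypm: dict[str, float]
    alaip_threshold: float = DEFAULT_ALAIP_THRESHOLD
    n_mypm: int = 0

    @property
    def alaip_set(self) -> frozenset[str]:
        """Categories qualifying as LAIP (>= threshold % of myP/M)."""
        return frozenset(
            c for c, p in self.pct_of_mypm.items() if p >= self.alaip_threshold
        )

    @property
    def minor_clones(self) -> frozenset[str]:
        """Categories present below the LAIP threshold."""
        return frozenset(
            c
            for c, p in self.pct_of_mypm.items()
            if 0 < p < self.alaip_threshold
        )


def detect_alaip(
    diagnosis: SubpopulationTable,
    threshold_pct: float = DEFAULT_ALAIP_THRESHOLD,
) -> DiagnosisProfile:
    """Identify aLAIP categories in a diagnostic sample.

    A category's involvement is the fraction of myP/M events carrying it
    (each event counts once per category; backbones partition myP/M, so the
    32 subpopulation counts sum correctly per category).
    """
    if threshold_pct <= 0:
        raise ValueError("aLAIP threshold must be positive")
    if diagnosis.n_mypm == 0:
        warnings.warn(
            f"diagnostic sample {diagnosis.sample_id!r} has no myP/M events; "
            "no LAIP can be defined",
            stacklevel=2,
        )
        return DiagnosisProfile(
            pct_of_mypm={c: 0.0 for c in CATEGORIES},
            alaip_threshold=threshold_pct,
            n_mypm=0,
        )
    pct = {
        c: 100.0 * diagnosis.category_count(c) / diagnosis.n_mypm
        for c in CATEGORIES
    }
    return DiagnosisProfile(
        pct_of_mypm=pct, alaip_threshold=threshold_pct, n_mypm=diagnosis.n_mypm
    )


@dataclass(frozen=True)
class PositiveSubpopulation:
    sid: SubpopulationID
    count: int
    pct: float
    ref_pct: float

    @property
    def burden(self) -> float:
        """Excess over the reference, in percentage points of CD45+."""
        return self.pct - self.ref_pct


@dataclass
class MRDResult:
    """Outcome of the reference-based MRD call for one follow-up sample."""

    status: str                                  # "pos" | "neg"
    positive_subpops: list[PositiveSubpopulation]
    category_sums: dict[str, float]              # summed burden per category
    mrd_load: float                              # max category sum (0 if neg)
    load_category: str | None                    # argmax category
    load_tie: bool
    origin: str | None    # aLAIP_only | ptDfN_only | aLAIP_and_ptDfN | no_diagnosis
    non_evaluable_subpops: list[SubpopulationID] # dropped by the event rule
    n_cd45: int
    min_events: int
    load_class: str | None = None                # "Lo" | "Hi" (positives only)
    eln_status: str | None = None
    immonly_status: str | None = None


def call_mrd(
    followup: SubpopulationTable,
    panel: ReferencePanel,
    diagnosis: DiagnosisProfile | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
    restrict_immature: bool = False,
) -> MRDResult:
    """Reference-based MRD call.

    With ``restrict_immature`` the analysis covers only the 24
    subpopulations with a marker of immaturity (reference values
    unchanged) — the ImmOnly scheme.
    """
    if followup.n_cd45 == 0:
        raise NonEvaluableSampleError("no CD45+ events: sample is non-evaluable")
    scope = enumerate_subpopulations(immature_only=restrict_immature)

    non_evaluable = [s for s in scope if followup.subpop_counts[s] < min_events]
    analyzed = [s for s in scope if followup.subpop_counts[s] >= min_events]

    positives = [
        PositiveSubpopulation(
            sid=s,
            count=followup.subpop_counts[s],
            pct=followup.pct(s),
            ref_pct=panel.ref_pct(s),
        )
        for s in analyzed
        if followup.pct(s) > panel.ref_pct(s)
    ]

    category_sums = {c: 0.0 for c in CATEGORIES}
    for p in positives:
        category_sums[p.sid.category] += p.burden

    if positives:
        mrd_load = max(category_sums.values())
        # deterministic tie-break: canonical category order
        leaders = [c for c in CATEGORIES if category_sums[c] == mrd_load]
        load_category, load_tie = leaders[0], len(leaders) > 1
        status = "pos"
    else:
        mrd_load, load_category, load_tie, status = 0.0, None, False, "neg"

    origin: str | None = None
    if status == "pos":
        if diagnosis is None:
            origin = "no_diagnosis"
        else:
            positive_categories = {c for c in CATEGORIES if category_sums[c] > 0}
            in_alaip = positive_categories & diagnosis.alaip_set
            de_novo = positive_categories - diagnosis.alaip_set
            if in_alaip and de_novo:
                origin = "aLAIP_and_ptDfN"
            elif in_alaip:
                origin = "aLAIP_only"
            else:
                origin = "ptDfN_only"

    return MRDResult(
        status=status,
        positive_subpops=positives,
        category_sums=category_sums,
        mrd_load=mrd_load,
        load_category=load_category,
        load_tie=load_tie,
        origin=origin,
        non_evaluable_subpops=non_evaluable,
        n_cd45=followup.n_cd45,
        min_events=min_events,
    )


def call_mrd_eln(
    followup: SubpopulationTable,
    min_events: int = DEFAULT_MIN_EVENTS,
    cutoff_pct: float = ELN_CUTOFF_PCT,
) -> str:
    """ELN-style call: immature subpopulations only, flat 0.1% cutoff.

    Positive when any of the 24 immature subpopulations with at least
    ``min_events`` events reaches ``cutoff_pct`` of CD45+ (inclusive).
    """
    if followup.n_cd45 == 0:
        raise NonEvaluableSampleError("no CD45+ events: sample is non-evaluable")
    for sid in enumerate_subpopulations(immature_only=True):
        if followup.subpop_counts[sid] >= min_events and (
            followup.pct(sid) >= cutoff_pct
        ):
            return "pos"
    return "neg"


def call_mrd_immonly(
    followup: SubpopulationTable,
    panel: ReferencePanel,
    diagnosis: DiagnosisProfile | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> str:
    """Reference scheme restricted to the 24 immature subpopulations."""
    return call_mrd(
        followup, panel, diagnosis, min_events=min_events, restrict_immature=True
    ).status


def classify_load(result: MRDResult, split: float = LOAD_SPLIT) -> str:
    """Lo/Hi split of a positive call.

    Hi when any positive subpopulation exceeds its reference by >= ``split``
    percentage points of CD45+ (the single-subpopulation reading), else Lo.
    """
    if result.status != "pos":
        raise ValueError("load class is only defined for MRD-positive results")
    max_excess = max(p.burden for p in result.positive_subpops)
    return "Hi" if max_excess >= split else "Lo"


def assess(
    followup: SubpopulationTable,
    panel: ReferencePanel,
    diagnosis: DiagnosisProfile | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> MRDResult:
    """Full assessment: reference call plus all alternative schemes."""
    result = call_mrd(followup, panel, diagnosis, min_events=min_events)
    result.eln_status = call_mrd_eln(followup, min_events=min_events)
    result.immonly_status = call_mrd_immonly(
        followup, panel, diagnosis, min_events=min_events
    )
    if result.status == "pos":
        result.load_class = classify_load(result)
    return result
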
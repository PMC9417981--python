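"""Synthetic bone-marrow samples with exact ground truth.

The generator emulates the cellular composition a one-tube AML MRD panel
sees in marrow: lymphocytes (with a CD7-strong T-cell fraction),
monocytes, granulocytes, CD34+ progenitors, CD45-negative cells, debris and
doublets, plus — for leukemia-free controls — low-frequency background
aberrancies in each of the 32 monitored subpopulations, and — for patient
samples — leukemic clones with configurable backbone, aberrant categories
and clone fraction.

Every marker intensity is drawn from a truncated normal on the transformed
scale whose truncation interval keeps a guard band of clearance around each
fixed gate threshold (and around the bounding box of the 2-D CD45/SSC
regions).  Within the guard band no event is generated, so the gating
cascade recovers the generator's bookkeeping *exactly*: ground-truth
subpopulation counts equal pipeline tabulation event for event.  Setting the
guard band to zero re-introduces borderline events for robustness testing.

Background aberrancy frequencies follow a zero-inflated lognormal per
subpopulation, with parameters depending on the control subcohort
(ALL molCR carries heavy CD56+/CD13- tails, hip surgery heavy CD33-,
PCNSL is quiet) and on the compartment (higher frequencies outside the
CD34/CD117 immature compartment; very low frequencies in HLA-DR- immature
subpopulations, which are therefore the detectability-limited ones).

All randomness flows from the single explicit seed of each sample spec.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .gating import CATEGORIES, GateConfig
from .panel_io import ANTIBODY_MARKERS, LFC_COHORTS, MARKERS, EventMatrix
from .populations import (
    ALL_SUBPOPULATIONS,
    BACKBONES,
    SubpopulationID,
    backbone_label,
)

#: Guard bands: minimum clearance between any generated value and the
#: nearest gate boundary (transformed units for markers, linear for scatter).
GUARD = 0.05
SSC_GUARD = 5.0
FSC_GUARD = 500.0

#: Default cohort composition of the leukemia-free control set.
DEFAULT_COHORT_MIX: dict[str, int] = {
    "BMD": 30, "ALL_molCR": 19, "hip_surgery": 32, "PCNSL": 9,
}


class SpecError(ValueError):
    """Infeasible or inconsistent sample specification."""


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Exact truncated-normal draws via inverse-CDF on a uniform slice."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if not b > a:
        raise SpecError(
            f"empty truncation interval [{lo}, {hi}] for N({mean}, {sd})"
        )
    u = rng.uniform(a, b, size)
    x = mean + sd * ndtri(u)
    return np.clip(x, lo, hi)


@dataclass(frozen=True)
class MarkerModel:
    """Truncated normal for one marker of one cell population."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return _truncated_normal(rng, self.mean, self.sd, self.lo, self.hi, n)


@dataclass(frozen=True)
class CellPopulationSpec:
    """One constituent population: name, share and per-marker model.

    ``markers`` must cover SSC-A, CD45 and the antibody markers; FSC-A has
    its own model and FSC-H follows FSC-A through the singlet ratio (or the
    fixed doublet ratio 2 when ``is_doublet``).  ``counts_cd45`` says
    whether the population belongs to the CD45+ pool (and hence the
    denominator); ``region`` annotates where the population lives on
    CD45/SSC ("pm", "lymph" or "out").
    """

    name: str
    fraction: float
    markers: Mapping[str, MarkerModel]
    fsc: MarkerModel
    counts_cd45: bool = True
    region: str = "out"
    is_doublet: bool = False
    ratio_jitter: float = 0.06

    def __post_init__(self) -> None:
        needed = set(ANTIBODY_MARKERS) | {"SSC-A"}
        missing = needed - set(self.markers)
        if missing:
            raise SpecError(f"population {self.name}: no model for {missing}")
        if self.fraction < 0:
            raise SpecError(f"population {self.name}: negative fraction")


@dataclass(frozen=True)
class CloneSpec:
    """A leukemic clone: backbone target, aberrant categories, size.

    ``fraction`` is the clone's share of CD45+ events.  CD13neg and CD33neg
    are mutually exclusive: a clone lacking both myeloid markers could never
    pass the CD13/CD33 OR gate, so such a spec is rejected.
    """

    backbone: tuple[bool, bool, bool]
    categories: frozenset[str]
    fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", frozenset(self.categories))
        unknown = self.categories - set(CATEGORIES)
        if unknown:
            raise SpecError(f"unknown aberrant categories {unknown}")
        if {"CD13neg", "CD33neg"} <= self.categories:
            raise SpecError(
                "clone with both CD13neg and CD33neg would fail the "
                "CD13/CD33 OR gate (infeasible myP/M phenotype)"
            )
        if not (0 <= self.fraction < 1):
            raise SpecError("clone fraction must be in [0, 1)")
        if len(self.backbone) != 3:
            raise SpecError("backbone must be (CD34, CD117, HLA-DR) flags")


@dataclass(frozen=True)
class BackgroundParams:
    """Zero-inflated lognormal for one subpopulation's %CD45+ frequency."""

    zero_prob: float
    ln_mean: float   # mean of ln(frequency in %)
    ln_sd: float

    def draw_pct(self, rng: np.random.Generator, cap: float = 3.0) -> float:
        if rng.uniform() < self.zero_prob:
            return 0.0
        return min(float(np.exp(rng.normal(self.ln_mean, self.ln_sd))), cap)


def background_params(sid: SubpopulationID, cohort: str | None) -> BackgroundParams:
    """Cohort- and compartment-dependent background-aberrancy parameters.

    Encodes the qualitative structure of leukemia-free marrow: frequencies
    are zero-heavy; the monopoietic (CD34-CD117-) compartment runs higher
    than the immature compartment; HLA-DR- immature subpopulations are
    rarest; ALL in molecular CR inflates CD56+ and CD13- tails, hip-surgery
    marrow inflates CD33-, PCNSL marrow is quiet.
    """
    zero_prob, ln_mean, ln_sd = 0.60, math.log(0.003), 1.0
    if not sid.immature:
        ln_mean += math.log(12.0)
    elif not sid.hladr:
        zero_prob, ln_mean, ln_sd = 0.80, math.log(0.0008), 0.9
    if cohort == "ALL_molCR" and sid.category in ("CD56pos", "CD13neg"):
        zero_prob = max(zero_prob - 0.35, 0.05)
        ln_mean += math.log(5.0)
        ln_sd = 1.3
    elif cohort == "hip_surgery" and sid.category == "CD33neg":
        zero_prob = max(zero_prob - 0.30, 0.05)
        ln_mean += math.log(4.0)
    elif cohort == "PCNSL":
        zero_prob = min(zero_prob + 0.15, 0.95)
        ln_mean += math.log(0.5)
    return BackgroundParams(zero_prob, ln_mean, ln_sd)


# -- marker-model builders -------------------------------------------------

def _pos(threshold: float, guard: float = GUARD) -> MarkerModel:
    return MarkerModel(threshold + 1.2, 0.40, threshold + guard, threshold + 3.5)


def _neg(threshold: float, guard: float = GUARD) -> MarkerModel:
    return MarkerModel(0.35, 0.25, 0.0, threshold - guard)


def _strong(threshold: float, guard: float = GUARD) -> MarkerModel:
    return MarkerModel(threshold + 0.9, 0.35, threshold + guard, threshold + 3.0)


def _not_strong(threshold: float, guard: float = GUARD) -> MarkerModel:
    return MarkerModel(0.50, 0.35, 0.0, threshold - guard)


def _polygon_box(vertices) -> tuple[float, float, float, float]:
    xs = [v[0] for v in vertices]
    ys = [v[1] for v in vertices]
    return min(xs), max(xs), min(ys), max(ys)


@dataclass(frozen=True)
class _Regions:
    """Guarded CD45/SSC sampling boxes derived from a gate configuration.

    The guard boxes shrink the *bounding box* of each polygon; for the
    default rectangular regions this is exact.  Non-rectangular user gates
    would need population specs placed manually.
    """

    pm_cd45: tuple[float, float]
    pm_ssc: tuple[float, float]
    lymph_cd45: tuple[float, float]
    lymph_ssc: tuple[float, float]
    ssc_min: float
    fsc_min: float
    cd45_threshold: float

    @classmethod
    def from_config(cls, config: GateConfig, guard: float = GUARD) -> "_Regions":
        pm = _polygon_box(config.pm_polygon)
        ly = _polygon_box(config.lymph_polygon)
        return cls(
            pm_cd45=(pm[0] + guard, pm[1] - guard),
            pm_ssc=(pm[2] + SSC_GUARD, pm[3] - SSC_GUARD),
            lymph_cd45=(ly[0] + guard, ly[1] - guard),
            lymph_ssc=(ly[2] + SSC_GUARD, ly[3] - SSC_GUARD),
            ssc_min=config.ssc_min,
            fsc_min=config.fsc_min,
            cd45_threshold=config.cd45_threshold,
        )


def _normal_fsc(r: _Regions) -> MarkerModel:
    return MarkerModel(65000, 9000, r.fsc_min + FSC_GUARD, 260000)


def default_populations(
    config: GateConfig | None = None, guard: float = GUARD
) -> list[CellPopulationSpec]:
    """Leukemia-free marrow constituents consistent with the gate defaults.

    Fractions are shares of the CD45+ pool for the CD45+ populations
    (granulocyte-dominant regenerated marrow) and are normalized at
    generation time after clones and background events take their share.
    """
    config = config or GateConfig()
    t = config.fixed_thresholds
    r = _Regions.from_config(config, guard)
    g = guard

    def boxed(lo_hi, mean, sd):
        return MarkerModel(mean, sd, lo_hi[0], lo_hi[1])

    lymph_base = {
        "SSC-A": boxed(r.lymph_ssc, 140, 45),
        "CD45": boxed(r.lymph_cd45, 4.1, 0.20),
        "CD13": _neg(t["cd13_pos"], g), "CD33": _neg(t["cd33_pos"], g),
        "CD34": _neg(t["cd34_pos"], g), "CD117": _neg(t["cd117_pos"], g),
        "HLA-DR": _neg(t["hladr_pos"], g),
        "CD56": _not_strong(t["cd56_strong"], g),
    }
    return [
        CellPopulationSpec(
            name="lymphocyte_T",
            fraction=0.11,
            markers={**lymph_base, "CD7": _strong(t["cd7_strong"], g)},
            fsc=_normal_fsc(r),
            region="lymph",
        ),
        CellPopulationSpec(
            name="lymphocyte_B",
            fraction=0.17,
            markers={**lymph_base, "CD7": _not_strong(t["cd7_strong"], g)},
            fsc=_normal_fsc(r),
            region="lymph",
        ),
        CellPopulationSpec(
            name="monocyte",
            fraction=0.08,
            markers={
                "SSC-A": boxed(r.pm_ssc, 450, 80),
                "CD45": boxed((max(r.pm_cd45[0], 2.6), r.pm_cd45[1]), 3.0, 0.15),
                "CD13": _pos(t["cd13_pos"], g), "CD33": _pos(t["cd33_pos"], g),
                "CD34": _neg(t["cd34_pos"], g), "CD117": _neg(t["cd117_pos"], g),
                "HLA-DR": _pos(t["hladr_pos"], g),
                "CD7": _not_strong(t["cd7_strong"], g),
                "CD56": _not_strong(t["cd56_strong"], g),
            },
            fsc=_normal_fsc(r),
            region="pm",
        ),
        CellPopulationSpec(
            name="granulocyte",
            fraction=0.56,
            markers={
                "SSC-A": MarkerModel(950, 130, r.pm_ssc[1] + 2 * SSC_GUARD, 2500),
                "CD45": MarkerModel(2.3, 0.2, r.cd45_threshold + g, 5.0),
                "CD13": _pos(t["cd13_pos"], g), "CD33": _pos(t["cd33_pos"], g),
                "CD34": _neg(t["cd34_pos"], g), "CD117": _neg(t["cd117_pos"], g),
                "HLA-DR": _neg(t["hladr_pos"], g),
                "CD7": _not_strong(t["cd7_strong"], g),
                "CD56": _not_strong(t["cd56_strong"], g),
            },
            fsc=_normal_fsc(r),
            region="out",
        ),
        CellPopulationSpec(
            name="progenitor",
            fraction=0.04,
            markers={
                "SSC-A": boxed((r.pm_ssc[0], min(r.pm_ssc[1], 500)), 300, 60),
                "CD45": boxed((r.pm_cd45[0], min(r.pm_cd45[1], 2.8)), 2.2, 0.2),
                "CD13": _pos(t["cd13_pos"], g), "CD33": _pos(t["cd33_pos"], g),
                "CD34": _pos(t["cd34_pos"], g), "CD117": _pos(t["cd117_pos"], g),
                "HLA-DR": _pos(t["hladr_pos"], g),
                "CD7": _not_strong(t["cd7_strong"], g),
                "CD56": _not_strong(t["cd56_strong"], g),
            },
            fsc=_normal_fsc(r),
            region="pm",
        ),
    ]


def _aberrant_markers(
    backbone: tuple[bool, bool, bool],
    categories: frozenset[str],
    config: GateConfig,
    guard: float = GUARD,
) -> dict[str, MarkerModel]:
    """Marker models for a myP/M event with the given phenotype."""
    t = config.fixed_thresholds
    r = _Regions.from_config(config, guard)
    cd34, cd117, hladr = backbone
    return {
        "SSC-A": MarkerModel(250, 60, r.pm_ssc[0], min(r.pm_ssc[1], 500)),
        "CD45": MarkerModel(2.0, 0.2, r.pm_cd45[0], min(r.pm_cd45[1], 2.8)),
        "CD13": _neg(t["cd13_pos"], guard) if "CD13neg" in categories
        else _pos(t["cd13_pos"], guard),
        "CD33": _neg(t["cd33_pos"], guard) if "CD33neg" in categories
        else _pos(t["cd33_pos"], guard),
        "CD34": _pos(t["cd34_pos"], guard) if cd34 else _neg(t["cd34_pos"], guard),
        "CD117": _pos(t["cd117_pos"], guard) if cd117
        else _neg(t["cd117_pos"], guard),
        "HLA-DR": _pos(t["hladr_pos"], guard) if hladr
        else _neg(t["hladr_pos"], guard),
        "CD7": _strong(t["cd7_strong"], guard) if "CD7pos" in categories
        else _not_strong(t["cd7_strong"], guard),
        "CD56": _strong(t["cd56_strong"], guard) if "CD56pos" in categories
        else _not_strong(t["cd56_strong"], guard),
    }


def _non_cd45_populations(
    config: GateConfig, guard: float = GUARD
) -> dict[str, CellPopulationSpec]:
    t = config.fixed_thresholds
    r = _Regions.from_config(config, guard)
    low = {
        "CD13": _neg(t["cd13_pos"], guard), "CD33": _neg(t["cd33_pos"], guard),
        "CD34": _neg(t["cd34_pos"], guard), "CD117": _neg(t["cd117_pos"], guard),
        "HLA-DR": _neg(t["hladr_pos"], guard),
        "CD7": _not_strong(t["cd7_strong"], guard),
        "CD56": _not_strong(t["cd56_strong"], guard),
    }
    return {
        "cd45neg": CellPopulationSpec(
            name="cd45neg",
            fraction=0.0,
            markers={
                **low,
                "SSC-A": MarkerModel(150, 60, r.ssc_min + SSC_GUARD, 800),
                "CD45": MarkerModel(0.3, 0.2, 0.0, r.cd45_threshold - guard),
            },
            fsc=_normal_fsc(r),
            counts_cd45=False,
        ),
        "debris": CellPopulationSpec(
            name="debris",
            fraction=0.0,
            markers={
                **low,
                "SSC-A": MarkerModel(80, 50, 0.0, 800),
                "CD45": MarkerModel(0.4, 0.3, 0.0, 5.0),
            },
            fsc=MarkerModel(7000, 3000, 0.0, r.fsc_min - FSC_GUARD),
            counts_cd45=False,
        ),
        "doublet": CellPopulationSpec(
            name="doublet",
            fraction=0.0,
            markers={
                **low,
                "SSC-A": MarkerModel(300, 120, r.ssc_min + SSC_GUARD, 2000),
                "CD45": MarkerModel(3.5, 0.5, 0.0, 5.0),
            },
            fsc=_normal_fsc(r),
            counts_cd45=False,
            is_doublet=True,
        ),
    }


@dataclass
class SampleSpec:
    """Complete recipe for one synthetic sample.

    500,000 events per sample is the targeted acquisition; the seed is
    mandatory so every sample is exactly reproducible.
    """

    seed: int
    n_events: int = 500_000
    populations: Sequence[CellPopulationSpec] = field(default_factory=tuple)
    clones: Sequence[CloneSpec] = field(default_factory=tuple)
    background_cohort: str | None = None
    doublet_rate: float = 0.02
    debris_rate: float = 0.03
    cd45neg_rate: float = 0.05
    guard: float = GUARD
    sample_id: str = "synthetic"
    sample_kind: str = "lfc"
    cohort_label: str | None = None

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise SpecError("n_events must be >= 1")
        if self.seed is None:
            raise SpecError("a seed is mandatory")
        if not self.populations:
            self.populations = tuple(default_populations(guard=self.guard))


@dataclass
class SampleTruth:
    """Generator bookkeeping for one sample: the gating oracle."""

    sample_id: str
    n_events: int
    n_cd45: int
    component: np.ndarray                       # per-event origin name
    main_counts: dict[tuple[bool, bool, bool], int]
    subpop_counts: dict[SubpopulationID, int]
    clone_counts: list[int]
    background_counts: dict[SubpopulationID, int]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_events": self.n_events,
            "n_cd45": self.n_cd45,
            "main_counts": {
                backbone_label(b): c for b, c in self.main_counts.items()
            },
            "subpop_counts": {
                s.label: c for s, c in self.subpop_counts.items()
            },
            "clone_counts": list(self.clone_counts),
            "background_counts": {
                s.label: c for s, c in self.background_counts.items()
            },
        }


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic integer split of `total` proportional to `weights`."""
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def _sample_block(
    rng: np.random.Generator, pop: CellPopulationSpec, n: int
) -> np.ndarray:
    """Draw n events for one population, in canonical marker order."""
    block = np.empty((n, len(MARKERS)))
    fsc_a = pop.fsc.sample(rng, n)
    if pop.is_doublet:
        fsc_h = fsc_a / 2.0
    else:
        jitter = _truncated_normal(
            rng, 0.0, pop.ratio_jitter, -0.25, 0.25, n
        )
        fsc_h = fsc_a / (1.0 + jitter)
    block[:, MARKERS.index("FSC-A")] = fsc_a
    block[:, MARKERS.index("FSC-H")] = fsc_h
    for name, model in pop.markers.items():
        block[:, MARKERS.index(name)] = model.sample(rng, n)
    return block


def generate_sample(
    spec: SampleSpec, config: GateConfig | None = None
) -> tuple[EventMatrix, SampleTruth]:
    """Draw one sample and its exact ground truth.

    ``config`` anchors the guard bands of clone and background phenotypes
    (defaults to the default gate configuration; it must match the
    configuration later used for gating if exact truth equality is wanted).
    """
    config = config or GateConfig()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events

    extras = _non_cd45_populations(config, spec.guard)
    n_doublet = int(round(n * spec.doublet_rate))
    n_debris = int(round(n * spec.debris_rate))
    n_cd45neg = int(round(n * spec.cd45neg_rate))
    n_cd45_pool = n - n_doublet - n_debris - n_cd45neg
    if n_cd45_pool < 1:
        raise SpecError("rates leave no CD45+ events")

    clone_counts = [int(round(n_cd45_pool * c.fraction)) for c in spec.clones]

    background_counts: dict[SubpopulationID, int] = {}
    if spec.background_cohort is not None:
        for sid in ALL_SUBPOPULATIONS:
            params = background_params(sid, spec.background_cohort)
            f = params.draw_pct(rng)
            count = int(rng.binomial(n_cd45_pool, f / 100.0)) if f > 0 else 0
            if count:
                background_counts[sid] = count

    n_taken = sum(clone_counts) + sum(background_counts.values())
    n_normal = n_cd45_pool - n_taken
    if n_normal < 0:
        raise SpecError(
            "clones plus background aberrancy exceed the CD45+ pool"
        )
    fractions = np.array([p.fraction for p in spec.populations], dtype=float)
    if fractions.sum() <= 0:
        raise SpecError("normal population fractions must sum to > 0")
    normal_counts = _largest_remainder(n_normal, fractions)

    # -- draw blocks ------------------------------------------------------
    blocks: list[np.ndarray] = []
    names: list[str] = []
    sizes: list[int] = []

    def add(pop: CellPopulationSpec, count: int, name: str | None = None):
        if count == 0:
            return
        blocks.append(_sample_block(rng, pop, count))
        names.append(name or pop.name)
        sizes.append(count)

    add(extras["doublet"], n_doublet)
    add(extras["debris"], n_debris)
    add(extras["cd45neg"], n_cd45neg)
    for pop, count in zip(spec.populations, normal_counts):
        add(pop, int(count))
    for i, (clone, count) in enumerate(zip(spec.clones, clone_counts)):
        pop = CellPopulationSpec(
            name=f"clone_{i}",
            fraction=0.0,
            markers=_aberrant_markers(
                clone.backbone, clone.categories, config, spec.guard
            ),
            fsc=_normal_fsc(_Regions.from_config(config, spec.guard)),
            region="pm",
        )
        add(pop, count)
    for sid, count in background_counts.items():
        pop = CellPopulationSpec(
            name=f"background_{sid.label}",
            fraction=0.0,
            markers=_aberrant_markers(
                sid.backbone, frozenset({sid.category}), config, spec.guard
            ),
            fsc=_normal_fsc(_Regions.from_config(config, spec.guard)),
            region="pm",
        )
        add(pop, count)

    values = np.concatenate(blocks, axis=0) if blocks else np.empty((0, 11))
    component = np.repeat(np.array(names, dtype=object), sizes)
    order = rng.permutation(values.shape[0])
    values = values[order]
    component = component[order]

    # -- ground truth ------------------------------------------------------
    main_counts = {b: 0 for b in BACKBONES}
    subpop_counts = {s: 0 for s in ALL_SUBPOPULATIONS}
    for pop, count in zip(spec.populations, normal_counts):
        if pop.region == "pm" and count:
            # normal P/M constituents express CD13/CD33 and count as myP/M
            backbone = _normal_backbone(pop, config)
            main_counts[backbone] += int(count)
    for clone, count in zip(spec.clones, clone_counts):
        main_counts[tuple(clone.backbone)] += count
        for category in clone.categories:
            subpop_counts[
                SubpopulationID(*clone.backbone, category)
            ] += count
    for sid, count in background_counts.items():
        main_counts[sid.backbone] += count
        subpop_counts[sid] += count

    truth = SampleTruth(
        sample_id=spec.sample_id,
        n_events=values.shape[0],
        n_cd45=n_cd45_pool,
        component=component,
        main_counts=main_counts,
        subpop_counts=subpop_counts,
        clone_counts=clone_counts,
        background_counts=background_counts,
    )
    events = EventMatrix(
        values,
        sample_id=spec.sample_id,
        sample_kind=spec.sample_kind,
        cohort_label=spec.cohort_label,
    )
    return events, truth


def _normal_backbone(
    pop: CellPopulationSpec, config: GateConfig
) -> tuple[bool, bool, bool]:
    """Backbone a normal P/M population's marker models imply."""
    t = config.fixed_thresholds
    return (
        pop.markers["CD34"].lo >= t["cd34_pos"],
        pop.markers["CD117"].lo >= t["cd117_pos"],
        pop.markers["HLA-DR"].lo >= t["hladr_pos"],
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_lfc_cohort(
    n_samples: int = 90,
    cohort_mix: Mapping[str, int] | None = None,
    seed: int = 0,
    config: GateConfig | None = None,
    n_events: int = 500_000,
) -> list[tuple[EventMatrix, SampleTruth]]:
    """Generate a leukemia-free control cohort with labelled subcohorts.

    The default mix reproduces a 30/19/32/9 BMD / ALL molCR / hip surgery /
    PCNSL composition, rescaled proportionally when ``n_samples`` differs
    from 90.
    """
    mix = dict(cohort_mix or DEFAULT_COHORT_MIX)
    unknown = set(mix) - set(LFC_COHORTS)
    if unknown:
        raise SpecError(f"unknown control cohorts {unknown}")
    if n_samples < 5:
        warnings.warn(
            f"very small control cohort (n={n_samples}); reference values "
            "will be unstable",
            stacklevel=2,
        )
    weights = np.array([mix.get(c, 0) for c in LFC_COHORTS], dtype=float)
    counts = _largest_remainder(n_samples, weights)
    labels = [
        c for c, k in zip(LFC_COHORTS, counts) for _ in range(int(k))
    ]
    seeds = _child_seeds(seed, n_samples)
    out = []
    for i, (label, s) in enumerate(zip(labels, seeds)):
        spec = SampleSpec(
            seed=int(s),
            n_events=n_events,
            background_cohort=label,
            sample_id=f"lfc_{i:03d}",
            sample_kind="lfc",
            cohort_label=label,
        )
        out.append(generate_sample(spec, config))
    return out


def generate_patient_pair(
    diagnosis_clone: CloneSpec,
    residual_fraction: float,
    phenotype_shift: frozenset[str] | set[str] | None = None,
    seed: int = 0,
    config: GateConfig | None = None,
    n_events: int = 500_000,
    background_cohort: str | None = None,
    sample_id: str = "patient",
) -> tuple[
    tuple[EventMatrix, SampleTruth], tuple[EventMatrix, SampleTruth]
]:
    """A diagnosis sample and its post-induction follow-up.

    The follow-up carries the diagnostic clone scaled to
    ``residual_fraction`` of CD45+ events; ``phenotype_shift`` replaces the
    clone's aberrant categories at follow-up to exercise ptDfN calls.  A
    residual fraction of 0 produces a leukemia-free follow-up.
    """
    if not (0 <= residual_fraction < 1):
        raise SpecError("residual_fraction must be in [0, 1)")
    dx_seed, fu_seed = (int(s) for s in _child_seeds(seed, 2))
    dx_spec = SampleSpec(
        seed=dx_seed,
        n_events=n_events,
        clones=(diagnosis_clone,),
        background_cohort=background_cohort,
        sample_id=f"{sample_id}_dx",
        sample_kind="diagnosis",
    )
    fu_categories = (
        frozenset(phenotype_shift)
        if phenotype_shift is not None
        else diagnosis_clone.categories
    )
    fu_clones: tuple[CloneSpec, ...] = ()
    if residual_fraction > 0:
        fu_clones = (
            replace(
                diagnosis_clone,
                categories=fu_categories,
                fraction=residual_fraction,
            ),
        )
    fu_spec = SampleSpec(
        seed=fu_seed,
        n_events=n_events,
        clones=fu_clones,
        background_cohort=background_cohort,
        sample_id=f"{sample_id}_fu",
        sample_kind="followup",
    )
    return generate_sample(dx_spec, config), generate_sample(fu_spec, config)
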
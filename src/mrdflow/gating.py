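"""Hierarchical gating cascade with fixed marker gates.

The cascade reproduces a standardized LAIP-based different-from-normal
workflow: doublet and debris exclusion, CD45+ leukocytes, the two
*individual* (per-sample adjustable) regions on CD45/SSC — progenitors +
monocytes (P/M) and lymphocytes — then the *fixed* gates: the myeloid
requirement (CD13 and/or CD33, "myP/M"), the backbone split by CD34 / CD117 /
HLA-DR into 8 main populations, and the four aberrant categories (deficiency
of CD13 or CD33, strong cross-lineage CD7 or CD56).

Conventions (documented because the source workflow leaves them open):

* every threshold test is inclusive: value >= cutoff counts as positive;
* events on a polygon boundary are inside (closed-region convention);
* doublets are removed by a bound on the deviation of FSC-A/FSC-H from
  unity, and events with
  FSC-H = 0 are always removed;
* deficiency reuses the positivity cutoffs (CD13 < cd13_pos means CD13
  deficient: true absence, not dim expression), while cross-lineage
  aberrancy uses separate, higher "strong" cutoffs for CD7/CD56.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .panel_io import EventMatrix

#: Aberrant categories in canonical (tie-break) order.
CATEGORIES: tuple[str, ...] = ("CD13neg", "CD33neg", "CD7pos", "CD56pos")

#: Threshold names and the marker + direction each one cuts.
FIXED_THRESHOLD_NAMES: tuple[str, ...] = (
    "cd13_pos", "cd33_pos", "cd34_pos", "cd117_pos",
    "hladr_pos", "cd7_strong", "cd56_strong",
)

_DEFAULT_PM = ((1.60, 30.0), (3.45, 30.0), (3.45, 650.0), (1.60, 650.0))
_DEFAULT_LYMPH = ((3.55, 30.0), (4.80, 30.0), (4.80, 300.0), (3.55, 300.0))


class GateConfigError(ValueError):
    """Inconsistent or degenerate gate configuration."""


class NonEvaluableSampleError(ValueError):
    """The sample has no CD45+ events and cannot be evaluated."""


@dataclass(frozen=True)
class GateConfig:
    """Adjustable pre-gates plus the seven fixed marker thresholds.

    Polygons are vertex lists in (CD45, SSC-A) space on the transformed
    scale; the seven fixed thresholds are scalar cutoffs on the transformed
    scale.  Only the pre-gates (doublet/debris bounds, CD45 cutoff and the
    two polygons) are meant to be adjusted per laboratory or per sample; the
    fixed thresholds define the standardized part of the strategy and stay
    constant across samples.
    """

    schema_version: str = "mrdflow-gates/1"
    doublet_ratio_tolerance: float = 0.30
    fsc_min: float = 15000.0
    ssc_min: float = 10.0
    cd45_threshold: float = 1.0
    pm_polygon: tuple[tuple[float, float], ...] = _DEFAULT_PM
    lymph_polygon: tuple[tuple[float, float], ...] = _DEFAULT_LYMPH
    cd13_pos: float = 1.5
    cd33_pos: float = 1.5
    cd34_pos: float = 1.5
    cd117_pos: float = 1.5
    hladr_pos: float = 1.5
    cd7_strong: float = 2.5
    cd56_strong: float = 2.5

    def __post_init__(self) -> None:
        scalars = (
            self.doublet_ratio_tolerance, self.fsc_min, self.ssc_min,
            self.cd45_threshold, *(getattr(self, n) for n in FIXED_THRESHOLD_NAMES),
        )
        if not np.isfinite(scalars).all():
            raise GateConfigError("all gate thresholds must be finite")
        if self.doublet_ratio_tolerance < 0:
            raise GateConfigError("doublet ratio tolerance must be >= 0")
        pm = _as_polygon(self.pm_polygon, "pm_polygon")
        ly = _as_polygon(self.lymph_polygon, "lymph_polygon")
        if pm.intersection(ly).area > 1e-12:
            raise GateConfigError("pm_polygon and lymph_polygon must be disjoint")

    @property
    def fixed_thresholds(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FIXED_THRESHOLD_NAMES}

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pm_polygon"] = [list(v) for v in self.pm_polygon]
        d["lymph_polygon"] = [list(v) for v in self.lymph_polygon]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateConfig":
        d = dict(d)
        for key in ("pm_polygon", "lymph_polygon"):
            if key in d:
                d[key] = tuple(tuple(float(x) for x in v) for v in d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON rendering; audits gate fixation."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _as_polygon(vertices, name: str) -> Polygon:
    if len(vertices) < 3:
        raise GateConfigError(f"{name} needs at least 3 vertices")
    poly = Polygon(vertices)
    if (not poly.is_valid) or poly.area <= 0:
        raise GateConfigError(f"{name} is degenerate or self-intersecting")
    return poly


def _in_polygon(x: np.ndarray, y: np.ndarray, vertices, name: str) -> np.ndarray:
    # shapely `intersects` includes the boundary: closed-region convention
    return shapely.intersects_xy(_as_polygon(vertices, name), x, y)


# -- cascade steps ---------------------------------------------------------

def exclude_doublets(events: EventMatrix, config: GateConfig) -> np.ndarray:
    """Singlet mask: |FSC-A/FSC-H - 1| <= tolerance; FSC-H = 0 excluded."""
    fsc_a, fsc_h = events.marker("FSC-A"), events.marker("FSC-H")
    ok = fsc_h > 0
    ratio = np.divide(fsc_a, fsc_h, out=np.full_like(fsc_a, np.inf), where=ok)
    return ok & (np.abs(ratio - 1.0) <= config.doublet_ratio_tolerance)


def exclude_debris(events: EventMatrix, config: GateConfig) -> np.ndarray:
    """Non-debris mask: FSC-A >= fsc_min and SSC-A >= ssc_min."""
    return (events.marker("FSC-A") >= config.fsc_min) & (
        events.marker("SSC-A") >= config.ssc_min
    )


def gate_cd45_leukocytes(
    events: EventMatrix, config: GateConfig, base_mask: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """CD45+ leukocyte mask among singlet non-debris events, and N_CD45.

    N_CD45 is the denominator for every subpopulation percentage.  A zero
    count does not raise here; the sample is flagged non-evaluable when the
    denominator is actually used (tabulation).
    """
    if base_mask is None:
        base_mask = exclude_doublets(events, config) & exclude_debris(events, config)
    mask = base_mask & (events.marker("CD45") >= config.cd45_threshold)
    return mask, int(mask.sum())


def gate_pm_lymph(
    events: EventMatrix, config: GateConfig, cd45_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Progenitor/monocyte and lymphocyte masks on (CD45, SSC-A)."""
    cd45, ssc = events.marker("CD45"), events.marker("SSC-A")
    pm = cd45_mask & _in_polygon(cd45, ssc, config.pm_polygon, "pm_polygon")
    ly = cd45_mask & _in_polygon(cd45, ssc, config.lymph_polygon, "lymph_polygon")
    return pm, ly


def gate_mypm(
    events: EventMatrix, config: GateConfig, pm_mask: np.ndarray
) -> np.ndarray:
    """Myeloid P/M: P/M events expressing CD13 and/or CD33."""
    myeloid = (events.marker("CD13") >= config.cd13_pos) | (
        events.marker("CD33") >= config.cd33_pos
    )
    return pm_mask & myeloid


def assign_backbone(events: EventMatrix, config: GateConfig) -> np.ndarray:
    """Backbone code per event: 4*CD34+ + 2*CD117+ + HLA-DR+ (0..7).

    Codes are computed for all events but only meaningful on myP/M events.
    """
    cd34 = events.marker("CD34") >= config.cd34_pos
    cd117 = events.marker("CD117") >= config.cd117_pos
    hladr = events.marker("HLA-DR") >= config.hladr_pos
    return (cd34.astype(np.int8) << 2) | (cd117.astype(np.int8) << 1) | hladr


def assign_categories(
    events: EventMatrix, config: GateConfig
) -> dict[str, np.ndarray]:
    """Aberrant-category flags per event (meaningful on myP/M events only).

    An event may carry several categories at once, or none.  CD13neg and
    CD33neg can never co-occur on a myP/M event — such an event would have
    failed the CD13/CD33 OR gate.
    """
    return {
        "CD13neg": events.marker("CD13") < config.cd13_pos,
        "CD33neg": events.marker("CD33") < config.cd33_pos,
        "CD7pos": events.marker("CD7") >= config.cd7_strong,
        "CD56pos": events.marker("CD56") >= config.cd56_strong,
    }


@dataclass
class EventLabels:
    """Per-event results of the full cascade for one sample."""

    singlet: np.ndarray
    non_debris: np.ndarray
    cd45: np.ndarray
    pm: np.ndarray
    lymph: np.ndarray
    mypm: np.ndarray
    backbone: np.ndarray          # int8 code, meaningful on myP/M events
    categories: dict[str, np.ndarray]
    n_cd45: int

    @property
    def evaluable(self) -> bool:
        return self.n_cd45 > 0


def label_events(events: EventMatrix, config: GateConfig) -> EventLabels:
    """Run the whole hierarchy; deterministic in events and config."""
    singlet = exclude_doublets(events, config)
    non_debris = exclude_debris(events, config)
    cd45_mask, n_cd45 = gate_cd45_leukocytes(events, config, singlet & non_debris)
    pm, lymph = gate_pm_lymph(events, config, cd45_mask)
    mypm = gate_mypm(events, config, pm)
    backbone = assign_backbone(events, config)
    categories = assign_categories(events, config)
    return EventLabels(
        singlet=singlet,
        non_debris=non_debris,
        cd45=cd45_mask,
        pm=pm,
        lymph=lymph,
        mypm=mypm,
        backbone=backbone,
        categories=categories,
        n_cd45=n_cd45,
    )
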
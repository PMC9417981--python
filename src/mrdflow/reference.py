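"""Reference values from leukemia-free controls.

For each of the 32 aberrant subpopulations the reference value is the upper
limit of the one-sided 97.5% reference range of its %CD45+ frequency across
a cohort of leukemia-free control samples.  The estimator is nonparametric
(quantile of the per-sample frequencies, linear interpolation between order
statistics by default): aberrant-subpopulation frequencies are zero-inflated
and strongly skewed, so Gaussian reference limits would be indefensible.

Each reference value is attributed to the control subcohort that drives it:
the cohort of the sample whose frequency is the quantile-determining order
statistic (nearest above or equal to the interpolated quantile).  Ties
across cohorts are broken lexicographically and flagged.

Because MRD calling requires at least 20 events in a subpopulation, a
subpopulation with a very low reference value can only turn positive when
enough CD45+ events were acquired: with reference r (% of CD45+), at least
ceil(20 / (r/100)) CD45+ events are needed — 2,000,000 for r = 0.001%.
:func:`detectability` makes that limit explicit per subpopulation.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .populations import ALL_SUBPOPULATIONS, SubpopulationID, SubpopulationTable

DEFAULT_QUANTILE = 0.975


class ReferenceEstimationError(ValueError):
    """Too few control samples, or inconsistent inputs."""


@dataclass(frozen=True)
class ReferenceValue:
    ref_pct: float
    driving_cohort: str
    tie: bool = False


@dataclass
class ReferencePanel:
    """32 upper reference limits (%CD45+) with cohort attribution."""

    values: dict[SubpopulationID, ReferenceValue]
    n_controls: int
    quantile: float = DEFAULT_QUANTILE
    method: str = "linear"

    def __post_init__(self) -> None:
        missing = [s for s in ALL_SUBPOPULATIONS if s not in self.values]
        if missing:
            raise ReferenceEstimationError(
                f"reference panel incomplete: missing {missing[0].label}"
            )
        for sid, rv in self.values.items():
            if not (rv.ref_pct >= 0):
                raise ReferenceEstimationError(
                    f"negative reference for {sid.label}"
                )

    def __getitem__(self, sid: SubpopulationID) -> ReferenceValue:
        return self.values[sid]

    def ref_pct(self, sid: SubpopulationID) -> float:
        return self.values[sid].ref_pct

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": "mrdflow-reference/1",
            "n_controls": self.n_controls,
            "quantile": self.quantile,
            "method": self.method,
            "values": {
                sid.label: {
                    "ref_pct": self.values[sid].ref_pct,
                    "driving_cohort": self.values[sid].driving_cohort,
                    "tie": self.values[sid].tie,
                }
                for sid in ALL_SUBPOPULATIONS
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "ReferencePanel":
        values = {
            SubpopulationID.from_label(label): ReferenceValue(
                ref_pct=float(v["ref_pct"]),
                driving_cohort=str(v["driving_cohort"]),
                tie=bool(v.get("tie", False)),
            )
            for label, v in d["values"].items()
        }
        return cls(
            values=values,
            n_controls=int(d["n_controls"]),
            quantile=float(d.get("quantile", DEFAULT_QUANTILE)),
            method=str(d.get("method", "linear")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePanel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def reference_quantile(
    values, quantile: float = DEFAULT_QUANTILE, method: str = "linear"
) -> float:
    """Upper limit of the one-sided reference range for one subpopulation.

    Nonparametric quantile of the per-sample frequencies; ``method`` is any
    quantile method accepted by :func:`numpy.quantile` (linear interpolation
    between order statistics by default).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(np.asarray(values, dtype=float), quantile, method=method))


def _attribute(
    pcts: np.ndarray, cohorts: Sequence[str], ref_pct: float
) -> tuple[str, bool]:
    """Cohort of the quantile-determining order statistic.

    The determining sample is the one with the smallest frequency >= the
    interpolated quantile (with interpolation the quantile never exceeds the
    maximum, so a candidate always exists).  When samples from several
    cohorts sit exactly on that frequency the lexicographically first cohort
    is reported and the tie flagged.
    """
    above = pcts >= ref_pct - 1e-12
    determining = pcts[above].min()
    at = np.abs(pcts - determining) <= 1e-12
    labels = sorted({cohorts[i] for i in np.flatnonzero(at)})
    return labels[0], len(labels) > 1


def estimate_reference(
    controls: Sequence[SubpopulationTable],
    quantile: float = DEFAULT_QUANTILE,
    method: str = "linear",
    min_samples: int = 2,
) -> ReferencePanel:
    """Estimate the 32 reference values from leukemia-free control tables.

    Cohort labels are taken from each table's ``cohort_label`` (missing
    labels become ``"unknown"`` with a warning).  Deterministic given the
    inputs.
    """
    controls = [t for t in controls if t.n_cd45 > 0]
    if len(controls) < min_samples:
        raise ReferenceEstimationError(
            f"need at least {min_samples} evaluable control samples, "
            f"got {len(controls)}"
        )
    cohorts = []
    for t in controls:
        if t.cohort_label is None:
            warnings.warn(
                f"control sample {t.sample_id!r} has no cohort label",
                stacklevel=2,
            )
        cohorts.append(t.cohort_label or "unknown")

    values: dict[SubpopulationID, ReferenceValue] = {}
    for sid in ALL_SUBPOPULATIONS:
        pcts = np.array([t.pct(sid) for t in controls], dtype=float)
        ref = reference_quantile(pcts, quantile, method)
        cohort, tie = _attribute(pcts, cohorts, ref)
        values[sid] = ReferenceValue(ref_pct=ref, driving_cohort=cohort, tie=tie)
    return ReferencePanel(
        values=values, n_controls=len(controls), quantile=quantile, method=method
    )


def attribute_cohorts(
    controls: Sequence[SubpopulationTable], panel: ReferencePanel
) -> dict[SubpopulationID, str]:
    """Re-derive the driving cohort for each subpopulation of a panel."""
    cohorts = [t.cohort_label or "unknown" for t in controls]
    out = {}
    for sid in ALL_SUBPOPULATIONS:
        pcts = np.array([t.pct(sid) for t in controls], dtype=float)
        out[sid], _ = _attribute(pcts, cohorts, panel.ref_pct(sid))
    return out


def min_cd45_required(ref_pct: float, min_events: int = 20) -> int:
    """CD45+ events needed so a subpopulation at its reference value yields
    at least ``min_events`` events.

    ``ref_pct`` is in % of CD45+; a zero reference needs only ``min_events``
    events (any exceedance is then driven by the event count itself).
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if ref_pct < 0:
        raise ValueError("ref_pct must be >= 0")
    if ref_pct == 0:
        return min_events
    # tiny slack guards the ceil against float rounding of exact ratios
    return math.ceil(min_events * 100.0 / ref_pct - 1e-9)


@dataclass(frozen=True)
class DetectabilityRecord:
    min_required: int
    evaluable: bool


def detectability(
    panel: ReferencePanel, n_acquired: int, min_events: int = 20
) -> dict[SubpopulationID, DetectabilityRecord]:
    """Flag subpopulations whose reference is too low to be reliably
    evaluable at the acquired CD45+ event count."""
    out = {}
    for sid in ALL_SUBPOPULATIONS:
        req = min_cd45_required(panel.ref_pct(sid), min_events)
        out[sid] = DetectabilityRecord(
            min_required=req, evaluable=n_acquired >= req
        )
    return out
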
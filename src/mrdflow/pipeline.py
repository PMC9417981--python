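"""End-to-end composition: gating -> tabulation -> MRD calling -> report.

The report is a versioned JSON document in which every number is traceable
to a module output and which embeds content hashes of the gate
configuration and the reference panel, so that the fixation of gates and
references — the core of the standardization claim — is auditable per
sample.  Rendering is deterministic: identical inputs produce
byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from . import __version__
from .gating import CATEGORIES, GateConfig, label_events
from .mrd import (
    DEFAULT_ALAIP_THRESHOLD,
    DEFAULT_MIN_EVENTS,
    DiagnosisProfile,
    MRDResult,
    assess,
    detect_alaip,
)
from .panel_io import EventMatrix, TransformSpec
from .populations import (
    ALL_SUBPOPULATIONS,
    BACKBONES,
    SubpopulationTable,
    backbone_label,
    tabulate,
)
from .reference import ReferencePanel

REPORT_SCHEMA = "mrdflow-report/1"
REPORT_PCT_DECIMALS = 4


@dataclass
class MRDReport:
    """Structured MRD report for one follow-up sample."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = self.data
        mrd = d["mrd"]
        lines = [
            f"MRD report ({d['schema_version']})",
            f"sample: {d['sample']['sample_id']}",
            (
                "gating: {n_events} events, {n_singlet} singlets, "
                "{n_cd45} CD45+, {n_pm} P/M, {n_mypm} myP/M"
            ).format(**d["gating"]),
            f"MRD status: {mrd['status'].upper()}"
            + (
                f"  (load {mrd['mrd_load']:.4f}% via {mrd['load_category']},"
                f" {mrd['load_class']}, origin {mrd['origin']})"
                if mrd["status"] == "pos"
                else ""
            ),
            f"ELN scheme: {mrd['eln_status']}; "
            f"ImmOnly scheme: {mrd['immonly_status']}",
        ]
        positives = mrd["positive_subpopulations"]
        if positives:
            lines.append("positive subpopulations (pct > reference):")
            for p in positives:
                lines.append(
                    f"  {p['subpopulation']}: {p['pct']:.4f}% "
                    f"(ref {p['ref_pct']:.4f}%, burden {p['burden']:.4f})"
                )
        return "\n".join(lines)


def _subpop_rows(
    table: SubpopulationTable,
    panel: ReferencePanel,
    min_events: int,
) -> list[dict]:
    rows = []
    for sid in ALL_SUBPOPULATIONS:
        count = table.subpop_counts[sid]
        pct = table.pct(sid)
        ref = panel.ref_pct(sid)
        rows.append(
            {
                "subpopulation": sid.label,
                "category": sid.category,
                "immature": sid.immature,
                "count": count,
                "pct": round(pct, REPORT_PCT_DECIMALS),
                "ref_pct": round(ref, REPORT_PCT_DECIMALS),
                "burden": round(max(pct - ref, 0.0), REPORT_PCT_DECIMALS),
                "evaluable": count >= min_events,
            }
        )
    return rows


def run_pipeline(
    events: EventMatrix,
    gate_config: GateConfig,
    panel: ReferencePanel,
    diagnosis_events: EventMatrix | None = None,
    transform: TransformSpec | None = None,
    min_events: int = DEFAULT_MIN_EVENTS,
    alaip_threshold: float = DEFAULT_ALAIP_THRESHOLD,
) -> MRDReport:
    """Run the full analysis on one follow-up sample.

    An optional diagnosis sample is gated with the same configuration to
    derive the aLAIP profile used for origin classification.
    """
    if transform is not None:
        events = transform.apply(events)
        if diagnosis_events is not None:
            diagnosis_events = transform.apply(diagnosis_events)

    labels = label_events(events, gate_config)
    table = tabulate(labels, sample_id=events.sample_id)

    profile: DiagnosisProfile | None = None
    if diagnosis_events is not None:
        dx_labels = label_events(diagnosis_events, gate_config)
        dx_table = tabulate(dx_labels, sample_id=diagnosis_events.sample_id)
        profile = detect_alaip(dx_table, threshold_pct=alaip_threshold)

    result = assess(table, panel, profile, min_events=min_events)
    report = _build_report(
        events, labels, table, panel, gate_config, result, profile, min_events
    )
    return report


def _build_report(
    events, labels, table, panel, gate_config, result: MRDResult, profile,
    min_events: int,
) -> MRDReport:
    data = {
        "schema_version": REPORT_SCHEMA,
        "sample": {
            "sample_id": events.sample_id,
            "sample_kind": events.sample_kind,
            "cohort_label": events.cohort_label,
        },
        "gating": {
            "n_events": int(events.n_events),
            "n_singlet": int(labels.singlet.sum()),
            "n_non_debris": int((labels.singlet & labels.non_debris).sum()),
            "n_cd45": int(labels.n_cd45),
            "n_pm": int(labels.pm.sum()),
            "n_lymph": int(labels.lymph.sum()),
            "n_mypm": int(labels.mypm.sum()),
        },
        "main_populations": [
            {
                "population": backbone_label(b),
                "count": table.main_counts[b],
                "pct": round(table.main_pct(b), REPORT_PCT_DECIMALS),
            }
            for b in BACKBONES
        ],
        "subpopulations": _subpop_rows(table, panel, min_events),
        "mrd": {
            "status": result.status,
            "mrd_load": round(result.mrd_load, REPORT_PCT_DECIMALS),
            "load_category": result.load_category,
            "load_tie": result.load_tie,
            "load_class": result.load_class,
            "origin": result.origin,
            "eln_status": result.eln_status,
            "immonly_status": result.immonly_status,
            "min_events": result.min_events,
            "category_sums": {
                c: round(result.category_sums[c], REPORT_PCT_DECIMALS)
                for c in CATEGORIES
            },
            "positive_subpopulations": [
                {
                    "subpopulation": p.sid.label,
                    "count": p.count,
                    "pct": round(p.pct, REPORT_PCT_DECIMALS),
                    "ref_pct": round(p.ref_pct, REPORT_PCT_DECIMALS),
                    "burden": round(p.burden, REPORT_PCT_DECIMALS),
                }
                for p in result.positive_subpops
            ],
            "n_non_evaluable_subpopulations": len(result.non_evaluable_subpops),
            "alaip_set": (
                sorted(profile.alaip_set) if profile is not None else None
            ),
        },
        "provenance": {
            "package_version": __version__,
            "gate_config_sha256": gate_config.content_hash(),
            "reference_panel_sha256": panel.content_hash(),
        },
    }
    return MRDReport(data)
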
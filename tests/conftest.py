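"""Shared fixtures: gate config, a small control cohort, builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrdflow.gating import GateConfig, label_events
from mrdflow.populations import (
    ALL_SUBPOPULATIONS,
    BACKBONES,
    SubpopulationID,
    SubpopulationTable,
    tabulate,
)
from mrdflow.reference import ReferencePanel, ReferenceValue, estimate_reference
from mrdflow.synthetic import generate_lfc_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> GateConfig:
    return GateConfig()


@pytest.fixture(scope="session")
def lfc_cohort(config):
    """20 leukemia-free control samples at 60k events (compact cohort)."""
    return generate_lfc_cohort(
        n_samples=20, seed=20260925, config=config, n_events=60_000
    )


@pytest.fixture(scope="session")
def lfc_tables(config, lfc_cohort):
    return [
        tabulate(
            label_events(ev, config),
            sample_id=ev.sample_id,
            cohort_label=ev.cohort_label,
        )
        for ev, _ in lfc_cohort
    ]


@pytest.fixture(scope="session")
def reference_panel(lfc_tables) -> ReferencePanel:
    return estimate_reference(lfc_tables)


def make_table(
    n_cd45: int,
    subpop_counts: dict[SubpopulationID, int] | None = None,
    extra_mypm: int = 0,
    sample_id: str = "fixture",
    cohort_label: str | None = None,
) -> SubpopulationTable:
    """Build a population table directly from intended subpopulation counts.

    Each supplied count is treated as a distinct set of single-category
    events, so the backbone main counts are the per-backbone sums (plus
    ``extra_mypm`` normal myP/M events on the all-positive backbone).
    """
    subpop_counts = dict(subpop_counts or {})
    main = {b: 0 for b in BACKBONES}
    for sid, count in subpop_counts.items():
        main[sid.backbone] += count
    main[BACKBONES[0]] += extra_mypm
    return SubpopulationTable(
        n_cd45=n_cd45,
        n_mypm=sum(main.values()),
        main_counts=main,
        subpop_counts=subpop_counts,
        sample_id=sample_id,
        cohort_label=cohort_label,
    )


def make_panel(
    ref_pct: float = 0.001, overrides: dict[SubpopulationID, float] | None = None
) -> ReferencePanel:
    """Constant reference panel with optional per-subpopulation overrides."""
    overrides = overrides or {}
    values = {
        sid: ReferenceValue(
            ref_pct=float(overrides.get(sid, ref_pct)), driving_cohort="BMD"
        )
        for sid in ALL_SUBPOPULATIONS
    }
    return ReferencePanel(values=values, n_controls=1)
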
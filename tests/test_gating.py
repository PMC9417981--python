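"""Gating cascade: exclusion gates, polygon gates, fixed thresholds."""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
import pytest

from mrdflow.gating import (
    GateConfig,
    GateConfigError,
    assign_backbone,
    assign_categories,
    exclude_debris,
    exclude_doublets,
    gate_cd45_leukocytes,
    gate_mypm,
    gate_pm_lymph,
    label_events,
)
from mrdflow.panel_io import MARKERS, EventMatrix
from mrdflow.synthetic import CloneSpec, SampleSpec, generate_sample


def events_from(rows: list[dict]) -> EventMatrix:
    """EventMatrix from sparse per-event marker dicts (rest defaults)."""
    defaults = {"FSC-A": 60000.0, "FSC-H": 60000.0, "SSC-A": 200.0}
    values = np.zeros((len(rows), len(MARKERS)))
    for i, row in enumerate(rows):
        merged = {**defaults, **row}
        for m, v in merged.items():
            values[i, MARKERS.index(m)] = v
    return EventMatrix(values)


class TestExclusionGates:
    def test_doublet_ratio_bound(self, config):
        ev = events_from(
            [
                {"FSC-A": 60000, "FSC-H": 60000},   # ratio 1 -> singlet
                {"FSC-A": 120000, "FSC-H": 60000},  # ratio 2 -> doublet
                {"FSC-A": 60000, "FSC-H": 0},       # FSC-H 0 -> excluded
            ]
        )
        np.testing.assert_array_equal(
            exclude_doublets(ev, config), [True, False, False]
        )

    def test_zero_tolerance_keeps_only_exact_ratio(self, config):
        cfg = replace(config, doublet_ratio_tolerance=0.0)
        ev = events_from(
            [{"FSC-A": 60000, "FSC-H": 60000}, {"FSC-A": 60001, "FSC-H": 60000}]
        )
        np.testing.assert_array_equal(exclude_doublets(ev, cfg), [True, False])

    def test_debris_thresholds(self, config):
        ev = events_from(
            [
                {"FSC-A": 60000, "SSC-A": 200},
                {"FSC-A": config.fsc_min - 1, "SSC-A": 200},
                {"FSC-A": 60000, "SSC-A": config.ssc_min - 1},
            ]
        )
        np.testing.assert_array_equal(
            exclude_debris(ev, config), [True, False, False]
        )

    def test_zero_minima_retain_everything(self, config):
        cfg = replace(config, fsc_min=0.0, ssc_min=0.0)
        ev = events_from([{"FSC-A": 1, "SSC-A": 0}, {"FSC-A": 0, "SSC-A": 5}])
        assert exclude_debris(ev, cfg).all()


class TestCD45Gate:
    def test_counts_cd45_positive_events(self, config):
        rows = [{"CD45": 4.0, "SSC-A": 200}] * 900 + [{"CD45": 0.0}] * 100
        ev = events_from(rows)
        mask, n = gate_cd45_leukocytes(ev, config)
        assert n == 900
        assert mask.sum() == 900

    def test_all_events_below_threshold_gives_zero_denominator(self, config):
        ev = events_from([{"CD45": 0.0}] * 10)
        _, n = gate_cd45_leukocytes(ev, config)
        assert n == 0
        assert not label_events(ev, config).evaluable


class TestPolygonGates:
    def test_interior_boundary_and_outside(self, config):
        # pm default region: CD45 in [1.60, 3.45], SSC in [30, 650]
        ev = events_from(
            [
                {"CD45": 2.5, "SSC-A": 300},   # interior
                {"CD45": 1.60, "SSC-A": 30},   # vertex: closed convention
                {"CD45": 4.9, "SSC-A": 900},   # outside both
                {"CD45": 4.0, "SSC-A": 100},   # lymphocyte region
            ]
        )
        cd45_mask, _ = gate_cd45_leukocytes(ev, config)
        pm, lymph = gate_pm_lymph(ev, config, cd45_mask)
        np.testing.assert_array_equal(pm, [True, True, False, False])
        np.testing.assert_array_equal(lymph, [False, False, False, True])

    def test_pm_and_lymph_are_disjoint_by_construction(self, config):
        rng = np.random.default_rng(5)
        values = np.zeros((2000, len(MARKERS)))
        values[:, MARKERS.index("FSC-A")] = 60000
        values[:, MARKERS.index("FSC-H")] = 60000
        values[:, MARKERS.index("CD45")] = rng.uniform(0, 5, 2000)
        values[:, MARKERS.index("SSC-A")] = rng.uniform(0, 1000, 2000)
        ev = EventMatrix(values)
        cd45_mask, _ = gate_cd45_leukocytes(ev, config)
        pm, lymph = gate_pm_lymph(ev, config, cd45_mask)
        assert not (pm & lymph).any()

    def test_degenerate_polygon_rejected(self, config):
        with pytest.raises(GateConfigError):
            GateConfig(pm_polygon=((1, 1), (2, 2), (3, 3)))

    def test_overlapping_regions_rejected(self, config):
        with pytest.raises(GateConfigError, match="disjoint"):
            GateConfig(lymph_polygon=config.pm_polygon)


class TestFixedGates:
    def test_mypm_requires_cd13_or_cd33(self, config):
        ev = events_from(
            [
                {"CD45": 2.5, "SSC-A": 300, "CD13": 3.0, "CD33": 0.0},
                {"CD45": 2.5, "SSC-A": 300, "CD13": 0.0, "CD33": 3.0},
                {"CD45": 2.5, "SSC-A": 300, "CD13": 0.0, "CD33": 0.0},
            ]
        )
        cd45_mask, _ = gate_cd45_leukocytes(ev, config)
        pm, _ = gate_pm_lymph(ev, config, cd45_mask)
        np.testing.assert_array_equal(
            gate_mypm(ev, config, pm), [True, True, False]
        )

    def test_backbone_grid_covers_all_eight_labels(self, config):
        # one event on each side of each backbone threshold: 2^3 grid
        lo, hi = 0.0, 3.0
        rows = [
            {"CD34": hi if cd34 else lo, "CD117": hi if cd117 else lo,
             "HLA-DR": hi if hladr else lo}
            for cd34, cd117, hladr in product((True, False), repeat=3)
        ]
        codes = assign_backbone(events_from(rows), config)
        expected = [
            (cd34 << 2) | (cd117 << 1) | hladr
            for cd34, cd117, hladr in product((True, False), repeat=3)
        ]
        np.testing.assert_array_equal(codes, expected)
        assert sorted(codes) == list(range(8))

    def test_threshold_is_inclusive(self, config):
        ev = events_from([{"CD34": config.cd34_pos}])
        assert assign_backbone(ev, config)[0] & 4

    def test_category_combinations(self, config):
        ev = events_from(
            [
                {"CD13": 0.0, "CD56": 3.5, "CD33": 3.0},  # CD13neg + CD56pos
                {"CD13": 3.0, "CD33": 3.0, "CD7": 0.0, "CD56": 0.0},  # none
            ]
        )
        cats = assign_categories(ev, config)
        assert cats["CD13neg"][0] and cats["CD56pos"][0]
        assert not any(cats[c][1] for c in cats)

    def test_cd13neg_cd33neg_pair_unreachable_for_mypm(self, config):
        """An event deficient in both myeloid markers fails the OR gate."""
        ev = events_from([{"CD45": 2.5, "SSC-A": 300, "CD13": 0.0, "CD33": 0.0}])
        cd45_mask, _ = gate_cd45_leukocytes(ev, config)
        pm, _ = gate_pm_lymph(ev, config, cd45_mask)
        mypm = gate_mypm(ev, config, pm)
        cats = assign_categories(ev, config)
        assert cats["CD13neg"][0] and cats["CD33neg"][0]
        assert not mypm[0]


@pytest.fixture(scope="module")
def sample(config):
    clone = CloneSpec(
        backbone=(True, False, True),
        categories=frozenset({"CD56pos"}),
        fraction=0.02,
    )
    spec = SampleSpec(
        seed=42, n_events=30_000, clones=(clone,),
        background_cohort="ALL_molCR", sample_id="cascade",
    )
    events, _ = generate_sample(spec, config)
    return events


class TestCascadeInvariants:
    def test_hierarchy_containment(self, config, sample):
        lab = label_events(sample, config)
        base = lab.singlet & lab.non_debris
        assert not (lab.cd45 & ~base).any()
        assert not (lab.pm & ~lab.cd45).any()
        assert not (lab.mypm & ~lab.pm).any()

    def test_double_deficiency_absent_from_mypm(self, config, sample):
        lab = label_events(sample, config)
        both = lab.categories["CD13neg"] & lab.categories["CD33neg"]
        assert not (both & lab.mypm).any()

    def test_gating_is_deterministic_and_order_independent(self, config, sample):
        lab1 = label_events(sample, config)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sample.n_events)
        shuffled = EventMatrix(sample.values[perm])
        lab2 = label_events(shuffled, config)
        np.testing.assert_array_equal(lab1.mypm[perm], lab2.mypm)
        np.testing.assert_array_equal(lab1.backbone[perm], lab2.backbone)
        assert lab1.n_cd45 == lab2.n_cd45

    def test_raising_strong_cutoffs_is_monotone(self, config, sample):
        lab = label_events(sample, config)
        for name, cat in [("cd56_strong", "CD56pos"), ("cd7_strong", "CD7pos")]:
            tighter = replace(config, **{name: getattr(config, name) + 0.5})
            lab2 = label_events(sample, tighter)
            assert (
                (lab2.categories[cat] & lab2.mypm).sum()
                <= (lab.categories[cat] & lab.mypm).sum()
            )

    def test_raising_positivity_cutoff_is_monotone_for_deficiency(
        self, config, sample
    ):
        # raising cd13_pos can only enlarge the CD13neg flag set
        looser = replace(config, cd13_pos=config.cd13_pos + 0.5)
        lab = label_events(sample, config)
        lab2 = label_events(sample, looser)
        assert lab2.categories["CD13neg"].sum() >= lab.categories["CD13neg"].sum()
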
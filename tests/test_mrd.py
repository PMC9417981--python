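"""aLAIP detection, MRD calling rules and alternative schemes."""

from __future__ import annotations

import pytest

from mrdflow.mrd import (
    DiagnosisProfile,
    assess,
    call_mrd,
    call_mrd_eln,
    call_mrd_immonly,
    classify_load,
    detect_alaip,
)
from mrdflow.populations import SubpopulationID

from conftest import make_panel, make_table

IMMATURE = SubpopulationID(True, True, True, "CD56pos")
MATURE = SubpopulationID(False, False, True, "CD56pos")  # no immaturity marker


def profile(alaip=(), minor=()):
    pct = {c: 0.0 for c in ("CD13neg", "CD33neg", "CD7pos", "CD56pos")}
    pct.update({c: 50.0 for c in alaip})
    pct.update({c: 2.0 for c in minor})
    return DiagnosisProfile(pct_of_mypm=pct, n_mypm=1000)


class TestDetectAlaip:
    def test_threshold_splits_alaip_from_minor_clone(self):
        # 150/1000 myP/M CD56+: 15% -> aLAIP at the 10% threshold
        table = make_table(100_000, {IMMATURE: 150}, extra_mypm=850)
        assert "CD56pos" in detect_alaip(table, 10.0).alaip_set

        # 9% is a minor clone at 10% but an aLAIP at 5%
        table = make_table(100_000, {IMMATURE: 90}, extra_mypm=910)
        p10 = detect_alaip(table, 10.0)
        assert "CD56pos" in p10.minor_clones and "CD56pos" not in p10.alaip_set
        assert "CD56pos" in detect_alaip(table, 5.0).alaip_set

    def test_clean_sample_has_empty_alaip_set(self):
        table = make_table(100_000, {}, extra_mypm=1000)
        p = detect_alaip(table)
        assert not p.alaip_set and not p.minor_clones

    def test_no_mypm_warns_and_returns_empty_profile(self):
        table = make_table(100_000, {})
        with pytest.warns(UserWarning, match="no myP/M"):
            p = detect_alaip(table)
        assert not p.alaip_set


class TestCallMrd:
    def test_hand_arithmetic_single_positive(self):
        # 30 events / 1e6 CD45+ = 0.003%; ref 0.001% -> burden 0.002
        table = make_table(1_000_000, {IMMATURE: 30})
        panel = make_panel(0.001)
        res = call_mrd(table, panel)
        assert res.status == "pos"
        assert res.mrd_load == pytest.approx(0.002)
        assert res.load_category == "CD56pos"
        assert [p.sid for p in res.positive_subpops] == [IMMATURE]

    def test_min_event_rule_drops_small_subpopulations(self):
        # 19 events at a pct far above reference: dropped, sample negative
        table = make_table(1_000_000, {IMMATURE: 19})
        res = call_mrd(table, make_panel(0.0))
        assert res.status == "neg"
        assert IMMATURE in res.non_evaluable_subpops
        assert res.mrd_load == 0.0

    def test_twenty_events_exactly_are_analyzed(self):
        table = make_table(1_000_000, {IMMATURE: 20})
        assert call_mrd(table, make_panel(0.0)).status == "pos"

    def test_positivity_is_strict_exceedance(self):
        # pct equal to the reference does not trigger positivity
        table = make_table(1_000_000, {IMMATURE: 1000})  # pct = 0.1
        assert call_mrd(table, make_panel(0.1)).status == "neg"

    def test_max_category_rule(self):
        a = SubpopulationID(True, True, True, "CD13neg")
        b = SubpopulationID(True, False, True, "CD13neg")
        c = SubpopulationID(True, True, True, "CD7pos")
        table = make_table(100_000, {a: 30, b: 25, c: 22})
        panel = make_panel(0.0)
        res = call_mrd(table, panel)
        # CD13neg burden = 0.03 + 0.025, CD7pos = 0.022 -> load from CD13neg
        assert res.load_category == "CD13neg"
        assert res.mrd_load == pytest.approx(0.055)
        assert res.category_sums["CD7pos"] == pytest.approx(0.022)

    def test_origin_classification(self):
        table = make_table(1_000_000, {
            SubpopulationID(True, True, True, "CD13neg"): 40,
        })
        panel = make_panel(0.001)
        assert call_mrd(table, panel, profile(alaip=["CD13neg"])).origin == "aLAIP_only"
        assert call_mrd(table, panel, profile()).origin == "ptDfN_only"
        assert call_mrd(table, panel, profile(minor=["CD13neg"])).origin == "ptDfN_only"
        assert call_mrd(table, panel, None).origin == "no_diagnosis"

        both = make_table(1_000_000, {
            SubpopulationID(True, True, True, "CD13neg"): 40,
            SubpopulationID(True, True, True, "CD56pos"): 40,
        })
        assert (
            call_mrd(both, panel, profile(alaip=["CD13neg"])).origin
            == "aLAIP_and_ptDfN"
        )

    def test_negative_result_has_empty_positive_list(self, reference_panel):
        table = make_table(1_000_000, {})
        res = call_mrd(table, reference_panel)
        assert res.status == "neg"
        assert res.positive_subpops == []
        assert res.mrd_load == 0.0
        assert res.origin is None

    def test_raising_min_events_only_flips_pos_to_neg(self):
        table = make_table(1_000_000, {IMMATURE: 50})
        panel = make_panel(0.001)
        statuses = [
            call_mrd(table, panel, min_events=m).status
            for m in (10, 20, 50, 51, 100)
        ]
        assert statuses == ["pos", "pos", "pos", "neg", "neg"]


class TestSchemes:
    def test_eln_flat_cutoff(self):
        # immature subpopulation at 0.15% -> positive
        table = make_table(1_000_000, {IMMATURE: 1500})
        assert call_mrd_eln(table) == "pos"
        # 0.09% -> negative under ELN, positive under a lower reference
        table = make_table(1_000_000, {IMMATURE: 900})
        assert call_mrd_eln(table) == "neg"
        assert call_mrd(table, make_panel(0.05)).status == "pos"

    def test_eln_excludes_compartment_without_immaturity_markers(self):
        # CD34-CD117- subpopulation at 5%: excluded from the ELN scheme
        table = make_table(1_000_000, {MATURE: 50_000})
        assert call_mrd_eln(table) == "neg"

    def test_eln_cutoff_is_inclusive(self):
        table = make_table(1_000_000, {IMMATURE: 1000})  # exactly 0.1%
        assert call_mrd_eln(table) == "pos"

    def test_immonly_restriction(self):
        panel = make_panel(0.001)
        mature_only = make_table(1_000_000, {MATURE: 5000})
        assert call_mrd(mature_only, panel).status == "pos"
        assert call_mrd_immonly(mature_only, panel) == "neg"

        immature_too = make_table(1_000_000, {IMMATURE: 5000})
        assert call_mrd_immonly(immature_too, panel) == "pos"

    def test_immonly_pos_implies_full_pos(self, reference_panel):
        import numpy as np

        rng = np.random.default_rng(2)
        from mrdflow.populations import ALL_SUBPOPULATIONS

        for _ in range(25):
            picks = rng.choice(32, size=3, replace=False)
            counts = {
                ALL_SUBPOPULATIONS[i]: int(rng.integers(0, 400)) for i in picks
            }
            table = make_table(1_000_000, counts)
            if call_mrd_immonly(table, reference_panel) == "pos":
                assert call_mrd(table, reference_panel).status == "pos"

    def test_load_split(self):
        panel = make_panel(0.001)
        lo = call_mrd(make_table(1_000_000, {IMMATURE: 510}), panel)   # 0.051-0.001
        assert classify_load(lo) == "Lo"
        hi = call_mrd(make_table(1_000_000, {IMMATURE: 1010}), panel)  # exactly 0.1
        assert classify_load(hi) == "Hi"
        big = call_mrd(make_table(1_000_000, {IMMATURE: 20010}), panel)
        assert classify_load(big) == "Hi"
        neg = call_mrd(make_table(1_000_000, {}), panel)
        with pytest.raises(ValueError):
            classify_load(neg)

    def test_assess_fills_all_schemes(self, reference_panel):
        table = make_table(1_000_000, {IMMATURE: 5000})
        res = assess(table, reference_panel)
        assert res.status == "pos"
        assert res.load_class in ("Lo", "Hi")
        assert res.eln_status in ("pos", "neg")
        assert res.immonly_status == "pos"
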
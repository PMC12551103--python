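import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfnbs.cutoffs import CutoffModel
from cfnbs.screening import (
    UNDIAGNOSED,
    PanelDefinition,
    ScreenResult,
    TwoTierScreener,
    classify_outcome,
    cohort_summary,
    counterfactual_cutoffs,
    counterfactual_panels,
    load_panel,
    screen_infant,
    screen_registry,
    sweat_classify,
)


def _record(irt, v1="", v2="", has_cf=True, specimen="2020-03-01", diagnosis=None, mi=False, **extra):
    row = {
        "infant_id": "x",
        "specimen_date": pd.Timestamp(specimen),
        "kit_id": "k",
        "irt": float(irt),
        "race": "White",
        "ethnicity": "NonHispanic",
        "sex": "F",
        "has_cf": has_cf,
        "variant1": v1,
        "variant2": v2,
        "meconium_ileus": mi,
        "diagnosis_date": pd.Timestamp(diagnosis) if diagnosis else pd.NaT,
        "sweat_dates": "",
        "sweat_results": "",
    }
    row.update(extra)
    return pd.Series(row)


PANEL = PanelDefinition("test", frozenset({"F508del", "G542X", "3876delA"}))


class TestScreenInfant:
    def test_low_irt_is_negative_regardless_of_genotype(self):
        res = screen_infant(_record(44.5, "F508del", "G542X"), PANEL, 55.0)
        assert res.disposition == "negative_low_irt"
        assert res.tier1 == "below_cutoff"
        assert res.variants_detected is None

    def test_elevated_irt_off_panel_genotype_is_negative(self):
        res = screen_infant(_record(246.4, "1811+1634A->G", "3271delGG"), PANEL, 55.0)
        assert res.disposition == "negative_no_variants"
        assert res.variants_detected == 0

    def test_one_panel_variant_is_positive(self):
        res = screen_infant(_record(176.7, "3876delA", "c.1811del"), PANEL, 55.0)
        assert res.disposition == "positive_one_variant"
        assert res.variants_detected == 1

    def test_panel_homozygote_counts_two(self):
        res = screen_infant(_record(120.0, "F508del", "F508del"), PANEL, 55.0)
        assert res.disposition == "positive_two_variants"
        assert res.variants_detected == 2

    def test_boundary_irt_screens_positive(self):
        assert screen_infant(_record(55.0, "F508del", ""), PANEL, 55.0).tier1 == "above_cutoff"

    def test_trimming_does_not_apply_to_decisions(self):
        # an IRT far above the trim threshold still screens positive
        assert screen_infant(_record(416.6, "F508del", ""), PANEL, 55.0).tier1 == "above_cutoff"


class TestClassify:
    def _screen(self, record):
        return screen_infant(record, PANEL, 55.0)

    def test_not_cf(self):
        rec = _record(80, "F508del", "", has_cf=False)
        assert classify_outcome(rec, self._screen(rec)).category == "not_cf"

    def test_missed_low_irt(self):
        rec = _record(44.5, "F508del", "G542X", diagnosis="2021-10-01")
        assert classify_outcome(rec, self._screen(rec)).category == "missed_low_irt"

    def test_missed_genetics(self):
        rec = _record(246.4, "1811+1634A->G", "3271delGG", diagnosis="2021-10-01")
        assert classify_outcome(rec, self._screen(rec)).category == "missed_genetics"

    def test_delayed_when_diagnosis_after_28_days(self):
        # specimen on day-of-life 2, diagnosis at age 62 days
        rec = _record(176.7, "3876delA", "", specimen="2020-03-03", diagnosis="2020-05-02")
        out = classify_outcome(rec, self._screen(rec))
        assert out.category == "delayed"
        assert out.age_at_diagnosis_days == 62

    def test_day_28_is_on_time(self):
        rec = _record(120, "F508del", "F508del", specimen="2020-03-03", diagnosis="2020-03-29")
        out = classify_outcome(rec, self._screen(rec))
        assert out.category == "on_time"
        assert out.age_at_diagnosis_days == 28

    def test_positive_without_diagnosis_is_undiagnosed_sentinel(self):
        rec = _record(120, "F508del", "F508del")
        assert classify_outcome(rec, self._screen(rec)).category == UNDIAGNOSED

    def test_delay_reason_carried_from_record(self):
        rec = _record(176.7, "3876delA", "", specimen="2020-03-03", diagnosis="2020-06-01",
                      delay_reason="sweat_scheduling")
        assert classify_outcome(rec, self._screen(rec)).delay_reason == "sweat_scheduling"


class TestSweat:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (74, "cf_range"),
            (60, "cf_range"),
            (59.999, "intermediate"),
            (30, "intermediate"),
            (29.999, "negative"),
            ("QNS", "qns"),
            ("qns", "qns"),
        ],
    )
    def test_classification(self, value, expected):
        assert sweat_classify(value) == expected

    def test_negative_chloride_rejected(self):
        with pytest.raises(ValueError):
            sweat_classify(-1.0)


class TestPanels:
    def test_load_panel_skips_comments_and_normalises(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("# header\nF508del\n  G542X  \n\n3120G->A # inline\n")
        panel = load_panel(path)
        assert panel.variants == {"F508del", "G542X", "3120G->A"}
        assert "  F508del " in panel

    def test_duplicate_variant_rejected(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("F508del\nF508del\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_panel(path)

    def test_empty_panel_detects_nothing(self):
        empty = PanelDefinition("empty", frozenset())
        assert empty.detected(["F508del", "G542X"]) == 0

    def test_large_deletions_missed_by_every_fixture_panel(self, all_panels):
        for panel in all_panels:
            assert panel.detected(["CFTRdele1", "CFTRdele21"]) == 0

    @settings(deadline=None, max_examples=50)
    @given(
        base=st.sets(st.sampled_from(["a", "b", "c", "d"])),
        extra=st.sets(st.sampled_from(["e", "f"])),
        genotype=st.lists(st.sampled_from(["a", "b", "e", "z"]), min_size=2, max_size=2),
    )
    def test_adding_variants_never_decreases_detection(self, base, extra, genotype):
        small = PanelDefinition("s", frozenset(base))
        big = PanelDefinition("b", frozenset(base | extra))
        assert big.detected(genotype) >= small.detected(genotype)


class TestCounterfactuals:
    def test_lower_cutoff_gives_superset_of_positives(self, table1, core_panel):
        high = screen_registry(table1, core_panel, 55.0)
        low = screen_registry(table1, core_panel, 40.0)
        high_pos = set(table1.loc[(high["tier1"] == "above_cutoff").to_numpy(), "infant_id"])
        low_pos = set(table1.loc[(low["tier1"] == "above_cutoff").to_numpy(), "infant_id"])
        assert high_pos <= low_pos

    def test_lowering_fixed_cutoff_never_increases_low_irt_missed(self, table1, core_panel):
        counts = []
        for cut in (65, 55, 45, 35, 25):
            strat = CutoffModel(mode="fixed", fixed_value=cut)
            table = counterfactual_cutoffs(table1, [strat], core_panel)
            counts.append(int(table.loc[0, "missed_low_irt"]))
        assert counts == sorted(counts, reverse=True)

    def test_single_strategy_matches_direct_tabulation(self, table1, core_panel, classified):
        table = counterfactual_cutoffs(
            table1, [CutoffModel(mode="fixed", fixed_value=55.0)], core_panel
        )
        direct = classified["category"].value_counts()
        for cat in ("on_time", "delayed", "missed_low_irt", "missed_genetics"):
            assert table.loc[0, cat] == direct.get(cat, 0)
        assert table.loc[0, "changed_cases"] == ""

    def test_near_miss_case_flips_under_high_floating_cutoff(self, table1, core_panel):
        """A CF case with IRT 63.5 is positive at fixed 55 but missed when the
        day's floating cut-off exceeds 63.5."""
        case = table1[table1["irt"] == 63.5].iloc[0]
        assert screen_infant(case, core_panel, 55.0).tier1 == "above_cutoff"
        assert screen_infant(case, core_panel, 70.0).disposition == "negative_low_irt"

    def test_counterfactual_panels_summary(self, table1, all_panels, classified):
        missed = classified[classified["category"] == "missed_genetics"]
        per_case, summary = counterfactual_panels(missed, all_panels)
        assert len(per_case) == 6
        summary = summary.set_index("panel")
        assert summary.loc["core", "n_ge1"] == 0
        assert summary.loc["expanded139", "n_ge1"] == 4
        assert summary.loc["expanded689", "n_ge1"] == 5
        assert summary.loc["expanded689", "n_eq2"] == 4  # one single-variant detection
        assert summary.loc["ngs1085", "n_ge1"] == 5

    def test_counterfactual_panels_requires_two_alleles(self, all_panels):
        cases = pd.DataFrame(
            {"infant_id": ["a"], "variant1": ["F508del"], "variant2": [""]}
        )
        with pytest.raises(ValueError, match="two-allele"):
            counterfactual_panels(cases, all_panels)


class TestInvariants:
    def test_cf_outcome_partition(self, classified):
        """Every CF record lands in exactly one outcome category and the
        categories sum to the CF total."""
        cf = classified[classified["has_cf"]]
        cats = cf["category"].value_counts()
        allowed = {"on_time", "delayed", "missed_low_irt", "missed_genetics", UNDIAGNOSED}
        assert set(cats.index) <= allowed
        assert cats.sum() == len(cf)

    def test_screening_consistency(self, classified, core_panel):
        two = classified[classified["disposition"] == "positive_two_variants"]
        for _, row in two.iterrows():
            assert row["variant1"] in core_panel and row["variant2"] in core_panel
        none = classified[classified["disposition"] == "negative_no_variants"]
        for _, row in none.iterrows():
            assert row["variant1"] not in core_panel and row["variant2"] not in core_panel

    def test_empty_cohort_summary_is_all_zero(self):
        empty = pd.DataFrame(
            columns=["has_cf", "race", "ethnicity", "sex", "category"]
        ).astype({"has_cf": bool})
        summary = cohort_summary(empty)
        assert (summary["overall_n"] == 0).all()

    def test_two_tier_screener_sklearn_surface(self, table1, core_panel):
        screener = TwoTierScreener(panel=core_panel, cutoff=CutoffModel(mode="fixed"))
        params = screener.get_params()
        assert params["birth_offset_days"] == 2
        preds = screener.fit(table1).predict(table1)
        assert len(preds) == len(table1)
        assert set(preds) <= {
            "negative_low_irt", "negative_no_variants",
            "positive_one_variant", "positive_two_variants",
        }
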
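"""Deduplication rules, target matching, age strata and demographic tables."""

import warnings

import pandas as pd
import pytest

import pvsignals as pv
from pvsignals.curation import (
    CaseReport,
    bucket_age,
    match_target_drug,
    normalize_drug_name,
    summarize_demographics,
)
from pvsignals.faers import DrugRecord, QuarterlyBundle


def make_bundle(demo_rows, deleted=(), quarter="2020Q1"):
    demo = pd.DataFrame(
        demo_rows, columns=["primaryid", "caseid", "fda_dt"], dtype=str
    )
    for col in ("event_dt", "age", "age_cod", "sex", "occp_cod", "reporter_country"):
        demo[col] = ""
    demo = demo[pv.faers.DEMO_COLUMNS]
    return QuarterlyBundle(
        quarter_label=quarter,
        demo=demo,
        drug=pd.DataFrame(columns=pv.faers.DRUG_COLUMNS, dtype=str),
        reac=pd.DataFrame(columns=pv.faers.REAC_COLUMNS, dtype=str),
        deleted=pd.DataFrame({"caseid": list(deleted)}, dtype=str),
    )


class TestDeduplicate:
    def test_later_date_beats_higher_primaryid(self):
        bundle = make_bundle([("100", "C1", "20200101"), ("90", "C1", "20210101")])
        result = pv.deduplicate([bundle])
        assert list(result.cases["primaryid"]) == ["90"]

    def test_date_tie_broken_by_numeric_primaryid(self):
        bundle = make_bundle([("100", "C1", "20200101"), ("101", "C1", "20200101")])
        result = pv.deduplicate([bundle])
        assert list(result.cases["primaryid"]) == ["101"]
        # numeric, not lexicographic: 99 < 100
        bundle = make_bundle([("99", "C2", "20200101"), ("100", "C2", "20200101")])
        assert list(pv.deduplicate([bundle]).cases["primaryid"]) == ["100"]

    def test_deleted_case_removed_across_quarters(self):
        b1 = make_bundle([("1", "C1", "20200101")], quarter="2020Q1")
        b2 = make_bundle([], deleted=["C1"], quarter="2020Q2")
        result = pv.deduplicate([b1, b2])
        assert len(result.cases) == 0
        assert result.n_deleted_removed == 1

    def test_idempotent_and_unique(self):
        rows = [
            ("11", "C1", "20200101"),
            ("12", "C1", "20200601"),
            ("21", "C2", "20190101"),
        ]
        once = pv.deduplicate([make_bundle(rows)])
        again = pv.deduplicate(
            [
                QuarterlyBundle(
                    quarter_label="2020Q4",
                    demo=once.cases,
                    drug=once.drug,
                    reac=once.reac,
                    deleted=pd.DataFrame(columns=["caseid"], dtype=str),
                )
            ]
        )
        pd.testing.assert_frame_equal(once.cases, again.cases)
        assert once.cases["caseid"].is_unique

    def test_conflicting_identical_keys_keep_first_and_log(self):
        demo_rows = [("10", "C1", "20200101"), ("10", "C1", "20200101")]
        bundle = make_bundle(demo_rows)
        bundle.demo.loc[1, "sex"] = "F"  # same identifiers, different content
        result = pv.deduplicate([bundle])
        assert result.n_conflicts == 1
        assert list(result.cases["sex"]) == [""]

    def test_unparseable_fda_dt_is_an_error(self):
        bundle = make_bundle([("10", "C1", "banana")])
        with pytest.raises(ValueError, match="fda_dt"):
            pv.deduplicate([bundle])


class TestTargetMatching:
    def _report(self, **drug_kwargs):
        defaults = dict(primaryid="1", caseid="1", drug_seq="1", role_cod="PS")
        defaults.update(drug_kwargs)
        return CaseReport(
            primaryid="1", caseid="1", fda_dt="20200101", drugs=(DrugRecord(**defaults),)
        )

    def test_case_insensitive_brand_match(self):
        report = self._report(drugname="GENVOYA")
        assert match_target_drug(report, ["Genvoya"])

    def test_ingredient_list_order_insensitive(self):
        report = self._report(
            drugname="",
            prod_ai="COBICISTAT; ELVITEGRAVIR; EMTRICITABINE; TENOFOVIR ALAFENAMIDE FUMARATE",
        )
        pattern = "ELVITEGRAVIR; COBICISTAT; EMTRICITABINE; TENOFOVIR ALAFENAMIDE FUMARATE"
        assert match_target_drug(report, [pattern])

    def test_role_filter(self):
        report = self._report(drugname="GENVOYA", role_cod="C")
        assert not match_target_drug(report, ["Genvoya"], roles={"PS"})
        assert match_target_drug(report, ["Genvoya"], roles={"PS", "C"})

    def test_no_substring_matching(self):
        report = self._report(drugname="GENVOYA PLUS SOMETHING")
        assert not match_target_drug(report, ["Genvoya"])

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  Genvoya.  ", "genvoya"),
            ("GEN  VOYA", "gen voya"),
            ("genvoya;", "genvoya"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_select_cohort_agrees_with_per_report_matching(self, toy_sim_config):
        bundles, _ = pv.generate(toy_sim_config)
        dedup = pv.deduplicate(bundles)
        cohort = pv.select_cohort(dedup, ["TargetDrug"])
        by_report = {
            r.caseid
            for r in dedup.case_reports()
            if match_target_drug(r, ["TargetDrug"])
        }
        assert set(cohort["caseid"]) == by_report
        assert len(cohort) > 0


class TestAgeBuckets:
    @pytest.mark.parametrize(
        "age, unit, expected",
        [
            ("45", "YR", "18-<65"),
            ("6", "MON", "<18"),
            ("65", "YR", ">=65"),
            ("17", "YR", "<18"),
            ("18", "YR", "18-<65"),
            ("64.9", "YR", "18-<65"),
            ("2", "DEC", "18-<65"),
            ("7", "DEC", ">=65"),
            ("700", "WK", "<18"),
            ("6600", "DY", "18-<65"),
            ("9000", "HR", "<18"),
            ("", "YR", "Unknown"),
            ("45", "", "Unknown"),
            ("45", "EON", "Unknown"),
        ],
    )
    def test_bucketing(self, age, unit, expected):
        assert bucket_age(age, unit) == expected

    def test_negative_age_warns_unknown(self):
        with pytest.warns(UserWarning, match="negative age"):
            assert bucket_age("-5", "YR") == "Unknown"


class TestDemographics:
    def test_degenerate_single_male_cohort(self):
        cohort = [CaseReport(primaryid="1", caseid="1", fda_dt="20200101", sex="M")]
        summary = summarize_demographics(cohort)
        assert summary.percentage("gender", "Male") == 100.00
        assert summary.percentage("gender", "Female") == 0.00

    def test_dimension_counts_sum_to_total(self, toy_sim_config):
        bundles, _ = pv.generate(toy_sim_config)
        dedup = pv.deduplicate(bundles)
        summary = summarize_demographics(dedup.cases, top_k_countries=3)
        for dim, grp in summary.strata.groupby("dimension"):
            assert grp["count"].sum() == summary.total
            # half-up rounding leaves at most 0.05 total slack per dimension
            assert abs(grp["percentage"].sum() - 100.0) <= 0.05 + 1e-9

    def test_country_ranking_ties_alphabetical(self):
        reports = [
            CaseReport(primaryid=str(i), caseid=str(i), fda_dt="20200101", reporter_country=c)
            for i, c in enumerate(["US", "US", "FR", "TR", "TR", "DE"])
        ]
        summary = summarize_demographics(reports, top_k_countries=2)
        countries = summary.strata.query("dimension == 'country'")
        # TR ties with nothing; FR and DE tie at 1 but fall outside top-2
        assert list(countries["category"])[:2] == ["TR", "US"] or list(
            countries["category"]
        )[:2] == ["US", "TR"]

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError, match="empty cohort"):
            summarize_demographics([])

    def test_reporter_code_mapping(self):
        reports = [
            CaseReport(primaryid=str(i), caseid=str(i), fda_dt="20200101", occp_cod=c)
            for i, c in enumerate(["MD", "PH", "HP", "CN", "LW", "OT", ""])
        ]
        summary = summarize_demographics(reports)
        get = lambda cat: int(
            summary.strata.query("dimension == 'reporter' and category == @cat")["count"].iloc[0]
        )
        assert get("Healthcare professional") == 3
        assert get("Consumer") == 1
        assert get("Other") == 2
        assert get("Unknown") == 1
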
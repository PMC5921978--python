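import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpselect import (
    AccountingSummary,
    ApplicationRecord,
    PerformanceRecord,
    accounting_summary,
    fte_time,
    link_and_filter,
    load_applications,
    load_performance,
    write_applications,
    write_performance,
)
from gpselect.cohort import DataIntegrityError, DuplicateIdentifierError, SchemaError


def _app(gmc="G1", year=2012, rnd="R1", cps=250.0, pdd=250.0, **kw):
    return ApplicationRecord(gmc_id=gmc, year=year, round=rnd, cps_score=cps, pd_score=pdd, **kw)


# ---------------------------------------------------------------------------
# loading


class TestLoadApplications:
    def test_three_valid_rows(self, tmp_path):
        p = tmp_path / "apps.csv"
        p.write_text(
            "gmc_id,year,round,cps_score,pd_score\n"
            "G1,2011,R1,250,260\nG2,2012,R2,240,230\nG3,2013,R1,199,301\n"
        )
        result = load_applications(p)
        assert len(result) == 3
        assert result.rejects.empty

    def test_round3_recoded_to_round2(self, tmp_path):
        p = tmp_path / "apps.csv"
        p.write_text("gmc_id,year,round,cps_score,pd_score\nG1,2014,R3,250,260\n")
        (rec,) = load_applications(p)
        assert rec.round == "R2"

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "apps.csv"
        p.write_text("gmc_id,year,round,cps_score,pd_score\n")
        assert len(load_applications(p)) == 0

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "apps.csv"
        p.write_text("gmc_id,year,round,cps_score\nG1,2011,R1,250\n")
        with pytest.raises(SchemaError, match="pd_score"):
            load_applications(p)

    def test_malformed_row_goes_to_rejects(self, tmp_path):
        p = tmp_path / "apps.csv"
        p.write_text(
            "gmc_id,year,round,cps_score,pd_score\n"
            "G1,2011,R1,250,260\nG2,2011,R1,twelve,260\n"
        )
        result = load_applications(p)
        assert len(result) == 1
        assert list(result.rejects["row"]) == [3]

    def test_stage2_total_is_component_sum(self):
        assert _app(cps=200.5, pdd=199.5).stage2_total == 400.0

    def test_competent_without_total_rejected(self):
        with pytest.raises(DataIntegrityError):
            _app(stage3_competent=True)


class TestPerformanceRecord:
    def test_registration_before_start_rejected(self):
        with pytest.raises(DataIntegrityError):
            PerformanceRecord(gmc_id="G1", start_month=140, registration_month=139)

    def test_arcp4_with_registration_rejected(self):
        with pytest.raises(DataIntegrityError):
            PerformanceRecord(gmc_id="G1", start_month=140, registration_month=180, arcp4=True)

    def test_ltft_oop_bounded_by_elapsed_time(self):
        with pytest.raises(DataIntegrityError):
            PerformanceRecord(
                gmc_id="G1", start_month=140, registration_month=150, ltft_months=8, oop_months=8
            )


_apps_strategy = st.lists(
    st.builds(
        ApplicationRecord,
        gmc_id=st.text(alphabet="ABC0123456789", min_size=1, max_size=8),
        year=st.integers(2011, 2014),
        round=st.sampled_from(["R1", "R2"]),
        cps_score=st.floats(100, 400, allow_nan=False),
        pd_score=st.floats(100, 400, allow_nan=False),
        stage3_total=st.one_of(st.none(), st.floats(0, 120, allow_nan=False)),
        withdrew=st.one_of(st.none(), st.booleans()),
        offer_accepted=st.one_of(st.none(), st.booleans()),
        gender=st.sampled_from(["F", "M"]),
        ethnicity_bme=st.booleans(),
        uk_pmq=st.booleans(),
    ),
    max_size=20,
)


@given(records=_apps_strategy)
@settings(max_examples=25, deadline=None)
def test_write_load_round_trip(records, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "apps.csv"
    write_applications(records, path)
    loaded = load_applications(path)
    assert loaded.rejects.empty
    assert list(loaded) == records


def test_performance_round_trip(tmp_path):
    records = [
        PerformanceRecord(gmc_id="G1", start_month=140, ltft_months=6.0, registration_month=190),
        PerformanceRecord(gmc_id="G2", start_month=140, arcp4=True),
    ]
    p = tmp_path / "perf.csv"
    write_performance(records, p)
    loaded = load_performance(p)
    assert loaded.rejects.empty
    assert list(loaded) == records


# ---------------------------------------------------------------------------
# linkage


class TestLinkAndFilter:
    def test_missing_gmc_excluded(self):
        apps = [_app(gmc=None), _app(gmc="G1"), _app(gmc="G2")]
        cohort = link_and_filter(apps)
        assert len(cohort) == 2
        assert cohort.exclusions["missing_gmc_id"] == 1

    def test_failed_stage1_excluded(self):
        cohort = link_and_filter([_app(passed_stage1=False), _app(gmc="G2")])
        assert len(cohort) == 1

    def test_withdrew_before_stage2_excluded(self):
        cohort = link_and_filter([_app(took_stage2=False), _app(gmc="G2")])
        assert len(cohort) == 1

    def test_exclusions_account_for_every_raw_row(self):
        apps = [
            _app(gmc=None),
            _app(passed_stage1=False),
            _app(took_stage2=False),
            _app(gmc="G9"),
        ]
        cohort = link_and_filter(apps)
        ex = cohort.exclusions
        assert (
            ex["missing_gmc_id"] + ex["failed_stage1"] + ex["withdrew_before_stage2"] + ex["included"]
            == ex["raw_rows"]
            == 4
        )

    def test_performance_links_to_successful_application_only(self):
        apps = [
            _app(gmc="G7", year=2011, offer_accepted=False),
            _app(gmc="G7", year=2013, offer_accepted=True),
        ]
        perf = [PerformanceRecord(gmc_id="G7", start_month=164, registration_month=204)]
        cohort = link_and_filter(apps, perf)
        f = cohort.frame
        assert np.isnan(f.loc[f["year"] == 2011, "fte_months"]).all()
        assert f.loc[f["year"] == 2013, "fte_months"].notna().all()

    def test_duplicate_performance_identifier_raises(self):
        perf = [
            PerformanceRecord(gmc_id="G1", start_month=140),
            PerformanceRecord(gmc_id="G1", start_month=152),
        ]
        with pytest.raises(DuplicateIdentifierError):
            link_and_filter([_app(offer_accepted=True)], perf)

    def test_unmatched_performance_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="matches no accepted application"):
            cohort = link_and_filter([_app(gmc="G1")], [PerformanceRecord(gmc_id="ZZ", start_month=140)])
        assert cohort.frame["fte_months"].isna().all()

    def test_never_invents_data(self):
        apps = [_app(gmc="G1", stage3_total=77.0, withdrew=False, offer_accepted=True)]
        perf = [
            PerformanceRecord(
                gmc_id="G1", start_month=140, ltft_months=10.0, oop_months=2.0, arcp4=False,
                registration_month=190,
            )
        ]
        f = link_and_filter(apps, perf).frame
        assert f.at[0, "stage3_total"] == 77.0
        assert f.at[0, "withdrew"] == 0.0
        assert f.at[0, "ltft"] == 1.0 and f.at[0, "oop"] == 1.0
        # 50 calendar months, 2 OOP, 10 LTFT at 60% FTE
        assert f.at[0, "fte_months"] == pytest.approx(38 + 10 / 1.67)

    def test_empty_input(self):
        assert len(link_and_filter([])) == 0


# ---------------------------------------------------------------------------
# FTE arithmetic


class TestFteTime:
    def test_full_time(self):
        assert fte_time(36, 0, 0) == 36

    def test_oop_subtracted(self):
        assert fte_time(48, 12, 0) == 36

    def test_ltft_scaled(self):
        assert fte_time(50, 0, 20) == pytest.approx(30 + 20 / 1.67)

    def test_precondition_violation(self):
        with pytest.raises(DataIntegrityError):
            fte_time(10, 8, 8)
        with pytest.raises(DataIntegrityError):
            fte_time(10, -1, 0)


# ---------------------------------------------------------------------------
# accounting


class TestAccounting:
    def test_printed_round1_numbers(self):
        acc = AccountingSummary.from_counts(20782, 4174, n_years=4)
        assert acc.max_fillable_r1 == 16608
        assert acc.annual_mean(acc.max_fillable_r1) == 4152

    def test_printed_round2_numbers(self):
        acc = AccountingSummary.from_counts(20782, 4174, n_years=4, included_r2=4578, withdrew_or_declined_r2=778)
        assert acc.max_fillable_r2 == 3800
        assert acc.annual_mean(acc.max_fillable_r2) == 950

    def test_empty_cohort(self):
        cohort = link_and_filter([])
        acc = accounting_summary(cohort, n_years=4)
        assert acc.included_r1 == acc.included_r2 == 0
        assert acc.max_fillable_r1 == acc.max_fillable_r2 == 0

    def test_bad_n_years(self):
        with pytest.raises(ValueError):
            AccountingSummary.from_counts(10, 2, n_years=0)

    def test_from_observed_cohort(self):
        apps = [
            _app(gmc="G1", withdrew=True, offer_accepted=False),
            _app(gmc="G2", withdrew=False, offer_accepted=True),
            _app(gmc="G3", withdrew=False, offer_accepted=False),
            _app(gmc="G4", rnd="R2", withdrew=False, offer_accepted=True),
        ]
        acc = accounting_summary(link_and_filter(apps), n_years=1)
        assert acc.included_r1 == 3 and acc.included_r2 == 1
        assert acc.withdrew_or_declined_r1 == 2
        assert acc.max_fillable_r1 == 1 and acc.max_fillable_r2 == 1

    def test_missing_flags_require_imputations(self):
        cohort = link_and_filter([_app(gmc="G1", withdrew=None)])
        with pytest.raises(ValueError, match="imputation"):
            accounting_summary(cohort, n_years=1)

    def test_mean_over_imputations(self, small_cohort, small_imputations):
        cohort, truth, _ = small_cohort
        acc = accounting_summary(cohort, small_imputations, n_years=2)
        # imputed withdrawn-or-declined fraction should sit near the truth
        true_frac = float(
            ((truth.frame["withdrew"] == 1) | (truth.frame["offer_accepted"] == 0)).mean()
        )
        est_frac = (acc.withdrew_or_declined_r1 + acc.withdrew_or_declined_r2) / len(cohort)
        assert abs(est_frac - true_frac) < 0.08
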
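"""Referent selection, feature construction and stratum assembly."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import casecross as cc
from casecross.design import DesignError

from conftest import make_deaths, make_panel, pm25_only_spec


class TestSelectReferents:
    @pytest.mark.parametrize(
        "case, expected",
        [
            (
                dt.date(2015, 7, 15),
                [dt.date(2015, 7, 1), dt.date(2015, 7, 8), dt.date(2015, 7, 22), dt.date(2015, 7, 29)],
            ),
            (
                dt.date(2000, 2, 29),
                [dt.date(2000, 2, 1), dt.date(2000, 2, 8), dt.date(2000, 2, 15), dt.date(2000, 2, 22)],
            ),
        ],
    )
    def test_worked_examples(self, case, expected):
        assert cc.select_referents(case) == expected

    @given(st.dates(min_value=dt.date(1995, 1, 1), max_value=dt.date(2030, 12, 31)))
    def test_same_weekday_month_year_case_excluded(self, case):
        refs = cc.select_referents(case)
        assert case not in refs
        assert len(refs) in (3, 4)
        assert refs == sorted(refs)
        for r in refs:
            assert (r.weekday(), r.month, r.year) == (case.weekday(), case.month, case.year)

    @given(st.dates(min_value=dt.date(2000, 1, 1), max_value=dt.date(2015, 12, 31)))
    def test_referent_symmetry(self, case):
        # selecting referents of any referent recovers the original case day
        for r in cc.select_referents(case):
            assert case in cc.select_referents(r)


class TestBuildFeatures:
    def test_moving_average_arithmetic(self):
        panel = make_panel("2010-06-01", "2010-06-10")
        panel.loc[panel["date"] == "2010-06-03", "pm25"] = 10.0
        panel.loc[panel["date"] == "2010-06-04", "pm25"] = 20.0
        panel.loc[panel["date"] == "2010-06-05", "pm25"] = 30.0
        vec = cc.build_features(panel, "R1", "2010-06-05", pm25_only_spec())
        assert vec["pm25_ma02"] == pytest.approx(20.0)

    def test_constant_series_and_square(self):
        panel = make_panel("2010-06-01", "2010-06-20", fill=7.0)
        spec = cc.FeatureSpec(
            (
                cc.Feature("pm25", "lag", 0, "x"),
                cc.Feature("pm25", "ma", (0, 2), "m"),
                cc.Feature("pm25", "lead", 1, "l"),
                cc.Feature("pm25", "square_of", "x", "x2"),
            )
        )
        vec = cc.build_features(panel, "R1", "2010-06-10", spec)
        assert vec["x"] == vec["m"] == vec["l"] == 7.0
        assert vec["x2"] == pytest.approx(49.0)

    def test_lead_is_next_day_lag0(self):
        panel = make_panel("2010-06-01", "2010-06-20")
        spec = cc.FeatureSpec(
            (cc.Feature("pm25", "lag", 0, "x"), cc.Feature("pm25", "lead", 1, "l"))
        )
        from casecross.design import compute_feature_table

        table = compute_feature_table(panel, spec)
        for d in pd.date_range("2010-06-05", "2010-06-15"):
            assert table.loc[(d, "R1"), "l"] == table.loc[(d + pd.Timedelta(days=1), "R1"), "x"]

    def test_missing_day_flags_incomplete(self):
        panel = make_panel("2010-06-01", "2010-06-20")
        panel = panel[panel["date"] != pd.Timestamp("2010-06-08")]
        vec = cc.build_features(panel, "R1", "2010-06-09", pm25_only_spec())
        assert np.isnan(vec["pm25_ma02"])


class TestAssembleStrata:
    def test_full_june_death_has_four_referents(self):
        panel = make_panel("2010-05-25", "2010-07-05")
        deaths = make_deaths(["2010-06-16"])  # a Wednesday
        strata = cc.assemble_strata(deaths, panel, pm25_only_spec())
        assert strata.n_strata == 1
        assert strata.counts[0] == 5  # case + 4 referents
        got = set(pd.to_datetime(strata.row_dates).date)
        assert got == {dt.date(2010, 6, d) for d in (2, 9, 16, 23, 30)}

    def test_missing_panel_day_drops_one_referent(self):
        panel = make_panel("2010-05-25", "2010-07-05")
        panel = panel[panel["date"] != pd.Timestamp("2010-06-02")]
        deaths = make_deaths(["2010-06-16"])
        strata = cc.assemble_strata(deaths, panel, pm25_only_spec())
        # referent 06-02 needs 05-31..06-02; dropped, 3 referents remain
        assert strata.counts[0] == 4
        assert dt.date(2010, 6, 2) not in set(pd.to_datetime(strata.row_dates).date)

    def test_case_missing_lead_coverage_drops_stratum(self):
        panel = make_panel("2010-05-25", "2010-06-30")
        deaths = make_deaths(["2010-06-16", "2010-06-30"])
        strata = cc.assemble_strata(deaths, panel, pm25_only_spec(lead=True))
        # the 06-30 death needs 07-01 for its lead-1 feature
        assert strata.n_strata == 1
        assert strata.meta["case_date"].iloc[0] == pd.Timestamp("2010-06-16")

    def test_unknown_region_is_hard_error(self):
        panel = make_panel()
        deaths = make_deaths(["2010-06-16"], regions=["R9"])
        with pytest.raises(DesignError, match="R9"):
            cc.assemble_strata(deaths, panel, pm25_only_spec())

    def test_duplicate_deaths_become_separate_strata(self):
        panel = make_panel("2010-05-25", "2010-07-05")
        deaths = make_deaths(["2010-06-16", "2010-06-16"])
        strata = cc.assemble_strata(deaths, panel, pm25_only_spec())
        assert strata.n_strata == 2
        a = strata.X[strata.starts[0] : strata.starts[0] + strata.counts[0]]
        b = strata.X[strata.starts[1] :]
        np.testing.assert_array_equal(a, b)

    def test_noninformative_strata_dropped(self):
        panel = make_panel("2010-05-25", "2010-07-05", fill=5.0)
        deaths = make_deaths(["2010-06-16"])
        with pytest.raises(DesignError, match="informative"):
            cc.assemble_strata(deaths, panel, pm25_only_spec())


class TestStratumInvariants:
    def test_homogeneity_and_counts_on_simulated_world(self, small_strata):
        dates = pd.to_datetime(small_strata.row_dates)
        strat = small_strata.row_stratum
        df = pd.DataFrame(
            {"s": strat, "wd": dates.weekday, "m": dates.month, "y": dates.year}
        )
        per = df.groupby("s").nunique()
        assert (per[["wd", "m", "y"]] == 1).all().all()
        # complete panel: every stratum has (same-weekday days in month) rows
        case_dates = pd.to_datetime(small_strata.meta["case_date"])
        expected = np.array([len(cc.select_referents(d.date())) + 1 for d in case_dates])
        # all-but-edge strata are complete; edge months lose lag/lead days
        full = small_strata.counts == expected
        assert full.mean() > 0.9
        assert (small_strata.counts <= expected).all()

    def test_feature_vectors_all_finite(self, small_strata):
        assert np.isfinite(small_strata.X).all()

    def test_subset_and_select_features_roundtrip(self, small_strata):
        sub = small_strata.subset(np.arange(small_strata.n_strata) % 2 == 0)
        assert sub.n_strata == (small_strata.n_strata + 1) // 2
        sel = sub.select_features(["pm25_ma02", "temp_lag0"])
        assert sel.feature_labels == ["pm25_ma02", "temp_lag0"]
        assert sel.X.shape == (sub.n_rows, 2)
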
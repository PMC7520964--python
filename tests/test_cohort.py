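"""Cohort I/O, exclusion rules and SGA derivation."""

import numpy as np
import pandas as pd
import pytest

from parage import (
    FilterReport,
    ParseError,
    SchemaError,
    derive_sga,
    filter_cohort,
    read_births,
    write_births,
    simulate_cohort,
    default_sim_config,
)
from conftest import make_cohort


class TestReadBirths:
    def test_parses_rows_and_missing_father(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("mage,page,preterm\n20,25,0\n30,31,1\n28,,0\n")
        cohort = read_births(p)
        assert len(cohort) == 3
        recs = list(cohort.records)
        assert [r.maternal_age for r in recs] == [20, 30, 28]
        assert recs[2].paternal_age is None
        assert recs[1].outcomes["preterm"] is True
        assert recs[0].outcomes["sga"] is None  # column absent -> missing

    def test_header_only_gives_empty_cohort(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("mage,page,ds,cd\n")
        assert len(read_births(p)) == 0

    def test_missing_maternal_age_column_is_schema_error(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("page,ds\n31,0\n")
        with pytest.raises(SchemaError, match="mage"):
            read_births(p)

    def test_bad_age_cell_names_row(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("mage,page\n20,25\nxx,30\n")
        with pytest.raises(ParseError, match="row 2"):
            read_births(p)

    def test_unknown_columns_ignored(self, tmp_path, caplog):
        p = tmp_path / "b.csv"
        p.write_text("mage,bogus\n20,7\n")
        cohort = read_births(p)
        assert len(cohort) == 1
        assert "bogus" not in cohort.df.columns

    def test_round_trip_identity(self, tmp_path):
        cfg = default_sim_config(n_births=500, seed=9)
        cfg = type(cfg).from_dict({**cfg.to_dict(), "include_birthweight": True})
        cohort, _ = simulate_cohort(cfg)
        path = tmp_path / "rt.csv"
        write_births(cohort, path)
        back = read_births(path)
        pd.testing.assert_frame_equal(
            cohort.df, back.df[cohort.df.columns], check_dtype=False
        )


class TestFilterCohort:
    def test_single_young_mother_excluded(self):
        rows = [{"mage": 14, "page": 20}] + [{"mage": 20 + i, "page": 25} for i in range(9)]
        kept, rep = filter_cohort(make_cohort(rows))
        assert len(kept) == 9
        assert rep.n_mother_under_min == 1
        assert rep.n_deleted_for_parent_age == 1

    def test_missing_father_counted_in_father_category(self):
        kept, rep = filter_cohort(make_cohort([{"mage": 30, "page": None}]))
        assert len(kept) == 0
        assert rep.n_father_out_of_range_or_missing == 1

    def test_parent_age_takes_precedence_over_missing_outcome(self):
        rows = [{"mage": 14, "page": 20, "preterm": None}]
        _, rep = filter_cohort(make_cohort(rows))
        assert rep.n_mother_under_min == 1
        assert rep.n_deleted_for_missing_outcome == 0

    def test_missing_outcome_excluded_after_parent_rules(self):
        rows = [{"mage": 30, "page": 31, "nicu": None}, {"mage": 30, "page": 31}]
        kept, rep = filter_cohort(make_cohort(rows))
        assert len(kept) == 1
        assert rep.n_deleted_for_missing_outcome == 1

    def test_inverted_range_raises(self):
        with pytest.raises(ValueError, match="[Ii]nverted"):
            filter_cohort(make_cohort([{"mage": 30, "page": 31}]), maternal_range=(49, 15))

    def test_report_conserves_and_matches_planted_counts(self, sim_default):
        rep = sim_default["report"]
        assert rep.as_dict() == sim_default["truth"].planted
        assert rep.n_input == rep.n_retained + rep.n_deleted_for_parent_age + rep.n_deleted_for_missing_outcome

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError):
            FilterReport(10, 1, 0, 0, 1, 0, 5)


class TestDeriveSGA:
    def test_hand_computed_quantile_flags_two_lightest(self):
        rows = [
            {"mage": 30, "page": 31, "birthweight_g": 100 * (i + 1), "gestation_days": 270}
            for i in range(20)
        ]
        out = derive_sga(make_cohort(rows))
        flags = out.df["sga"].to_numpy(dtype=bool)
        # linear-interpolated 10th percentile of 100..2000 is 290
        assert flags.sum() == 2
        assert flags[:2].all()

    def test_identical_weights_flag_nothing(self):
        rows = [{"mage": 30, "page": 31, "birthweight_g": 3000, "gestation_days": 270}] * 15
        out = derive_sga(make_cohort(rows))
        assert not out.df["sga"].any()

    def test_gestation_days_thresholds_independent(self):
        rng = np.random.default_rng(0)
        rows = []
        for day, lo in ((250, 1000), (280, 3000)):
            for w in rng.integers(lo, lo + 500, size=40):
                rows.append({"mage": 30, "page": 31, "birthweight_g": int(w), "gestation_days": day})
        cohort = make_cohort(rows)
        out = derive_sga(cohort)
        df = out.df
        for day in (250, 280):
            grp = df[df["gestation_days"] == day]
            w = grp["birthweight_g"].to_numpy(dtype=float)
            thr = np.quantile(w, 0.10, method="linear")
            assert (grp["sga"].to_numpy(dtype=bool) == (w < thr)).all()

    def test_flags_about_ten_percent_of_large_group(self):
        rng = np.random.default_rng(1)
        rows = [
            {"mage": 30, "page": 31, "birthweight_g": int(w), "gestation_days": 270}
            for w in rng.normal(3300, 450, size=10000)
        ]
        out = derive_sga(make_cohort(rows))
        frac = out.df["sga"].to_numpy(dtype=bool).mean()
        assert 0.09 <= frac <= 0.11

    def test_records_without_weight_keep_existing_flag(self):
        rows = [{"mage": 30, "page": 31, "sga": True}]
        out = derive_sga(make_cohort(rows + [
            {"mage": 30, "page": 31, "birthweight_g": 3000, "gestation_days": 270}
        ] * 12))
        assert bool(out.df.loc[0, "sga"]) is True
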
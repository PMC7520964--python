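"""Cross-tabulation correctness and marginalization identities."""

import numpy as np
import pytest

from parage import (
    OUTCOMES,
    read_counts,
    tabulate_binary,
    tabulate_by_age,
    tabulate_joint,
    write_counts,
)
from conftest import make_cohort


def test_counts_at_single_age():
    rows = [{"mage": 30, "page": 35, "death": i == 0} for i in range(4)]
    t = tabulate_by_age(make_cohort(rows), "maternal")
    assert t.n[30 - 15] == 4
    assert t.Y["death"][30 - 15] == 1
    assert t.n.sum() == 4


def test_empty_cohort_gives_full_zero_span():
    t = tabulate_by_age(make_cohort([]), "paternal")
    assert len(t.ages) == 51 and t.ages[0] == 15 and t.ages[-1] == 65
    assert t.n.sum() == 0 and all(t.Y[k].sum() == 0 for k in OUTCOMES)


def test_age_sums_equal_cohort_totals(sim_default):
    filt = sim_default["filtered"]
    t = tabulate_by_age(filt, "maternal")
    for k in OUTCOMES:
        assert t.Y[k].sum() == int(filt.df[k].astype(bool).sum())
    assert t.n.sum() == len(filt)


def test_single_record_fills_exactly_one_cell():
    j = tabulate_joint(make_cohort([{"mage": 30, "page": 35, "nicu": True}]))
    assert j.n.sum() == 1 and j.n[30 - 15, 35 - 15] == 1
    assert j.Y["nicu"].sum() == 1 and j.Y["nicu"][30 - 15, 35 - 15] == 1


def test_joint_grid_complete_regardless_of_sparsity():
    j = tabulate_joint(make_cohort([{"mage": 20, "page": 22}]))
    assert j.n.shape == (35, 51)
    assert j.n.size == 1785


def test_joint_marginals_equal_univariate_tables(sim_default):
    filt = sim_default["filtered"]
    j = tabulate_joint(filt)
    for axis in ("maternal", "paternal"):
        u = tabulate_by_age(filt, axis)
        m = j.marginal(axis)
        assert np.array_equal(m.n, u.n)
        for k in OUTCOMES:
            assert np.array_equal(m.Y[k], u.Y[k])


def test_unfiltered_ages_rejected():
    with pytest.raises(ValueError, match="filter"):
        tabulate_by_age(make_cohort([{"mage": 12, "page": 30}]), "maternal")


class TestTabulateBinary:
    def test_symmetric_table_has_unit_sample_or(self):
        rows = (
            [{"mage": 30, "page": 31, "ds": True, "death": True},
             {"mage": 30, "page": 31, "ds": True}]
            + [{"mage": 30, "page": 31, "death": True}, {"mage": 30, "page": 31}]
        )
        t = tabulate_binary(make_cohort(rows), "ds")
        c = t.counts["death"]
        assert (c.cases_exposed, c.births_exposed, c.cases_unexposed, c.births_unexposed) == (1, 2, 1, 2)

    def test_no_exposed_births_when_flags_false(self):
        t = tabulate_binary(make_cohort([{"mage": 30, "page": 31}] * 5), "cd")
        assert all(c.births_exposed == 0 for c in t.counts.values())

    def test_ds_positive_cd_negative_is_unexposed_for_cd(self):
        rows = [{"mage": 30, "page": 31, "ds": True}, {"mage": 30, "page": 31, "cd": True}]
        t = tabulate_binary(make_cohort(rows), "cd")
        assert t.counts["death"].births_exposed == 1
        assert t.counts["death"].births_unexposed == 1

    def test_counts_match_per_record_recount(self):
        rng = np.random.default_rng(4)
        rows = [
            {
                "mage": 30,
                "page": 31,
                "ds": bool(rng.random() < 0.3),
                "cd": bool(rng.random() < 0.2),
                "death": bool(rng.random() < 0.4),
            }
            for _ in range(200)
        ]
        t = tabulate_binary(make_cohort(rows), "ds")
        c = t.counts["death"]
        brute = [
            sum(1 for r in rows if r["ds"] and r["death"]),
            sum(1 for r in rows if r["ds"]),
            sum(1 for r in rows if not r["ds"] and r["death"]),
            sum(1 for r in rows if not r["ds"]),
        ]
        assert list(c) == brute


def test_count_csv_round_trip(tmp_path, sim_default):
    filt = sim_default["filtered"]
    u = tabulate_by_age(filt, "maternal")
    p = tmp_path / "counts.csv"
    write_counts(u, p)
    back = read_counts(p)
    assert np.array_equal(back.n, u.n)
    for k in OUTCOMES:
        assert np.array_equal(back.Y[k], u.Y[k])

    j = tabulate_joint(filt, outcomes=("death",))
    pj = tmp_path / "joint.csv"
    write_counts(j, pj)
    backj = read_counts(pj)
    assert np.array_equal(backj.n, j.n)
    assert np.array_equal(backj.Y["death"], j.Y["death"])
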
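"""Two-group statistics: t-tests, chi-square, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats import weightstats

from tfbsmeth import (
    AnalysisParams,
    DataError,
    bh_adjust,
    chi_square_2x2,
    differential_units,
    global_burden_test,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_matches_independent_package_to_ten_digits(self):
        a = [0.8, 0.85, 0.9, 0.82]
        b = [0.5, 0.55, 0.6]
        t, df, p = two_sample_t(a, b, "student_pooled")
        t_ref, p_ref, df_ref = weightstats.ttest_ind(a, b, usevar="pooled")
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert df == df_ref
        t, df, p = two_sample_t(a, b, "welch")
        t_ref, p_ref, df_ref = weightstats.ttest_ind(a, b, usevar="unequal")
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert df == pytest.approx(df_ref, rel=1e-12)

    def test_zero_variance_conventions(self):
        t, _, p = two_sample_t([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)
        t, _, p = two_sample_t([2, 2, 2], [3, 3, 3])
        assert np.isinf(t) and p == 0.0

    def test_insufficient_n_rejected(self):
        with pytest.raises(DataError):
            two_sample_t([1.0], [1, 2, 3])

    def test_missing_values_dropped(self):
        t1 = two_sample_t([1, 2, np.nan, 3], [4, 5, 6])
        t2 = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t1 == t2


class TestDifferentialUnits:
    def _sheet(self, na=4, nb=3):
        return pd.DataFrame(
            {
                "sample_id": [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)],
                "group": ["NFPA"] * na + ["GHPA"] * nb,
            }
        )

    def test_relabeling_swaps_direction_keeps_p(self):
        rng = np.random.default_rng(0)
        sheet = self._sheet()
        values = pd.DataFrame(
            rng.random((30, 7)), index=[f"u{i:02d}" for i in range(30)],
            columns=sheet["sample_id"],
        )
        res1, _ = differential_units(values, sheet, AnalysisParams(group_a="NFPA", group_b="GHPA"))
        res2, _ = differential_units(values, sheet, AnalysisParams(group_a="GHPA", group_b="NFPA"))
        m = res1.merge(res2, on="unit_id", suffixes=("_1", "_2"))
        assert np.allclose(m["p_value_1"], m["p_value_2"])
        swap = {"hypo_in_b": "hypo_in_a", "hypo_in_a": "hypo_in_b", "none": "none"}
        assert (m["direction_1"].map(swap) == m["direction_2"]).all()

    def test_matches_scalar_path_per_unit(self):
        rng = np.random.default_rng(1)
        sheet = self._sheet(5, 4)
        values = pd.DataFrame(
            rng.random((20, 9)), index=[f"u{i:02d}" for i in range(20)], columns=sheet["sample_id"]
        )
        values.iloc[rng.random((20, 9)) < 0.1] = np.nan
        for variant in ("student_pooled", "welch"):
            res, skipped = differential_units(
                values, sheet, AnalysisParams(test_variant=variant)
            )
            for row in res.itertuples(index=False):
                a = values.loc[row.unit_id, sheet.loc[sheet["group"] == "NFPA", "sample_id"]]
                b = values.loc[row.unit_id, sheet.loc[sheet["group"] == "GHPA", "sample_id"]]
                t, df, p = two_sample_t(a, b, variant)
                assert row.t_stat == pytest.approx(t, rel=1e-10)
                assert row.df == pytest.approx(df, rel=1e-10)
                assert row.p_value == pytest.approx(p, rel=1e-10)

    def test_units_with_insufficient_data_are_skipped(self):
        sheet = self._sheet(3, 3)
        values = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [np.nan, np.nan, 0.3, 0.4, 0.5, 0.6]],
            index=["ok", "thin"], columns=sheet["sample_id"],
        )
        res, skipped = differential_units(values, sheet)
        assert skipped == ["thin"]
        assert res["unit_id"].tolist() == ["ok"]

    def test_location_shift_equivariance(self):
        """Adding a constant to every value leaves t and p unchanged."""
        rng = np.random.default_rng(2)
        sheet = self._sheet()
        values = pd.DataFrame(
            rng.random((15, 7)) * 0.5, index=[f"u{i}" for i in range(15)], columns=sheet["sample_id"]
        )
        res1, _ = differential_units(values, sheet)
        res2, _ = differential_units(values + 0.3, sheet)
        assert np.allclose(res1["t_stat"], res2["t_stat"])
        assert np.allclose(res1["p_value"], res2["p_value"])

    def test_sorted_by_p_then_unit_id(self):
        rng = np.random.default_rng(3)
        sheet = self._sheet()
        values = pd.DataFrame(
            rng.random((25, 7)), index=[f"u{i:02d}" for i in range(25)], columns=sheet["sample_id"]
        )
        res, _ = differential_units(values, sheet)
        key = list(zip(res["p_value"], res["unit_id"]))
        assert key == sorted(key)


class TestBurdenTest:
    def test_equal_count_vectors_give_p_one(self):
        sheet = pd.DataFrame({"sample_id": list("abcdef"), "group": ["X"] * 3 + ["Y"] * 3})
        counts = pd.Series([5, 6, 7, 5, 6, 7], index=list("abcdef"))
        out = global_burden_test(counts, sheet)
        assert out["p_value"] == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        sheet = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)], "group": ["X"] * 5 + ["Y"] * 5}
        )
        counts = pd.Series(rng.integers(0, 50, 10), index=sheet["sample_id"])
        out1 = global_burden_test(counts, sheet)
        out2 = global_burden_test(counts.sample(frac=1, random_state=9), sheet)
        assert out1 == out2

    def test_missing_sample_is_error(self):
        sheet = pd.DataFrame({"sample_id": ["a", "b", "c", "d"], "group": ["X", "X", "Y", "Y"]})
        counts = pd.Series([1, 2, 3], index=["a", "b", "c"])
        with pytest.raises(DataError, match="missing"):
            global_burden_test(counts, sheet)


class TestChiSquare:
    def test_uniform_table_is_null(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_pearson(self):
        # sum (O-E)^2/E with all E = 12.5 -> 4 * 7.5^2/12.5 = 18
        chi2, p = chi_square_2x2([[20, 5], [5, 20]])
        assert chi2 == pytest.approx(18.0)

    def test_transposition_invariance(self):
        t = np.array([[13, 4], [7, 21]])
        assert chi_square_2x2(t) == chi_square_2x2(t.T)

    def test_zero_marginal_suggests_exact_test(self):
        with pytest.raises(DataError, match="exact"):
            chi_square_2x2([[0, 0], [5, 10]])


def manual_bh(p):
    """Independent step-up oracle: q_i = min over j with p_j >= p_i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_worked_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_manual_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50))).clip(1e-12, 1.0)
            assert np.allclose(bh_adjust(p), manual_bh(p), atol=1e-12)
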
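"""Normalization and differential testing against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lncpanel as lp
from lncpanel.errors import InputError


def bh_step_up_oracle(p):
    """Literal BH step-up enumeration: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q[order[i]] = running
    return q


def student_two_sample_p(x, y):
    """Textbook pooled-variance two-tailed Student t-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * stats.t.sf(abs(t), nx + ny - 2)


def make_matrix(tumor_rows, normal_rows, probes=None):
    """Paired matrix from per-probe tumor/normal value lists."""
    tumor_rows = np.atleast_2d(np.asarray(tumor_rows, float))
    normal_rows = np.atleast_2d(np.asarray(normal_rows, float))
    n_pairs = tumor_rows.shape[1]
    cols, data = [], []
    for i in range(n_pairs):
        cols += [f"P{i + 1:02d}_T", f"P{i + 1:02d}_N"]
        data += [tumor_rows[:, i], normal_rows[:, i]]
    probes = probes or [f"PR{i}" for i in range(tumor_rows.shape[0])]
    return pd.DataFrame(np.column_stack(data), index=probes, columns=cols)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame(
            {"a": [1.0, 4.0, 2.0], "b": [1.0, 4.0, 2.0]}, index=list("xyz")
        )
        out = lp.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_two_by_two_sorted_mean(self):
        df = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]}, index=["p", "q"])
        out = lp.quantile_normalize(df)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0]}, index=list("xyz"))
        pd.testing.assert_frame_equal(lp.quantile_normalize(df), df)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(5, 1, size=(50, 4)))
        once = lp.quantile_normalize(df)
        twice = lp.quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((30, 3)))
        out = lp.quantile_normalize(df)
        for c in df.columns:
            assert (
                np.argsort(out[c].to_numpy(), kind="mergesort")
                == np.argsort(df[c].to_numpy(), kind="mergesort")
            ).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            lp.quantile_normalize(pd.DataFrame())


class TestPairedLog2fc:
    def test_exact_doubling(self):
        m = make_matrix([[200.0, 400.0]], [[100.0, 200.0]])
        # pseudocount 0 keeps the ratio exact
        assert lp.paired_log2fc(m, pseudocount=0.0).iloc[0] == pytest.approx(1.0)

    def test_no_change_is_zero(self):
        m = make_matrix([[50.0, 70.0]], [[50.0, 70.0]])
        assert lp.paired_log2fc(m, pseudocount=0.0).iloc[0] == 0.0

    def test_mean_of_ratios_example(self):
        m = make_matrix([[4.0, 8.0]], [[1.0, 2.0]])
        assert lp.paired_log2fc(m, pseudocount=0.0).iloc[0] == pytest.approx(2.0)

    def test_ratio_of_means_estimator(self):
        m = make_matrix([[4.0, 8.0]], [[1.0, 2.0]])
        expected = np.log2(6.0 / 1.5)
        got = lp.paired_log2fc(m, pseudocount=0.0, estimator="ratio_of_means")
        assert got.iloc[0] == pytest.approx(expected)

    def test_unpaired_column_error_names_pair(self):
        df = pd.DataFrame({"P01_T": [1.0], "P01_N": [1.0], "P02_T": [1.0]},
                          index=["x"])
        with pytest.raises(InputError, match="P02"):
            lp.paired_log2fc(df)


class TestTTest:
    def test_identical_groups_give_p_one(self):
        m = make_matrix([[3.0, 7.0, 5.0]], [[3.0, 7.0, 5.0]])
        assert lp.t_test(m, mode="two_sample").iloc[0] == pytest.approx(1.0)

    def test_degenerate_zero_variance_paired(self):
        # log2 differences are constant and non-zero: p defined as 1
        m = make_matrix([[3.0, 3.0, 3.0]], [[1.0, 1.0, 1.0]])
        assert lp.t_test(m, mode="paired").iloc[0] == 1.0

    def test_two_sample_matches_textbook_formula(self):
        # intensities chosen so log2(v+1) = (1,2,3) vs (4,5,6)
        t = 2.0 ** np.array([1.0, 2.0, 3.0]) - 1
        n = 2.0 ** np.array([4.0, 5.0, 6.0]) - 1
        m = make_matrix([t], [n])
        expected = student_two_sample_p([1, 2, 3], [4, 5, 6])
        assert lp.t_test(m, mode="two_sample").iloc[0] == pytest.approx(
            expected, abs=1e-10
        )

    @pytest.mark.parametrize("n_pairs", [2, 3, 4, 5, 6])
    def test_random_inputs_match_oracle(self, n_pairs):
        rng = np.random.default_rng(n_pairs)
        tumor = rng.uniform(10, 1000, size=(8, n_pairs))
        normal = rng.uniform(10, 1000, size=(8, n_pairs))
        m = make_matrix(tumor, normal)
        got = lp.t_test(m, mode="two_sample")
        for i in range(8):
            expected = student_two_sample_p(
                np.log2(tumor[i] + 1), np.log2(normal[i] + 1)
            )
            assert got.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_paired_matches_scipy_rel(self):
        rng = np.random.default_rng(9)
        tumor = rng.uniform(10, 1000, size=(5, 6))
        normal = rng.uniform(10, 1000, size=(5, 6))
        m = make_matrix(tumor, normal)
        got = lp.t_test(m, mode="paired")
        expected = stats.ttest_rel(
            np.log2(tumor + 1), np.log2(normal + 1), axis=1
        ).pvalue
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)

    def test_single_pair_rejected(self):
        m = make_matrix([[3.0]], [[1.0]])
        with pytest.raises(InputError):
            lp.t_test(m)


class TestBenjaminiHochberg:
    def test_all_tied_share_value(self):
        np.testing.assert_allclose(
            lp.benjamini_hochberg([0.01] * 5), [0.01] * 5, atol=1e-15
        )

    def test_hand_derived_step_up(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        np.testing.assert_allclose(lp.benjamini_hochberg(p), [0.05] * 5, atol=1e-15)

    def test_single_p_unchanged(self):
        assert lp.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            lp.benjamini_hochberg([0.5, 1.2])
        with pytest.raises(InputError):
            lp.benjamini_hochberg([-0.1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(
                lp.benjamini_hochberg(p), bh_step_up_oracle(p), atol=1e-12
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_bounded(self, p):
        q = lp.benjamini_hochberg(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0 + 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestVolcanoFilter:
    def make_de(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr"],
                            index=[f"p{i}" for i in range(len(rows))])

    def test_boundary_fold_change_excluded(self):
        de = self.make_de([[1.0, 0.01]])  # fold change exactly 2.0
        up, down = lp.volcano_filter(de)
        assert up == [] and down == []

    def test_empty_table(self):
        up, down = lp.volcano_filter(self.make_de([]))
        assert up == [] and down == []

    def test_three_probe_example(self):
        de = self.make_de([[1.5, 0.01], [-2.0, 0.04], [3.0, 0.2]])
        up, down = lp.volcano_filter(de)
        assert up == ["p0"] and down == ["p1"]

    def test_fdr_threshold_one_disables_gate(self):
        de = self.make_de([[2.0, 1.0]])
        up, down = lp.volcano_filter(de, fdr_threshold=1.0)
        assert up == ["p0"]


class TestDeTable:
    def test_per_class_bh_matches_manual_split(self, dataset):
        matrix, truth = dataset
        classes = truth.set_index("probe_id")["probe_class"]
        table = lp.de_table(matrix, probe_classes=classes)
        for cls in ("lncrna", "mrna"):
            ids = classes.index[classes == cls]
            manual = lp.benjamini_hochberg(table.loc[ids, "p_raw"].to_numpy())
            np.testing.assert_allclose(
                table.loc[ids, "fdr"].to_numpy(), manual, atol=1e-12
            )

    def test_direction_consistent_with_sign(self, dataset):
        matrix, truth = dataset
        table = lp.de_table(matrix)
        passing = table[table["passes_filter"]]
        assert (passing.loc[passing["log2fc"] > 0, "direction"] == "up").all()
        assert (passing.loc[passing["log2fc"] < 0, "direction"] == "down").all()
        assert (table.loc[~table["passes_filter"], "direction"] == "none").all()
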
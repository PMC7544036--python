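"""Feature-table group comparison: Wilcoxon, BH FDR, abundance summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from irgps import abundance_summary, compare_groups, filter_quality, simulate_cell_fractions


def bh_oracle(pvals):
    """BH step-up directly from its definition with a cumulative minimum."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _table(values, features=None, index=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"CellType{i:02d}" for i in range(1, values.shape[1] + 1)]
    index = index or [f"s{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=index, columns=features)


class TestFilterQuality:
    def test_keeps_samples_below_threshold(self):
        table = _table(np.ones((6, 2)))
        table["p_value"] = [0.001, 0.04, 0.05, 0.2, 0.049, 0.9]
        assert filter_quality(table).shape[0] == 3  # 0.05 itself is dropped

    def test_378_sample_style_funnel(self):
        rng = np.random.default_rng(0)
        table = _table(rng.dirichlet(np.ones(5), size=378))
        p = np.full(378, 0.001)
        p[[10, 99, 200, 333]] = 0.5
        table["p_value"] = p
        assert filter_quality(table).shape[0] == 374

    def test_all_pass_is_identity(self):
        table = _table(np.ones((4, 2)))
        table["p_value"] = 0.01
        pd.testing.assert_frame_equal(filter_quality(table), table)

    def test_threshold_zero_empties_table(self):
        table = _table(np.ones((4, 2)))
        table["p_value"] = 0.01
        filtered = filter_quality(table, p_threshold=0.0)
        assert filtered.shape[0] == 0
        with pytest.raises(ValueError):
            compare_groups(filtered, pd.Series(dtype=object))

    def test_missing_quality_column_rejected(self):
        with pytest.raises(KeyError, match="p_value"):
            filter_quality(_table(np.ones((3, 2))))


class TestCompareGroups:
    def test_bh_step_up_hand_example(self):
        # p = [.01, .02, .03, .04], m = 4 -> q = [.04, .04, .04, .04]
        q = bh_oracle([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        _, q_sm, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert q_sm == pytest.approx(q)

    def test_q_values_reproduce_step_up_oracle(self):
        rng = np.random.default_rng(2)
        table = _table(rng.normal(size=(60, 9)))
        table.iloc[:30, 0] += 2.0
        groups = pd.Series(["high"] * 30 + ["low"] * 30, index=table.index)
        result = compare_groups(table, groups)
        assert result["fdr_q"].to_numpy() == pytest.approx(bh_oracle(result["wilcoxon_p"]), abs=1e-12)

    def test_bh_invariant_to_feature_order(self):
        rng = np.random.default_rng(7)
        table = _table(rng.normal(size=(40, 6)))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=table.index)
        forward = compare_groups(table, groups)
        shuffled = compare_groups(table[list(table.columns[::-1])], groups)
        assert forward.loc["CellType03", "fdr_q"] == pytest.approx(shuffled.loc["CellType03", "fdr_q"])

    def test_exact_mode_matches_enumeration_small_n(self):
        a = [1.3, 0.2, 2.9, 0.7]
        b = [1.9, 0.4, 3.3, 2.1]
        table = _table(np.array(a + b)[:, None], features=["f"])
        groups = pd.Series(["x"] * 4 + ["y"] * 4, index=table.index)
        got = compare_groups(table, groups).loc["f", "wilcoxon_p"]
        ranks = pd.Series(a + b).rank().to_numpy()
        observed = ranks[:4].sum()
        centre = ranks.sum() / 2
        stats_all = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(8), 4)])
        p_exact = np.mean(np.abs(stats_all - centre) >= abs(observed - centre) - 1e-12)
        assert got == pytest.approx(p_exact, abs=1e-12)

    def test_shifted_feature_flagged(self):
        rng = np.random.default_rng(15)
        table = _table(rng.normal(0, 1, size=(300, 8)))
        table.iloc[:150, 3] += 2.0  # two pooled SDs on one feature
        groups = pd.Series(["high"] * 150 + ["low"] * 150, index=table.index)
        result = compare_groups(table, groups)
        assert result.iloc[3]["fdr_q"] < 0.01
        assert result["fdr_q"].drop(result.index[3]).min() > 0.01

    def test_null_features_rarely_discovered(self):
        rng = np.random.default_rng(99)
        groups = pd.Series(["high"] * 80 + ["low"] * 80, index=[f"s{i}" for i in range(160)])
        fractions = simulate_cell_fractions(groups, seed=5)
        result = compare_groups(fractions, groups, compositional=True)
        assert int(result["significant"].sum()) == 0

    def test_constant_feature_warns_with_p_one(self):
        table = _table(np.column_stack([np.ones(10), np.arange(10.0)]), features=["const", "varies"])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=table.index)
        with pytest.warns(UserWarning, match="identical values"):
            result = compare_groups(table, groups)
        assert result.loc["const", "wilcoxon_p"] == 1.0

    def test_compositional_validation(self):
        table = _table(np.full((4, 2), 0.3))
        groups = pd.Series(["a", "a", "b", "b"], index=table.index)
        with pytest.raises(ValueError, match="sum to 1"):
            compare_groups(table, groups, compositional=True)

    def test_quality_columns_never_treated_as_features(self):
        rng = np.random.default_rng(3)
        table = _table(rng.dirichlet(np.ones(4), size=20))
        table["p_value"] = 0.01
        table["Correlation"] = 0.8
        table["RMSE"] = 0.4
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=table.index)
        result = compare_groups(table, groups, compositional=True)
        assert set(result.index) == {f"CellType{i:02d}" for i in range(1, 5)}


class TestAbundanceSummary:
    def test_min_fraction_bounds(self):
        rng = np.random.default_rng(6)
        groups = pd.Series(["high"] * 30 + ["low"] * 30, index=[f"s{i}" for i in range(60)])
        fractions = simulate_cell_fractions(groups, seed=8)
        assert abundance_summary(fractions, groups, min_fraction=0.0) == list(fractions.columns)
        assert abundance_summary(fractions, groups, min_fraction=1.0) == []

    def test_constructed_table_selects_exactly_the_abundant_feature(self):
        high = np.array([[0.06, 0.02, 0.92], [0.06, 0.02, 0.92]])
        low = np.array([[0.07, 0.01, 0.92], [0.07, 0.01, 0.92]])
        table = _table(np.vstack([high, low]), features=["abundant", "rare", "bulk"])
        groups = pd.Series(["high", "high", "low", "low"], index=table.index)
        assert abundance_summary(table, groups, min_fraction=0.05) == ["abundant", "bulk"]
        assert abundance_summary(table, groups, min_fraction=0.5) == ["bulk"]

    def test_invalid_fraction_rejected(self):
        table = _table(np.ones((2, 2)))
        groups = pd.Series(["a", "b"], index=table.index)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            abundance_summary(table, groups, min_fraction=1.5)
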
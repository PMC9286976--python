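import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from climbkit.fly_simulator import simulate_flight_window
from climbkit.group_stats import (
    fisher_exact,
    marascuilo,
    two_way_anova_tukey,
    window_analysis,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def balanced_anova_oracle(df, response, fa, fb):
    """Least-squares SS decomposition for a balanced two-way layout."""
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(df[fa].unique())
    b_levels = sorted(df[fb].unique())
    r = len(df) / (len(a_levels) * len(b_levels))
    mean_a = {a: df.loc[df[fa] == a, response].mean() for a in a_levels}
    mean_b = {b: df.loc[df[fb] == b, response].mean() for b in b_levels}
    cell = {
        (a, b): df.loc[(df[fa] == a) & (df[fb] == b), response].mean()
        for a in a_levels
        for b in b_levels
    }
    ss_a = len(b_levels) * r * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = len(a_levels) * r * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = r * sum(
        (cell[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_res = sum(
        (row[response] - cell[(row[fa], row[fb])]) ** 2 for _, row in df.iterrows()
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = len(df) - len(a_levels) * len(b_levels)
    ms_res = ss_res / df_res
    return {
        "ss": (ss_a, ss_b, ss_ab, ss_res),
        "F": (ss_a / df_a / ms_res, ss_b / df_b / ms_res, ss_ab / df_ab / ms_res),
    }


@pytest.fixture
def balanced_2x2():
    # 2x2, 3 replicates per cell, integer responses
    rows = []
    data = {
        ("control", 0.0): [10, 12, 14],
        ("control", 9.0): [8, 9, 10],
        ("park25", 0.0): [4, 5, 6],
        ("park25", 9.0): [9, 10, 11],
    }
    for (g, d), ys in data.items():
        for y in ys:
            rows.append({"genotype": g, "dose": d, "metric": y})
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_fixture_matches_oracle(self, balanced_2x2):
        res = two_way_anova_tukey(balanced_2x2, "metric", "genotype", "dose")
        oracle = balanced_anova_oracle(balanced_2x2, "metric", "genotype", "dose")
        t = res.anova_table
        got_ss = (
            t.loc["genotype", "sum_sq"],
            t.loc["dose", "sum_sq"],
            t.loc["genotype:dose", "sum_sq"],
            t.loc["Residual", "sum_sq"],
        )
        assert got_ss == pytest.approx(oracle["ss"])
        got_f = (
            t.loc["genotype", "F"],
            t.loc["dose", "F"],
            t.loc["genotype:dose", "F"],
        )
        assert got_f == pytest.approx(oracle["F"])

    def test_ss_total_decomposition_balanced(self, balanced_2x2):
        res = two_way_anova_tukey(balanced_2x2, "metric", "genotype", "dose")
        y = balanced_2x2["metric"].to_numpy(dtype=float)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert res.anova_table["sum_sq"].sum() == pytest.approx(ss_total)

    def test_no_effect_configuration(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in ("a", "b"):
            for d in ("x", "y"):
                noise = rng.normal(0, 1, 6)
                noise = noise - noise.mean()  # identical cell means, noise within
                rows.extend(
                    {"g": g, "d": d, "y": 5.0 + e} for e in noise
                )
        df = pd.DataFrame(rows)
        res = two_way_anova_tukey(df, "y", "g", "d")
        for factor in ("g", "d", "g:d"):
            assert res.anova_table.loc[factor, "sum_sq"] == pytest.approx(0.0, abs=1e-9)
            assert res.anova_table.loc[factor, "F"] == pytest.approx(0.0, abs=1e-9)

    def test_tukey_identical_groups(self):
        rows = []
        for g in ("a", "b"):
            for d in ("x", "y"):
                rows.extend({"g": g, "d": d, "y": v} for v in (1.0, 2.0, 3.0))
        res = two_way_anova_tukey(pd.DataFrame(rows), "y", "g", "d", tukey_on="g")
        row = res.tukey_table.iloc[0]
        assert float(row["meandiff"]) == pytest.approx(0.0)
        assert float(row["p-adj"]) == pytest.approx(1.0, abs=1e-6)

    def test_undefined_values_dropped_with_count(self, balanced_2x2):
        df = balanced_2x2.copy()
        df.loc[0, "metric"] = math.nan
        res = two_way_anova_tukey(df, "metric", "genotype", "dose")
        assert res.n_dropped == 1
        assert res.n_used == len(df) - 1

    def test_empty_cell_named_in_error(self, balanced_2x2):
        df = balanced_2x2[
            ~((balanced_2x2["genotype"] == "park25") & (balanced_2x2["dose"] == 9.0))
        ]
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova_tukey(df, "metric", "genotype", "dose")

    def test_constant_response_rejected(self, balanced_2x2):
        df = balanced_2x2.assign(metric=7.0)
        with pytest.raises(ValueError, match="constant"):
            two_way_anova_tukey(df, "metric", "genotype", "dose")

    def test_type3_option_runs(self, balanced_2x2):
        res = two_way_anova_tukey(balanced_2x2, "metric", "genotype", "dose", ss_type=3)
        assert "genotype" in res.anova_table.index


class TestFisherExact:
    def test_hand_enumerated_example(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_p_in_unit_interval(self):
        p = fisher_exact([[10, 2], [3, 9]])
        assert 0 < p <= 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])

    def test_matches_enumeration_small_tables(self):
        # spot check across the N <= 30 grid (full sweep in acceptance suite)
        for a, b, c, d in [
            (2, 3, 4, 5), (1, 9, 9, 1), (7, 0, 2, 6), (3, 3, 3, 3), (12, 1, 2, 15),
        ]:
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )


class TestMarascuilo:
    def test_identical_groups_not_significant(self):
        res = marascuilo([(10, 50), (10, 50)])
        assert not res.pairwise["significant"].any()
        assert res.fisher_p == pytest.approx(1.0)

    def test_degenerate_variance_forced_significant(self):
        res = marascuilo([(0, 100), (100, 100)], alpha=0.05, bonferroni_m=1)
        row = res.pairwise.iloc[0]
        assert row["abs_diff"] == 1.0
        assert row["critical_range"] == 0.0
        assert row["significant"]

    def test_three_group_pattern(self):
        # direct evaluation of the critical-range formula on these counts
        res = marascuilo([(10, 100), (12, 100), (60, 100)])
        sig = {
            frozenset((r["group_i"], r["group_j"])): r["significant"]
            for _, r in res.pairwise.iterrows()
        }
        assert not sig[frozenset(("g0", "g1"))]
        assert sig[frozenset(("g0", "g2"))]
        assert sig[frozenset(("g1", "g2"))]

    def test_control_vs_each_only(self):
        res = marascuilo(
            [(10, 100), (12, 100), (60, 100)],
            labels=["ctrl", "t1", "t2"],
            control="ctrl",
        )
        assert len(res.pairwise) == 2
        assert res.bonferroni_m == 2
        assert set(res.pairwise["group_i"]) == {"ctrl"}

    def test_monotone_in_difference(self):
        # at fixed n, growing |p_i - p_j| never flips significant -> not
        was_significant = False
        for k2 in range(50, 101):
            res = marascuilo([(50, 100), (k2, 100)], bonferroni_m=1)
            sig = bool(res.pairwise["significant"].iloc[0])
            assert sig or not was_significant
            was_significant = was_significant or sig

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            marascuilo([(5, 10)])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            marascuilo([(11, 10), (5, 10)])


class TestWindowAnalysis:
    def test_recovers_known_edge(self):
        day_probs = {d: (0.45 if d <= 5 else 0.06) for d in range(9)}
        records = simulate_flight_window(day_probs, 0.06, n_per_group=50, seed=11)
        res = window_analysis(records)
        assert res.window_edges["park25"] == 5

    def test_all_days_at_baseline_no_edge(self):
        day_probs = {d: 0.10 for d in range(4)}
        records = simulate_flight_window(day_probs, 0.10, n_per_group=40, seed=3)
        res = window_analysis(records)
        assert res.window_edges["park25"] is None

    def test_single_day_rejected(self):
        records = simulate_flight_window({0: 0.5}, 0.05, n_per_group=20, seed=0)
        with pytest.raises(ValueError, match="start days"):
            window_analysis(records)

    def test_table_contents(self):
        day_probs = {0: 0.5, 1: 0.5, 2: 0.05}
        records = simulate_flight_window(day_probs, 0.05, n_per_group=40, seed=5)
        res = window_analysis(records)
        assert set(res.table["start_day"]) == {0, 1, 2}
        assert (res.table["n_treated"] == 40).all()
        assert (res.table["n_untreated"] == 40).all()

    def test_missing_baseline_skipped(self, caplog):
        day_probs = {0: 0.5, 1: 0.5}
        records = [
            r
            for r in simulate_flight_window(day_probs, 0.05, n_per_group=20, seed=1)
            if r.dose_ug_per_ml > 0
        ]
        with caplog.at_level("WARNING"):
            res = window_analysis(records)
        assert res.window_edges == {}
        assert "no untreated baseline" in caplog.text
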
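"""Group-comparison battery: t, exact Wilcoxon / Mann-Whitney against
brute-force enumeration oracles, and ANOVA + Newman-Keuls closure."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vesselperm import (
    anova_newman_keuls,
    compare_groups,
    mann_whitney,
    t_test,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different code paths from the package)


def oracle_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by explicit sign enumeration."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


def oracle_mann_whitney_p(x, y):
    """Exact two-sided U-test p by relabeling; U counted pairwise, not
    via ranks, so the oracle shares no arithmetic with the package."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        us.append(u_stat(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# t tests


class TestTTest:
    def test_identical_paired_data_p_one(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.p_value == 1.0
        assert "zero-variance differences" in res.notes

    def test_identical_unpaired_groups(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_direct_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        # direct arithmetic: means 2.5/4.5, pooled s^2 = 5/3,
        # SE = sqrt(5/3 * 1/2) -> t = -2/sqrt(5/6)
        expected = -2.0 / np.sqrt(5.0 / 6.0)
        res = t_test(x, y)
        assert res.statistic == pytest.approx(expected)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 6

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.5, 1, 10)
        res = t_test(x, y, paired=True)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_welch_flag(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 3, 12)
        res = t_test(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_mismatched_pair_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatched pair ids"):
            t_test([1.0, 2.0], [2.0, 3.0], paired=True,
                   pair_ids_x=["a", "b"], pair_ids_y=["b", "a"])


# ---------------------------------------------------------------------------
# rank tests


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)  # 2/8 sign patterns
        assert res.method == "exact"

    def test_antisymmetric_differences(self):
        assert wilcoxon_signed_rank(np.array([1.0, -1.0])).p_value == 1.0

    def test_all_zero_differences(self):
        res = wilcoxon_signed_rank(np.zeros(5))
        assert res.p_value == 1.0
        assert "all differences zero" in res.notes

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, -3.0]))
        assert "2 zero differences dropped" in res.notes

    def test_exact_matches_enumeration_oracle_n12(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = rng.integers(-5, 6, size=12).astype(float)
            if np.all(d == 0):
                continue
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                oracle_signed_rank_p(d), abs=1e-12
            )

    def test_large_n_switches_to_asymptotic(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.7, 1, 30)
        res = wilcoxon_signed_rank(d)
        assert res.method == "asymptotic"
        ref = sps.wilcoxon(d, mode="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitney:
    def test_separated_pairs_exact_p(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)

    def test_identical_multisets(self):
        assert mann_whitney([1.0, 2.0, 2.0], [2.0, 1.0, 2.0]).p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 14 - n1 + 1))
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            assert mann_whitney(x, y).p_value == pytest.approx(
                oracle_mann_whitney_p(x, y), abs=1e-12
            )

    def test_study_design_sizes_use_asymptotic_mode(self):
        # 8 vs 13 exceeds the exact-enumeration bound; clearly separated
        # groups must still reject
        rng = np.random.default_rng(10)
        x = rng.normal(0.05, 0.01, 8)
        y = rng.normal(0.15, 0.03, 13)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        assert res.p_value < 0.05


class TestRankInvariances:
    @given(
        x=st.lists(st.integers(-10, 10), min_size=2, max_size=7),
        y=st.lists(st.integers(-10, 10), min_size=2, max_size=7),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mann_whitney_symmetric_in_groups(self, x, y):
        p_xy = mann_whitney(x, y).p_value
        p_yx = mann_whitney(y, x).p_value
        assert 0.0 <= p_xy <= 1.0
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    @given(d=st.lists(st.integers(-10, 10), min_size=2, max_size=10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_signed_rank_invariant_under_negation(self, d):
        d = np.asarray(d, float)
        p_pos = wilcoxon_signed_rank(d).p_value
        p_neg = wilcoxon_signed_rank(-d).p_value
        assert 0.0 <= p_pos <= 1.0
        assert p_pos == pytest.approx(p_neg, abs=1e-12)


# ---------------------------------------------------------------------------
# ANOVA + Newman-Keuls


def oracle_newman_keuls(groups, alpha=0.05):
    """Independently coded studentized-range stepwise check."""
    names = list(groups)
    arrs = [np.asarray(groups[g], float) for g in names]
    k = len(arrs)
    ns = [len(a) for a in arrs]
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / (sum(ns) - k)
    df = sum(ns) - k
    order = sorted(range(k), key=lambda i: arrs[i].mean())
    sig = {}
    def test_span(i, j):
        if (i, j) in sig:
            return
        se = np.sqrt(mse / 2 * (1 / ns[order[i]] + 1 / ns[order[j]]))
        q = (arrs[order[j]].mean() - arrs[order[i]].mean()) / se if se else np.inf
        crit = sps.studentized_range.ppf(1 - alpha, j - i + 1, df)
        if q > crit:
            sig[(i, j)] = True
            if j - i > 1:
                test_span(i, j - 1)
                test_span(i + 1, j)
        else:
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    sig.setdefault((a, b), False)
    test_span(0, k - 1)
    return {
        frozenset((names[order[i]], names[order[j]]))
        for (i, j), s in sig.items() if s
    }


class TestAnovaNewmanKeuls:
    def test_identical_groups(self):
        anova, posthoc = anova_newman_keuls({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert anova.statistic == 0.0
        assert anova.p_value == 1.0
        assert posthoc.significant_pairs() == set()

    def test_forced_ordering_two_low_one_high(self):
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 1e-3, 3)
        groups = {
            "a": np.zeros(3) + jitter,
            "b": np.zeros(3),
            "c": np.full(3, 10.0),
        }
        anova, posthoc = anova_newman_keuls(groups)
        sig = posthoc.significant_pairs()
        assert frozenset(("a", "b")) not in sig
        assert frozenset(("a", "c")) in sig
        assert frozenset(("b", "c")) in sig

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 6) for i in range(4)}
        anova, _ = anova_newman_keuls(groups)
        ref = sps.f_oneway(*groups.values())
        assert anova.statistic == pytest.approx(ref.statistic)
        assert anova.p_value == pytest.approx(ref.pvalue)

    def test_four_group_decisions_match_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 2), 1, int(rng.integers(3, 7)))
                for i in range(4)
            }
            _, posthoc = anova_newman_keuls(groups)
            assert posthoc.significant_pairs() == oracle_newman_keuls(groups)

    def test_closure_no_significant_pair_inside_failed_span(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            k = int(rng.integers(3, 6))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 1.5), 1, int(rng.integers(3, 6)))
                for i in range(k)
            }
            _, posthoc = anova_newman_keuls(groups)
            order = sorted(posthoc.pairs, key=lambda p: p.span)
            # index groups by ordered means to check nesting
            names = sorted({p.group_a for p in posthoc.pairs} | {p.group_b for p in posthoc.pairs})
            means = {n: np.mean(groups[n]) for n in names}
            rank = {n: r for r, n in enumerate(sorted(names, key=means.get))}
            failed = [(rank[p.group_a], rank[p.group_b]) for p in posthoc.pairs
                      if p.tested and not p.significant]
            for p in posthoc.pairs:
                if p.significant:
                    i, j = sorted((rank[p.group_a], rank[p.group_b]))
                    for fi, fj in failed:
                        lo, hi = sorted((fi, fj))
                        assert not (lo <= i and j <= hi)

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_newman_keuls({"a": [1.0], "b": [1.0, 2.0], "c": [3.0, 4.0]})
        with pytest.raises(ValueError, match="3 groups"):
            anova_newman_keuls({"a": [1.0, 2.0], "b": [3.0, 4.0]})


# ---------------------------------------------------------------------------
# assay rule: automatic test choice


class TestCompareGroups:
    @staticmethod
    def _table(matched: bool):
        rng = np.random.default_rng(4)
        n = 8
        rows = []
        for i in range(n):
            rows.append({"condition": "normal", "p_um_s": rng.normal(0.05, 0.01),
                         "matched_pair_id": f"p{i}" if matched else None})
            rows.append({"condition": "tumor", "p_um_s": rng.normal(0.15, 0.03),
                         "matched_pair_id": f"p{i}" if matched else None})
        return pd.DataFrame(rows)

    def test_matched_samples_get_wilcoxon(self):
        res = compare_groups(self._table(matched=True))
        assert res.test == "Wilcoxon signed-rank"
        assert res.pairing == "matched"

    def test_unmatched_samples_get_mann_whitney(self):
        res = compare_groups(self._table(matched=False))
        assert res.test == "Mann-Whitney U"
        assert res.pairing == "independent"

    def test_t_mode_respects_pairing(self):
        assert compare_groups(self._table(True), test="t").test == "paired t"
        assert compare_groups(self._table(False), test="t").test == "unpaired t (pooled)"

    def test_more_than_two_groups_rejected(self):
        df = pd.DataFrame({"condition": ["a", "b", "c"], "p_um_s": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="exactly 2 groups"):
            compare_groups(df, pair=None)
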
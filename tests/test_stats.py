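"""Correlation, KS, ANOVA, t and power contracts against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from petihc import stats as st


def rank_midranks(v):
    """Mid-rank assignment by explicit counting (oracle helper)."""
    v = list(v)
    return [1 + sum(x < y for x in v) + (sum(x == y for x in v) - 1) / 2 for y in v]


def kendall_enumeration_p(x, y):
    """Two-sided permutation p for tau by literal enumeration of all n! orderings."""
    def tau(a, b):
        s = sum(np.sign((a[i] - a[j]) * (b[i] - b[j]))
                for i, j in itertools.combinations(range(len(a)), 2))
        return s / math.comb(len(a), 2)

    obs = abs(tau(x, y))
    perms = list(itertools.permutations(y))
    hits = sum(abs(tau(x, list(p))) >= obs - 1e-9 for p in perms)
    return hits / len(perms)


class TestSpearman:
    def test_monotone_is_one(self):
        x = [1.0, 2.5, 4.0, 7.0, 9.0]
        assert st.spearman(x, [math.exp(v) for v in x]).estimate == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        y = [-v for v in x]
        assert st.spearman(x, y).estimate == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self, rng):
        """n=6: estimate equals Pearson correlation of independently computed mid-ranks."""
        x, y = rng.normal(size=6), rng.normal(size=6)
        rx, ry = rank_midranks(x), rank_midranks(y)
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
        assert st.spearman(x, y).estimate == pytest.approx(num / den)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            st.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestKendall:
    def test_identical_ordering(self):
        assert st.kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).estimate == pytest.approx(1.0)

    def test_single_discordant_swap_pair_count(self):
        # x=(1,2,3,4), y=(1,2,4,3): C=5, D=1 -> tau = 4/6
        r = st.kendall_tau([1, 2, 3, 4], [1, 2, 4, 3])
        assert r.estimate == pytest.approx((5 - 1) / math.comb(4, 2))

    def test_exact_p_matches_enumeration_n5(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        r = st.kendall_tau(x, y)
        assert r.p_value == pytest.approx(kendall_enumeration_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_exact_p_exhaustive_small_n(self, n, rng):
        """Exact small-n p agrees with full n! enumeration for every tested instance."""
        for _ in range(4):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = st.kendall_tau(x, y)
            assert r.p_value == pytest.approx(kendall_enumeration_p(x, y), abs=1e-12)

    def test_permutation_mode_with_ties(self, rng):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 2.0, 5.0, 4.0]
        r = st.kendall_tau(x, y, method="permutation", n_perm=4000, seed=1)
        assert 0 <= r.p_value <= 1
        # tau-b with ties still matches scipy's estimate
        import scipy.stats as sps
        assert r.estimate == pytest.approx(sps.kendalltau(x, y).statistic)


class TestKS:
    def test_identical_samples(self):
        r = st.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0 and r.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert st.ks_two_sample([1, 2, 3], [4, 5, 6]).D == 1.0

    def test_brute_force_sup_oracle(self, rng):
        """n1=n2=8: D equals the max ECDF gap over all 16 sorted breakpoints."""
        a, b = rng.normal(size=8), rng.normal(0.5, 1.2, size=8)
        d_oracle = max(
            abs(sum(v <= t for v in a) / 8 - sum(v <= t for v in b) / 8)
            for t in sorted(np.concatenate([a, b])))
        assert st.ks_two_sample(a, b).D == pytest.approx(d_oracle)

    def test_permutation_p_against_independent_resampler(self, rng):
        """Permutation-mode p within 0.01 of an independently coded 1e5-resample p."""
        a, b = rng.normal(size=8), rng.normal(0.7, 1.0, size=8)
        r = st.ks_two_sample(a, b, method="permutation", n_perm=100_000, seed=11)

        # independent vectorised oracle: indicator matrix over pooled thresholds
        pooled = np.concatenate([a, b])
        oracle_rng = np.random.default_rng(99)
        n_res = 100_000
        C = pooled[None, :] <= pooled[:, None]  # C[t, i] = 1{x_i <= threshold_t}
        labels = np.argsort(oracle_rng.random((n_res, 16)), axis=1) < 8  # in-sample-a
        weights = np.where(labels, 1 / 8, -1 / 8).T  # (16, n_res)
        d_perm = np.abs(C.astype(float) @ weights).max(axis=0)
        hits = int((d_perm >= r.D - 1e-12).sum())
        assert r.p_value == pytest.approx((hits + 1) / (n_res + 1), abs=0.01)

    @given(seed=hst.integers(0, 2**16),
           transform=hst.sampled_from([math.exp, math.atan, lambda v: v**3]))
    @settings(max_examples=25, deadline=None)
    def test_d_invariant_under_monotone_transform(self, seed, transform):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=7), r.normal(0.4, 1, size=9)
        d0 = st.ks_two_sample(a, b).D
        d1 = st.ks_two_sample([transform(v) for v in a], [transform(v) for v in b]).D
        assert d1 == pytest.approx(d0)

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            st.ks_two_sample([1.0], [1.0, 2.0])


class TestOneWayANOVA:
    def test_null_case(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0]]
        r = st.one_way_anova(groups)
        assert r.effects[0][1] == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for *_, p in r.posthoc)

    def test_ss_decomposition_oracle(self, rng):
        """3 groups of 4: F reconstructed from a hand sums-of-squares partition."""
        groups = [list(rng.normal(m, 1, 4)) for m in (0.0, 1.0, 2.5)]
        allv = [v for g in groups for v in g]
        grand = sum(allv) / len(allv)
        ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ss_w = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        ss_t = sum((v - grand) ** 2 for v in allv)
        assert ss_t == pytest.approx(ss_b + ss_w)  # conservation
        f_oracle = (ss_b / 2) / (ss_w / 9)
        r = st.one_way_anova(groups)
        name, f, df1, df2, p = r.effects[0]
        assert (df1, df2) == (2, 9)
        assert f == pytest.approx(f_oracle)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            st.one_way_anova([[1.0, 1.0], [2.0, 2.0]])


class TestMixedANOVA:
    @staticmethod
    def toy_table():
        # 3 subjects per group, 2 groups, 2 within levels
        rows = []
        data = {("g1", 0): [3.0, 4.0, 5.0], ("g1", 1): [5.0, 6.0, 8.0],
                ("g2", 0): [2.0, 3.0, 3.0], ("g2", 1): [2.0, 2.0, 4.0]}
        for (grp, day), vals in data.items():
            for i, v in enumerate(vals):
                rows.append({"subject": f"{grp}-{i}", "group": grp, "day": day,
                             "y": v})
        return pd.DataFrame(rows)

    def test_hand_ss_partition(self):
        """2x2 toy: F values match a hand-computed mixed-design SS partition."""
        df = self.toy_table()
        piv = df.pivot_table(index=["subject", "group"], columns="day", values="y")
        subj_means = piv.mean(axis=1)
        grand = df["y"].mean()
        n_per, k, w = 3, 2, 2
        grp_means = df.groupby("group")["y"].mean()
        ss_between = w * n_per * sum((m - grand) ** 2 for m in grp_means)
        ss_subj_within_grp = w * sum(
            (subj_means[s] - grp_means[s[1]]) ** 2 for s in piv.index)
        day_means = df.groupby("day")["y"].mean()
        ss_within = k * n_per * sum((m - grand) ** 2 for m in day_means)
        cell_means = df.groupby(["group", "day"])["y"].mean()
        ss_inter = n_per * sum(
            (cell_means[g, d] - grp_means[g] - day_means[d] + grand) ** 2
            for g in grp_means.index for d in day_means.index)
        ss_total = ((df["y"] - grand) ** 2).sum()
        ss_err = ss_total - ss_between - ss_subj_within_grp - ss_within - ss_inter

        f_between = (ss_between / (k - 1)) / (ss_subj_within_grp / (k * (n_per - 1)))
        f_within = (ss_within / (w - 1)) / (ss_err / (k * (n_per - 1) * (w - 1)))
        f_inter = (ss_inter / ((k - 1) * (w - 1))) / (ss_err / (k * (n_per - 1) * (w - 1)))

        r = st.mixed_anova(df, dv="y", between="group", within="day",
                           subject="subject")
        got = {name.lower(): f for name, f, *_ in r.effects}
        assert got["group"] == pytest.approx(f_between)
        assert got["day"] == pytest.approx(f_within)
        assert got["interaction"] == pytest.approx(f_inter)

    def test_all_equal_gives_zero_f(self):
        df = self.toy_table()
        df["y"] = 5.0
        r = st.mixed_anova(df, dv="y", between="group", within="day",
                           subject="subject")
        for name, f, *_ in r.effects:
            assert f == pytest.approx(0.0, abs=1e-10) or math.isnan(f)

    def test_unbalanced_names_missing_cells(self):
        df = self.toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="g2-2"):
            st.mixed_anova(df, dv="y", between="group", within="day",
                           subject="subject")

    def test_doubling_subjects_keeps_within_f_in_expectation(self):
        """Null simulation: mean within-effect F is stable when every subject
        is duplicated, once the error df is large enough for E[F] ~ 1."""
        rng = np.random.default_rng(7)
        means = []
        for n_subj in (40, 80):
            fs = []
            for _ in range(60):
                rows = []
                for s in range(n_subj):
                    grp = "g1" if s < n_subj // 2 else "g2"
                    for day in (0, 1):
                        rows.append({"subject": s, "group": grp, "day": day,
                                     "y": rng.normal()})
                r = st.mixed_anova(pd.DataFrame(rows), dv="y", between="group",
                                   within="day", subject="subject")
                fs.append({n.lower(): f for n, f, *_ in r.effects}["day"])
            means.append(np.mean(fs))
        assert abs(means[0] - means[1]) < 0.5


class TestUnpairedT:
    def test_equal_samples(self):
        t, df, p = st.unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_arithmetic_3v3(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, df, _ = st.unpaired_t(a, b)
        assert t == pytest.approx(t_oracle) and df == 4

    def test_swap_flips_sign(self, rng):
        a, b = rng.normal(size=5), rng.normal(1, 1, size=5)
        t1, _, p1 = st.unpaired_t(a, b)
        t2, _, p2 = st.unpaired_t(b, a)
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)


class TestPercentChange:
    @pytest.mark.parametrize("v_from,v_to,expected",
                             [(2.0, 1.0, -50.0), (3.7, 3.7, 0.0), (0.10, 0.15, 50.0)])
    def test_values(self, v_from, v_to, expected):
        assert st.percent_change(v_from, v_to) == pytest.approx(expected)

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError):
            st.percent_change(0.0, 1.0)


class TestPower:
    def test_monotone_in_rho(self):
        ns = [st.required_n_correlation(r).n_required for r in (0.2, 0.3, 0.4, 0.6)]
        assert ns == sorted(ns, reverse=True)

    @pytest.mark.parametrize("rho", [0.30, 0.35, 0.40, 0.45, 0.50])
    def test_exact_and_fisher_z_agree_within_one(self, rho):
        n_exact = st.required_n_correlation(rho, method="exact").n_required
        n_z = st.required_n_correlation(rho, method="fisher-z").n_required
        assert abs(n_exact - n_z) <= 1

    def test_power_increases_with_n(self):
        p1 = st.correlation_power(0.4, 20)
        p2 = st.correlation_power(0.4, 60)
        assert p2 > p1

    def test_unreachable_power_bounded_search(self):
        with pytest.raises(ValueError, match="unreachable"):
            st.required_n_correlation(0.01, n_max=200)

    def test_validation(self):
        with pytest.raises(ValueError):
            st.correlation_power(0.0, 20)
        with pytest.raises(ValueError):
            st.required_n_correlation(0.4, alpha=0.05, power=0.04)
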
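"""Nonparametric tests against enumeration/permutation oracles, ranking, suite."""

from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from petdenoise.stats import (
    IMAGE_SETS,
    RelatedSamplesTable,
    ScoreTable,
    ValidationError,
    bonferroni_threshold,
    friedman,
    kruskal_wallis,
    mann_whitney_u,
    rank_by_mean,
    run_comparison_suite,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------- oracles


def friedman_statistic_oracle(data):
    """Friedman chi-square with mid-rank ties, computed from first principles."""
    ranks = np.apply_along_axis(rankdata, 1, data)
    n, k = data.shape
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
    # tie correction
    correction = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        correction += np.sum(counts**3 - counts)
    denom = 1.0 - correction / (n * k * (k**2 - 1))
    return chi2 / denom if denom > 0 else 0.0


def friedman_permutation_p(data):
    """Exact permutation p: independently permute each row, all (k!)^n cases."""
    n, k = data.shape
    observed = friedman_statistic_oracle(data)
    perms = list(permutations(range(k)))
    count = total = 0
    for combo in product(perms, repeat=n):
        permuted = np.array([data[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_statistic_oracle(permuted) >= observed - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p(d):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ew = ranks.sum() / 2.0
    dev = abs(w_obs - ew)
    count = total = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if abs(w - ew) >= dev - 1e-12:
            count += 1
    return count / total


def mann_whitney_exact_p(a, b):
    """Two-sided exact p by enumerating all label assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    eu = na * b.size / 2.0
    dev = abs(u_obs - eu)
    count = total = 0
    for idx in combinations(range(pooled.size), na):
        r = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        total += 1
        if abs(r - eu) >= dev - 1e-12:
            count += 1
    return count / total


def kruskal_permutation_p(groups):
    """Exact permutation p over all assignments of pooled values to groups."""
    from scipy.stats import kruskal

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = kruskal(*groups).statistic
    idx_all = range(pooled.size)
    count = total = 0
    for first in combinations(idx_all, sizes[0]):
        rest = [i for i in idx_all if i not in first]
        for second in combinations(rest, sizes[1]):
            third = [i for i in rest if i not in second]
            parts = [pooled[list(first)], pooled[list(second)], pooled[third]]
            h = kruskal(*parts).statistic
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
    return count / total


# ----------------------------------------------------------------- friedman


class TestFriedman:
    def test_identical_columns_degenerate(self):
        t = RelatedSamplesTable(np.tile([[1.0, 1.0, 1.0]], (4, 1)), ("a", "b", "c"))
        res = friedman(t)
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.degenerate

    def test_strictly_ordered_3x3_statistic(self):
        data = np.array([[1, 2, 3], [1.5, 2.5, 3.5], [0, 1, 2]], dtype=float)
        res = friedman(RelatedSamplesTable(data, ("a", "b", "c")))
        assert res.statistic == pytest.approx(6.0)
        assert res.statistic == pytest.approx(friedman_statistic_oracle(data))

    def test_p_close_to_exact_permutation_on_4x3(self, rng):
        data = rng.normal(size=(4, 3))
        data[:, 2] += 1.0
        res = friedman(RelatedSamplesTable(data, ("a", "b", "c")))
        exact = friedman_permutation_p(data)
        # chi-square approximation at n=4: documented accuracy is coarse
        assert res.pvalue == pytest.approx(exact, abs=0.12)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            RelatedSamplesTable(np.ones((1, 3)), ("a", "b", "c"))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.pvalue == 1.0 and res.degenerate

    def test_exact_p_matches_sign_enumeration_n6(self):
        # absolute differences are all distinct, so the exact path applies
        x = np.array([1.0, 4.0, 2.5, 7.0, 3.0, 0.5])
        y = np.array([0.2, 2.0, 3.5, 2.0, 0.9, 2.7])
        res = wilcoxon_signed_rank(x, y)
        assert "exact" in res.method
        assert res.pvalue == pytest.approx(wilcoxon_exact_p(x - y))

    def test_approximation_close_to_exact_at_n20(self, rng):
        d = rng.normal(0.3, 1.0, size=20)
        d = d[d != 0]
        x = d
        y = np.zeros_like(d)
        exact = wilcoxon_signed_rank(x, y)  # n=20 -> exact path
        assert "exact" in exact.method
        from scipy import stats as sps

        approx = sps.wilcoxon(d, alternative="two-sided", method="approx",
                              correction=True)
        assert approx.pvalue == pytest.approx(exact.pvalue, abs=0.01)

    def test_zero_differences_dropped(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [1, 2, 3, 5, 7, 4, 9]  # three zero differences
        res = wilcoxon_signed_rank(x, y)
        assert res.n == 4


class TestBonferroni:
    def test_five_groups_give_ten_comparisons_at_0005(self):
        threshold, m = bonferroni_threshold(0.05, 5)
        assert m == 10 and threshold == pytest.approx(0.005)

    @pytest.mark.parametrize(
        "alpha,k,m,thr", [(0.05, 2, 1, 0.05), (0.10, 4, 6, 0.10 / 6)]
    )
    def test_formula(self, alpha, k, m, thr):
        threshold, mm = bonferroni_threshold(alpha, k)
        assert mm == m and threshold == pytest.approx(thr)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 1)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_p_close_to_permutation_oracle_small_n(self, rng):
        groups = [rng.normal(size=3), rng.normal(size=3) + 1.2, rng.normal(size=2)]
        res = kruskal_wallis(groups)
        exact = kruskal_permutation_p(groups)
        assert res.pvalue == pytest.approx(exact, abs=0.08)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=6), rng.normal(size=5) + 0.5, rng.normal(size=7)]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert a == pytest.approx(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestMannWhitney:
    def test_same_sample_p_near_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue > 0.9

    def test_separated_samples_exact_enumeration(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(2 / 6)
        assert res.pvalue == pytest.approx(mann_whitney_exact_p([1, 2], [3, 4]))

    def test_exact_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=4) + 0.8
        res = mann_whitney_u(a, b)
        assert "exact" in res.method
        assert res.pvalue == pytest.approx(mann_whitney_exact_p(a, b))

    def test_approximation_close_to_exact_at_n10(self, rng):
        from scipy import stats as sps

        a = rng.normal(size=10)
        b = rng.normal(size=10) + 0.7
        exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        approx = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert approx.pvalue == pytest.approx(exact.pvalue, abs=0.02)

    def test_monotone_invariance(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=9)
        assert mann_whitney_u(a, b).statistic == pytest.approx(
            mann_whitney_u(np.exp(a), np.exp(b)).statistic
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRankByMean:
    def test_example_ranking(self):
        scores = ScoreTable.from_means(
            {
                ("Reader 1", "noise"): {
                    "1.5 min": 2.5,
                    "1.5 min CNN": 4.5,
                    "1 min": 1.0,
                    "1 min CNN": 3.2,
                    "4 min": 3.8,
                }
            }
        )
        order, tied = rank_by_mean(scores, "Reader 1", "noise")
        assert order == ["1.5 min CNN", "4 min", "1 min CNN", "1.5 min", "1 min"]
        assert not tied

    def test_all_equal_means_flagged(self):
        scores = ScoreTable.from_means(
            {("R", "noise"): {s: 3.0 for s in IMAGE_SETS}}
        )
        order, tied = rank_by_mean(scores, "R", "noise")
        assert tied and order == list(IMAGE_SETS)

    def test_strictly_decreasing_means_identity(self):
        scores = ScoreTable.from_means(
            {("R", "c"): {s: 5.0 - i for i, s in enumerate(IMAGE_SETS)}}
        )
        order, tied = rank_by_mean(scores, "R", "c")
        assert order == list(IMAGE_SETS) and not tied

    def test_missing_image_set_rejected(self):
        scores = ScoreTable.from_means({("R", "noise"): {"4 min": 3.0}})
        with pytest.raises(ValueError, match="missing"):
            rank_by_mean(scores, "R", "noise")


class TestComparisonSuite:
    @staticmethod
    def _metrics(n_subjects=8, noise_shift=0.0, suv_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subjects):
            base_cov = rng.uniform(0.08, 0.16)
            for s in IMAGE_SETS:
                cov = base_cov * {"4 min": 0.7, "1.5 min": 1.0, "1.5 min CNN": 1.0 - noise_shift,
                                  "1 min": 1.3, "1 min CNN": 1.3 * (1 - noise_shift)}[s]
                rows.append(dict(subject=f"s{i}", image_set=s, lesion=None,
                                 suv_max=None, suv_peak=None,
                                 cov=cov + rng.normal(0, 0.002)))
            for l in range(3):
                base = rng.uniform(2, 8)
                for s in IMAGE_SETS:
                    shift = suv_shift if s.endswith("CNN") else 0.0
                    smax = base * (1 + shift) + rng.normal(0, 0.05)
                    rows.append(dict(subject=f"s{i}", image_set=s, lesion=f"l{l}",
                                     suv_max=smax, suv_peak=smax * 0.8,
                                     cov=None))
        return pd.DataFrame(rows)

    def test_ten_pairwise_rows_per_metric(self):
        report = run_comparison_suite(self._metrics())
        counts = report.pairwise.groupby("metric").size()
        assert set(counts.index) == {"suv_max", "suv_peak", "cov"}
        assert (counts == 10).all()
        assert report.threshold == pytest.approx(0.005)

    def test_identical_metric_values_nothing_significant(self):
        df = self._metrics(noise_shift=0.0, suv_shift=0.0, seed=1)
        # make every image set identical per subject/lesion
        for col in ("suv_max", "suv_peak", "cov"):
            df[col] = df.groupby(["subject", "lesion"], dropna=False)[col].transform(
                "mean"
            )
        report = run_comparison_suite(df)
        assert not report.pairwise["significant"].any()

    def test_true_noise_reduction_flags_cov_but_not_suv(self):
        """With a genuine COV reduction and no SUV shift, the CNN-vs-input COV
        pair is significant at 0.005 while the SUV pairs are not."""
        df = self._metrics(n_subjects=10, noise_shift=0.25, suv_shift=0.0, seed=7)
        report = run_comparison_suite(df)
        pw = report.pairwise.set_index(["metric", "pair"])
        assert pw.loc[("cov", "1.5 min-1.5 min CNN"), "significant"]
        assert not pw.loc[("suv_max", "1.5 min-1.5 min CNN"), "significant"]
        assert not pw.loc[("suv_peak", "1.5 min-1.5 min CNN"), "significant"]

    def test_incomplete_coverage_raises_with_missing_cells(self):
        df = self._metrics()
        df = df[~((df.subject == "s0") & (df.image_set == "1 min"))]
        with pytest.raises(ValidationError, match="1 min"):
            run_comparison_suite(df)

    def test_reader_scores_battery_shapes(self, rng):
        rows = []
        for reader in ("R1", "R2"):
            for cat in ("noise", "contrast"):
                for s in IMAGE_SETS:
                    mean = {"4 min": 4.2, "1.5 min": 3.0, "1.5 min CNN": 4.4,
                            "1 min": 1.8, "1 min CNN": 4.0}[s]
                    for _ in range(25):
                        score = int(np.clip(round(rng.normal(mean, 0.6)), 1, 5))
                        rows.append(dict(reader=reader, category=cat,
                                         image_set=s, score=score))
        scores = pd.DataFrame(rows)
        report = run_comparison_suite(self._metrics(), scores=scores)
        assert len(report.reader_pairwise) == 2 * 2 * 10
        assert (report.reader_omnibus["pvalue"] < 0.05).all()
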
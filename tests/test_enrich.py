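import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from ampfit import enrich


def hypergeom_tail_exact(k, N, K, n, upper=True):
    """Independent oracle: exact tail from integer binomial coefficients."""
    lo, hi = max(0, n - (N - K)), min(n, K)
    if upper:
        support = range(max(k, lo), hi + 1)
    else:
        support = range(lo, min(k, hi) + 1)
    total = Fraction(0)
    for j in support:
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j),
                          math.comb(N, n))
    return float(total)


class TestHypergeomTail:
    def test_example_5_over_210(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert enrich.hypergeom_tail(4, 10, 5, 4) == pytest.approx(5 / 210)

    def test_example_1_over_20(self):
        assert enrich.hypergeom_tail(3, 6, 3, 3) == pytest.approx(1 / 20)

    def test_zero_overlap_tail_is_one(self):
        assert enrich.hypergeom_tail(0, 50, 10, 5) == 1.0

    def test_exhaustive_agreement_up_to_N12(self):
        """Log-space tail vs exact rational enumeration, every configuration."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n - (N - K)), min(n, K)
                    for k in range(lo, hi + 1):
                        for upper in (True, False):
                            got = enrich.hypergeom_tail(k, N, K, n, upper)
                            want = hypergeom_tail_exact(k, N, K, n, upper)
                            assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_k(self):
        N, K, n = 200, 40, 30
        tails = [enrich.hypergeom_tail(k, N, K, n) for k in range(0, 31)]
        assert tails[0] == 1.0
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_matches_scipy_at_scale(self):
        N, K, n = 4871, 431, 300
        for k in (10, 26, 60, 120):
            assert enrich.hypergeom_tail(k, N, K, n) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )


class TestHypergeomEnrich:
    BACKGROUND = {f"g{i}" for i in range(10)}

    def test_counts_and_pvalue(self):
        terms = {"t": {f"g{i}" for i in range(5)}}
        res = enrich.hypergeom_enrich({"g0", "g1", "g2", "g3"}, terms,
                                      self.BACKGROUND)[0]
        assert (res.overlap_k, res.term_K, res.query_n, res.background_N) == \
            (4, 5, 4, 10)
        assert res.p_value == pytest.approx(5 / 210)
        assert res.direction == "over"

    def test_empty_term_gives_p_one(self):
        res = enrich.hypergeom_enrich({"g0"}, {"t": set()}, self.BACKGROUND)[0]
        assert res.p_value == 1.0

    def test_term_genes_outside_background_dropped(self):
        terms = {"t": {"g0", "g1", "zz1", "zz2"}}
        res = enrich.hypergeom_enrich({"g0", "g1"}, terms, self.BACKGROUND)[0]
        assert res.term_K == 2

    def test_query_outside_background_is_error(self):
        with pytest.raises(ValueError):
            enrich.hypergeom_enrich({"nope"}, {}, self.BACKGROUND)
        with pytest.raises(ValueError):
            enrich.hypergeom_enrich(set(), {}, self.BACKGROUND)

    def test_null_significance_rate(self):
        """Random term sets essentially never reach p < 5e-4."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(400)]
        background = set(genes)
        query = set(rng.choice(genes, 40, replace=False))
        terms = {
            f"t{i}": set(rng.choice(genes, int(rng.integers(10, 80)),
                                    replace=False))
            for i in range(2000)
        }
        results = enrich.hypergeom_enrich(query, terms, background)
        rate = np.mean([r.significant for r in results])
        assert rate <= 0.002


def ranksum_dp_oracle(ranks, n, observed, sides):
    """Distribution of the query rank-sum by DP convolution over doubled
    (integer) midranks — an implementation-independent check."""
    iranks = [int(round(2 * r)) for r in ranks]
    total = len(iranks)
    # dp[j][s]: number of ways to choose j ranks summing to s
    max_sum = sum(sorted(iranks)[-n:]) if n else 0
    dp = [{0: 1}] + [dict() for _ in range(n)]
    for r in iranks:
        for j in range(min(n, total), 0, -1):
            for s, c in list(dp[j - 1].items()):
                dp[j][s + r] = dp[j].get(s + r, 0) + c
    dist = dp[n]
    denom = sum(dist.values())
    obs2 = int(round(2 * observed))
    if sides == "greater":
        num = sum(c for s, c in dist.items() if s >= obs2)
    elif sides == "less":
        num = sum(c for s, c in dist.items() if s <= obs2)
    else:
        mu = sum(s * c for s, c in dist.items()) / denom
        num = sum(c for s, c in dist.items()
                  if abs(s - mu) >= abs(obs2 - mu) - 1e-9)
    return num / denom


class TestRanksum:
    def feature(self, x, y):
        vals = {}
        for i, v in enumerate(x):
            vals[f"q{i}"] = v
        for i, v in enumerate(y):
            vals[f"b{i}"] = v
        query = {f"q{i}" for i in range(len(x))}
        background = query | {f"b{i}" for i in range(len(y))}
        return query, background, vals

    def test_enumerated_one_sided_sixth(self):
        query, background, vals = self.feature([1, 2], [3, 4])
        res = enrich.ranksum_feature(query, background, vals, sides="less")
        assert res.p_value == pytest.approx(1 / 6)
        assert res.direction == "lower"

    def test_identical_groups_two_sided_one(self):
        query, background, vals = self.feature([1, 2, 3], [1, 2, 3])
        res = enrich.ranksum_feature(query, background, vals, sides="two")
        assert res.p_value == 1.0

    def test_degenerate_constant_feature(self):
        query, background, vals = self.feature([5, 5], [5, 5, 5])
        res = enrich.ranksum_feature(query, background, vals)
        assert res.degenerate and res.p_value == 1.0

    def test_exact_matches_dp_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            nx = int(rng.integers(1, 7))
            ny = int(rng.integers(1, 7))
            vals = rng.integers(0, 6, nx + ny).astype(float)  # many ties
            x, y = vals[:nx], vals[nx:]
            if np.ptp(vals) == 0:
                continue
            query, background, fmap = self.feature(x, y)
            ranks = stats.rankdata(vals)
            observed = ranks[:nx].sum()
            for sides in ("two", "greater", "less"):
                res = enrich.ranksum_feature(query, background, fmap,
                                             sides=sides)
                want = ranksum_dp_oracle(ranks, nx, observed, sides)
                assert res.p_value == pytest.approx(want, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            nx, ny = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = rng.permutation(np.arange(nx + ny, dtype=float) * 1.7)
            query, background, fmap = self.feature(vals[:nx], vals[nx:])
            res = enrich.ranksum_feature(query, background, fmap, sides="greater")
            want = stats.mannwhitneyu(vals[:nx], vals[nx:],
                                      alternative="greater",
                                      method="exact").pvalue
            assert res.p_value == pytest.approx(want, abs=1e-12)

    def test_normal_approximation_near_exact_at_crossover(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(0.3, 1, 8)
            y = rng.normal(0, 1, 12)
            query, background, fmap = self.feature(x, y)
            exact = enrich.ranksum_feature(query, background, fmap).p_value
            ranks = stats.rankdata(np.concatenate([x, y]))
            approx = enrich._normal_ranksum_p(ranks, 8, ranks[:8].sum(), "two")
            assert approx == pytest.approx(exact, abs=0.02)

    def test_null_pvalues_uniform(self):
        """n=m=50 from one distribution: KS check of p-value uniformity."""
        rng = np.random.default_rng(100)
        pvals = []
        for _ in range(500):
            vals = rng.normal(size=100)
            query, background, fmap = self.feature(vals[:50], vals[50:])
            pvals.append(
                enrich.ranksum_feature(query, background, fmap).p_value
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_feature_missing_for_group_is_error(self):
        with pytest.raises(ValueError):
            enrich.ranksum_feature({"a"}, {"a", "b"}, {"b": 1.0})


class TestTranslationExclusion:
    def test_set_difference(self):
        assert enrich.exclude_translation({"a", "b", "c"}, {"b"}) == {"a", "c"}
        assert enrich.exclude_translation({"a"}, {"x"}) == {"a"}

    def test_retest_after_removal_consistent(self):
        """Removing translation genes from query and background changes
        N, K, n, k coherently (verified against a brute-force recount)."""
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(60)]
        background = set(genes)
        query = set(rng.choice(genes, 20, replace=False))
        term = set(rng.choice(genes, 25, replace=False))
        translation = set(rng.choice(genes, 15, replace=False))
        q2 = enrich.exclude_translation(query, translation)
        bg2 = enrich.exclude_translation(background, translation)
        res = enrich.hypergeom_enrich(q2, {"t": term}, bg2)[0]
        k = len(term & q2 & bg2)
        K = len(term & bg2)
        assert (res.overlap_k, res.term_K, res.query_n, res.background_N) == \
            (k, K, len(q2), len(bg2))
        assert res.p_value == pytest.approx(
            hypergeom_tail_exact(k, len(bg2), K, len(q2)), abs=1e-12
        )
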
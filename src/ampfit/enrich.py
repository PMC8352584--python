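"""Enrichment statistics against configurable backgrounds.

Categorical terms are tested with the hypergeometric distribution (query
drawn without replacement from the background); continuous gene features
with the Wilcoxon rank-sum test between the query and the rest of the
background.  Because functional gene lists overlap heavily, standard FDR
correction across terms over-corrects; the primary significance rule is
therefore a stringent raw p < 5e-4, with BH values reported alongside as
annotation.  A translation-gene exclusion helper supports re-testing with
translation machinery removed, a common robustness check since ribosome
biogenesis dominates many deleterious-gene lists.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy import stats

from .diffabund import adjust_bh

SIGNIFICANCE_P = 5e-4

#: exact rank-sum enumeration limits; larger designs use the normal approximation
EXACT_MIN_GROUP = 8
EXACT_TOTAL = 20


@dataclass
class EnrichmentResult:
    """One term or feature comparison against a background."""

    name: str
    test: str                      # "hypergeometric" | "ranksum"
    p_value: float
    direction: str                 # over/under (terms), higher/lower (features)
    significant: bool
    fdr: float = float("nan")
    # hypergeometric bookkeeping
    overlap_k: int | None = None
    query_n: int | None = None
    term_K: int | None = None
    background_N: int | None = None
    p_depletion: float | None = None
    # rank-sum bookkeeping
    n_query: int | None = None
    n_comparison: int | None = None
    rank_sum: float | None = None
    degenerate: bool = False


def _log_comb(n, k):
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, N: int, K: int, n: int, upper: bool = True) -> float:
    """P(X >= k) (or P(X <= k)) for X ~ Hypergeometric(N, K, n), in log space."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    if upper and k <= lo:
        return 1.0
    if not upper and k >= hi:
        return 1.0
    if upper:
        support = np.arange(max(k, lo), hi + 1)
    else:
        support = np.arange(lo, min(k, hi) + 1)
    if support.size == 0:
        return 0.0
    logp = (
        _log_comb(K, support)
        + _log_comb(N - K, n - support)
        - _log_comb(N, n)
    )
    return float(min(1.0, math.exp(logsumexp(logp))))


def hypergeom_enrich(
    query: set,
    terms: dict,
    background: set,
    alpha: float = SIGNIFICANCE_P,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the query.

    The query must be a subset of the background; term genes outside the
    background are dropped before testing.  Each result carries the
    over-representation p-value (primary), the depletion (lower-tail)
    p-value, and BH-adjusted values across terms as annotation.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError(
            f"{len(query - background)} query genes outside the background"
        )
    N, n = len(background), len(query)
    results = []
    for name, genes in terms.items():
        term_bg = set(genes) & background
        K = len(term_bg)
        k = len(term_bg & query)
        p_over = 1.0 if K == 0 else hypergeom_tail(k, N, K, n, upper=True)
        p_under = hypergeom_tail(k, N, K, n, upper=False)
        results.append(
            EnrichmentResult(
                name=name,
                test="hypergeometric",
                p_value=p_over,
                direction="over" if k * N >= K * n else "under",
                significant=p_over < alpha,
                overlap_k=k,
                query_n=n,
                term_K=K,
                background_N=N,
                p_depletion=p_under,
            )
        )
    if results:
        fdr = adjust_bh([r.p_value for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    return results


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_ranksum_p(
    ranks: np.ndarray, n: int, observed: float, sides: str
) -> float:
    """Enumerate all assignments of n of the pooled midranks to the query."""
    total = ranks.size
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, n)),
        dtype=float,
        count=math.comb(total, n),
    )
    eps = 1e-9
    if sides == "greater":
        return float(np.mean(sums >= observed - eps))
    if sides == "less":
        return float(np.mean(sums <= observed + eps))
    mu = sums.mean()
    return float(min(1.0, np.mean(np.abs(sums - mu) >= abs(observed - mu) - eps)))


def _normal_ranksum_p(
    ranks: np.ndarray, n: int, observed: float, sides: str
) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    total = ranks.size
    m = total - n
    mu = n * (total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if sides == "greater":
        return float(stats.norm.sf((observed - mu - 0.5) / sd))
    if sides == "less":
        return float(stats.norm.cdf((observed - mu + 0.5) / sd))
    z = (abs(observed - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def ranksum_feature(
    query: set,
    background: set,
    feature: dict,
    sides: str = "two",
    name: str = "feature",
    alpha: float = SIGNIFICANCE_P,
) -> EnrichmentResult:
    """Wilcoxon rank-sum comparison of a continuous gene feature.

    The query is compared with the rest of the background (background minus
    query) over genes with a defined feature value.  Midranks handle ties;
    p is exact by enumeration when ``min(n, m) <= 8`` and ``n + m <= 20``,
    otherwise a tie-corrected normal approximation with continuity
    correction.  ``sides``: "two", "greater" (query higher) or "less".
    If every value is identical the comparison is degenerate with p = 1.
    """
    if sides not in ("two", "greater", "less"):
        raise ValueError(f"sides must be two|greater|less, got {sides!r}")
    query = set(query)
    comparison = set(background) - query
    x = np.array([feature[g] for g in sorted(query) if g in feature], float)
    y = np.array([feature[g] for g in sorted(comparison) if g in feature], float)
    if x.size == 0 or y.size == 0:
        raise ValueError("feature undefined for one of the groups")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    observed = float(ranks[: x.size].sum())
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        p = 1.0
    elif min(x.size, y.size) <= EXACT_MIN_GROUP and pooled.size <= EXACT_TOTAL:
        p = _exact_ranksum_p(ranks, x.size, observed, sides)
    else:
        p = _normal_ranksum_p(ranks, x.size, observed, sides)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    direction = "higher" if med_x > med_y else ("lower" if med_x < med_y else "equal")
    return EnrichmentResult(
        name=name,
        test="ranksum",
        p_value=p,
        direction=direction,
        significant=p < alpha,
        n_query=int(x.size),
        n_comparison=int(y.size),
        rank_sum=observed,
        degenerate=bool(degenerate),
    )


def exclude_translation(genes: set, translation: set) -> set:
    """Remove translation-machinery genes from a query or background set."""
    return set(genes) - set(translation)
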
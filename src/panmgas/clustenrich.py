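"""Projection of functional clusters onto disease-called MSP sets.

For each cluster x cohort x direction, a hypergeometric upper-tail test
asks whether the cluster's associated MSPs overlap the cohort's
enriched (or depleted) MSPs more than chance. Only clusters with at
least 10 associated MSPs are tested; significance is p < 1e-4. The same
total/subtracted frequency rule used for species labels clusters as
commonly enriched or depleted across cohorts.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .association import classify_frequency
from .funclust import FunctionalCluster

__all__ = ["hypergeom_upper_tail", "project_clusters", "cluster_frequency"]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"infeasible hypergeometric parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def project_clusters(
    clusters: list[FunctionalCluster],
    enriched: dict[str, set[str]],
    depleted: dict[str, set[str]],
    tested: dict[str, list[str]],
    min_cluster_msps: int = 10,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Hypergeometric projection records per cluster x cohort x direction.

    The population N is the set of MSPs actually tested in the cohort
    (the sampling frame of the calls), K the cluster's associated MSPs
    within it, n the called set, k their overlap. significant iff
    p < alpha (strict).
    """
    rows = []
    for cohort_id in sorted(tested):
        population = set(tested[cohort_id])
        N = len(population)
        for direction, calls in (("enriched", enriched), ("depleted", depleted)):
            called = calls.get(cohort_id, set()) & population
            n = len(called)
            for cluster in clusters:
                assoc = cluster.associated_msps & population
                K = len(assoc)
                if K < min_cluster_msps:
                    continue
                k = len(assoc & called)
                p = hypergeom_upper_tail(N, K, n, k)
                rows.append(
                    {
                        "cluster_id": cluster.cluster_id,
                        "cohort_id": cohort_id,
                        "direction": direction,
                        "overlap_k": k,
                        "cluster_size_K": K,
                        "draw_size_n": n,
                        "population_N": N,
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "cohort_id", "direction", "overlap_k",
            "cluster_size_K", "draw_size_n", "population_N",
            "p_value", "significant",
        ],
    )


def cluster_frequency(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-cohort frequency summary over significant projections,
    using the species frequency rule (total >= 3, |subtracted| >= 2)."""
    sig = records[records["significant"]] if len(records) else records
    enriched: dict[str, set[str]] = {}
    depleted: dict[str, set[str]] = {}
    if len(sig):
        for (cohort_id, direction), grp in sig.groupby(["cohort_id", "direction"]):
            target = enriched if direction == "enriched" else depleted
            target[cohort_id] = set(grp["cluster_id"])
    out = classify_frequency(enriched, depleted)
    return out.rename(columns={"msp_id": "cluster_id"})
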
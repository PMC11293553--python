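"""Pan-metagenomics association: one-sided Wilcoxon effect sizes per
MSP x cohort and the cross-cohort frequency classification.

The effect size is the Z statistic derived from the one-sided rank-sum
p-value divided by the square root of the total sample count; 0.3 (a
medium effect) is the call threshold. A species is "commonly" enriched
or depleted when its total call frequency across cohorts is >= 3 and the
absolute subtracted frequency (enriched - depleted) is >= 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, SampleMetadata

logger = logging.getLogger("panmgas")

__all__ = [
    "wilcoxon_effect_size",
    "cohort_association",
    "classify_frequency",
    "AssociationResult",
    "default_pairing",
]


def wilcoxon_effect_size(
    disease_values, healthy_values, alternative: str = "greater"
) -> tuple[float, float, float]:
    """One-sided Wilcoxon rank-sum test summarized as (p, Z, ES).

    p is exact (by enumeration) when N <= 25 and the pooled values carry
    no ties, otherwise the normal approximation with tie and continuity
    correction; Z = Phi^-1(1 - p); ES = Z / sqrt(N). Fully tied inputs
    give (0.5, 0, 0).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(disease_values, dtype=float)
    y = np.asarray(healthy_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n = x.size + y.size
    if n < 4:
        raise ValueError(f"need N >= 4 samples (got {n})")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.debug("all values tied; ES set to 0")
        return 0.5, 0.0, 0.0
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    p = float(res.pvalue)
    z = float(stats.norm.isf(p))  # p > 0.5 gives a negative Z
    return p, z, z / np.sqrt(n)


@dataclass
class AssociationResult:
    effect_sizes: pd.DataFrame  # one row per tested MSP x cohort
    enriched: dict[str, set[str]]  # cohort_id -> called MSP ids
    depleted: dict[str, set[str]]
    skipped: dict[str, list[str]]  # cohort_id -> MSPs not tested
    tested: dict[str, list[str]]  # cohort_id -> MSPs tested (population frame)


def default_pairing(metadata: SampleMetadata) -> dict[str, str]:
    """Map each disease cohort to a healthy cohort from the same country.

    A country's (single) healthy cohort may control several disease
    cohorts; disease cohorts without a same-country healthy cohort are
    omitted (warned).
    """
    cohorts = metadata.cohorts()
    healthy = cohorts[cohorts["status"] == "healthy"]
    by_country = {c: list(g.index) for c, g in healthy.groupby("country")}
    pairing = {}
    for cid, row in cohorts[cohorts["status"] == "diseased"].iterrows():
        candidates = by_country.get(row["country"], [])
        if not candidates:
            logger.warning("cohort %s: no healthy cohort in %s", cid, row["country"])
            continue
        pairing[cid] = candidates[0]
    return pairing


def cohort_association(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    pairing: dict[str, str] | None = None,
    es_threshold: float = 0.3,
    min_test_prevalence: int = 5,
) -> AssociationResult:
    """Test every MSP in every disease cohort against its matched controls.

    Both one-sided alternatives are recorded; an MSP is called enriched
    (depleted) when the corresponding ES >= ``es_threshold``. MSPs with
    nonzero abundance in fewer than ``min_test_prevalence`` samples of
    the combined case+control group are skipped (full-tie tests carry no
    information).
    """
    metadata.require_samples(abundance.sample_ids)
    if pairing is None:
        pairing = default_pairing(metadata)
    values = abundance.values
    present = set(values.columns)

    rows = []
    enriched: dict[str, set[str]] = {}
    depleted: dict[str, set[str]] = {}
    skipped: dict[str, list[str]] = {}
    tested: dict[str, list[str]] = {}
    for cohort_id, control_id in sorted(pairing.items()):
        case_ids = [s for s in metadata.cohort_samples(cohort_id) if s in present]
        ctrl_ids = [s for s in metadata.cohort_samples(control_id) if s in present]
        if not case_ids or not ctrl_ids:
            logger.warning("cohort %s/%s: missing samples; skipped", cohort_id, control_id)
            continue
        case = values[case_ids].to_numpy()
        ctrl = values[ctrl_ids].to_numpy()
        prevalence = (np.concatenate([case, ctrl], axis=1) > 0).sum(axis=1)
        enriched[cohort_id] = set()
        depleted[cohort_id] = set()
        skipped[cohort_id] = []
        tested[cohort_id] = []
        for i, msp_id in enumerate(values.index):
            if prevalence[i] < min_test_prevalence:
                skipped[cohort_id].append(msp_id)
                continue
            tested[cohort_id].append(msp_id)
            p_enr, _, es_enr = wilcoxon_effect_size(case[i], ctrl[i], "greater")
            p_dep, _, es_dep = wilcoxon_effect_size(case[i], ctrl[i], "less")
            rows.append(
                {
                    "msp_id": msp_id,
                    "cohort_id": cohort_id,
                    "control_cohort_id": control_id,
                    "es_enriched": es_enr,
                    "es_depleted": es_dep,
                    "p_enriched": p_enr,
                    "p_depleted": p_dep,
                    "n_disease": len(case_ids),
                    "n_healthy": len(ctrl_ids),
                }
            )
            if es_enr >= es_threshold:
                enriched[cohort_id].add(msp_id)
            if es_dep >= es_threshold:
                depleted[cohort_id].add(msp_id)
    table = pd.DataFrame(
        rows,
        columns=[
            "msp_id", "cohort_id", "control_cohort_id",
            "es_enriched", "es_depleted", "p_enriched", "p_depleted",
            "n_disease", "n_healthy",
        ],
    )
    if len(table):
        # BH-adjusted p-values as an extra column (calls remain ES-based)
        for col in ("p_enriched", "p_depleted"):
            table[col + "_bh"] = _benjamini_hochberg(table[col].to_numpy())
    return AssociationResult(table, enriched, depleted, skipped, tested)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def classify_frequency(
    enriched: dict[str, set[str]],
    depleted: dict[str, set[str]],
    disease_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cross-cohort call frequencies and the common enriched/depleted label.

    total = n_enriched + n_depleted; subtracted = n_enriched - n_depleted;
    label common_enriched iff total >= 3 and subtracted >= 2,
    common_depleted iff total >= 3 and subtracted <= -2, else none.
    """
    msps = sorted(
        set().union(*enriched.values(), *depleted.values())
        if (enriched or depleted)
        else set()
    )
    rows = []
    for msp in msps:
        e_cohorts = [c for c, s in sorted(enriched.items()) if msp in s]
        d_cohorts = [c for c, s in sorted(depleted.items()) if msp in s]
        n_e, n_d = len(e_cohorts), len(d_cohorts)
        total, sub = n_e + n_d, n_e - n_d
        if total >= 3 and sub >= 2:
            label = "common_enriched"
        elif total >= 3 and sub <= -2:
            label = "common_depleted"
        else:
            label = "none"
        diseases = set()
        if disease_labels:
            diseases = {
                disease_labels[c] for c in e_cohorts + d_cohorts if c in disease_labels
            }
        rows.append(
            {
                "msp_id": msp,
                "n_enriched_cohorts": n_e,
                "n_depleted_cohorts": n_d,
                "total_frequency": total,
                "subtracted_frequency": sub,
                "label": label,
                "n_distinct_diseases": len(diseases),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "msp_id", "n_enriched_cohorts", "n_depleted_cohorts",
            "total_frequency", "subtracted_frequency", "label",
            "n_distinct_diseases",
        ],
    )
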
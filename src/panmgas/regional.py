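"""Region/country enrichment of species and gene-content profiles.

A species' regional enrichment is a Z-score for the difference between
its mean relative abundance in one country (or region group) and in the
entire population. The top-100 overrepresented MSPs per region group
feed a gene-content comparison: annotated genes of those species are
counted per functional term (CAZyme / AMR / virulence analogues), each
group's counts normalized to sum 1, and the largest signed differences
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, AnnotationTable, MspCatalog, SampleMetadata

logger = logging.getLogger("panmgas")

__all__ = ["region_zscore", "top_region_msps", "gene_content_profile", "CategoryProfile"]


def _group_zscores(
    values: pd.DataFrame, groups: pd.Series, z_denominator: str = "se"
) -> pd.DataFrame:
    """Z(m, g) = (mean_g(m) - mean_all(m)) / denom, denom in
    {sd_all/sqrt(n_g) ('se'), sd_all ('sd'), 1 ('none')}; 0 when sd_all=0."""
    arr = values.to_numpy(dtype=float)
    mean_all = arr.mean(axis=1)
    sd_all = arr.std(axis=1, ddof=1)
    out = {}
    for g in sorted(groups.unique()):
        cols = list(groups.index[groups == g])
        if len(cols) < 2:
            logger.warning("group %s has < 2 samples; excluded", g)
            continue
        mean_g = values[cols].to_numpy().mean(axis=1)
        if z_denominator == "se":
            denom = sd_all / np.sqrt(len(cols))
        elif z_denominator == "sd":
            denom = sd_all
        elif z_denominator == "none":
            denom = np.ones_like(sd_all)
        else:
            raise ValueError(f"unknown z_denominator {z_denominator!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mean_g - mean_all) / denom
        z[~np.isfinite(z)] = 0.0
        out[g] = z
    return pd.DataFrame(out, index=values.index)


def region_zscore(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    by: str = "country",
    z_denominator: str = "se",
) -> pd.DataFrame:
    """Per-MSP Z-scores of each country (or region group) against the
    entire population; rows MSPs, columns groups."""
    if abundance.scale != "relative":
        raise ValueError("region_zscore expects relative abundances")
    metadata.require_samples(abundance.sample_ids)
    groups = metadata.table.loc[abundance.sample_ids, by]
    if groups.nunique() < 2:
        raise ValueError(f"need >= 2 distinct {by} groups")
    return _group_zscores(abundance.values, groups, z_denominator)


def top_region_msps(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    k: int = 100,
    z_denominator: str = "se",
) -> dict[str, list[str]]:
    """Top-k overrepresented MSPs in the western and nonwestern groups,
    ranked by group-level Z-score (ties by id)."""
    z = region_zscore(abundance, metadata, by="region_class", z_denominator=z_denominator)
    if k > len(z):
        logger.info("k=%d exceeds %d MSPs; returning full ranking", k, len(z))
    out = {}
    for g in z.columns:
        ranked = sorted(z.index, key=lambda m: (-z.at[m, g], m))
        out[g] = ranked[:k]
    return out


@dataclass
class CategoryProfile:
    """Per-group normalized gene-content weights over functional terms."""

    weights: pd.DataFrame  # term x group, each group column sums to 1
    counts: pd.DataFrame  # raw annotated-gene counts
    top_differences: pd.DataFrame  # term, category, signed difference


def gene_content_profile(
    top_lists: dict[str, list[str]],
    catalog: MspCatalog,
    annotations: AnnotationTable,
    categories: tuple[str, ...] = ("cazyme", "amr", "virulence"),
    top_k: int = 18,
    group_pair: tuple[str, str] = ("western", "nonwestern"),
) -> CategoryProfile:
    """Count annotated genes per term over the genes of each group's top
    MSPs, normalize per group, and report the ``top_k`` terms with the
    largest |difference| between the two groups (signed, first minus
    second)."""
    ann = annotations.table
    ann = ann[ann["category"].isin(categories)]
    counts = {}
    for group, msps in sorted(top_lists.items()):
        genes = {g for m in msps if m in catalog.entries for g in catalog[m].genes}
        sub = ann[ann["gene_id"].isin(genes)]
        counts[group] = sub.groupby("term_id").size()
    count_df = pd.DataFrame(counts).fillna(0.0).sort_index()
    if count_df.empty or count_df.to_numpy().sum() == 0:
        raise ValueError("no annotated genes found in the top MSP lists")
    weights = count_df / count_df.sum(axis=0).replace(0, 1.0)
    a, b = group_pair
    diff = (weights.get(a, 0.0) - weights.get(b, 0.0)).rename("difference")
    cats = annotations.term_categories()
    top = (
        diff.to_frame()
        .assign(category=lambda d: d.index.map(cats))
        .assign(absdiff=lambda d: d["difference"].abs())
        .sort_values(["absdiff", "difference"], ascending=[False, False], kind="mergesort")
        .drop(columns="absdiff")
        .head(top_k)
        .rename_axis("term_id")
        .reset_index()
    )
    return CategoryProfile(weights=weights, counts=count_df, top_differences=top)
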
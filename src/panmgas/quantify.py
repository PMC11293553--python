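"""Gene counts -> MSP abundance profiles.

The estimator follows the marker-gene rule: each species' abundance in a
sample is the mean count of its marker genes (zero counts included), set
to zero when fewer than ``min_marker_fraction`` of the markers are seen.
Before estimation, samples are rarefied (sampled without replacement) to
a common target depth and shallower samples excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import substream
from .datatypes import AbundanceMatrix, GeneCountMatrix, MspCatalog

logger = logging.getLogger("panmgas")

__all__ = [
    "QuantifyParams",
    "downsize_counts",
    "msp_abundance",
    "to_relative",
    "to_per_million",
    "select_markers",
]


@dataclass
class QuantifyParams:
    target_depth: int = 10_000_000
    min_marker_fraction: float = 0.10
    markers_per_msp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth < 1:
            raise ValueError("target_depth must be >= 1")
        if not 0 < self.min_marker_fraction <= 1:
            raise ValueError("min_marker_fraction out of (0, 1]")


def downsize_counts(
    counts: GeneCountMatrix, params: QuantifyParams
) -> tuple[GeneCountMatrix, list[str]]:
    """Rarefy every sample to ``target_depth`` reads; exclude shallower ones.

    Sampling is without replacement (multivariate hypergeometric over the
    sample's reads), so no gene count ever increases and column sums hit
    the target exactly. Each sample gets its own sub-seed derived from
    (seed, sample id): the result is independent of sample order.
    """
    depths = counts.depths
    excluded = sorted(depths.index[depths < params.target_depth])
    kept = [s for s in counts.sample_ids if s not in set(excluded)]
    if excluded:
        logger.warning(
            "%d sample(s) below %d reads excluded", len(excluded), params.target_depth
        )
    if not kept:
        raise ValueError(
            f"all {len(excluded)} samples fall below the target depth "
            f"{params.target_depth}; nothing to quantify"
        )
    out = {}
    arr = counts.counts
    for sid in kept:
        col = arr[sid].to_numpy()
        total = int(col.sum())
        if total == params.target_depth:
            out[sid] = col
            continue
        rng = substream(params.seed, "rarefy", sid)
        out[sid] = rng.multivariate_hypergeometric(col, params.target_depth)
    down = pd.DataFrame(out, index=arr.index, dtype="int64")
    return GeneCountMatrix(down), excluded


def msp_abundance(
    counts: GeneCountMatrix, catalog: MspCatalog, params: QuantifyParams
) -> AbundanceMatrix:
    """Mean marker-gene count per MSP, zeroed under sparse marker detection.

    abundance(m, s) = mean over m's markers of counts (zeros included);
    forced to 0 when the fraction of markers with count > 0 falls below
    ``min_marker_fraction`` (a fraction exactly at the threshold is kept).
    """
    mat = counts.counts
    gene_index = {g: i for i, g in enumerate(mat.index)}
    values = mat.to_numpy()
    rows = {}
    for msp_id, entry in catalog.entries.items():
        if not entry.markers:
            raise ValueError(f"MSP {msp_id} has no marker genes")
        idx = [gene_index[g] for g in entry.markers if g in gene_index]
        if not idx:
            raise ValueError(f"MSP {msp_id}: no marker gene present in count matrix")
        sub = values[idx, :]
        mean = sub.mean(axis=0)
        seen_fraction = (sub > 0).mean(axis=0)
        mean[seen_fraction < params.min_marker_fraction] = 0.0
        rows[msp_id] = mean
    df = pd.DataFrame(rows, index=mat.columns).T
    return AbundanceMatrix(df, scale="raw_mean")


def to_relative(abundance: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each column to sum to 1; all-zero columns stay zero (flagged)."""
    if abundance.scale != "raw_mean":
        raise ValueError(f"expected raw_mean scale, got {abundance.scale}")
    df = abundance.values
    colsum = df.sum(axis=0)
    zero = sorted(colsum.index[colsum == 0])
    if zero:
        logger.warning("all-zero abundance column(s): %s", zero)
    safe = colsum.replace(0, 1.0)
    return AbundanceMatrix(df / safe, scale="relative", zero_samples=tuple(zero))


def to_per_million(abundance: AbundanceMatrix) -> AbundanceMatrix:
    rel = to_relative(abundance) if abundance.scale == "raw_mean" else abundance
    return AbundanceMatrix(
        rel.values * 1e6, scale="per_million", zero_samples=rel.zero_samples
    )


def select_markers(counts: GeneCountMatrix, gene_set, k: int) -> list[str]:
    """Pick the k genes that correlate the most altogether.

    Genes are ranked by their mean Spearman correlation to every other
    candidate gene across samples; ties break lexicographically.
    Constant genes contribute correlation 0 to their pairs.
    """
    genes = sorted(set(gene_set))
    if len(genes) < k:
        raise ValueError(f"gene_set has {len(genes)} genes, need at least k={k}")
    mat = counts.counts.loc[genes]
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples for marker selection")
    arr = mat.to_numpy(dtype=float)
    constant = arr.std(axis=1) == 0
    if constant.any():
        logger.info("%d constant gene(s) in marker selection", int(constant.sum()))
    rho = np.atleast_2d(stats.spearmanr(arr, axis=1).statistic)
    if rho.shape != (len(genes), len(genes)):  # scipy collapses the 2-gene case
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, np.nan)
    score = np.nanmean(rho, axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in order[:k]]
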
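"""Synthetic shotgun-metagenomics generator with planted ground truth.

Emulates the structure of a multi-cohort stool metagenome compendium:
log-normal baseline species abundances, multinomial allocation of reads
to catalog genes at variable sequencing depth, planted disease
fold-changes, planted region/country-specific species, and
block-structured co-conserved functional annotations. The planted truth
is returned alongside the data so every downstream stage can be scored
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seeds import substream
from .datatypes import (
    AnnotationTable,
    GeneCountMatrix,
    MspCatalog,
    MspEntry,
    SampleMetadata,
)

__all__ = [
    "CohortSpec", "DiseaseEffect", "RegionEffect", "TermBlock",
    "SimulationConfig", "PlantedTruth",
    "simulate_catalog", "simulate_counts", "simulate_annotations",
    "simulate_dataset",
]


@dataclass
class CohortSpec:
    """One cohort: a country, its regional class, and a health status."""

    cohort_id: str
    country: str
    region_class: str
    n_samples: int
    disease_label: str = ""  # empty => healthy cohort

    @property
    def status(self) -> str:
        return "diseased" if self.disease_label else "healthy"


@dataclass
class DiseaseEffect:
    msp_id: str
    disease_label: str
    fold_change: float


@dataclass
class RegionEffect:
    """Fold-change applied in a region class ('western'/'nonwestern') or
    in one named country."""

    msp_id: str
    fold_change: float
    region_class: str = ""
    country: str = ""


@dataclass
class TermBlock:
    """A block of functional terms carried by exactly the same MSP set
    (perfect within-block co-conservation)."""

    block_id: str
    n_terms: int
    member_msp_ids: tuple[str, ...]
    category: str = "ko"


@dataclass
class SimulationConfig:
    n_msps: int = 30
    genes_per_msp: int = 100
    markers_per_msp: int = 100
    cohorts: list[CohortSpec] = field(default_factory=list)
    # sequencing depth ~ LogNormal(mu, sigma) truncated below at `minimum`
    depth_log_mean: float = np.log(100_000.0)
    depth_log_sigma: float = 0.25
    depth_minimum: int = 10_000
    planted_disease_effects: list[DiseaseEffect] = field(default_factory=list)
    planted_region_effects: list[RegionEffect] = field(default_factory=list)
    planted_term_blocks: list[TermBlock] = field(default_factory=list)
    n_background_terms: int = 40
    background_term_rate: float = 0.05
    # baseline species abundance ~ LogNormal(mu, sigma); sigma 1.5 spans
    # roughly three orders of magnitude, typical of gut species profiles
    abundance_log_mean: float = 0.0
    abundance_log_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_msp > self.genes_per_msp:
            raise ValueError(
                f"markers_per_msp={self.markers_per_msp} exceeds "
                f"genes_per_msp={self.genes_per_msp}"
            )
        if not self.cohorts:
            self.cohorts = _default_cohorts()
        for c in self.cohorts:
            if c.n_samples < 2:
                raise ValueError(f"cohort {c.cohort_id}: n_samples must be >= 2")
        for e in self.planted_disease_effects + self.planted_region_effects:
            if e.fold_change <= 0:
                raise ValueError(f"fold_change must be > 0 (got {e.fold_change})")
        if not 0 <= self.background_term_rate <= 1:
            raise ValueError("background_term_rate out of [0, 1]")

    def msp_id(self, i: int) -> str:
        return f"msp_{i:04d}"

    @property
    def msp_ids(self) -> list[str]:
        return [self.msp_id(i) for i in range(self.n_msps)]


def _default_cohorts() -> list[CohortSpec]:
    """A small multi-country layout: disease cohorts with country-matched
    healthy controls plus two nonwestern healthy cohorts."""
    return [
        CohortSpec("coh_se_h", "SE", "western", 30),
        CohortSpec("coh_se_crc", "SE", "western", 30, disease_label="CRC"),
        CohortSpec("coh_us_h", "US", "western", 30),
        CohortSpec("coh_us_crc", "US", "western", 30, disease_label="CRC"),
        CohortSpec("coh_fj_h", "FJ", "nonwestern", 30),
        CohortSpec("coh_tz_h", "TZ", "nonwestern", 30),
    ]


@dataclass
class PlantedTruth:
    """Ground truth echoed by the generator: per-sample true relative MSP
    abundances and the planted effect/block lists."""

    relative_abundance: pd.DataFrame  # msp x sample, columns sum to 1
    disease_effects: list[DiseaseEffect]
    region_effects: list[RegionEffect]
    term_blocks: list[TermBlock]
    depths: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "relative_abundance": {
                s: self.relative_abundance[s].round(12).to_dict()
                for s in self.relative_abundance.columns
            },
            "disease_effects": [asdict(e) for e in self.disease_effects],
            "region_effects": [asdict(e) for e in self.region_effects],
            "term_blocks": [asdict(b) for b in self.term_blocks],
            "depths": self.depths.to_dict(),
        }


def simulate_catalog(config: SimulationConfig) -> MspCatalog:
    """Disjoint per-MSP gene sets; the first ``markers_per_msp`` genes of
    each MSP are flagged as its markers."""
    entries = {}
    for i in range(config.n_msps):
        msp = config.msp_id(i)
        genes = tuple(f"{msp}_g{j:04d}" for j in range(config.genes_per_msp))
        entries[msp] = MspEntry(
            genes=genes,
            markers=genes[: config.markers_per_msp],
            taxonomy=f"Synthetica species {i}",
        )
    return MspCatalog(entries)


def _sample_metadata(config: SimulationConfig) -> SampleMetadata:
    rows = []
    for c in config.cohorts:
        for k in range(c.n_samples):
            rows.append(
                {
                    "sample_id": f"{c.cohort_id}_s{k:03d}",
                    "cohort_id": c.cohort_id,
                    "country": c.country,
                    "region_class": c.region_class,
                    "status": c.status,
                    "disease_label": c.disease_label,
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


def _fold_vector(config: SimulationConfig, cohort: CohortSpec) -> np.ndarray:
    """Combined planted fold-change per MSP for samples of one cohort."""
    fold = np.ones(config.n_msps)
    index = {m: i for i, m in enumerate(config.msp_ids)}
    for e in config.planted_disease_effects:
        if cohort.disease_label and e.disease_label == cohort.disease_label:
            fold[index[e.msp_id]] *= e.fold_change
    for e in config.planted_region_effects:
        if (e.region_class and e.region_class == cohort.region_class) or (
            e.country and e.country == cohort.country
        ):
            fold[index[e.msp_id]] *= e.fold_change
    return fold


def simulate_counts(
    catalog: MspCatalog, config: SimulationConfig
) -> tuple[GeneCountMatrix, SampleMetadata, PlantedTruth]:
    """Draw per-sample species abundances and allocate reads to genes.

    For each sample: baseline MSP abundance ~ LogNormal, multiplied by
    the product of matching planted fold-changes, renormalized to a true
    relative composition; total depth drawn log-normally (truncated at
    the configured minimum) and reads spread multinomially over genes
    uniformly within each MSP. Column sums equal drawn depths exactly.
    """
    unknown = {e.msp_id for e in config.planted_disease_effects + config.planted_region_effects} - set(config.msp_ids)
    if unknown:
        raise ValueError(f"planted effects reference unknown MSPs: {sorted(unknown)}")
    metadata = _sample_metadata(config)
    msp_ids = config.msp_ids
    gene_ids = [g for m in msp_ids for g in catalog[m].genes]
    n_genes_per = config.genes_per_msp

    rel_cols: dict[str, np.ndarray] = {}
    count_cols: dict[str, np.ndarray] = {}
    depths: dict[str, int] = {}
    for cohort in config.cohorts:
        fold = _fold_vector(config, cohort)
        for k in range(cohort.n_samples):
            sid = f"{cohort.cohort_id}_s{k:03d}"
            rng = substream(config.seed, "counts", sid)
            base = rng.lognormal(
                config.abundance_log_mean, config.abundance_log_sigma, config.n_msps
            )
            a = base * fold
            rel = a / a.sum()
            depth = max(
                int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sigma))),
                config.depth_minimum,
            )
            gene_p = np.repeat(rel / n_genes_per, n_genes_per)
            counts = rng.multinomial(depth, gene_p)
            rel_cols[sid] = rel
            count_cols[sid] = counts
            depths[sid] = depth

    sample_ids = sorted(rel_cols)
    counts_df = pd.DataFrame(
        {s: count_cols[s] for s in sample_ids}, index=gene_ids, dtype="int64"
    )
    truth_rel = pd.DataFrame({s: rel_cols[s] for s in sample_ids}, index=msp_ids)
    truth = PlantedTruth(
        relative_abundance=truth_rel.sort_index(),
        disease_effects=list(config.planted_disease_effects),
        region_effects=list(config.planted_region_effects),
        term_blocks=list(config.planted_term_blocks),
        depths=pd.Series(depths).sort_index(),
    )
    return GeneCountMatrix(counts_df), metadata, truth


def simulate_annotations(catalog: MspCatalog, config: SimulationConfig) -> AnnotationTable:
    """Planted co-conserved term blocks plus independent background terms.

    Each block term is attached to one gene of every member MSP, so the
    carrier sets of all terms in a block are identical (within-block
    Jaccard 1). Background terms are assigned to each MSP independently
    with probability ``background_term_rate``.
    """
    known = set(catalog.msp_ids)
    rows = []
    for block in config.planted_term_blocks:
        missing = set(block.member_msp_ids) - known
        if missing:
            raise ValueError(
                f"term block {block.block_id} references unknown MSPs: {sorted(missing)}"
            )
        for t in range(block.n_terms):
            term = f"{block.block_id}_t{t:03d}"
            for j, msp in enumerate(sorted(block.member_msp_ids)):
                # spread block terms over distinct genes of the member MSP
                gene = catalog[msp].genes[t % len(catalog[msp].genes)]
                rows.append({"gene_id": gene, "term_id": term, "category": block.category})
    rng = substream(config.seed, "annotations")
    for b in range(config.n_background_terms):
        term = f"bg_t{b:03d}"
        carried = rng.random(len(catalog)) < config.background_term_rate
        for msp, hit in zip(catalog.msp_ids, carried):
            if hit:
                gene = catalog[msp].genes[-1 - (b % len(catalog[msp].genes))]
                rows.append({"gene_id": gene, "term_id": term, "category": "pfam"})
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "category"])
    df = df.drop_duplicates(["gene_id", "term_id"])
    return AnnotationTable(df)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: catalog, counts, metadata, annotations, truth."""
    catalog = simulate_catalog(config)
    counts, metadata, truth = simulate_counts(catalog, config)
    annotations = simulate_annotations(catalog, config)
    return catalog, counts, metadata, annotations, truth
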
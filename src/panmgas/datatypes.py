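"""Domain containers shared by every pipeline stage.

All tabular data live in pandas objects with a canonical lexicographic
ordering of gene, MSP and sample identifiers, so that every downstream
output is reproducible regardless of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("panmgas")

#: maximum marker genes per MSP in the reference configuration
REFERENCE_MARKER_COUNT = 100

REGION_CLASSES = ("western", "nonwestern")
STATUSES = ("healthy", "diseased")

__all__ = [
    "GeneCountMatrix",
    "MspEntry",
    "MspCatalog",
    "SampleMetadata",
    "AnnotationTable",
    "AbundanceMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object violates its structural contract."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")


@dataclass
class GeneCountMatrix:
    """Integer read counts of catalog genes (rows) per sample (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if not all(np.issubdtype(t, np.integer) for t in df.dtypes):
            raise ValidationError("gene counts must be integers")
        if (df.to_numpy() < 0).any():
            raise ValidationError("gene counts must be non-negative")
        self.counts = df.sort_index(axis=0).sort_index(axis=1)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Total mapped reads per sample."""
        return self.counts.sum(axis=0)

    def equals(self, other: "GeneCountMatrix") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class MspEntry:
    """One metagenomic species pan-genome: its gene set and marker genes."""

    genes: tuple[str, ...]
    markers: tuple[str, ...]
    taxonomy: str = ""

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(set(self.genes)))
        self.markers = tuple(self.markers)  # marker order is meaningful (rank)
        missing = set(self.markers) - set(self.genes)
        if missing:
            raise ValidationError(
                f"marker genes not in member gene set: {sorted(missing)[:10]}"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("duplicate marker genes")


@dataclass
class MspCatalog:
    """MSP id -> member genes / marker genes / taxonomy label.

    Member gene sets are pairwise disjoint: a catalog gene belongs to at
    most one species pan-genome.
    """

    entries: dict[str, MspEntry]

    def __post_init__(self) -> None:
        self.entries = {m: self.entries[m] for m in sorted(self.entries)}
        seen: dict[str, str] = {}
        for msp_id, entry in self.entries.items():
            for g in entry.genes:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} belongs to both {seen[g]!r} and {msp_id!r}"
                    )
                seen[g] = msp_id
            if len(entry.markers) > REFERENCE_MARKER_COUNT:
                logger.warning(
                    "MSP %s has %d marker genes (> reference %d)",
                    msp_id, len(entry.markers), REFERENCE_MARKER_COUNT,
                )

    @property
    def msp_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, msp_id: str) -> MspEntry:
        return self.entries[msp_id]

    def all_genes(self) -> set[str]:
        return {g for e in self.entries.values() for g in e.genes}

    def gene_to_msp(self) -> dict[str, str]:
        return {g: m for m, e in self.entries.items() for g in e.genes}

    def drop_missing_markers(self, present_genes: set[str]) -> "MspCatalog":
        """Return a catalog whose marker lists only reference *present_genes*.

        Markers absent from the count matrix are dropped with a warning;
        quantification then averages over the remaining markers.
        """
        new: dict[str, MspEntry] = {}
        for msp_id, e in self.entries.items():
            kept = tuple(g for g in e.markers if g in present_genes)
            if len(kept) < len(e.markers):
                logger.warning(
                    "MSP %s: %d marker gene(s) absent from count matrix, dropped",
                    msp_id, len(e.markers) - len(kept),
                )
            new[msp_id] = MspEntry(genes=e.genes, markers=kept, taxonomy=e.taxonomy)
        return MspCatalog(new)


@dataclass
class SampleMetadata:
    """Per-sample cohort, country, regional class and health status."""

    table: pd.DataFrame

    REQUIRED = ("cohort_id", "country", "region_class", "status", "disease_label")

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("metadata needs a sample_id column")
        _check_unique(df.index, "sample")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df = df.copy()
        df["disease_label"] = df["disease_label"].fillna("").astype(str)
        bad_region = set(df["region_class"]) - set(REGION_CLASSES)
        if bad_region:
            raise ValidationError(f"unknown region_class values: {sorted(bad_region)}")
        bad_status = set(df["status"]) - set(STATUSES)
        if bad_status:
            raise ValidationError(f"unknown status values: {sorted(bad_status)}")
        sick_unlabeled = df[(df["status"] == "diseased") & (df["disease_label"] == "")]
        if len(sick_unlabeled):
            raise ValidationError(
                f"diseased samples without disease_label: {list(sick_unlabeled.index)[:10]}"
            )
        self.table = df.sort_index()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def require_samples(self, sample_ids) -> None:
        unknown = sorted(set(sample_ids) - set(self.table.index))
        if unknown:
            raise ValidationError(f"samples absent from metadata: {unknown[:10]}")

    def cohort_samples(self, cohort_id: str) -> list[str]:
        return list(self.table.index[self.table["cohort_id"] == cohort_id])

    def cohorts(self) -> pd.DataFrame:
        """One row per cohort: country, region_class, status, disease_label, n."""
        grp = self.table.groupby("cohort_id")
        out = grp.agg(
            country=("country", "first"),
            region_class=("region_class", "first"),
            status=("status", "first"),
            disease_label=("disease_label", "first"),
            n_samples=("country", "size"),
        )
        return out.sort_index()


@dataclass
class AnnotationTable:
    """Long-form gene -> functional term assignments with a category label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        need = {"gene_id", "term_id", "category"}
        missing = need - set(df.columns)
        if missing:
            raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
        df = df[["gene_id", "term_id", "category"]].astype(str)
        if df.duplicated(["gene_id", "term_id"]).any():
            raise ValidationError("duplicate (gene_id, term_id) annotation pairs")
        cats = df.groupby("term_id")["category"].nunique()
        multi = cats[cats > 1]
        if len(multi):
            raise ValidationError(
                f"terms with more than one category: {list(multi.index)[:10]}"
            )
        self.table = df.sort_values(["gene_id", "term_id"]).reset_index(drop=True)

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.table["term_id"].unique())

    def term_categories(self) -> pd.Series:
        return self.table.drop_duplicates("term_id").set_index("term_id")["category"]


SCALES = ("raw_mean", "relative", "per_million")


@dataclass
class AbundanceMatrix:
    """MSP (rows) x sample (columns) abundances on a declared scale."""

    values: pd.DataFrame
    scale: str = "raw_mean"
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; one of {SCALES}")
        df = self.values
        _check_unique(df.index, "msp")
        _check_unique(df.columns, "sample")
        if (df.to_numpy() < 0).any():
            raise ValidationError("abundances must be non-negative")
        self.values = df.astype(float).sort_index(axis=0).sort_index(axis=1)
        colsum = self.values.sum(axis=0).to_numpy()
        nz = colsum > 0
        if self.scale == "relative" and nz.any():
            if not np.allclose(colsum[nz], 1.0, atol=1e-9):
                raise ValidationError("relative columns must sum to 1")
        if self.scale == "per_million" and nz.any():
            if not np.allclose(colsum[nz], 1e6, atol=1e-3):
                raise ValidationError("per_million columns must sum to 1e6")

    @property
    def msp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)
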
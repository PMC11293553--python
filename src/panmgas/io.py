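"""Readers and writers for the pipeline's on-disk exchange formats.

Gene counts and abundance matrices travel as dense TSV (first column the
row identifier, remaining columns sample ids); the MSP catalog as JSON
(or a 3-column TSV); metadata and annotations as headered TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig, validate_run_config
from .datatypes import (
    AbundanceMatrix,
    AnnotationTable,
    GeneCountMatrix,
    MspCatalog,
    MspEntry,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("panmgas")

__all__ = [
    "read_gene_counts", "write_gene_counts",
    "read_abundance", "write_abundance", "write_matrix",
    "read_catalog", "write_catalog",
    "read_metadata", "write_metadata",
    "read_annotations", "write_annotations",
    "load_dataset",
]


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_gene_counts(path: str | Path) -> GeneCountMatrix:
    df = pd.read_csv(_require(path), sep="\t", index_col="gene_id")
    return GeneCountMatrix(df.astype("int64"))


def write_gene_counts(matrix: GeneCountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_abundance(path: str | Path, scale: str = "relative") -> AbundanceMatrix:
    df = pd.read_csv(_require(path), sep="\t", index_col="msp_id")
    return AbundanceMatrix(df, scale=scale)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    # 17 significant digits: float64 round-trips exactly
    matrix.values.to_csv(path, sep="\t", index_label="msp_id", float_format="%.17g")


def write_matrix(matrix, path: str | Path) -> None:
    """Write either matrix flavour; integer counts round-trip exactly,
    reals within 1e-12 relative."""
    if isinstance(matrix, GeneCountMatrix):
        write_gene_counts(matrix, path)
    elif isinstance(matrix, AbundanceMatrix):
        write_abundance(matrix, path)
    else:
        raise TypeError(f"cannot write {type(matrix).__name__}")


def read_catalog(path: str | Path) -> MspCatalog:
    p = _require(path)
    if p.suffix.lower() == ".json":
        raw = json.loads(p.read_text())
        entries = {
            msp: MspEntry(
                genes=tuple(v["genes"]),
                markers=tuple(v.get("markers", ())),
                taxonomy=v.get("taxonomy", ""),
            )
            for msp, v in raw.items()
        }
        return MspCatalog(entries)
    # 3-column TSV dialect: msp_id  gene_id  is_marker
    df = pd.read_csv(p, sep="\t", dtype={"msp_id": str, "gene_id": str})
    need = {"msp_id", "gene_id", "is_marker"}
    if not need <= set(df.columns):
        raise ValidationError(f"catalog TSV needs columns {sorted(need)}")
    entries = {}
    for msp, grp in df.groupby("msp_id", sort=True):
        entries[str(msp)] = MspEntry(
            genes=tuple(grp["gene_id"]),
            markers=tuple(grp.loc[grp["is_marker"].astype(int) == 1, "gene_id"]),
        )
    return MspCatalog(entries)


def write_catalog(catalog: MspCatalog, path: str | Path) -> None:
    raw = {
        msp: {"genes": list(e.genes), "markers": list(e.markers), "taxonomy": e.taxonomy}
        for msp, e in catalog.entries.items()
    }
    Path(path).write_text(json.dumps(raw, indent=1, sort_keys=True) + "\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(
        _require(path), sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(_require(path), sep="\t", dtype=str)
    return AnnotationTable(df)


def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    annotations.table.to_csv(path, sep="\t", index=False)


def load_dataset(
    counts_path: str | Path,
    catalog_path: str | Path,
    metadata_path: str | Path,
    annotations_path: str | Path | None = None,
    config: dict | RunConfig | None = None,
) -> tuple[GeneCountMatrix, MspCatalog, SampleMetadata, AnnotationTable | None]:
    """Load and cross-validate the four pipeline inputs.

    Every sample column of the count matrix must have a metadata row;
    catalog marker genes absent from the matrix are dropped with a
    warning so quantification averages over the markers actually present.
    """
    validate_run_config(config)
    counts = read_gene_counts(counts_path)
    catalog = read_catalog(catalog_path)
    metadata = read_metadata(metadata_path)
    metadata.require_samples(counts.sample_ids)
    catalog = catalog.drop_missing_markers(set(counts.gene_ids))
    annotations = read_annotations(annotations_path) if annotations_path else None
    return counts, catalog, metadata, annotations
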
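"""End-to-end pipeline driver: simulate/load -> quantify -> associate ->
functional clusters -> cluster projection -> regional -> proportionality
-> classification. Writes plain-text outputs; a fixed seed makes the
whole run byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .association import classify_frequency, cohort_association, default_pairing
from .biomarker import ClassifierSpec, balanced_cohort, directional_shap, train_evaluate
from .clustenrich import cluster_frequency, project_clusters
from .config import RunConfig
from .datatypes import (
    AbundanceMatrix,
    AnnotationTable,
    GeneCountMatrix,
    MspCatalog,
    SampleMetadata,
)
from .funclust import find_clusters
from .io import (
    write_abundance,
    write_annotations,
    write_catalog,
    write_gene_counts,
    write_metadata,
)
from .propnet import build_network, permutation_fdr, prevalence_filter, rho_matrix
from .quantify import QuantifyParams, downsize_counts, msp_abundance, to_relative
from .regional import gene_content_profile, region_zscore, top_region_msps
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("panmgas")

__all__ = ["run_pipeline"]


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g", **kw)


def run_pipeline(
    out_dir: str | Path,
    config: RunConfig,
    sim_config: SimulationConfig | None = None,
    data: tuple[GeneCountMatrix, MspCatalog, SampleMetadata, AnnotationTable] | None = None,
    fdr_permutations: int = 20,
    classify_diseases: list[str] | None = None,
) -> dict:
    """Run every stage and write its outputs under ``out_dir``.

    Either a ``SimulationConfig`` (synthetic run, inputs are generated
    and also written) or pre-loaded ``data`` must be given. Returns a
    summary dict of headline quantities.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    if data is None:
        if sim_config is None:
            raise ValueError("either sim_config or data is required")
        catalog, counts, metadata, annotations, truth = simulate_dataset(sim_config)
        write_catalog(catalog, out / "catalog.json")
        write_gene_counts(counts, out / "counts.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_annotations(annotations, out / "annotations.tsv")
        (out / "truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=1, sort_keys=True) + "\n"
        )
    else:
        counts, catalog, metadata, annotations = data
        truth = None

    # --- quantification ---------------------------------------------------
    qp = QuantifyParams(
        target_depth=config.target_depth,
        min_marker_fraction=config.min_marker_fraction,
        markers_per_msp=config.markers_per_msp,
        seed=config.seed,
    )
    down, excluded = downsize_counts(counts, qp)
    raw = msp_abundance(down, catalog, qp)
    rel = to_relative(raw)
    write_abundance(rel, out / "msp_abundance.tsv")
    (out / "excluded_samples.txt").write_text("".join(s + "\n" for s in excluded))
    summary["n_samples_quantified"] = len(rel.sample_ids)
    summary["n_samples_excluded"] = len(excluded)
    summary["n_msps"] = len(rel.msp_ids)

    metadata_kept = SampleMetadata(metadata.table.loc[rel.sample_ids].reset_index())

    # --- pan-MGAS ---------------------------------------------------------
    pairing = default_pairing(metadata_kept)
    assoc = cohort_association(
        rel, metadata_kept, pairing,
        es_threshold=config.es_threshold,
        min_test_prevalence=config.min_test_prevalence,
    )
    _write_tsv(assoc.effect_sizes, out / "effect_sizes.tsv", index=False)
    calls = pd.DataFrame(
        [
            {"cohort_id": c, "direction": d, "msp_id": m}
            for d, sets in (("enriched", assoc.enriched), ("depleted", assoc.depleted))
            for c, ms in sorted(sets.items())
            for m in sorted(ms)
        ],
        columns=["cohort_id", "direction", "msp_id"],
    )
    _write_tsv(calls, out / "calls.tsv", index=False)
    disease_labels = metadata_kept.cohorts()["disease_label"].to_dict()
    freq = classify_frequency(assoc.enriched, assoc.depleted, disease_labels)
    _write_tsv(freq, out / "frequency_summary.tsv", index=False)
    summary["n_enriched_calls"] = int(sum(len(s) for s in assoc.enriched.values()))
    summary["n_depleted_calls"] = int(sum(len(s) for s in assoc.depleted.values()))

    # --- functional clusters ----------------------------------------------
    if annotations is not None:
        clusters, singletons, presence = find_clusters(
            annotations, catalog,
            jaccard_threshold=config.jaccard_threshold,
            walk_steps=config.walk_steps,
            coverage=config.association_coverage,
            min_species=config.min_representative_species,
        )
        (out / "clusters.json").write_text(
            json.dumps(
                {
                    c.cluster_id: {
                        "terms": sorted(c.member_terms),
                        "msps": sorted(c.associated_msps),
                        "representative": c.is_representative,
                    }
                    for c in clusters
                },
                indent=1, sort_keys=True,
            )
            + "\n"
        )
        (out / "singletons.txt").write_text("".join(t + "\n" for t in singletons))
        summary["n_functional_clusters"] = len(clusters)
        summary["n_singletons"] = len(singletons)

        records = project_clusters(
            clusters, assoc.enriched, assoc.depleted, assoc.tested,
            min_cluster_msps=config.min_cluster_msps,
            alpha=config.hypergeom_alpha,
        )
        _write_tsv(records, out / "cluster_enrichment.tsv", index=False)
        _write_tsv(cluster_frequency(records), out / "cluster_frequency.tsv", index=False)

    # --- regional ----------------------------------------------------------
    z = region_zscore(rel, metadata_kept, by="country")
    _write_tsv(z, out / "region_z.tsv", index_label="msp_id")
    top = top_region_msps(rel, metadata_kept, k=config.top_k_region)
    _write_tsv(
        pd.DataFrame(
            [
                {"region_class": g, "rank": i + 1, "msp_id": m}
                for g, lst in sorted(top.items())
                for i, m in enumerate(lst)
            ]
        ),
        out / "top_region_msps.tsv", index=False,
    )
    if annotations is not None:
        try:
            profile = gene_content_profile(
                top, catalog, annotations,
                categories=tuple(sorted(set(annotations.table["category"]))),
                top_k=config.top_k_differences,
            )
            _write_tsv(profile.weights, out / "category_profile.tsv", index_label="term_id")
            _write_tsv(profile.top_differences, out / "category_top_differences.tsv", index=False)
        except ValueError as exc:
            logger.warning("gene-content profile skipped: %s", exc)

    # --- proportionality ---------------------------------------------------
    kept = prevalence_filter(rel, min_present=config.min_prevalence_samples)
    summary["n_msps_prevalent"] = len(kept)
    if len(kept) >= 2:
        sub = AbundanceMatrix(rel.values.loc[kept], scale="raw_mean")
        rho = rho_matrix(sub)
        _write_tsv(rho, out / "rho.tsv", index_label="msp_id")
        net = build_network(rho, threshold=config.rho_threshold)
        edges = pd.DataFrame(
            sorted((a, b, d["rho"]) for a, b, d in net.edges(data=True)),
            columns=["msp_a", "msp_b", "rho"],
        )
        _write_tsv(edges, out / "network_edges.tsv", index=False)
        summary["n_network_edges"] = len(edges)
        if fdr_permutations > 0:
            fdr = permutation_fdr(
                sub, thresholds=[config.rho_threshold],
                n_perm=fdr_permutations, seed=config.seed,
            )
            _write_tsv(fdr, out / "fdr.tsv", index=False)

    # --- classification -----------------------------------------------------
    if classify_diseases is None:
        classify_diseases = sorted(
            set(metadata_kept.table["disease_label"]) - {""}
        )
    metrics = {}
    for disease in classify_diseases:
        X, y = balanced_cohort(rel, metadata_kept, disease, seed=config.seed)
        spec = ClassifierSpec(
            n_trees=config.n_trees,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        handle = train_evaluate(X, y, spec)
        scores = directional_shap(handle)
        _write_tsv(scores, out / f"shap_scores_{disease}.tsv", index=False)
        metrics[disease] = {
            "auroc_train": round(handle.auroc_train, 12),
            "auroc_test": round(handle.auroc_test, 12),
            "n_per_group": int(len(y) // 2),
        }
    (out / "model_metrics.json").write_text(
        json.dumps(metrics, indent=1, sort_keys=True) + "\n"
    )
    summary["classification"] = metrics
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n"
    )
    return summary
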
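import numpy as np
import pandas as pd
import pytest

from panmgas.datatypes import (
    AbundanceMatrix,
    GeneCountMatrix,
    MspCatalog,
    MspEntry,
    SampleMetadata,
)
from panmgas.simulate import (
    CohortSpec,
    DiseaseEffect,
    SimulationConfig,
    TermBlock,
    simulate_dataset,
)


@pytest.fixture
def toy_catalog() -> MspCatalog:
    entries = {
        f"msp_{i}": MspEntry(
            genes=tuple(f"msp_{i}_g{j}" for j in range(4)),
            markers=tuple(f"msp_{i}_g{j}" for j in range(2)),
        )
        for i in range(3)
    }
    return MspCatalog(entries)


@pytest.fixture
def toy_counts(toy_catalog) -> GeneCountMatrix:
    rng = np.random.default_rng(0)
    genes = sorted(toy_catalog.all_genes())
    samples = [f"s{k:02d}" for k in range(12)]
    df = pd.DataFrame(
        rng.integers(0, 50, size=(len(genes), len(samples))),
        index=genes, columns=samples, dtype="int64",
    )
    return GeneCountMatrix(df)


@pytest.fixture
def toy_metadata(toy_counts) -> SampleMetadata:
    rows = []
    for i, s in enumerate(toy_counts.sample_ids):
        diseased = i % 2 == 1
        rows.append(
            {
                "sample_id": s,
                "cohort_id": "coh_d" if diseased else "coh_h",
                "country": "SE",
                "region_class": "western",
                "status": "diseased" if diseased else "healthy",
                "disease_label": "CRC" if diseased else "",
            }
        )
    return SampleMetadata(pd.DataFrame(rows))


def two_cohort_config(seed: int, n_msps: int = 30, n_per: int = 60,
                      planted: int = 5, fold: float = 4.0,
                      genes_per_msp: int = 50) -> SimulationConfig:
    """One country, one disease cohort with matched healthy controls."""
    msps = [f"msp_{i:04d}" for i in range(n_msps)]
    return SimulationConfig(
        n_msps=n_msps,
        genes_per_msp=genes_per_msp,
        markers_per_msp=genes_per_msp,
        cohorts=[
            CohortSpec("coh_h", "SE", "western", n_per),
            CohortSpec("coh_d", "SE", "western", n_per, disease_label="CRC"),
        ],
        planted_disease_effects=[DiseaseEffect(m, "CRC", fold) for m in msps[:planted]],
        seed=seed,
    )


def rel_abundance_from(values: np.ndarray, prefix: str = "msp") -> AbundanceMatrix:
    """Wrap an array (msp x sample) as a relative AbundanceMatrix."""
    values = np.asarray(values, dtype=float)
    rel = values / values.sum(axis=0, keepdims=True)
    df = pd.DataFrame(
        rel,
        index=[f"{prefix}_{i:03d}" for i in range(values.shape[0])],
        columns=[f"s{j:04d}" for j in range(values.shape[1])],
    )
    return AbundanceMatrix(df, scale="relative")


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded full synthetic dataset reused by read-only tests."""
    msps = [f"msp_{i:04d}" for i in range(30)]
    cfg = SimulationConfig(
        seed=11,
        planted_disease_effects=[DiseaseEffect(m, "CRC", 4.0) for m in msps[:5]],
        planted_term_blocks=[
            TermBlock(f"blk{b}", 5, tuple(msps[b * 5:(b + 1) * 5])) for b in range(4)
        ],
    )
    return cfg, simulate_dataset(cfg)
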
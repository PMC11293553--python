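"""Co-conserved functional clusters across species.

Functional terms that are carried by nearly the same set of species are
co-conserved. Pairs with carrier-set Jaccard >= 0.75 form an undirected
co-occurrence network; communities found by the short-random-walk
(walktrap) algorithm are the functional clusters. A cluster is
representative when more than three species carry it (at the association
coverage), and an MSP is associated with a cluster when it carries more
than 75% of the cluster's terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd

from .datatypes import AnnotationTable, MspCatalog

logger = logging.getLogger("panmgas")

__all__ = [
    "TermPresenceMatrix",
    "FunctionalCluster",
    "term_presence",
    "jaccard_matrix",
    "build_conservation_network",
    "detect_communities",
    "associate_msps",
    "select_representative",
    "find_clusters",
]


@dataclass
class TermPresenceMatrix:
    """Binary term x MSP matrix: does the species carry >= 1 gene with
    the term? Terms with zero carriers are removed (logged)."""

    presence: pd.DataFrame

    def __post_init__(self) -> None:
        df = (self.presence.astype(int) > 0).astype("int8")
        carriers = df.sum(axis=1)
        empty = sorted(carriers.index[carriers == 0])
        if empty:
            logger.info("removed %d zero-carrier term(s)", len(empty))
            df = df.drop(index=empty)
        self.presence = df.sort_index(axis=0).sort_index(axis=1)

    @property
    def term_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def msp_ids(self) -> list[str]:
        return list(self.presence.columns)

    def carriers(self, term_id: str) -> set[str]:
        row = self.presence.loc[term_id]
        return set(row.index[row > 0])


@dataclass
class FunctionalCluster:
    cluster_id: str
    member_terms: frozenset[str]
    associated_msps: frozenset[str] = field(default_factory=frozenset)
    is_representative: bool = False


def term_presence(annotations: AnnotationTable, catalog: MspCatalog) -> TermPresenceMatrix:
    """Project gene-level annotations to the species level."""
    gene_to_msp = catalog.gene_to_msp()
    df = annotations.table.copy()
    df["msp_id"] = df["gene_id"].map(gene_to_msp)
    df = df.dropna(subset=["msp_id"])
    pres = pd.crosstab(df["term_id"], df["msp_id"])
    pres = pres.reindex(columns=catalog.msp_ids, fill_value=0)
    pres.index.name = None
    pres.columns.name = None
    return TermPresenceMatrix(pres)


def jaccard_matrix(presence: TermPresenceMatrix) -> pd.DataFrame:
    """J(a,b) = |carriers(a) ∩ carriers(b)| / |carriers(a) ∪ carriers(b)|."""
    mat = presence.presence.to_numpy(dtype=np.int64)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 terms")
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    jac = inter / union  # union > 0: zero-carrier terms were removed
    np.fill_diagonal(jac, 1.0)
    return pd.DataFrame(jac, index=presence.term_ids, columns=presence.term_ids)


def build_conservation_network(J: pd.DataFrame, threshold: float = 0.75) -> igraph.Graph:
    """Edge (a, b) iff J(a, b) >= threshold (inclusive), a != b.

    Isolated terms stay in the graph as nodes; they end up as singletons.
    """
    terms = list(J.index)
    arr = J.to_numpy()
    iu = np.triu_indices(len(terms), k=1)
    keep = arr[iu] >= threshold
    edges = [(int(i), int(j)) for i, j in zip(iu[0][keep], iu[1][keep])]
    g = igraph.Graph(n=len(terms), edges=edges, directed=False)
    g.vs["name"] = terms
    return g


def detect_communities(
    graph: igraph.Graph, walk_steps: int = 4
) -> tuple[list[set[str]], list[str]]:
    """Partition terms into clusters via walktrap; size-1 components are
    singletons.

    Returns (clusters, singletons); every term lands in exactly one of
    the two. Determinism follows from the canonical lexicographic node
    order of the input graph.
    """
    if graph.vcount() == 0:
        return [], []
    names = graph.vs["name"]
    comp = graph.connected_components()
    singletons = sorted(names[v[0]] for v in comp if len(v) == 1)
    keep = [v for c in comp if len(c) > 1 for v in c]
    if not keep:
        return [], singletons
    sub = graph.induced_subgraph(sorted(keep))
    clustering = sub.community_walktrap(steps=walk_steps).as_clustering()
    clusters = [
        set(sub.vs[v]["name"] for v in community) for community in clustering
    ]
    clusters.sort(key=lambda s: min(s))
    return clusters, singletons


def associate_msps(
    member_terms: set[str], presence: TermPresenceMatrix, coverage: float = 0.75
) -> set[str]:
    """MSPs carrying strictly more than ``coverage`` of the cluster's terms."""
    terms = sorted(set(member_terms) & set(presence.term_ids))
    if not terms:
        return set()
    sub = presence.presence.loc[terms]
    frac = sub.mean(axis=0)
    return set(frac.index[frac > coverage])


def select_representative(
    clusters: list[FunctionalCluster],
    min_species: int = 3,
) -> list[FunctionalCluster]:
    """Flag clusters whose functions are found in more than ``min_species``
    species (strictly), counting MSPs that pass the association rule."""
    return [
        FunctionalCluster(
            cluster_id=c.cluster_id,
            member_terms=c.member_terms,
            associated_msps=c.associated_msps,
            is_representative=len(c.associated_msps) > min_species,
        )
        for c in clusters
    ]


def find_clusters(
    annotations: AnnotationTable,
    catalog: MspCatalog,
    jaccard_threshold: float = 0.75,
    walk_steps: int = 4,
    coverage: float = 0.75,
    min_species: int = 3,
) -> tuple[list[FunctionalCluster], list[str], TermPresenceMatrix]:
    """Full detection chain: presence -> Jaccard -> network -> walktrap ->
    association -> representativeness. Returns (clusters, singletons,
    presence matrix); cluster ids are CL-0001... in order of smallest
    member term."""
    presence = term_presence(annotations, catalog)
    J = jaccard_matrix(presence)
    graph = build_conservation_network(J, threshold=jaccard_threshold)
    raw, singletons = detect_communities(graph, walk_steps=walk_steps)
    clusters = []
    for i, terms in enumerate(raw):
        msps = associate_msps(terms, presence, coverage=coverage)
        clusters.append(
            FunctionalCluster(
                cluster_id=f"CL-{i + 1:04d}",
                member_terms=frozenset(terms),
                associated_msps=frozenset(msps),
            )
        )
    clusters = select_representative(clusters, min_species=min_species)
    return clusters, singletons, presence
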
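"""Proportionality (rho) between species abundance profiles.

Correlation is misleading on compositional data; proportionality
rho(a, b) = 1 - var(y_a - y_b) / (var y_a + var y_b), with y = log
abundance, is symmetric in [-1, 1] and equals 1 exactly when two
species' abundances are proportional across samples. Species present in
more than 50 samples enter; pairs with rho > 0.65 form the network.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import substream
from .datatypes import AbundanceMatrix

logger = logging.getLogger("panmgas")

__all__ = [
    "prevalence_filter",
    "pseudocount",
    "rho_matrix",
    "permutation_fdr",
    "build_network",
]


def prevalence_filter(abundance: AbundanceMatrix, min_present: int = 50) -> list[str]:
    """MSPs with nonzero abundance in strictly more than ``min_present``
    samples."""
    nonzero = (abundance.values > 0).sum(axis=1)
    return sorted(nonzero.index[nonzero > min_present])


def pseudocount(values: pd.DataFrame) -> float:
    """Half the smallest nonzero value of the matrix (zero-replacement delta)."""
    arr = values.to_numpy()
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("matrix is all zero; no pseudocount defined")
    return float(nz.min() / 2.0)


def _log_transform(values: pd.DataFrame, delta: float | None, clr: bool) -> np.ndarray:
    if delta is None:
        delta = pseudocount(values)
    y = np.log(values.to_numpy(dtype=float) + delta)
    if clr:
        y = y - y.mean(axis=0, keepdims=True)  # center per sample
    return y


def rho_matrix(
    abundance: AbundanceMatrix,
    delta: float | None = None,
    clr: bool = False,
) -> pd.DataFrame:
    """Symmetric proportionality matrix on log(abundance + delta).

    rho(a, b) = 1 - var(y_a - y_b)/(var y_a + var y_b) across samples;
    diagonal 1; species with zero log-scale variance get rho 0 (logged).
    """
    return _rho_from_values(abundance.values, delta, clr)


def _rho_from_values(values: pd.DataFrame, delta: float | None, clr: bool) -> pd.DataFrame:
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for proportionality")
    y = _log_transform(values, delta, clr)
    var = y.var(axis=1, ddof=1)
    zero_var = var == 0
    if zero_var.any():
        logger.warning("%d zero-variance MSP(s); rho set to 0", int(zero_var.sum()))
    centered = y - y.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (y.shape[1] - 1)
    denom = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        # var(ya - yb) = var a + var b - 2 cov
        rho = 1.0 - (var[:, None] + var[None, :] - 2.0 * cov) / denom
    rho[zero_var, :] = 0.0
    rho[:, zero_var] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.index, columns=values.index)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def permutation_fdr(
    abundance: AbundanceMatrix,
    thresholds,
    n_perm: int = 100,
    seed: int = 0,
    delta: float | None = None,
    clr: bool = False,
) -> pd.DataFrame:
    """Permutation estimate of the FDR at each rho threshold.

    Each permutation independently shuffles every MSP's sample order,
    destroying all between-species association while preserving each
    species' marginal distribution. FDR(t) = mean permuted pair count at
    rho >= t divided by the observed count (NA when nothing observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    thresholds = list(thresholds)
    values = abundance.values
    if delta is None:
        delta = pseudocount(values)  # fixed across permutations
    observed = _upper(_rho_from_values(values, delta, clr).to_numpy())
    obs_counts = {t: int((observed >= t).sum()) for t in thresholds}
    perm_counts = {t: 0 for t in thresholds}
    arr = values.to_numpy()
    for b in range(n_perm):
        rng = substream(seed, "propr-fdr", b)
        shuffled = np.stack([row[rng.permutation(arr.shape[1])] for row in arr])
        perm = pd.DataFrame(shuffled, index=values.index, columns=values.columns)
        pr = _upper(_rho_from_values(perm, delta, clr).to_numpy())
        for t in thresholds:
            perm_counts[t] += int((pr >= t).sum())
    rows = []
    for t in thresholds:
        obs = obs_counts[t]
        mean_perm = perm_counts[t] / n_perm
        rows.append(
            {
                "threshold": t,
                "observed_pairs": obs,
                "mean_permuted_pairs": mean_perm,
                "fdr": (mean_perm / obs) if obs > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def build_network(rho: pd.DataFrame, threshold: float = 0.65) -> nx.Graph:
    """Undirected network over all filtered MSPs; edges where rho is
    strictly greater than the threshold (isolated nodes retained)."""
    g = nx.Graph()
    g.add_nodes_from(rho.index)
    arr = rho.to_numpy()
    iu = np.triu_indices(len(rho), k=1)
    for i, j in zip(*iu):
        if arr[i, j] > threshold:
            g.add_edge(rho.index[i], rho.index[j], rho=float(arr[i, j]))
    return g
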
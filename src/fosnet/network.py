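"""Signed Spearman co-activation networks.

One condition's co-activation network has a node per brain region and an
undirected edge for every pair of regions whose activation values are
significantly rank-correlated across the animals of that condition
(two-tailed p < alpha, default 0.05, uncorrected — no multiple-testing
correction is applied across the pair matrix; see the methods note).  Edge
weights keep the sign of the correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "CoactivationNetwork",
    "spearman_matrix",
    "build_network",
    "edge_composition",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ("animal_id", "group")


def region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations for one group's activation table.

    ``rho`` and ``p`` are symmetric with fixed diagonals (1 and 0); pairs
    involving a constant region are NaN in both (undefined, never zero).
    """

    regions: list[str]
    rho: np.ndarray
    p: np.ndarray
    n: int

    def __post_init__(self) -> None:
        k = len(self.regions)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("rho and p must be square over the region list")
        if not (
            np.allclose(self.rho, self.rho.T, equal_nan=True)
            and np.allclose(self.p, self.p.T, equal_nan=True)
        ):
            raise ValueError("rho and p must be symmetric")
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and np.abs(finite).max() > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


@dataclass
class CoactivationNetwork:
    """Significance-thresholded signed correlation graph for one condition."""

    regions: list[str]
    edges: list[tuple[str, str, float, float]]  # (i, j, rho, p) with i < j order
    alpha: float
    n_defined_pairs: int
    axis: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j, rho, p in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not p < self.alpha:
                raise ValueError(f"edge ({i}, {j}) has p={p} >= alpha={self.alpha}")
            if rho == 0:
                raise ValueError("zero-weight edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.regions)

    def to_networkx(self) -> nx.Graph:
        """Graph with signed ``weight``, ``abs_weight`` and ``length`` (1/|w|)."""
        g = nx.Graph()
        g.add_nodes_from(self.regions)
        for i, j, rho, p in self.edges:
            g.add_edge(i, j, weight=rho, abs_weight=abs(rho), length=1.0 / abs(rho), p=p)
        return g

    def abs_weight_matrix(self) -> np.ndarray:
        """Dense |rho| adjacency in region order (0 where no edge)."""
        idx = {r: k for k, r in enumerate(self.regions)}
        w = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, rho, _ in self.edges:
            w[idx[i], idx[j]] = w[idx[j], idx[i]] = abs(rho)
        return w

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["region_i", "region_j", "rho", "p"])


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=0, method="average")


def rho_p_from_values(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-rank Spearman rho and asymptotic two-tailed p for all columns.

    Constant columns yield NaN rows/columns.  Fast path shared by the network
    builder and the permutation machinery in :mod:`fosnet.compare`.
    """
    n, k = values.shape
    ranks = _rank_matrix(values)
    sd = ranks.std(axis=0)
    constant = sd == 0
    centered = ranks - ranks.mean(axis=0)
    denom = np.where(constant, 1.0, sd * n)
    normed = centered / denom
    rho = normed.T @ normed * n
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(p, 0.0)
    return rho, p


def _exact_permutation_p(ranks: np.ndarray, rho_obs: np.ndarray) -> np.ndarray:
    """Exhaustive permutation p per pair: all n! orderings of one margin."""
    n, k = ranks.shape
    perms = np.array(list(itertools.permutations(range(n))))
    sd = ranks.std(axis=0)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 0.0)
    centered = ranks - ranks.mean(axis=0)
    for i in range(k):
        if sd[i] == 0:
            continue
        xi = centered[:, i] / (sd[i] * n)
        for j in range(i + 1, k):
            if sd[j] == 0:
                continue
            yj = centered[:, j] / sd[j]
            dist = (yj[perms] * xi).sum(axis=1)
            p[i, j] = p[j, i] = np.mean(np.abs(dist) >= np.abs(rho_obs[i, j]) - 1e-12)
    return p


def spearman_matrix(
    table: pd.DataFrame, p_method: str = "t"
) -> CorrelationMatrix:
    """Spearman correlation matrix of one group's activation table.

    ``p_method`` is ``"t"`` (asymptotic t approximation, the default) or
    ``"permutation"`` (exhaustive over all n! animal orderings; n <= 9 only).
    Rows with missing region values are dropped and logged.
    """
    regions = region_columns(table)
    values = table[regions].to_numpy(dtype=float)
    keep = np.isfinite(values).all(axis=1)
    if not keep.all():
        logger.warning("dropping %d animals with missing region values", (~keep).sum())
        values = values[keep]
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"at least 4 animals required, got {n}")
    rho, p = rho_p_from_values(values)
    if p_method == "permutation":
        if n > 9:
            raise ValueError("exact permutation p is limited to n <= 9 animals")
        p = _exact_permutation_p(_rank_matrix(values), rho)
    elif p_method != "t":
        raise ValueError(f"unknown p_method {p_method!r}")
    if np.isnan(rho[np.triu_indices(len(regions), 1)]).any():
        logger.warning("constant regions produced undefined correlations")
    return CorrelationMatrix(regions=regions, rho=rho, p=p, n=n)


def build_network(
    matrix: CorrelationMatrix,
    alpha: float = 0.05,
    axis: dict[str, str] | None = None,
) -> CoactivationNetwork:
    """Keep the edges with p strictly below alpha; isolated nodes are retained.

    Pairs with undefined correlations are excluded from both the edge set and
    the possible-pair count.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    k = len(matrix.regions)
    edges = []
    defined = 0
    for i in range(k):
        for j in range(i + 1, k):
            rho, p = matrix.rho[i, j], matrix.p[i, j]
            if np.isnan(rho) or np.isnan(p):
                continue
            defined += 1
            if p < alpha and rho != 0:
                edges.append((matrix.regions[i], matrix.regions[j], float(rho), float(p)))
    return CoactivationNetwork(
        regions=list(matrix.regions),
        edges=edges,
        alpha=alpha,
        n_defined_pairs=defined,
        axis=dict(axis or {}),
    )


def edge_composition(network: CoactivationNetwork) -> tuple[int, int, int]:
    """(positive edges, negative edges, possible pairs) for one network."""
    n_pos = sum(1 for *_ij, rho, _p in network.edges if rho > 0)
    n_neg = len(network.edges) - n_pos
    return n_pos, n_neg, network.n_defined_pairs
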
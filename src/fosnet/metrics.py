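"""Node centralities, hub detection, and global graph metrics.

Distance-based metrics run on absolute edge weights with edge length
``1/|rho|``, so a strong correlation (|rho| near 1) is a short, efficient
link and every inverse distance stays in [0, 1].  The sign of an edge is kept
in the data model but enters only the edge-composition and E/I analyses.

Hubs: a node is a *candidate* when it sits at or above the 90th percentile of
the observed network's node distribution on degree, strength, or betweenness;
it is a *hub* when the flagged metric also exceeds the 95th percentile of that
node's distribution under the diagonal-preserving shuffle null.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import CoactivationNetwork, region_columns, rho_p_from_values

__all__ = [
    "Partition",
    "node_centralities",
    "global_efficiency",
    "global_clustering",
    "mean_strength",
    "louvain_partition",
    "select_resolution",
    "detect_hubs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Partition:
    assignment: dict[str, int]
    modularity_q: float
    resolution: float
    n_modules: int


# ---------------------------------------------------------------------------
# fast array kernels (shared with fosnet.compare's permutation loops)

def efficiency_from_abs_weights(w: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs; 0 for no pairs."""
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    if not w.any():
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return float(inv[off].mean())


def transitivity_from_abs_weights(w: np.ndarray) -> float:
    """Binarized transitivity: 3 * triangles / connected triplets."""
    a = (w > 0).astype(float)
    deg = a.sum(axis=0)
    triplets = float((deg * (deg - 1)).sum())
    if triplets == 0:
        return 0.0
    return float(np.trace(a @ a @ a) / triplets)


def mean_strength_from_abs_weights(w: np.ndarray) -> float:
    return float(np.abs(w).sum(axis=0).mean())


# ---------------------------------------------------------------------------
# network-facing operations

def node_centralities(network: CoactivationNetwork) -> pd.DataFrame:
    """Degree, strength (sum of |rho|), and weighted betweenness per region.

    Betweenness uses edge length ``1/|rho|`` and unnormalized counts with
    fractional credit for tied shortest paths; isolated nodes get zeros.
    """
    g = network.to_networkx()
    degree = dict(g.degree())
    strength = {
        node: sum(d["abs_weight"] for _, _, d in g.edges(node, data=True))
        for node in g.nodes
    }
    betweenness = nx.betweenness_centrality(g, weight="length", normalized=False)
    return pd.DataFrame(
        {
            "region": network.regions,
            "degree": [degree[r] for r in network.regions],
            "strength": [strength[r] for r in network.regions],
            "betweenness": [betweenness[r] for r in network.regions],
        }
    ).set_index("region")


def global_efficiency(network: CoactivationNetwork) -> float:
    """Network integration: mean of 1/d(i, j) over ordered node pairs."""
    return efficiency_from_abs_weights(network.abs_weight_matrix())


def global_clustering(network: CoactivationNetwork) -> float:
    """Transitivity of the binarized edge set (0, with a log note, if no triplets)."""
    if network.n_nodes < 3:
        raise ValueError("global clustering needs at least 3 nodes")
    value = transitivity_from_abs_weights(network.abs_weight_matrix())
    if value == 0.0 and not network.edges:
        logger.info("no connected triplets; clustering reported as 0")
    return value


def mean_strength(network: CoactivationNetwork) -> float:
    """Arithmetic mean of node strengths (handshake: 2 * sum |rho| / n)."""
    if network.n_nodes < 1:
        raise ValueError("mean strength needs at least 1 node")
    return mean_strength_from_abs_weights(network.abs_weight_matrix())


def louvain_partition(
    network: CoactivationNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    binarize: bool = False,
) -> Partition:
    """Louvain communities on absolute weights at the given resolution.

    The reported modularity Q is always evaluated at resolution 1 on the final
    assignment, so partitions found at different resolutions stay comparable.
    An edgeless network yields singleton modules with Q = 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = network.to_networkx()
    if binarize:
        for *_uv, data in g.edges(data=True):
            data["abs_weight"] = 1.0
    if g.number_of_edges() == 0:
        logger.warning("edgeless network: every node is its own module, Q = 0")
        assignment = {r: i for i, r in enumerate(network.regions)}
        return Partition(assignment, 0.0, resolution, len(assignment))
    communities = nx.community.louvain_communities(
        g, weight="abs_weight", resolution=resolution, seed=seed
    )
    q = nx.community.modularity(g, communities, weight="abs_weight", resolution=1.0)
    assignment = {
        node: idx for idx, comm in enumerate(communities) for node in comm
    }
    return Partition(assignment, float(q), resolution, len(communities))


def _bootstrap_networks(
    table: pd.DataFrame, B: int, alpha: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Abs-weight matrices of networks rebuilt on animal-resampled tables.

    Animals are resampled with replacement within their group, the defensible
    biological replicate.
    """
    regions = region_columns(table)
    groups = table["group"] if "group" in table.columns else pd.Series(
        ["all"] * len(table), index=table.index
    )
    blocks = [np.flatnonzero(groups.to_numpy() == g) for g in groups.unique()]
    values = table[regions].to_numpy(dtype=float)
    out = []
    for _ in range(B):
        idx = np.concatenate(
            [rng.choice(block, size=block.size, replace=True) for block in blocks]
        )
        rho, p = rho_p_from_values(values[idx])
        w = np.where(np.nan_to_num(p, nan=1.0) < alpha, np.abs(rho), 0.0)
        np.fill_diagonal(w, 0.0)
        out.append(w)
    return out


def select_resolution(
    table: pd.DataFrame,
    grid: Sequence[float],
    B: int,
    seed: int,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Pick the Louvain resolution whose bootstrap module count is most stable.

    For every candidate resolution the network is rebuilt on ``B``
    animal-resampled tables and Louvain is run; the winner is the resolution
    whose modal module count (isolated nodes excluded) recurs most often,
    ties broken toward the resolution closest to 1.
    """
    if B < 10:
        raise ValueError("B must be at least 10")
    if not len(grid):
        raise ValueError("resolution grid must be nonempty")
    rng = np.random.default_rng(seed)
    weight_mats = _bootstrap_networks(table, B, alpha, rng)
    if all(not w.any() for w in weight_mats):
        raise ValueError("degenerate bootstrap: every resampled network is edgeless")
    best: tuple[float, float, int] | None = None  # (freq, -|log r|, modal count)
    best_r = None
    for r in grid:
        counts = []
        for b, w in enumerate(weight_mats):
            if not w.any():
                continue
            g = nx.from_numpy_array(w)
            communities = nx.community.louvain_communities(
                g, weight="weight", resolution=r, seed=int(seed + b + 1)
            )
            connected = {i for i in g.nodes if g.degree(i) > 0}
            counts.append(sum(1 for c in communities if c & connected))
        modal, freq = Counter(counts).most_common(1)[0]
        key = (freq / len(counts), -abs(np.log(r)), modal)
        if best is None or key[:2] > best[:2]:
            best, best_r = key, float(r)
    assert best is not None and best_r is not None
    return best_r, int(best[2])


def detect_hubs(
    metrics: pd.DataFrame,
    null: Mapping[str, np.ndarray] | None = None,
    percentile: float = 90.0,
    null_percentile: float = 95.0,
) -> pd.DataFrame:
    """Flag hub regions against the observed distribution and the shuffle null.

    ``metrics`` is the frame from :func:`node_centralities`; ``null`` maps each
    metric name to a (B, n_nodes) array of null values aligned with the frame's
    row order (see :func:`fosnet.compare.null_metric_distributions`).  A node
    is a candidate when it reaches the 90th percentile of the observed node
    distribution on any metric, and a hub when that same metric also exceeds
    the 95th percentile of the node's null distribution.
    """
    out = metrics.copy()
    names = ["degree", "strength", "betweenness"]
    candidate_on = {name: np.zeros(len(out), dtype=bool) for name in names}
    for name in names:
        values = out[name].to_numpy(dtype=float)
        cut = np.percentile(values, percentile)
        candidate_on[name] = values >= cut
    is_candidate = np.logical_or.reduce(list(candidate_on.values()))
    out["is_candidate"] = is_candidate
    if null is None:
        logger.warning("no null ensemble supplied; hub significance not assessed")
        out["is_hub"] = pd.NA
        out["hub_evidence"] = [
            ";".join(f"{m}>=p{percentile:g}" for m in names if candidate_on[m][k])
            for k in range(len(out))
        ]
        return out
    is_hub = np.zeros(len(out), dtype=bool)
    evidence = [[] for _ in range(len(out))]
    for name in names:
        null_values = np.asarray(null[name], dtype=float)
        if null_values.shape[1] != len(out):
            raise ValueError("null distributions do not match the node set")
        # Above-chance check against the null distribution of the network
        # MAXIMUM of the metric (one value per shuffled member): a node is
        # significant only if no node of a chance network would be expected
        # to reach its value, which controls the family-wise false-hub rate
        # across the candidate ties a homogeneous network produces.
        cut = np.percentile(null_values.max(axis=1), null_percentile)
        observed = out[name].to_numpy(dtype=float)
        for k in range(len(out)):
            if not candidate_on[name][k]:
                continue
            evidence[k].append(f"{name}>=p{percentile:g}")
            if observed[k] > cut:
                is_hub[k] = True
                evidence[k].append(f"{name}>null_p{null_percentile:g}")
    out["is_hub"] = is_hub
    out["hub_evidence"] = [";".join(e) for e in evidence]
    return out
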
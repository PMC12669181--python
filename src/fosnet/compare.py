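"""Null models, reference normalization, and between-network tests.

Chance calibration follows the shuffle-null recipe: from one observed
correlation matrix, 100 surrogate matrices are drawn by permuting rows and
columns simultaneously (diagonal restored), which destroys node identity while
preserving the value multiset.  Group networks are compared by permuting
animal group labels (an exact exchangeability null at these sample sizes) and
edge densities by chi-square tests on the edge/non-edge contingency.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (
    efficiency_from_abs_weights,
    mean_strength_from_abs_weights,
    transitivity_from_abs_weights,
)
from .network import (
    CoactivationNetwork,
    CorrelationMatrix,
    edge_composition,
    region_columns,
    rho_p_from_values,
)

__all__ = [
    "NullEnsemble",
    "NormalizedMetrics",
    "shuffle_null_models",
    "lattice_reference",
    "normalize_metric",
    "null_metric_distributions",
    "bootstrap_compare_metric",
    "edge_count_tests",
]

logger = logging.getLogger(__name__)

METRICS = ("efficiency", "clustering", "modularity", "mean_strength")


@dataclass
class NullEnsemble:
    """B diagonal-preserving row/column shuffles of one correlation matrix."""

    source: CorrelationMatrix
    rho: np.ndarray  # (B, n, n)
    p: np.ndarray  # (B, n, n), co-permuted with rho
    seed: int

    @property
    def B(self) -> int:
        return self.rho.shape[0]

    def member(self, b: int) -> CorrelationMatrix:
        return CorrelationMatrix(
            regions=list(self.source.regions),
            rho=self.rho[b],
            p=self.p[b],
            n=self.source.n,
        )


@dataclass(frozen=True)
class NormalizedMetrics:
    metric: str
    raw: float
    random_mean: float
    lattice_mean: float
    normalized: float
    small_world_style_ratio: float | None


def shuffle_null_models(
    matrix: CorrelationMatrix, B: int = 100, seed: int = 0
) -> NullEnsemble:
    """Shuffle the correlation structure while keeping the main diagonal intact.

    Each member redistributes the observed (rho, p) value pairs uniformly at
    random over the off-diagonal positions (symmetrically, so members remain
    valid correlation-style matrices).  This destroys which regions are
    connected while preserving the diagonal and the off-diagonal value
    multiset exactly — and, because p moves with rho, the thresholded edge
    count of every member equals the source's.  A permutation-of-node-labels
    shuffle would leave every global graph metric literally unchanged and
    could not serve as a chance reference.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(matrix.regions)
    iu = np.triu_indices(n, 1)
    rho_vals = matrix.rho[iu]
    p_vals = matrix.p[iu]
    rho = np.zeros((B, n, n))
    p = np.zeros((B, n, n))
    diag_rho = np.diag(matrix.rho).copy()
    diag_p = np.diag(matrix.p).copy()
    for b in range(B):
        perm = rng.permutation(rho_vals.size)
        rb = np.zeros((n, n))
        pb = np.zeros((n, n))
        rb[iu] = rho_vals[perm]
        pb[iu] = p_vals[perm]
        rho[b] = rb + rb.T
        p[b] = pb + pb.T
        np.fill_diagonal(rho[b], diag_rho)
        np.fill_diagonal(p[b], diag_p)
    return NullEnsemble(source=matrix, rho=rho, p=p, seed=seed)


def lattice_reference(network: CoactivationNetwork, seed: int = 0) -> CoactivationNetwork:
    """Ring-lattice reference with matched node and edge counts.

    Edges fill the shortest ring distances first (seeded choice among the
    tied pairs at the boundary distance); the observed |rho| values are sorted
    descending onto the shortest ring distances, so strong weights sit on
    short-range links.  The result is a synthetic reference graph, not a
    thresholded correlation network; edge p-values are reported as 0.
    """
    m = len(network.edges)
    if m < 1:
        raise ValueError("lattice reference needs at least one edge")
    n = network.n_nodes
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ring_dist = lambda i, j: min(abs(i - j), n - abs(i - j))
    by_dist: dict[int, list[tuple[int, int]]] = {}
    for i, j in pairs:
        by_dist.setdefault(ring_dist(i, j), []).append((i, j))
    chosen: list[tuple[int, int]] = []
    for d in sorted(by_dist):
        tier = by_dist[d]
        if len(chosen) + len(tier) <= m:
            chosen.extend(tier)
        else:
            need = m - len(chosen)
            pick = rng.choice(len(tier), size=need, replace=False)
            chosen.extend(tier[k] for k in sorted(pick))
        if len(chosen) == m:
            break
    weights = sorted((abs(rho) for *_ij, rho, _p in network.edges), reverse=True)
    edges = [
        (network.regions[i], network.regions[j], w, 0.0)
        for (i, j), w in zip(chosen, weights)
    ]
    return CoactivationNetwork(
        regions=list(network.regions),
        edges=edges,
        alpha=network.alpha,
        n_defined_pairs=len(pairs),
        axis=dict(network.axis),
    )


def _metric_from_abs_weights(w: np.ndarray, metric: str, seed: int = 0) -> float:
    if metric == "efficiency":
        return efficiency_from_abs_weights(w)
    if metric == "clustering":
        return transitivity_from_abs_weights(w)
    if metric == "mean_strength":
        return mean_strength_from_abs_weights(w)
    if metric == "modularity":
        if not w.any():
            return 0.0
        g = nx.from_numpy_array(w)
        communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
        return float(nx.community.modularity(g, communities, weight="weight"))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _thresholded_abs_weights(rho: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    w = np.where(np.nan_to_num(p, nan=1.0) < alpha, np.abs(np.nan_to_num(rho)), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


def normalize_metric(
    network: CoactivationNetwork,
    ensemble: NullEnsemble,
    lattice: CoactivationNetwork | None,
    metric: str,
    seed: int = 0,
) -> NormalizedMetrics:
    """Standardize a global metric against the shuffle-null ensemble.

    ``normalized = raw / mean(metric over thresholded null members)``; the
    matched ring-lattice value is reported alongside.  For efficiency and
    clustering a small-world-style position between random and lattice,
    ``(raw - random) / (lattice - random)``, is also returned.
    """
    raw = _metric_from_abs_weights(network.abs_weight_matrix(), metric, seed=seed)
    null_values = [
        _metric_from_abs_weights(
            _thresholded_abs_weights(ensemble.rho[b], ensemble.p[b], network.alpha),
            metric,
            seed=seed + b + 1,
        )
        for b in range(ensemble.B)
    ]
    random_mean = float(np.mean(null_values))
    lattice_mean = float("nan")
    if lattice is not None:
        lattice_mean = _metric_from_abs_weights(
            lattice.abs_weight_matrix(), metric, seed=seed
        )
    if random_mean == 0:
        raise ZeroDivisionError(
            f"null-ensemble mean of {metric!r} is 0; normalized value undefined "
            f"(network has {len(network.edges)} edges at alpha={network.alpha})"
        )
    ratio = None
    if metric in ("efficiency", "clustering") and np.isfinite(lattice_mean):
        span = lattice_mean - random_mean
        ratio = float((raw - random_mean) / span) if span != 0 else None
    return NormalizedMetrics(
        metric=metric,
        raw=float(raw),
        random_mean=random_mean,
        lattice_mean=lattice_mean,
        normalized=float(raw / random_mean),
        small_world_style_ratio=ratio,
    )


def null_metric_distributions(
    ensemble: NullEnsemble, alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """Per-node degree/strength/betweenness over the thresholded null members.

    Returns (B, n_nodes) arrays aligned with the source region order, the form
    :func:`fosnet.metrics.detect_hubs` expects.
    """
    n = len(ensemble.source.regions)
    out = {name: np.zeros((ensemble.B, n)) for name in ("degree", "strength", "betweenness")}
    for b in range(ensemble.B):
        w = _thresholded_abs_weights(ensemble.rho[b], ensemble.p[b], alpha)
        out["degree"][b] = (w > 0).sum(axis=0)
        out["strength"][b] = w.sum(axis=0)
        g = nx.from_numpy_array(np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0))
        bc = nx.betweenness_centrality(g, weight="weight", normalized=False)
        out["betweenness"][b] = [bc[i] for i in range(n)]
    return out


def bootstrap_compare_metric(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str,
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    two_tailed: bool = True,
) -> tuple[float, float]:
    """Group-label permutation test for a global network metric.

    The observed statistic is ``metric(A) - metric(B)``.  Animals are pooled
    and group labels permuted ``B`` times, both networks rebuilt, and the
    add-one permutation p-value ``(1 + #{|null| >= |obs|}) / (B + 1)``
    returned (one-tailed on the observed sign if ``two_tailed=False``).
    """
    regions = region_columns(table_a)
    if regions != region_columns(table_b):
        raise ValueError("both tables must share the same region columns")
    xa = table_a[regions].to_numpy(dtype=float)
    xb = table_b[regions].to_numpy(dtype=float)
    if len(xa) < 4 or len(xb) < 4:
        raise ValueError("each group needs at least 4 animals")

    def metric_of(values: np.ndarray, seed_: int) -> tuple[float, bool]:
        rho, p = rho_p_from_values(values)
        w = _thresholded_abs_weights(rho, p, alpha)
        return _metric_from_abs_weights(w, metric, seed=seed_), not w.any()

    obs_a, empty_a = metric_of(xa, seed)
    obs_b, empty_b = metric_of(xb, seed)
    observed = obs_a - obs_b
    pooled = np.vstack([xa, xb])
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    n_degenerate = int(empty_a) + int(empty_b)
    for b in range(B):
        perm = rng.permutation(len(pooled))
        va, vb = pooled[perm[: len(xa)]], pooled[perm[len(xa):]]
        ma, ea = metric_of(va, seed + 2 * b + 1)
        mb, eb = metric_of(vb, seed + 2 * b + 2)
        null[b] = ma - mb
        n_degenerate += int(ea) + int(eb)
    if n_degenerate > B:  # more than half of the 2(B+1) networks are edgeless
        raise RuntimeError(
            f"degenerate permutation null: {n_degenerate} of {2 * (B + 1)} "
            "rebuilt networks were edgeless"
        )
    if two_tailed:
        exceed = np.abs(null) >= abs(observed) - 1e-12
    else:
        exceed = null >= observed - 1e-12 if observed >= 0 else null <= observed + 1e-12
    p_value = (1.0 + int(exceed.sum())) / (B + 1.0)
    return float(observed), float(p_value)


def edge_count_tests(networks: dict[str, CoactivationNetwork]):
    """Omnibus and pairwise chi-square tests on edge proportions per group.

    The contingency table is groups x {edge, non-edge} from
    :func:`edge_composition`; pairwise 2x2 tests are Bonferroni-corrected over
    the number of group pairs.  Expected cells below 1 trigger the
    continuity-corrected variant with a warning.
    """
    if len(networks) < 2:
        raise ValueError("at least two groups are required")
    rows, proportions = [], {}
    for group, net in networks.items():
        n_pos, n_neg, n_possible = edge_composition(net)
        if n_possible <= 0:
            raise ValueError(f"group {group!r} has no defined pairs")
        n_edges = n_pos + n_neg
        rows.append([n_edges, n_possible - n_edges])
        proportions[group] = n_edges / n_possible
    table = np.array(rows)

    def chi2(obs: np.ndarray) -> tuple[float, int, float]:
        expected = stats.contingency.expected_freq(obs)
        correct = bool((expected < 1).any()) and obs.shape == (2, 2)
        if (expected < 1).any():
            warnings.warn("expected cell below 1; interpret the test with caution")
        res = stats.chi2_contingency(obs, correction=correct)
        return float(res.statistic), int(res.dof), float(res.pvalue)

    stat, dof, p = chi2(table)
    pairs = list(itertools.combinations(networks, 2))
    records = []
    for ga, gb in pairs:
        idx = [list(networks).index(ga), list(networks).index(gb)]
        s, d, praw = chi2(table[idx])
        records.append(
            (ga, gb, s, d, praw, min(1.0, praw * len(pairs)))
        )
    pairwise = pd.DataFrame(
        records,
        columns=["groupA", "groupB", "statistic", "df", "p_raw", "p_corrected"],
    )
    return {
        "statistic": stat,
        "df": dof,
        "p": p,
        "proportions": proportions,
        "pairwise": pairwise,
    }
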
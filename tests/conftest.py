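from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fosnet.datasets import FactorSpec, generate_activation_table
from fosnet.network import CoactivationNetwork, CorrelationMatrix


def net_from_weights(weights: np.ndarray, alpha: float = 0.05) -> CoactivationNetwork:
    """Wrap a symmetric signed weight matrix as a significance-passed network."""
    n = weights.shape[0]
    regions = [f"r{i}" for i in range(n)]
    edges = [
        (regions[i], regions[j], float(weights[i, j]), alpha / 10.0)
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i, j] != 0
    ]
    return CoactivationNetwork(
        regions=regions, edges=edges, alpha=alpha,
        n_defined_pairs=n * (n - 1) // 2,
    )


def matrix_from_weights(weights: np.ndarray, alpha: float = 0.05) -> CorrelationMatrix:
    """Correlation-matrix view of a weight matrix: nonzero entries significant."""
    n = weights.shape[0]
    rho = weights.astype(float).copy()
    np.fill_diagonal(rho, 1.0)
    p = np.where(weights != 0, alpha / 10.0, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        regions=[f"r{i}" for i in range(n)], rho=rho, p=p, n=10
    )


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.4) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.3, 1.0)
    return w


@pytest.fixture(scope="session")
def two_module_spec() -> FactorSpec:
    regions = {f"A{i}": "modA" for i in range(12)} | {f"B{i}": "modB" for i in range(12)}
    return FactorSpec(module_assignment=regions, loading=0.7, noise_sd=0.4)


@pytest.fixture(scope="session")
def small_activation_table(two_module_spec) -> pd.DataFrame:
    return generate_activation_table(
        two_module_spec, {"g1": 7, "g2": 7}, seed=11
    )
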
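"""Independent brute-force oracles used by the test suite."""

import heapq
from functools import lru_cache
from itertools import product

import numpy as np


def _prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


@lru_cache(maxsize=None)
def all_spanning_trees(n: int) -> np.ndarray:
    """Edge lists of every labelled tree on n nodes, shape (n^(n-2), n-1, 2).

    Cayley's formula via Prufer sequences; exhaustive and independent of
    any MST algorithm.
    """
    if n == 1:
        return np.zeros((1, 0, 2), dtype=np.int64)
    if n == 2:
        return np.array([[[0, 1]]], dtype=np.int64)
    trees = [_prufer_to_edges(seq, n) for seq in product(range(n), repeat=n - 2)]
    return np.array(trees, dtype=np.int64)


def min_spanning_weight_bruteforce(dist: np.ndarray) -> int:
    """Minimum total weight over ALL spanning trees, by full enumeration."""
    n = dist.shape[0]
    trees = all_spanning_trees(n)
    if trees.shape[1] == 0:
        return 0
    weights = dist[trees[:, :, 0], trees[:, :, 1]].sum(axis=1)
    return int(weights.min())


def pearson_chi2_bruteforce(table: np.ndarray) -> float:
    """Sum of (O - E)^2 / E over all cells, no corrections."""
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
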
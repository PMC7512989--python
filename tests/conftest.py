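"""Shared fixtures and independent oracles for the test suite.

The oracles here re-derive quantities by brute force (exhaustive subset
enumeration, exhaustive community matching, direct formula evaluation)
and stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnsnet import AttributedGraph, Partition, icp, toy_fixture


@pytest.fixture(scope="session")
def toy() -> AttributedGraph:
    return toy_fixture()[0]


@pytest.fixture(scope="session")
def toy_truth() -> Partition:
    return toy_fixture()[1]


def random_attributed_graph(
    rng: np.random.Generator,
    n_nodes: int | None = None,
    n_attrs: int = 2,
    max_domain: int = 4,
    edge_p: float = 0.3,
) -> AttributedGraph:
    """Small random attributed graph for property tests."""
    if n_nodes is None:
        n_nodes = int(rng.integers(4, 12))
    nodes = [f"x{i}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_p:
            g.add_edge(nodes[i], nodes[j])
    cols = {}
    for m in range(n_attrs):
        k = int(rng.integers(2, max_domain + 1))
        cols[f"a{m}"] = [f"v{int(rng.integers(k))}" for _ in nodes]
    return AttributedGraph(g, pd.DataFrame(cols, index=nodes))


def random_partition(rng: np.random.Generator, nodes: list[str], max_k: int) -> Partition:
    k = int(rng.integers(1, max_k + 1))
    return Partition({n: f"c{int(rng.integers(k))}" for n in nodes})


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_inter_relative(g: AttributedGraph, m: str, n: str, x: str, y: str) -> float:
    """min over ALL subsets B of F_n of 2 - P(B|x) - P(complement|y)."""
    domain = g.domain(n)
    best = np.inf
    for r in range(len(domain) + 1):
        for B in itertools.combinations(domain, r):
            comp = frozenset(domain) - frozenset(B)
            val = 2.0 - icp(g, n, m, frozenset(B), x) - icp(g, n, m, comp, y)
            best = min(best, val)
    return best


def _contingency(truth: Partition, detected: Partition):
    t_labels = sorted(set(truth.assignment.values()))
    d_labels = sorted(set(detected.assignment.values()))
    table = np.zeros((len(t_labels), len(d_labels)))
    for node in truth.assignment:
        table[t_labels.index(truth[node]), d_labels.index(detected[node])] += 1
    return table


def brute_force_nmi(truth: Partition, detected: Partition) -> float:
    """Direct evaluation of the NMI formula from the contingency table."""
    table = _contingency(truth, detected)
    n = table.sum()
    a, b = table.sum(axis=1), table.sum(axis=0)
    num = 0.0
    for r in range(table.shape[0]):
        for k in range(table.shape[1]):
            if table[r, k] > 0:
                num += -2.0 * (table[r, k] / n) * np.log(
                    (n * table[r, k]) / (a[r] * b[k])
                )
    den = sum((ai / n) * np.log(ai / n) for ai in a if ai > 0) + sum(
        (bj / n) * np.log(bj / n) for bj in b if bj > 0
    )
    if den == 0.0:
        return 1.0
    return num / den


def brute_force_f_measure(truth: Partition, detected: Partition) -> float:
    table = _contingency(truth, detected)
    n = table.sum()
    a, b = table.sum(axis=1), table.sum(axis=0)
    total = 0.0
    for r in range(table.shape[0]):
        best = 0.0
        for k in range(table.shape[1]):
            if table[r, k] == 0:
                continue
            p, rc = table[r, k] / b[k], table[r, k] / a[r]
            best = max(best, 2 * p * rc / (p + rc))
        total += a[r] / n * best
    return total


def brute_force_accuracy(truth: Partition, detected: Partition) -> float:
    """Exhaustive enumeration of one-to-one community matchings."""
    table = _contingency(truth, detected)
    R, K = table.shape
    small, large = (R, K) if R <= K else (K, R)
    best = 0.0
    for perm in itertools.permutations(range(large), small):
        score = sum(
            table[i, perm[i]] if R <= K else table[perm[i], i] for i in range(small)
        )
        best = max(best, score)
    return best / table.sum()
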
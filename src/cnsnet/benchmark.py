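"""Synthetic attributed benchmarks and the 7-author toy network.

The structure generator is a degree-heterogeneous planted-partition
sampler in the LFR style: community sizes are drawn in [minc, maxc] to
sum to N, node degrees follow a truncated power law (exponent 2) with
the mean pinned to ``avgk`` and a hard cap at ``maxk``, and each node's
stubs are split internal/external by a Binomial(degree, mu) draw before
being wired by configuration-model pairing (internal within the
community, external across communities), rejecting self-loops and
duplicates.  The realised mean degree stays within 10% of avgk and the
node-averaged mixing fraction within 0.05 of mu at N >= 100; both are
asserted in the test suite.

Categorical attributes over the planted communities follow three rules:

* rule1 — every node carries its community's identifier (perfectly
  informative);
* rule2 — a uniformly random value from a domain whose size defaults to
  the number of communities (uninformative);
* rule3 — rule1 with a fraction ``nl`` of each community's nodes
  (round(nl·size)) reassigned a random *other* community's identifier.

The default attribute trio is (rule1, rule2, rule3@nl), matching the
synthetic evaluation protocol this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph_model import AttributedGraph, Partition

__all__ = [
    "BenchmarkSpec",
    "toy_fixture",
    "generate_structure",
    "assign_attributes",
    "generate_benchmark",
]


# ---------------------------------------------------------------------------
# Toy fixture: the 7-author co-authoring network
# ---------------------------------------------------------------------------

_TOY_ATTRIBUTES = {
    # node: (topic, country)
    "David": ("ML", "US"),
    "Jia": ("DM", "CN"),
    "Jones": ("DM", "US"),
    "George": ("DM", "AU"),
    "Ying": ("DM", "CN"),
    "Hua": ("ML", "CN"),
    "Pitt": ("DM", "AU"),
}

_TOY_EDGES = [
    ("David", "Jia"),
    ("David", "Jones"),
    ("Jia", "Jones"),
    ("Jones", "George"),
    ("George", "Ying"),
    ("Ying", "Hua"),
    ("Ying", "Pitt"),
    ("Hua", "Pitt"),
]

_TOY_TRUTH = {
    "David": "C1",
    "Jia": "C1",
    "Jones": "C1",
    "George": "C2",
    "Ying": "C2",
    "Hua": "C2",
    "Pitt": "C2",
}


def toy_fixture() -> tuple[AttributedGraph, Partition]:
    """The 7-author co-authoring network with topic/country attributes.

    Two communities of authors, one bridged by George, whose topic ties
    and country co-authoring patterns pull him toward the {Ying, Hua,
    Pitt} side.  Ground truth places George in that community.
    """
    g = nx.Graph()
    g.add_edges_from(_TOY_EDGES)
    attrs = pd.DataFrame.from_dict(
        _TOY_ATTRIBUTES, orient="index", columns=["topic", "country"]
    )
    return AttributedGraph(g, attrs), Partition(_TOY_TRUTH)


# ---------------------------------------------------------------------------
# Benchmark spec and structure generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a synthetic attributed network.

    Defaults are the small-network evaluation setting: 100 nodes, mean
    degree 5 capped at 10, communities of 10–30 nodes, and the
    (rule1, rule2, rule3) attribute trio with noise level 0.3.
    """

    N: int = 100
    avgk: float = 5.0
    maxk: int = 10
    minc: int = 10
    maxc: int = 30
    mu: float = 0.1
    attribute_rules: tuple[str, ...] = ("rule1", "rule2", "rule3")
    nl: float = 0.3
    seed: int = 0
    rule2_domain_size: int | None = None  # default: number of communities

    def __post_init__(self):
        if not (0 < self.minc <= self.maxc <= self.N):
            raise ValueError("require 0 < minc <= maxc <= N")
        if not (1 <= self.avgk <= self.maxk < self.N):
            raise ValueError("require 1 <= avgk <= maxk < N")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 <= self.nl <= 1.0):
            raise ValueError("nl must lie in [0, 1]")
        bad = [r for r in self.attribute_rules if r not in ("rule1", "rule2", "rule3")]
        if bad:
            raise ValueError(f"unknown attribute rule(s) {bad}")


def _community_sizes(spec: BenchmarkSpec, rng: np.random.Generator) -> list[int]:
    sizes: list[int] = []
    while sum(sizes) < spec.N:
        remaining = spec.N - sum(sizes)
        if remaining >= spec.minc:
            sizes.append(int(rng.integers(spec.minc, min(spec.maxc, remaining) + 1)))
        else:
            # spread the remainder over existing communities without
            # exceeding maxc
            headroom = sum(spec.maxc - s for s in sizes)
            if headroom < remaining:
                raise ValueError("community size constraints infeasible for N")
            i = 0
            while remaining > 0:
                if sizes[i % len(sizes)] < spec.maxc:
                    sizes[i % len(sizes)] += 1
                    remaining -= 1
                i += 1
    return sizes


def _sample_degrees(spec: BenchmarkSpec, rng: np.random.Generator) -> np.ndarray:
    """Power-law-ish degrees (exponent 2) with mean pinned to avgk."""
    maxk = spec.maxk
    # find the lower cutoff whose truncated p(k) ∝ k^-2 mean is closest to avgk
    best_kmin, best_err = 1, np.inf
    for kmin in range(1, maxk + 1):
        ks = np.arange(kmin, maxk + 1, dtype=float)
        p = ks**-2.0
        mean = (ks * p).sum() / p.sum()
        if abs(mean - spec.avgk) < best_err:
            best_kmin, best_err = kmin, abs(mean - spec.avgk)
    ks = np.arange(best_kmin, maxk + 1)
    p = ks.astype(float) ** -2.0
    p /= p.sum()
    deg = rng.choice(ks, size=spec.N, p=p)
    # nudge individual degrees until the total hits round(N * avgk)
    target = int(round(spec.N * spec.avgk))
    while deg.sum() != target:
        i = int(rng.integers(spec.N))
        if deg.sum() < target and deg[i] < maxk:
            deg[i] += 1
        elif deg.sum() > target and deg[i] > 1:
            deg[i] -= 1
    return deg.astype(int)


def _pair_stubs(stubs: list[int], forbidden, existing, rng, rounds: int = 20):
    """Configuration-model pairing with rejection of self-loops, duplicate
    edges and `forbidden` pairs; irreparable leftover stubs are dropped."""
    edges: list[tuple[int, int]] = []
    pool = list(stubs)
    for _ in range(rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        leftover: list[int] = []
        for a, b in zip(pool[::2], pool[1::2]):
            key = (min(a, b), max(a, b))
            if a == b or key in existing or forbidden(a, b):
                leftover.extend((a, b))
            else:
                existing.add(key)
                edges.append(key)
        if len(pool) % 2 == 1:
            leftover.append(pool[-1])
        if len(leftover) == len(pool):
            break
        pool = leftover
    return edges


def generate_structure(
    spec: BenchmarkSpec, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, Partition]:
    """Planted-partition structure with LFR-style degree heterogeneity.

    Returns the simple undirected graph (nodes "n0".."n{N-1}") and the
    planted ground-truth partition.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sizes = _community_sizes(spec, rng)
    community = np.repeat(np.arange(len(sizes)), sizes)
    rng.shuffle(community)
    degrees = _sample_degrees(spec, rng)

    # split each node's stubs internal/external: stochastic rounding of
    # degree*mu per node (expectation mu, far less variance than a
    # binomial split), with the global external total pinned to mu
    want = degrees * spec.mu
    external = np.floor(want).astype(int) + (rng.random(spec.N) < want - np.floor(want))
    target_ext = int(round(degrees.sum() * spec.mu))
    while external.sum() != target_ext:
        i = int(rng.integers(spec.N))
        if external.sum() < target_ext and external[i] < degrees[i]:
            external[i] += 1
        elif external.sum() > target_ext and external[i] > 0:
            external[i] -= 1
    internal = degrees - external
    for i in range(spec.N):
        cap = sizes[community[i]] - 1
        if internal[i] > cap:
            excess = internal[i] - cap
            internal[i] = cap
            if spec.mu > 0:
                external[i] += excess

    members: dict[int, list[int]] = {}
    for i, c in enumerate(community):
        members.setdefault(int(c), []).append(i)

    existing: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    for c, nodes_c in members.items():
        # internal stub total must be even
        odd = [i for i in nodes_c if internal[i] > 0]
        if sum(int(internal[i]) for i in nodes_c) % 2 == 1 and odd:
            j = odd[int(rng.integers(len(odd)))]
            internal[j] -= 1
            if spec.mu > 0:
                external[j] += 1
        stubs = [i for i in nodes_c for _ in range(int(internal[i]))]
        edges += _pair_stubs(stubs, lambda a, b: False, existing, rng)

    ext_stubs = [i for i in range(spec.N) for _ in range(int(external[i]))]
    if len(ext_stubs) % 2 == 1:
        ext_stubs.pop(int(rng.integers(len(ext_stubs))))
    edges += _pair_stubs(
        ext_stubs, lambda a, b: community[a] == community[b], existing, rng
    )

    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(spec.N))
    g.add_edges_from((f"n{a}", f"n{b}") for a, b in edges)
    truth = Partition({f"n{i}": f"c{int(community[i])}" for i in range(spec.N)})
    return g, truth


# ---------------------------------------------------------------------------
# Attribute assignment rules
# ---------------------------------------------------------------------------


def assign_attributes(
    partition: Partition,
    rule: str,
    nl: float = 0.0,
    rng: np.random.Generator | None = None,
    domain_size: int | None = None,
) -> dict[str, str]:
    """One attribute column over the nodes of a planted partition.

    rule1 assigns each node its community identifier; rule2 a uniform
    random value from a domain of ``domain_size`` values (default: the
    number of communities); rule3 applies rule1 and then flips
    round(nl·size) nodes per community to a random other community's
    identifier.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0.0 <= nl <= 1.0:
        raise ValueError("nl must lie in [0, 1]")
    labels = partition.labels
    if rule == "rule1":
        return {n: partition[n] for n in partition.nodes}
    if rule == "rule2":
        size = domain_size if domain_size is not None else len(labels)
        values = [f"v{k}" for k in range(size)]
        return {n: values[int(rng.integers(size))] for n in partition.nodes}
    if rule == "rule3":
        column = {n: partition[n] for n in partition.nodes}
        if len(labels) < 2:
            if nl > 0:
                raise ValueError("rule3 noise needs at least two communities")
            return column
        for label in labels:
            nodes_c = sorted(partition.members(label))
            n_noise = int(round(nl * len(nodes_c)))
            if n_noise == 0:
                continue
            chosen = rng.choice(len(nodes_c), size=n_noise, replace=False)
            others = [l for l in labels if l != label]
            for idx in chosen:
                column[nodes_c[int(idx)]] = others[int(rng.integers(len(others)))]
        return column
    raise ValueError(f"unknown attribute rule {rule!r}")


def generate_benchmark(spec: BenchmarkSpec) -> tuple[AttributedGraph, Partition]:
    """Structure plus one attribute column per configured rule."""
    rng = np.random.default_rng(spec.seed)
    graph, truth = generate_structure(spec, rng)
    columns = {}
    for k, rule in enumerate(spec.attribute_rules, start=1):
        columns[f"attr{k}"] = assign_attributes(
            truth, rule, nl=spec.nl, rng=rng, domain_size=spec.rule2_domain_size
        )
    attrs = pd.DataFrame(columns).loc[[f"n{i}" for i in range(spec.N)]]
    return AttributedGraph(graph, attrs), truth
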
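"""Community detection on similarity-weighted graphs.

The pipeline: a node-pair similarity S is restricted to the adjacency to
give edge weights, W(i,j) = S(i,j) if the edge exists, else 0.  Three
clustering algorithms then run on the weighted graph:

* **SLPA** — speaker–listener label propagation.  Every node starts with
  a unique label and a memory; each iteration every listener receives one
  label from each neighbour (the speaker's modal memory label, ties
  uniform at random) and stores the label with the largest total incoming
  edge weight.  After T iterations each node adopts its modal memory
  label, yielding a disjoint partition.
* **BGLL** — greedy two-phase weighted-modularity (Louvain) optimisation.
  Modularity is the ordered-pair form
      WQ = (1/m_w) sum_{i,j} [W(i,j) − d_i^w d_j^w / m_w] 1(c_i = c_j)
  with m_w the ordered-pair weight total; WQ never decreases across
  accepted moves and aggregation phases.
* **K-medoids** — clustering straight from the similarity matrix, with
  the similarity of disconnected node pairs taken as 0; the medoid of a
  cluster is the member with maximal average similarity to the cluster.

SLPA and K-medoids are stochastic; ``run_repeated`` reruns them with
per-restart seeds spawned from a master seed and averages the scores.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .graph_model import AttributedGraph, Partition, WeightedGraph
from .similarity import SimilarityMatrix, similarity_matrix

logger = logging.getLogger("cnsnet")

__all__ = [
    "DetectionConfig",
    "build_weighted_graph",
    "slpa",
    "weighted_modularity",
    "bgll",
    "kmedoids",
    "run_repeated",
]

_TOL = 1e-12


@dataclass
class DetectionConfig:
    """Parameters of a detection run.

    restarts follows the evaluation protocol of averaging stochastic
    algorithms over repeated runs (100 in the reference experiments).
    """

    algorithm: str = "bgll"
    slpa_iterations: int = 20
    kmedoids_K: int | None = None
    restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("slpa", "bgll", "kmedoids"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def build_weighted_graph(g: AttributedGraph, s: SimilarityMatrix) -> WeightedGraph:
    """Edge weights W(i,j) = S(i,j) on the adjacency, 0 elsewhere.

    Edges whose similarity is exactly 0 are kept with weight 0.
    """
    idx = {u: a for a, u in enumerate(s.nodes)}
    weights = {(u, v): float(s.matrix[idx[u], idx[v]]) for u, v in g.edges()}
    return WeightedGraph(g.nodes, weights)


# ---------------------------------------------------------------------------
# SLPA
# ---------------------------------------------------------------------------


def _modal_label(memory: list[str], rng: np.random.Generator | None) -> str:
    counts = Counter(memory)
    top = max(counts.values())
    modes = sorted(l for l, c in counts.items() if c == top)
    if len(modes) == 1 or rng is None:
        return modes[0]
    return modes[int(rng.integers(len(modes)))]


def slpa(w: WeightedGraph, iterations: int = 20, seed: int = 0) -> Partition:
    """Speaker–listener label propagation on a weighted graph.

    Each node's memory starts with its own unique label; after
    ``iterations`` rounds every node adopts its modal memory label
    (final ties broken deterministically by label order).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(w.nodes)
    memory: dict[str, list[str]] = {u: [u] for u in nodes}
    adj = {u: [(v, w.weight(u, v)) for v in w.graph.neighbors(u)] for u in nodes}

    for _ in range(iterations):
        order = list(nodes)
        rng.shuffle(order)
        for listener in order:
            neigh = adj[listener]
            if not neigh:
                continue
            received: dict[str, float] = {}
            for speaker, wt in neigh:
                label = _modal_label(memory[speaker], rng)
                received[label] = received.get(label, 0.0) + wt
            top = max(received.values())
            winners = sorted(l for l, wt in received.items() if wt >= top - _TOL)
            choice = winners[int(rng.integers(len(winners)))] if len(winners) > 1 else winners[0]
            memory[listener].append(choice)

    return Partition({u: _modal_label(memory[u], None) for u in nodes})


# ---------------------------------------------------------------------------
# Weighted modularity and BGLL (Louvain)
# ---------------------------------------------------------------------------


def weighted_modularity(w: WeightedGraph, p: Partition) -> float:
    """Ordered-pair weighted modularity WQ of a partition.

    WQ = (1/m_w) sum over ordered pairs i,j of
    [W(i,j) − d_i^w d_j^w / m_w] for i, j in the same community, with
    m_w the ordered-pair weight total (twice the edge-weight sum).
    """
    mw = w.total_weight
    if mw <= 0:
        raise ValueError("total weight is zero: modularity undefined")
    label = p.assignment
    intra = 0.0  # ordered-pair internal weight
    for u, v, wt in w.edges():
        if label[u] == label[v]:
            intra += 2.0 * wt
    deg_sum: dict[str, float] = {}
    for u in w.nodes:
        deg_sum[label[u]] = deg_sum.get(label[u], 0.0) + w.weighted_degree(u)
    return intra / mw - sum(d * d for d in deg_sum.values()) / (mw * mw)


def _one_level(adj, k, com, K, m2, rng):
    """One Louvain local-move phase; mutates com/K, returns True if any move."""
    nodes = list(adj)
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for u in order:
            cu = com[u]
            links: dict[int, float] = {}
            for v, wt in adj[u].items():
                if v != u:
                    links[com[v]] = links.get(com[v], 0.0) + wt
            K[cu] -= k[u]
            base = links.get(cu, 0.0) - K[cu] * k[u] / m2
            best_c, best_gain = cu, 0.0
            for c, l in links.items():
                if c == cu:
                    continue
                gain = (l - K[c] * k[u] / m2) - base
                if gain > best_gain + _TOL:
                    best_c, best_gain = c, gain
            com[u] = best_c
            K[best_c] = K.get(best_c, 0.0) + k[u]
            if best_c != cu:
                improved = True
                moved_any = True
    return moved_any


def bgll(
    w: WeightedGraph,
    seed: int = 0,
    return_history: bool = False,
    on_move=None,
):
    """Two-phase greedy weighted-modularity optimisation (Louvain).

    Phase 1 sweeps nodes in a seeded random order, moving each to the
    neighbouring community with maximal strictly positive WQ gain; phase 2
    aggregates communities into super-nodes (internal weight as
    self-loops) and repeats until WQ stops increasing.

    Parameters
    ----------
    on_move:
        Optional callback invoked after every accepted move with the
        flattened node->community partition (used to audit the WQ
        monotonicity contract).
    return_history:
        If True also return the list of WQ values after each phase pair.
    """
    m2 = w.total_weight
    if m2 <= 0:
        raise ValueError("total weight is zero: modularity undefined")
    rng = np.random.default_rng(seed)

    # working multigraph as dict-of-dicts; self-loops hold ordered-pair weight
    adj: dict = {u: {} for u in w.nodes}
    for u, v, wt in w.edges():
        adj[u][v] = adj[u].get(v, 0.0) + wt
        adj[v][u] = adj[v].get(u, 0.0) + wt
    mapping = {u: u for u in w.nodes}  # original node -> current super-node
    history: list[float] = []

    while True:
        nodes = list(adj)
        k = {
            u: sum(wt for v, wt in adj[u].items() if v != u) + adj[u].get(u, 0.0)
            for u in nodes
        }
        com = {u: i for i, u in enumerate(nodes)}
        K = {com[u]: k[u] for u in nodes}

        if on_move is None:
            moved = _one_level(adj, k, com, K, m2, rng)
        else:
            moved = _one_level_audited(adj, k, com, K, m2, rng, mapping, w, on_move)

        flat = {orig: com[sup] for orig, sup in mapping.items()}
        history.append(weighted_modularity(w, Partition({u: str(c) for u, c in flat.items()})))
        if not moved:
            break
        # aggregate
        new_adj: dict[int, dict[int, float]] = {}
        for u in nodes:
            cu = com[u]
            row = new_adj.setdefault(cu, {})
            for v, wt in adj[u].items():
                row[com[v]] = row.get(com[v], 0.0) + wt
        adj = new_adj
        mapping = {orig: com[sup] for orig, sup in mapping.items()}

    partition = Partition({u: str(c) for u, c in flat.items()})
    if return_history:
        return partition, history
    return partition


def _one_level_audited(adj, k, com, K, m2, rng, mapping, w, on_move):
    """Local-move phase that reports the flattened partition after each
    accepted move (slow; intended for contract auditing on small graphs)."""
    nodes = list(adj)
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for u in order:
            cu = com[u]
            links: dict[int, float] = {}
            for v, wt in adj[u].items():
                if v != u:
                    links[com[v]] = links.get(com[v], 0.0) + wt
            K[cu] -= k[u]
            base = links.get(cu, 0.0) - K[cu] * k[u] / m2
            best_c, best_gain = cu, 0.0
            for c, l in links.items():
                if c == cu:
                    continue
                gain = (l - K[c] * k[u] / m2) - base
                if gain > best_gain + _TOL:
                    best_c, best_gain = c, gain
            com[u] = best_c
            K[best_c] = K.get(best_c, 0.0) + k[u]
            if best_c != cu:
                improved = True
                moved_any = True
                on_move({orig: com[sup] for orig, sup in mapping.items()})
    return moved_any


# ---------------------------------------------------------------------------
# K-medoids from a similarity matrix
# ---------------------------------------------------------------------------


def kmedoids(
    s: SimilarityMatrix, K: int, seed: int = 0, max_iter: int = 100
) -> Partition:
    """Similarity-based K-medoids clustering.

    K distinct initial medoids are drawn uniformly at random; each node
    joins the medoid of maximal similarity (ties to the lowest medoid
    index; a node with zero similarity to every medoid is assigned a
    random medoid); each medoid is then replaced by the cluster member
    whose average similarity to the cluster is maximal, until the medoid
    set stabilises.
    """
    nodes = list(s.nodes)
    N = len(nodes)
    if K > N:
        raise ValueError(f"K={K} exceeds the number of nodes {N}")
    rng = np.random.default_rng(seed)
    S = s.matrix
    medoids = sorted(rng.choice(N, size=K, replace=False).tolist())

    assign = np.zeros(N, dtype=int)
    for _ in range(max_iter):
        sims = S[:, medoids]  # N x K
        best = sims.max(axis=1)
        assign = sims.argmax(axis=1)  # lowest medoid index on ties
        orphan = best <= 0.0
        # a medoid always belongs to its own cluster, whatever its
        # (possibly zero) self-similarity says
        for c, mi in enumerate(medoids):
            assign[mi] = c
            orphan[mi] = False
        if orphan.any():
            logger.debug("%d node(s) with zero similarity to all medoids", orphan.sum())
            assign[orphan] = rng.integers(K, size=int(orphan.sum()))
        new_medoids = []
        for c in range(K):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                logger.debug("cluster %d collapsed empty", c)
                new_medoids.append(medoids[c])
                continue
            avg = S[np.ix_(members, members)].mean(axis=1)
            new_medoids.append(int(members[int(avg.argmax())]))
        new_medoids = sorted(set(new_medoids))
        if len(new_medoids) < K:  # collapsed medoids: keep K by refilling
            pool = [i for i in range(N) if i not in new_medoids]
            extra = rng.choice(len(pool), size=K - len(new_medoids), replace=False)
            new_medoids = sorted(new_medoids + [pool[int(e)] for e in extra])
        if new_medoids == medoids:
            break
        medoids = new_medoids

    return Partition({nodes[i]: str(int(assign[i])) for i in range(N)})


# ---------------------------------------------------------------------------
# Repeated stochastic runs
# ---------------------------------------------------------------------------


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(x) for x in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def detect(
    g: AttributedGraph,
    measure: str,
    config: DetectionConfig,
    alpha_scheme: str = "others-uniform",
    seed: int | None = None,
) -> tuple[Partition, WeightedGraph]:
    """One detection run: similarity -> edge weights -> clustering."""
    run_seed = config.seed if seed is None else seed
    s = similarity_matrix(g, measure, alpha_scheme=alpha_scheme)
    w = build_weighted_graph(g, s)
    if config.algorithm == "slpa":
        p = slpa(w, iterations=config.slpa_iterations, seed=run_seed)
    elif config.algorithm == "bgll":
        p = bgll(w, seed=run_seed)
    else:
        K = config.kmedoids_K
        if K is None:
            raise ValueError("kmedoids_K must be set for the kmedoids algorithm")
        p = kmedoids(s, K, seed=run_seed)
    return p, w


def run_repeated(
    g: AttributedGraph,
    measure: str,
    config: DetectionConfig,
    truth: Partition,
    alpha_scheme: str = "others-uniform",
) -> dict:
    """Run the configured algorithm ``restarts`` times and average scores.

    Per-restart seeds are spawned deterministically from the master seed.
    Returns mean and sd of NMI, F-Measure and Accuracy, plus the mean WQ
    of the detected partitions.
    """
    from .evaluation import evaluate

    seeds = _spawn_seeds(config.seed, config.restarts)
    scores = {"nmi": [], "f_measure": [], "accuracy": [], "wq": []}
    for run_seed in seeds:
        p, w = detect(g, measure, config, alpha_scheme, seed=run_seed)
        rep = evaluate(truth, p)
        scores["nmi"].append(rep.nmi)
        scores["f_measure"].append(rep.f_measure)
        scores["accuracy"].append(rep.accuracy)
        try:
            scores["wq"].append(weighted_modularity(w, p))
        except ValueError:
            scores["wq"].append(float("nan"))
    out = {"measure": measure, "algorithm": config.algorithm, "restarts": config.restarts}
    for key, vals in scores.items():
        arr = np.asarray(vals, dtype=float)
        out[f"{key}_mean"] = float(np.nanmean(arr))
        out[f"{key}_sd"] = float(np.nanstd(arr, ddof=0))
    return out
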
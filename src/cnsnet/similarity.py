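"""Coupled node similarity (CNS) and baseline node similarities.

CNS scores a pair of nodes in a categorically attributed network by
combining, per attribute m, three ingredients evaluated at the nodes'
value pair (x, y):

* intra-attribute coupled similarity
      delta_intra(x,y) = |g(x)||g(y)| / (|g(x)| + |g(y)| + |g(x)||g(y)|),
  a frequency-based similarity between the two values (g(x) is the set of
  nodes carrying value x);
* inter-attribute coupled similarity delta_inter(x,y): how similarly x
  and y co-occur with the values of every *other* attribute, built from
  information conditional probabilities (ICP)
      P(B|x) = |g_n*(B) ∩ g_m(x)| / |g_m(x)|
  through the set-minimisation
      delta_{m|n}(x,y) = min_{B ⊆ F_n} [2 − P(B|x) − P(B̄|y)],
  which collapses to the closed form
      sum_w min{P({w}|x), P({w}|y)}
  (choose B = {w : P(w|x) ≥ P(w|y)}; verified against exhaustive subset
  enumeration in the test suite);
* attribute-to-structure similarity delta_struct(x,y): the fraction of
  realised edges among all ordered node pairs (v1, v2) with v1 in g(x),
  v2 in g(y) — a homophily measure of how strongly the value pair aligns
  with the wiring.  For x = y the ordered-pair sum counts each internal
  edge twice against a denominator of |g(x)|².

The default combination (variant ``cns1``) is
    CNS(i,j) = sum_m delta_intra · delta_inter · delta_struct
evaluated at (F_m(i), F_m(j)); variants cns2..cns4 are the alternative
additive/multiplicative mixes.  CAS is the structure-free product
sum_m delta_intra · delta_inter.

Two weighting schemes for the other-attribute average are supported:
``others-uniform`` (weights 1/(M−1) over the M−1 other attributes, the
default, which makes delta_inter a true average in [0, 1]) and
``all-uniform`` (weights 1/M).  With a single attribute delta_inter is
defined as 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_model import AttributedGraph

logger = logging.getLogger("cnsnet")

__all__ = [
    "ALPHA_SCHEMES",
    "MEASURES",
    "CNS_VARIANTS",
    "ValuePairTable",
    "SimilarityMatrix",
    "intra_attribute_similarity",
    "icp",
    "inter_relative_similarity",
    "inter_attribute_similarity",
    "coupled_attribute_value_similarity",
    "attribute_structure_similarity",
    "cas",
    "cns",
    "baseline_similarity",
    "build_value_pair_table",
    "similarity_matrix",
    "write_similarity_tsv",
]

ALPHA_SCHEMES = ("others-uniform", "all-uniform")
CNS_VARIANTS = ("cns1", "cns2", "cns3", "cns4")
MEASURES = ("adjacency", "cosine", "jaccard", "smc", "cas") + CNS_VARIANTS

#: measures whose node-pair values are only needed on the adjacency support
EDGE_SUPPORT_MEASURES = ("adjacency",) + CNS_VARIANTS


# ---------------------------------------------------------------------------
# Value-pair primitives
# ---------------------------------------------------------------------------


def _group_sizes(g: AttributedGraph, m: str) -> dict[str, int]:
    return {v: len(s) for v, s in g.value_groups(m).items()}


def _check_value(g: AttributedGraph, m: str, x: str) -> None:
    if x not in g.value_groups(m):
        raise KeyError(f"value {x!r} not in domain of attribute {m!r}")


def intra_attribute_similarity(g: AttributedGraph, m: str, x: str, y: str) -> float:
    """Frequency-based similarity between two values of one attribute.

    Lies in [1/3, 1): 1/3 when both values are singletons, approaching 1
    for two very frequent values.  Defined (by the same formula) for x=y.
    """
    _check_value(g, m, x)
    _check_value(g, m, y)
    sizes = _group_sizes(g, m)
    cx, cy = sizes[x], sizes[y]
    return (cx * cy) / (cx + cy + cx * cy)


def icp(g: AttributedGraph, n: str, m: str, B: frozenset[str] | set[str], x: str) -> float:
    """Information conditional probability P_{n|m}(B | x).

    The fraction of nodes carrying value x on attribute m whose value on
    attribute n lies in the subset B.  Monotone in B; P(F_n|x)=1, P(∅|x)=0.
    """
    if n == m:
        raise ValueError("conditioning attribute must differ from the value's attribute")
    _check_value(g, m, x)
    groups_n = g.value_groups(n)
    unknown = set(B) - set(groups_n)
    if unknown:
        raise KeyError(f"values {sorted(unknown)} not in domain of attribute {n!r}")
    gx = g.value_groups(m)[x]
    hits = sum(1 for node in gx if g.value(node, n) in B)
    return hits / len(gx)


def inter_relative_similarity(g: AttributedGraph, m: str, n: str, x: str, y: str) -> float:
    """delta_{m|n}(x,y): co-occurrence similarity of x,y via attribute n.

    Equals min over all subsets B of F_n of 2 − P(B|x) − P(B̄|y), computed
    by the O(|F_n|) closed form sum_w min{P({w}|x), P({w}|y)}.  Lies in
    [0, 1] and equals 1 when x = y.
    """
    if n == m:
        raise ValueError("attributes m and n must differ")
    _check_value(g, m, x)
    _check_value(g, m, y)
    gx = g.value_groups(m)[x]
    gy = g.value_groups(m)[y]
    total = 0.0
    for w, gw in g.value_groups(n).items():
        px = len(gw & gx) / len(gx)
        py = len(gw & gy) / len(gy)
        total += min(px, py)
    return total


def inter_attribute_similarity(
    g: AttributedGraph, m: str, x: str, y: str, alpha_scheme: str = "others-uniform"
) -> float:
    """delta_inter(x,y): weighted average of delta_{m|n} over the other attributes."""
    if alpha_scheme not in ALPHA_SCHEMES:
        raise ValueError(f"unknown alpha scheme {alpha_scheme!r}")
    others = [n for n in g.attribute_names if n != m]
    if not others:
        logger.info("single attribute %r: inter-attribute similarity defined as 1", m)
        return 1.0
    alpha = 1.0 / len(others) if alpha_scheme == "others-uniform" else 1.0 / g.n_attributes
    return sum(alpha * inter_relative_similarity(g, m, n, x, y) for n in others)


def coupled_attribute_value_similarity(
    g: AttributedGraph, m: str, x: str, y: str, alpha_scheme: str = "others-uniform"
) -> float:
    """delta_attr = delta_intra × delta_inter for one value pair."""
    return intra_attribute_similarity(g, m, x, y) * inter_attribute_similarity(
        g, m, x, y, alpha_scheme
    )


def attribute_structure_similarity(g: AttributedGraph, m: str, x: str, y: str) -> float:
    """delta_struct(x,y): realised edges over possible ordered pairs.

    Sum of A(v1,v2) over ordered pairs v1 in g(x), v2 in g(y), divided by
    |g(x)|·|g(y)|.  For x = y each internal edge contributes twice and the
    denominator is |g(x)|².
    """
    _check_value(g, m, x)
    _check_value(g, m, y)
    gx = g.value_groups(m)[x]
    gy = g.value_groups(m)[y]
    count = sum(1 for v1 in gx for v2 in gy if g.has_edge(v1, v2))
    return count / (len(gx) * len(gy))


# ---------------------------------------------------------------------------
# Node-pair similarities
# ---------------------------------------------------------------------------


def cas(g: AttributedGraph, i: str, j: str, alpha_scheme: str = "others-uniform") -> float:
    """Coupled attribute similarity: sum over attributes of delta_intra × delta_inter."""
    return sum(
        coupled_attribute_value_similarity(
            g, m, g.value(i, m), g.value(j, m), alpha_scheme
        )
        for m in g.attribute_names
    )


def _combine(variant: str, ia: float, ie: float, st: float) -> float:
    if variant == "cns1":
        return ia * ie * st
    if variant == "cns2":
        return (ia + ie) * st
    if variant == "cns3":
        return ia * ie + st
    if variant == "cns4":
        return ia + ie + st
    raise ValueError(f"unknown CNS variant {variant!r}")


def cns(
    g: AttributedGraph,
    i: str,
    j: str,
    variant: str = "cns1",
    alpha_scheme: str = "others-uniform",
) -> float:
    """Coupled node similarity between nodes i and j.

    ``cns1`` (the default) is sum_m delta_intra·delta_inter·delta_struct;
    cns2..cns4 are the alternative combinations of the same three factors.
    """
    if variant not in CNS_VARIANTS:
        raise ValueError(f"unknown CNS variant {variant!r}")
    total = 0.0
    for m in g.attribute_names:
        x, y = g.value(i, m), g.value(j, m)
        ia = intra_attribute_similarity(g, m, x, y)
        ie = inter_attribute_similarity(g, m, x, y, alpha_scheme)
        st = attribute_structure_similarity(g, m, x, y)
        total += _combine(variant, ia, ie, st)
    return total


def baseline_similarity(g: AttributedGraph, i: str, j: str, kind: str) -> float:
    """Structure / attribute baseline similarities.

    adjacency: A(i,j); cosine: |Γi∩Γj|/√(|Γi||Γj|); jaccard:
    |Γi∩Γj|/|Γi∪Γj|; smc: fraction of matching attribute values.  Cosine
    and jaccard of an isolated node are 0 by convention.
    """
    if kind == "adjacency":
        return 1.0 if g.has_edge(i, j) else 0.0
    if kind == "smc":
        matches = sum(1 for m in g.attribute_names if g.value(i, m) == g.value(j, m))
        return matches / g.n_attributes
    gi, gj = g.neighbors(i), g.neighbors(j)
    if kind == "cosine":
        if not gi or not gj:
            return 0.0
        return len(gi & gj) / np.sqrt(len(gi) * len(gj))
    if kind == "jaccard":
        union = gi | gj
        if not union:
            return 0.0
        return len(gi & gj) / len(union)
    raise ValueError(f"unknown baseline similarity {kind!r}")


# ---------------------------------------------------------------------------
# Precomputed per-attribute value-pair tables (phase 1 of the learning
# algorithm) and the node-pair driver (phase 2)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValuePairTable:
    """All four delta quantities for every value pair of one attribute.

    Arrays are square over the sorted value domain; entry [a, b] is the
    quantity for the value pair (values[a], values[b]).  All four arrays
    are symmetric and delta_attr = delta_intra × delta_inter.
    """

    attribute: str
    values: tuple[str, ...]
    delta_intra: np.ndarray
    delta_inter: np.ndarray
    delta_attr: np.ndarray
    delta_struct: np.ndarray

    def index(self, value: str) -> int:
        return self.values.index(value)


def build_value_pair_table(
    g: AttributedGraph, m: str, alpha_scheme: str = "others-uniform"
) -> ValuePairTable:
    """Vectorised construction of the value-pair table for one attribute."""
    if alpha_scheme not in ALPHA_SCHEMES:
        raise ValueError(f"unknown alpha scheme {alpha_scheme!r}")
    values = tuple(g.domain(m))
    vidx = {v: a for a, v in enumerate(values)}
    R = len(values)
    counts = np.array([len(g.value_groups(m)[v]) for v in values], dtype=float)

    cx = counts[:, None]
    cy = counts[None, :]
    delta_intra = (cx * cy) / (cx + cy + cx * cy)

    others = [n for n in g.attribute_names if n != m]
    if not others:
        delta_inter = np.ones((R, R))
    else:
        alpha = 1.0 / len(others) if alpha_scheme == "others-uniform" else 1.0 / g.n_attributes
        delta_inter = np.zeros((R, R))
        col_m = g.attributes[m].to_numpy()
        for n in others:
            wvals = g.domain(n)
            widx = {w: b for b, w in enumerate(wvals)}
            # joint counts: rows = values of m, cols = values of n
            joint = np.zeros((R, len(wvals)))
            col_n = g.attributes[n].to_numpy()
            for vm, vn in zip(col_m, col_n):
                joint[vidx[vm], widx[vn]] += 1
            cond = joint / counts[:, None]  # P({w} | x), rows sum to 1
            # delta_{m|n}(x,y) = sum_w min(P(w|x), P(w|y))
            delta_inter += alpha * np.minimum(cond[:, None, :], cond[None, :, :]).sum(axis=2)

    edge_counts = np.zeros((R, R))
    col = g.attributes[m]
    for u, v in g.edges():
        a, b = vidx[col.at[u]], vidx[col.at[v]]
        edge_counts[a, b] += 1
        edge_counts[b, a] += 1
    delta_struct = edge_counts / (cx * cy)

    return ValuePairTable(
        attribute=m,
        values=values,
        delta_intra=delta_intra,
        delta_inter=delta_inter,
        delta_attr=delta_intra * delta_inter,
        delta_struct=delta_struct,
    )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Dense symmetric node-pair similarity matrix with a measure tag."""

    nodes: tuple[str, ...]
    matrix: np.ndarray
    measure: str
    alpha_scheme: str = "others-uniform"

    def value(self, i: str, j: str) -> float:
        idx = {u: a for a, u in enumerate(self.nodes)}
        return float(self.matrix[idx[i], idx[j]])


def similarity_matrix(
    g: AttributedGraph,
    measure: str,
    alpha_scheme: str = "others-uniform",
    full: bool = False,
) -> SimilarityMatrix:
    """Node-pair similarity matrix for any supported measure.

    Runs in two phases: the per-attribute value-pair tables are built
    once, then node-pair entries are filled from them.  For measures used
    only as edge weights (adjacency, cns1..cns4) just the adjacent pairs
    are materialised unless ``full=True``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    N = g.n_nodes
    S = np.zeros((N, N))
    idx = g.node_index

    if measure in ("cosine", "jaccard", "smc"):
        for i, j in itertools.combinations(g.nodes, 2):
            s = baseline_similarity(g, i, j, measure)
            S[idx[i], idx[j]] = S[idx[j], idx[i]] = s
        if measure == "smc":
            for i in g.nodes:
                S[idx[i], idx[i]] = 1.0
        return SimilarityMatrix(tuple(g.nodes), S, measure, alpha_scheme)

    if measure == "adjacency":
        for u, v in g.edges():
            S[idx[u], idx[v]] = S[idx[v], idx[u]] = 1.0
        return SimilarityMatrix(tuple(g.nodes), S, measure, alpha_scheme)

    # cas / cns*: phase 1 — value-pair tables per attribute
    tables = {m: build_value_pair_table(g, m, alpha_scheme) for m in g.attribute_names}

    def node_pair(i: str, j: str) -> float:
        total = 0.0
        for m, t in tables.items():
            a, b = t.index(g.value(i, m)), t.index(g.value(j, m))
            if measure == "cas":
                total += t.delta_attr[a, b]
            else:
                total += _combine(
                    measure, t.delta_intra[a, b], t.delta_inter[a, b], t.delta_struct[a, b]
                )
        return total

    # phase 2 — node pairs (adjacent only for edge-weight measures)
    if measure == "cas" or full:
        pairs = itertools.combinations(g.nodes, 2)
    else:
        pairs = g.edges()
    for i, j in pairs:
        s = node_pair(i, j)
        S[idx[i], idx[j]] = S[idx[j], idx[i]] = s
    return SimilarityMatrix(tuple(g.nodes), S, measure, alpha_scheme)


def write_similarity_tsv(s: SimilarityMatrix, path: str | Path) -> None:
    """Write nonzero entries as ``i<TAB>j<TAB>s`` (upper triangle), with a
    sidecar ``<path>.meta.json`` recording the measure and scheme."""
    import json

    with open(path, "w") as fh:
        fh.write("i\tj\ts\n")
        for a, i in enumerate(s.nodes):
            for b in range(a + 1, len(s.nodes)):
                if s.matrix[a, b] != 0.0:
                    fh.write(f"{i}\t{s.nodes[b]}\t{s.matrix[a, b]:.10g}\n")
    meta = {"measure": s.measure, "alpha_scheme": s.alpha_scheme, "n_nodes": len(s.nodes)}
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
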
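"""Weighted gene networks: z-score standardization of heterogeneous edge
weights, integration by per-edge averaging, and seeded subgraph extraction.

Co-expression, physical, regulatory, and association evidence arrive on
incomparable weight scales. Continuous networks are standardized to
zero-mean, unit-sd edge weights; binary evidence (presence/absence edge
lists) is placed at a fixed confidence constant on the same z scale.
Integration averages each pair's weight across the networks that actually
score it, yielding one functional network. A query expands a seed gene set
by the k genes with the greatest total connection weight to the growing set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "QuerySpec",
    "Subgraph",
    "standardize_edge_weights",
    "integrate",
    "extract_subgraph",
    "read_edge_list",
    "write_edge_list",
    "write_subgraph",
]

NET_TYPES = ("coexpression", "physical", "regulatory", "functional")


def edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


@dataclass
class WeightedNetwork:
    """Undirected weighted network over a gene universe.

    ``edges`` maps lexicographically ordered pairs to finite weights.
    ``complete`` marks networks scoring every universe pair (co-expression).
    """

    universe: frozenset[str]
    edges: dict[tuple[str, str], float]
    net_type: str = "functional"
    dataset_id: str = ""
    complete: bool = False

    def __post_init__(self) -> None:
        if self.net_type not in NET_TYPES:
            raise ValueError(f"unknown net_type {self.net_type!r}")
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge {u}")
            if u > v:
                raise ValueError(f"edge key not ordered: ({u}, {v})")
            if u not in self.universe or v not in self.universe:
                raise ValueError(f"edge endpoint outside universe: ({u}, {v})")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on ({u}, {v})")

    def weight(self, u: str, v: str, default: float = 0.0) -> float:
        return self.edges.get(edge_key(u, v), default)

    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class QuerySpec:
    """Seed genes plus neighborhood size k for subgraph extraction."""

    query_genes: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if not self.query_genes:
            raise ValueError("query gene set is empty")
        if len(set(self.query_genes)) != len(self.query_genes):
            raise ValueError("query genes must be unique")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class Subgraph:
    nodes: frozenset[str]
    seed_nodes: frozenset[str]
    added_nodes: list[str]
    edges: dict[tuple[str, str], float]
    add_scores: dict[str, float] = field(default_factory=dict)


def standardize_edge_weights(
    net: WeightedNetwork, binary_confidence: float = 2.0
) -> WeightedNetwork:
    """Put edge weights on a common z-score-like confidence scale.

    Networks with at least two distinct weights are z-standardized across
    their own edges. Binary networks (all present edges share one weight,
    typical of physical/regulatory edge lists) get ``binary_confidence`` on
    every edge — by default 2.0, the conventional high-confidence threshold
    on the z scale; absent pairs stay unscored.
    """
    if not net.edges:
        raise ValueError("cannot standardize an empty network")
    weights = np.array(list(net.edges.values()))
    if np.unique(weights).size < 2:
        new = {k: float(binary_confidence) for k in net.edges}
        return replace(net, edges=new)
    mu, sd = weights.mean(), weights.std(ddof=1)
    new = {k: float((w - mu) / sd) for k, w in net.edges.items()}
    return replace(net, edges=new)


def integrate(
    nets: Sequence[WeightedNetwork], mode: str = "scoreable"
) -> WeightedNetwork:
    """Average standardized weights per edge across input networks.

    A pair is scoreable in a network if that network stores it explicitly
    (complete networks store every universe pair). With ``mode="scoreable"``
    (default) the mean runs over scoreable networks only, so sparse physical
    evidence is not diluted by zeros; ``mode="all"`` divides by the total
    network count, treating unscored pairs as 0.
    """
    if not nets:
        raise ValueError("integrate requires at least one network")
    if mode not in ("scoreable", "all"):
        raise ValueError(f"unknown average mode {mode!r}")
    universe = frozenset().union(*(n.universe for n in nets))
    values: dict[tuple[str, str], list[float]] = {}
    for net in nets:
        for key, w in net.edges.items():
            values.setdefault(key, []).append(w)
    denom = len(nets)
    # math.fsum is exact, so the mean is invariant to network ordering
    edges = {
        key: math.fsum(vals) / (len(vals) if mode == "scoreable" else denom)
        for key, vals in values.items()
    }
    return WeightedNetwork(
        universe=universe,
        edges=edges,
        net_type="functional",
        dataset_id="integrated",
        complete=False,
    )


def extract_subgraph(net: WeightedNetwork, q: QuerySpec) -> Subgraph:
    """Grow the query set by the k best-connected genes, greedily.

    At each step the candidate maximizing score(v) = sum of w(u, v) over the
    current set (unscored pairs contribute 0) is added; ties break
    lexicographically. Exactly min(k, |universe| - |seeds|) genes are added.
    Query genes absent from the universe are dropped; if none remain, an
    error lists them.
    """
    seeds = [g for g in q.query_genes if g in net.universe]
    missing = [g for g in q.query_genes if g not in net.universe]
    if not seeds:
        raise ValueError(f"no query genes found in network universe: missing {missing}")

    genes = sorted(net.universe)
    idx = {g: i for i, g in enumerate(genes)}
    in_set = np.zeros(len(genes), dtype=bool)
    score = np.zeros(len(genes))
    # score starts as connectivity to the seed set
    for g in seeds:
        in_set[idx[g]] = True
    for (u, v), w in net.edges.items():
        iu, iv = idx[u], idx[v]
        if in_set[iu] and not in_set[iv]:
            score[iv] += w
        elif in_set[iv] and not in_set[iu]:
            score[iu] += w

    added: list[str] = []
    add_scores: dict[str, float] = {}
    n_add = min(q.k, len(genes) - len(seeds))
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in net.edges.items():
        adj.setdefault(idx[u], []).append((idx[v], w))
        adj.setdefault(idx[v], []).append((idx[u], w))
    for _ in range(n_add):
        best = -1
        for i, g in enumerate(genes):
            if in_set[i]:
                continue
            if best < 0 or score[i] > score[best]:
                best = i
        # lexicographic tie-break comes free: genes sorted, strict > keeps first
        g = genes[best]
        added.append(g)
        add_scores[g] = float(score[best])
        in_set[best] = True
        for j, w in adj.get(best, []):
            if not in_set[j]:
                score[j] += w

    nodes = frozenset(seeds) | frozenset(added)
    induced = {
        key: w for key, w in net.edges.items() if key[0] in nodes and key[1] in nodes
    }
    return Subgraph(
        nodes=nodes,
        seed_nodes=frozenset(seeds),
        added_nodes=added,
        edges=induced,
        add_scores=add_scores,
    )


# --- edge-list I/O ----------------------------------------------------------

def read_edge_list(
    path: str | Path, net_type: str = "functional", dataset_id: str = ""
) -> WeightedNetwork:
    """Read gene1 TAB gene2 TAB weight lines ('#' comments allowed).

    Duplicate pairs keep the maximum weight; self-edges are rejected.
    """
    edges: dict[tuple[str, str], float] = {}
    universe: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            u, v, ws = parts
            if u == v:
                raise ValueError(f"{path}: line {lineno}: self-edge {u}")
            w = float(ws)
            key = edge_key(u, v)
            if key in edges:
                edges[key] = max(edges[key], w)
            else:
                edges[key] = w
            universe.update(key)
    return WeightedNetwork(
        universe=frozenset(universe),
        edges=edges,
        net_type=net_type,
        dataset_id=dataset_id,
    )


def write_edge_list(
    net: WeightedNetwork, path: str | Path, threshold: float | None = None
) -> None:
    """Write sorted gene1 TAB gene2 TAB weight lines; optional |w| threshold."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for (u, v) in sorted(net.edges):
            w = net.edges[(u, v)]
            if threshold is not None and abs(w) < threshold:
                continue
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_subgraph(sub: Subgraph, out_dir: str | Path) -> None:
    """Write a node table (role, add rank, add score) and induced edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rank = {g: i + 1 for i, g in enumerate(sub.added_nodes)}
    with open(out / "nodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\trole\tadd_rank\tadd_score\n")
        for g in sorted(sub.nodes):
            if g in sub.seed_nodes:
                fh.write(f"{g}\tseed\t\t\n")
            else:
                fh.write(f"{g}\tadded\t{rank[g]}\t{sub.add_scores[g]:.10g}\n")
    with open(out / "edges.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for (u, v) in sorted(sub.edges):
            fh.write(f"{u}\t{v}\t{sub.edges[(u, v)]:.10g}\n")
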
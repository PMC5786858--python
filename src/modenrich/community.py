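"""Modularity and greedy two-phase modularity maximization (Louvain/BGLL).

The partitioner is deterministic for a fixed (graph, seed, resolution):
node sweep order is a seeded shuffle per pass, and ties between equal-gain
moves are broken toward the lowest community label.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Tuple

from modenrich.graph_io import WeightedGraph

#: per-pass modularity gain below which aggregation stops
_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class Partition:
    """Node -> module-label assignment with its modularity score.

    Labels are contiguous integers starting at 0, ordered by descending
    module size (ties broken by the smallest member identifier).
    """

    assignment: Mapping[str, int]
    modularity: float
    seed: int

    def modules(self) -> Dict[int, FrozenSet[str]]:
        groups: Dict[int, set] = {}
        for node, label in self.assignment.items():
            groups.setdefault(label, set()).add(node)
        return {label: frozenset(members) for label, members in groups.items()}

    def labels(self) -> List[int]:
        return sorted(set(self.assignment.values()))

    def __len__(self) -> int:
        return len(set(self.assignment.values()))


def modularity(
    graph: WeightedGraph,
    assignment: Mapping[str, int],
    resolution: float = 1.0,
) -> float:
    """Weighted Newman-Girvan modularity Q of an assignment.

    Q = sum over communities c of [ W_c / W - resolution * (S_c / 2W)^2 ]
    where W is total edge weight, W_c intra-community weight and S_c the
    summed strength of community c.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("modularity of an empty graph is undefined")
    for node in graph.nodes:
        if node not in assignment:
            raise ValueError(f"node {node!r} missing from assignment")
    total = float(graph.total_weight())
    if total <= 0:
        raise ValueError("graph has no edges; modularity is undefined")
    intra: Dict[int, float] = {}
    strength: Dict[int, float] = {}
    for node in graph.nodes:
        c = assignment[node]
        strength[c] = strength.get(c, 0.0) + graph.strength(node)
    for u, v, w in graph.edges():
        if assignment[u] == assignment[v]:
            c = assignment[u]
            intra[c] = intra.get(c, 0.0) + w
    q = 0.0
    for c, s in strength.items():
        q += intra.get(c, 0.0) / total - resolution * (s / (2.0 * total)) ** 2
    return q


def _one_level(
    adj: List[Dict[int, float]],
    self_w: List[float],
    total_w: float,
    rng: random.Random,
    resolution: float,
) -> Tuple[List[int], bool]:
    """Phase 1: greedy local moves until no single move improves modularity.

    Returns (community of each node, whether any node moved).
    """
    n = len(adj)
    comm = list(range(n))
    strength = [2.0 * self_w[i] + sum(adj[i].values()) for i in range(n)]
    comm_strength = strength.copy()
    moved_any = False
    while True:
        moved = 0
        order = list(range(n))
        rng.shuffle(order)
        for i in order:
            ci = comm[i]
            links: Dict[int, float] = {}
            for j, w in adj[i].items():
                cj = comm[j]
                links[cj] = links.get(cj, 0.0) + w
            s_i = strength[i]
            comm_strength[ci] -= s_i
            # gain (scaled by W) of inserting i into community c, relative
            # to i sitting alone; comparing gains compares full moves
            def gain(c: int) -> float:
                return links.get(c, 0.0) - resolution * comm_strength[c] * s_i / (
                    2.0 * total_w
                )

            best_c = ci
            best_gain = gain(ci)
            for c in sorted(links):
                if c == ci:
                    continue
                g = gain(c)
                if g > best_gain + _GAIN_TOL or (
                    g > best_gain - _GAIN_TOL and c < best_c
                ):
                    best_c, best_gain = c, g
            comm[i] = best_c
            comm_strength[best_c] += s_i
            if best_c != ci:
                moved += 1
                moved_any = True
        if moved == 0:
            break
    return comm, moved_any


def _aggregate(
    adj: List[Dict[int, float]],
    self_w: List[float],
    comm: List[int],
) -> Tuple[List[Dict[int, float]], List[float], List[int]]:
    """Phase 2: collapse communities into super-nodes with self-loops."""
    labels = sorted(set(comm))
    relabel = {c: i for i, c in enumerate(labels)}
    m = len(labels)
    new_adj: List[Dict[int, float]] = [dict() for _ in range(m)]
    new_self = [0.0] * m
    for i, nbrs in enumerate(adj):
        ci = relabel[comm[i]]
        new_self[ci] += self_w[i]
        for j, w in nbrs.items():
            if j < i:
                continue
            cj = relabel[comm[j]]
            if ci == cj:
                new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    mapping = [relabel[c] for c in comm]
    return new_adj, new_self, mapping


def _level_modularity(
    adj: List[Dict[int, float]],
    self_w: List[float],
    comm: List[int],
    total_w: float,
    resolution: float,
) -> float:
    intra: Dict[int, float] = {}
    strength: Dict[int, float] = {}
    for i, nbrs in enumerate(adj):
        c = comm[i]
        strength[c] = strength.get(c, 0.0) + 2.0 * self_w[i] + sum(nbrs.values())
        intra[c] = intra.get(c, 0.0) + self_w[i]
        for j, w in nbrs.items():
            if j > i and comm[j] == c:
                intra[c] = intra.get(c, 0.0) + w
    q = 0.0
    for c, s in strength.items():
        q += intra.get(c, 0.0) / total_w - resolution * (s / (2.0 * total_w)) ** 2
    return q


def louvain_partition(
    graph: WeightedGraph, seed: int, resolution: float = 1.0
) -> Partition:
    """Partition a weighted graph by two-phase greedy modularity maximization.

    Phase 1 sweeps nodes in a seeded shuffled order, moving each node to the
    neighboring community with the largest positive modularity gain (ties to
    the lowest label); phase 2 aggregates communities into super-nodes with
    self-loops. Levels repeat until a full pass improves modularity by less
    than 1e-12. Identical inputs give identical output.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    nodes = sorted(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    total_w = float(graph.total_weight())
    if total_w <= 0:
        raise ValueError("cannot partition a graph with no edges")

    adj: List[Dict[int, float]] = [dict() for _ in nodes]
    for u, v, w in graph.edges():
        adj[index[u]][index[v]] = float(w)
        adj[index[v]][index[u]] = float(w)
    self_w = [0.0] * len(nodes)

    rng = random.Random(seed)
    # membership of each original node in the current-level super-node graph
    node_comm = list(range(len(nodes)))
    q_prev = _level_modularity(adj, self_w, list(range(len(adj))), total_w, resolution)
    while True:
        comm, moved = _one_level(adj, self_w, total_w, rng, resolution)
        q_now = _level_modularity(adj, self_w, comm, total_w, resolution)
        if not moved or q_now - q_prev < _GAIN_TOL:
            break
        adj, self_w, mapping = _aggregate(adj, self_w, comm)
        node_comm = [mapping[s] for s in node_comm]
        q_prev = q_now

    assignment = _canonical_labels({nodes[i]: node_comm[i] for i in range(len(nodes))})
    q = modularity(graph, assignment, resolution=resolution)
    return Partition(assignment=assignment, modularity=q, seed=seed)


def _canonical_labels(raw: Mapping[str, int]) -> Dict[str, int]:
    """Relabel communities 0..M-1 by descending size, ties by smallest member."""
    groups: Dict[int, List[str]] = {}
    for node, c in raw.items():
        groups.setdefault(c, []).append(node)
    ordered = sorted(groups.values(), key=lambda members: (-len(members), min(members)))
    out: Dict[str, int] = {}
    for label, members in enumerate(ordered):
        for node in members:
            out[node] = label
    return out


def partition_summary(partition: Partition) -> List[Tuple[int, int]]:
    """Rows of (module label, size), sorted by label; sizes sum to the node
    count."""
    sizes: Dict[int, int] = {}
    for label in partition.assignment.values():
        sizes[label] = sizes.get(label, 0) + 1
    return sorted(sizes.items())
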
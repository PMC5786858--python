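"""Synthetic inputs with the statistical structure the pipeline assumes:
a stochastic block model network with planted communities, gene sets
concentrated in chosen blocks, per-symptom planted bipartite maps, and
target sets overlapping a planted set.

All randomness flows from explicit seeds; per-symptom seeds derive as
seed + index so a whole scenario reproduces from one integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from modenrich.graph_io import BipartiteMap, GeneSet, WeightedGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SBMSpec:
    """Planted-partition (stochastic block model) parameters."""

    block_sizes: Tuple[int, ...]
    p_in: float
    p_out: float
    edge_weight: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("all block sizes must be >= 1")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if not 0 <= self.edge_weight <= 1000:
            raise ValueError("edge_weight must be in [0, 1000]")


@dataclass(frozen=True)
class PlantSpec:
    """Bernoulli planting of a gene set: rate q_in inside the enriched
    blocks, q_out elsewhere."""

    enriched_blocks: Tuple[int, ...]
    q_in: float
    q_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "enriched_blocks", tuple(self.enriched_blocks))
        if not 0.0 <= self.q_out < self.q_in <= 1.0:
            raise ValueError(
                f"need 0 <= q_out < q_in <= 1, got q_in={self.q_in}, q_out={self.q_out}"
            )


def _node_name(block: int, index: int) -> str:
    return f"B{block}_N{index}"


def generate_sbm(spec: SBMSpec) -> Tuple[WeightedGraph, Dict[str, int]]:
    """Sample an SBM graph; returns the graph and the true node->block map.

    Nodes are named B{block}_N{index}; every generated edge carries the
    constant spec.edge_weight. Same seed, same graph.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: List[List[str]] = []
    assignment: Dict[str, int] = {}
    for b, size in enumerate(spec.block_sizes):
        names = [_node_name(b, i) for i in range(size)]
        blocks.append(names)
        for name in names:
            assignment[name] = b

    graph = WeightedGraph()
    for name in assignment:
        graph.add_node(name)

    nb = len(blocks)
    for bi in range(nb):
        for bj in range(bi, nb):
            p = spec.p_in if bi == bj else spec.p_out
            if bi == bj:
                pairs = [
                    (blocks[bi][a], blocks[bi][b])
                    for a in range(len(blocks[bi]))
                    for b in range(a + 1, len(blocks[bi]))
                ]
            else:
                pairs = [(u, v) for u in blocks[bi] for v in blocks[bj]]
            if not pairs or p == 0.0:
                continue
            draws = rng.random(len(pairs))
            for (u, v), d in zip(pairs, draws):
                if d < p:
                    graph.add_edge(u, v, spec.edge_weight)
    return graph, assignment


def plant_gene_set(
    true_assignment: Mapping[str, int],
    spec: PlantSpec,
    name: str = "planted",
    source: str = "disease",
) -> GeneSet:
    """Independent Bernoulli inclusion per node: rate q_in in enriched
    blocks, q_out elsewhere."""
    n_blocks = max(true_assignment.values()) + 1 if true_assignment else 0
    for b in spec.enriched_blocks:
        if not 0 <= b < n_blocks:
            raise ValueError(f"enriched block index {b} out of range [0, {n_blocks})")
    rng = np.random.default_rng(spec.seed)
    enriched = set(spec.enriched_blocks)
    nodes = sorted(true_assignment)
    draws = rng.random(len(nodes))
    members = {
        node
        for node, d in zip(nodes, draws)
        if d < (spec.q_in if true_assignment[node] in enriched else spec.q_out)
    }
    return GeneSet(name=name, source=source, members=frozenset(members))


def generate_symptom_map(
    true_assignment: Mapping[str, int],
    symptoms: Sequence[str],
    spec: PlantSpec,
) -> BipartiteMap:
    """Plant one gene set per symptom (seed + index each); symptoms whose
    draw comes up empty are dropped with a warning."""
    if not symptoms:
        raise ValueError("need at least one symptom label")
    associations: Dict[str, frozenset] = {}
    for idx, symptom in enumerate(symptoms):
        sub = PlantSpec(
            enriched_blocks=spec.enriched_blocks,
            q_in=spec.q_in,
            q_out=spec.q_out,
            seed=spec.seed + idx,
        )
        gs = plant_gene_set(true_assignment, sub, name=symptom, source="symptom")
        if gs.members:
            associations[symptom] = gs.members
        else:
            logger.warning("symptom %r drew an empty gene set; dropped", symptom)
    return BipartiteMap(associations=associations)


def generate_target_sets(
    planted_gene_set: GeneSet,
    overlap_fraction: float,
    decoy_count: int,
    seed: int,
    forbidden: Sequence[str] = (),
    name: str = "targets",
    source: str = "target_drug",
) -> GeneSet:
    """Sample floor(overlap_fraction * |planted|) members of the planted set
    plus decoy_count fresh identifiers outside it (and outside *forbidden*,
    e.g. the graph's node set)."""
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if decoy_count < 0:
        raise ValueError("decoy_count must be >= 0")
    rng = np.random.default_rng(seed)
    pool = sorted(planted_gene_set.members)
    n_take = math.floor(overlap_fraction * len(pool))
    taken = set(rng.choice(pool, size=n_take, replace=False)) if n_take else set()
    avoid = set(planted_gene_set.members) | set(forbidden)
    decoys: List[str] = []
    counter = 0
    while len(decoys) < decoy_count:
        candidate = f"DECOY_{seed}_{counter}"
        counter += 1
        if candidate in avoid:
            continue  # collides with a real node; resample next counter value
        decoys.append(candidate)
    return GeneSet(name=name, source=source, members=frozenset(taken) | frozenset(decoys))
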
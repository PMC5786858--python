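"""Merging disease-gene sources into one union with a provenance ledger.

The manual literature screening behind such lists is not reproducible; this
module reproduces the arithmetic of merging ordered sources — per-source
sizes, pairwise overlaps, and the count each source adds beyond the running
union — plus an exclusion report for manually discarded candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

from modenrich.graph_io import GeneSet


@dataclass(frozen=True)
class SourceLedger:
    """Overlap accounting for an ordered merge of gene sources."""

    per_source_sizes: Mapping[str, int]
    pairwise_overlaps: Mapping[Tuple[str, str], int]
    new_per_source: Mapping[str, int]
    union_size: int
    provenance: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)


def merge_sources(sets: Sequence[GeneSet]) -> Tuple[GeneSet, SourceLedger]:
    """Union an ordered list of gene sets, recording per-source sizes,
    pairwise overlaps and the novel contribution of each source given the
    stated order. union_size always equals the sum of new_per_source."""
    if not sets:
        raise ValueError("merge_sources needs at least one gene set")
    names = [gs.name for gs in sets]
    if len(set(names)) != len(names):
        raise ValueError("source names must be distinct")

    sizes: Dict[str, int] = {gs.name: len(gs.members) for gs in sets}
    overlaps: Dict[Tuple[str, str], int] = {}
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            overlaps[(a.name, b.name)] = len(a.members & b.members)

    running: set = set()
    new_counts: Dict[str, int] = {}
    provenance: Dict[str, List[str]] = {}
    for gs in sets:
        new_counts[gs.name] = len(gs.members - running)
        running |= gs.members
        for gene in gs.members:
            provenance.setdefault(gene, []).append(gs.name)

    merged = GeneSet(
        name="+".join(names), source=sets[0].source, members=frozenset(running)
    )
    ledger = SourceLedger(
        per_source_sizes=sizes,
        pairwise_overlaps=overlaps,
        new_per_source=new_counts,
        union_size=len(running),
        provenance={g: tuple(srcs) for g, srcs in provenance.items()},
    )
    return merged, ledger


def exclusion_report(
    candidates: GeneSet,
    excluded: GeneSet,
    ambiguous: Iterable[str] = (),
) -> Tuple[GeneSet, float]:
    """Remove *excluded* from *candidates* and report the fraction of
    excluded members flagged as ambiguous (caller-supplied metadata),
    rounded to 4 decimals."""
    if not excluded.members <= candidates.members:
        extra = sorted(excluded.members - candidates.members)[:5]
        raise ValueError(f"excluded set is not a subset of candidates (e.g. {extra})")
    kept = GeneSet(
        name=f"{candidates.name}_kept",
        source=candidates.source,
        members=candidates.members - excluded.members,
    )
    flagged = frozenset(ambiguous) & excluded.members
    fraction = (
        round(len(flagged) / len(excluded.members), 4) if excluded.members else 0.0
    )
    return kept, fraction
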
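"""I/O for weighted interaction networks, gene sets, GMT collections, and
symptom-gene bipartite maps.

The network loader applies the confidence-score filter at read time
(default: keep edges with score strictly greater than the threshold) and
collapses reciprocal duplicate rows into single undirected edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Tuple

logger = logging.getLogger(__name__)

SOURCE_TAGS = frozenset(
    {
        "disease",
        "symptom",
        "target_drug",
        "target_formula_BS",
        "target_formula_PS",
        "annotation",
    }
)

STRING_COLUMNS = ("protein1", "protein2", "combined_score")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class WeightedGraph:
    """Undirected graph over opaque string identifiers with integer edge
    scores in [0, 1000].

    No self-loops; each unordered pair stored at most once (duplicate
    insertions keep the maximum score).
    """

    __slots__ = ("_adj",)

    def __init__(self) -> None:
        self._adj: Dict[str, Dict[str, int]] = {}

    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, {})

    def add_edge(self, u: str, v: str, weight: int) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        w = int(weight)
        self.add_node(u)
        self.add_node(v)
        prev = self._adj[u].get(v)
        if prev is None or w > prev:
            self._adj[u][v] = w
            self._adj[v][u] = w

    @property
    def nodes(self) -> FrozenSet[str]:
        return frozenset(self._adj)

    def neighbors(self, node: str) -> Mapping[str, int]:
        return self._adj[node]

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def weight(self, u: str, v: str) -> int:
        return self._adj[u][v]

    def edges(self) -> Iterator[Tuple[str, str, int]]:
        """Yield (u, v, weight) with u < v, in sorted order."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def strength(self, node: str) -> int:
        """Sum of incident edge weights."""
        return sum(self._adj[node].values())

    def total_weight(self) -> int:
        """Sum of edge weights, each edge counted once."""
        return sum(w for _, _, w in self.edges())

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def __len__(self) -> int:
        return len(self._adj)


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated collection of gene identifiers."""

    name: str
    source: str
    members: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if self.source not in SOURCE_TAGS:
            raise ValueError(
                f"unknown source tag {self.source!r}; expected one of "
                f"{sorted(SOURCE_TAGS)}"
            )
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class BipartiteMap:
    """Symptom term -> set of associated gene identifiers."""

    associations: Mapping[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        assoc = {k: frozenset(v) for k, v in self.associations.items()}
        for term, genes in assoc.items():
            if not genes:
                raise ValueError(f"symptom {term!r} maps to an empty gene set")
        object.__setattr__(self, "associations", assoc)

    def gene_universe(self) -> FrozenSet[str]:
        out: set = set()
        for genes in self.associations.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.associations)


def flatten_genes(bmap: BipartiteMap) -> FrozenSet[str]:
    """Union of all gene sets in a bipartite map."""
    return bmap.gene_universe()


def _data_lines(path: Path) -> Iterator[Tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_string_links(
    path: str | Path, min_score: int = 700, strict: bool = True
) -> WeightedGraph:
    """Load a whitespace-delimited links file (protein1, protein2,
    combined_score) into a :class:`WeightedGraph`, keeping only edges whose
    score passes the threshold (``> min_score`` when *strict*, else ``>=``).

    Reciprocal duplicate rows collapse to one undirected edge keeping the
    maximum score; self-loop rows are skipped with a warning; isolated nodes
    are dropped.
    """
    path = Path(path)
    if not 0 <= min_score <= 1000:
        raise ValueError(f"min_score must be in [0, 1000], got {min_score}")
    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty file, expected a header row")
    columns = header.split()
    col_index: Dict[str, int] = {}
    for col in STRING_COLUMNS:
        if col not in columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        col_index[col] = columns.index(col)
    need = max(col_index.values()) + 1

    best: Dict[Tuple[str, str], int] = {}
    for lineno, line in lines:
        parts = line.split()
        if len(parts) < need:
            raise FormatError(
                f"{path}:{lineno}: expected at least {need} fields, got {len(parts)}"
            )
        u = parts[col_index["protein1"]]
        v = parts[col_index["protein2"]]
        raw_score = parts[col_index["combined_score"]]
        try:
            score = int(raw_score)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer combined_score {raw_score!r}"
            )
        if not 0 <= score <= 1000:
            raise FormatError(
                f"{path}:{lineno}: combined_score {score} outside [0, 1000]"
            )
        if u == v:
            logger.warning("%s:%d: skipping self-loop row on %r", path, lineno, u)
            continue
        key = (u, v) if u < v else (v, u)
        if key not in best or score > best[key]:
            best[key] = score

    graph = WeightedGraph()
    for (u, v), score in best.items():
        keep = score > min_score if strict else score >= min_score
        if keep:
            graph.add_edge(u, v, score)
    return graph


def write_string_links(graph: WeightedGraph, path: str | Path) -> None:
    """Write a graph in the links dialect read by :func:`load_string_links`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein1 protein2 combined_score\n")
        for u, v, w in graph.edges():
            handle.write(f"{u} {v} {w}\n")


def load_gene_sets(path: str | Path, source: str) -> List[GeneSet]:
    """Load named gene sets from a two-column TSV (set name, gene id).

    A single-column file is interpreted as one set named after the file stem.
    Duplicate (name, gene) rows are deduplicated; identifiers are trimmed.
    """
    path = Path(path)
    groups: Dict[str, set] = {}
    order: List[str] = []
    ncols: int | None = None
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        parts = [p for p in parts if p != ""] if len(parts) > 2 else parts
        if len(parts) not in (1, 2) or any(p == "" for p in parts):
            raise FormatError(
                f"{path}:{lineno}: expected 1 or 2 tab-separated fields, "
                f"got {line!r}"
            )
        if ncols is None:
            ncols = len(parts)
        elif len(parts) != ncols:
            raise FormatError(
                f"{path}:{lineno}: inconsistent column count "
                f"(expected {ncols}, got {len(parts)})"
            )
        if ncols == 1:
            name, gene = path.stem, parts[0]
        else:
            name, gene = parts
        if name not in groups:
            groups[name] = set()
            order.append(name)
        groups[name].add(gene)
    if not groups:
        logger.warning("%s: empty gene-set file", path)
        return []
    return [GeneSet(name=name, source=source, members=frozenset(groups[name])) for name in order]


def load_gmt(path: str | Path) -> List[GeneSet]:
    """Load a GMT annotation collection: one set per line, fields are
    name, description (discarded), then one or more gene identifiers."""
    path = Path(path)
    sets: List[GeneSet] = []
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        parts = [p for p in parts if p != ""]
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f"at least one gene (got {len(parts)} fields)"
            )
        name, _desc, *genes = parts
        sets.append(GeneSet(name=name, source="annotation", members=frozenset(genes)))
    return sets


def load_bipartite(path: str | Path) -> BipartiteMap:
    """Load a two-column TSV (symptom term, gene id) into a grouped map."""
    path = Path(path)
    groups: Dict[str, set] = {}
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2 or any(p == "" for p in parts):
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {line!r}"
            )
        term, gene = parts
        groups.setdefault(term, set()).add(gene)
    if not groups:
        logger.warning("%s: empty bipartite file", path)
    return BipartiteMap(associations={t: frozenset(g) for t, g in groups.items()})


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as two-column TSV, sorted for byte stability."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            for gene in sorted(gs.members):
                handle.write(f"{gs.name}\t{gene}\n")


def write_bipartite(bmap: BipartiteMap, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for term in sorted(bmap.associations):
            for gene in sorted(bmap.associations[term]):
                handle.write(f"{term}\t{gene}\n")
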
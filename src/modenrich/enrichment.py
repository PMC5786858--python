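"""Hypergeometric enrichment of gene sets across network modules, and the
two module-selection rules: a raw p-value threshold (default 0.01) combined
with a relative-risk cut (module proportion at least 3x the background
proportion), plus the joint disease+symptom rule for syndrome modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Mapping, NamedTuple, Sequence

from modenrich.community import Partition
from modenrich.graph_io import GeneSet

logger = logging.getLogger(__name__)

BACKGROUND_POLICIES = ("covered_modules", "whole_graph", "custom")


@dataclass(frozen=True)
class EnrichmentInput:
    """Urn parameters of one hypergeometric test.

    N: background universe size; K: annotated genes in the background;
    n: module size within the background; k: overlap.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.n, self.k) < 0:
            raise ValueError("counts must be non-negative")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"K={self.K} and n={self.n} must not exceed N={self.N}")
        if self.k > min(self.K, self.n):
            raise ValueError(f"k={self.k} exceeds min(K={self.K}, n={self.n})")


@dataclass(frozen=True)
class ModuleEnrichment:
    """One module's enrichment record against a gene set."""

    module: int
    input: EnrichmentInput
    p_value: float
    proportion: float
    background_proportion: float
    is_potential: bool
    passes_p: bool
    passes_rr: bool


@dataclass(frozen=True)
class Background:
    """The urn's gene universe and the policy that produced it."""

    policy: str
    universe: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.policy not in BACKGROUND_POLICIES:
            raise ValueError(
                f"unknown background policy {self.policy!r}; "
                f"expected one of {BACKGROUND_POLICIES}"
            )
        object.__setattr__(self, "universe", frozenset(self.universe))


class PotentialModules(NamedTuple):
    labels: List[int]
    universe: FrozenSet[str]


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    Returns a value in (0, 1]; k = 0 gives exactly 1.0.
    """
    EnrichmentInput(N=N, K=K, n=n, k=k)  # validates the urn
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    kmax = min(K, n)
    logs = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(k, kmax + 1)
        if n - i <= N - K
    ]
    if not logs:
        return 0.0  # unreachable for a valid urn
    m = max(logs)
    tail = m + math.log(sum(math.exp(x - m) for x in logs))
    p = math.exp(tail)
    if p > 1.0:
        p = 1.0
    if p <= 0.0:
        p = 5e-324  # log-space underflow guard; tail mass is still positive
    return p


def select_potential_modules(
    partition: Partition, genes: GeneSet
) -> PotentialModules:
    """Labels of modules containing at least one gene from *genes*, plus the
    covered universe (union of those modules' members)."""
    if not genes.members:
        raise ValueError("gene set is empty")
    labels: List[int] = []
    universe: set = set()
    for label, members in sorted(partition.modules().items()):
        if members & genes.members:
            labels.append(label)
            universe |= members
    if not labels:
        logger.warning(
            "gene set %r is disjoint from the graph; no potential modules", genes.name
        )
    return PotentialModules(labels=labels, universe=frozenset(universe))


def covered_background(partition: Partition, genes: GeneSet) -> Background:
    """Background whose universe is the proteins covered by the potential
    modules of *genes* (the default policy)."""
    potential = select_potential_modules(partition, genes)
    return Background(policy="covered_modules", universe=potential.universe)


def whole_graph_background(partition: Partition) -> Background:
    return Background(
        policy="whole_graph", universe=frozenset(partition.assignment)
    )


def enrich_modules(
    partition: Partition,
    genes: GeneSet,
    background: Background,
    alpha: float = 0.01,
    rr_multiplier: float = 3.0,
) -> List[ModuleEnrichment]:
    """Hypergeometric upper-tail enrichment of *genes* in every module with
    nonzero membership inside the background universe.

    Genes outside the universe are dropped (with a logged count) before
    counting, so the urn stays coherent. Records are sorted by ascending
    p-value (ties by module label).
    """
    universe = background.universe
    if not universe:
        raise ValueError("background universe is empty")
    annotated = genes.members & universe
    dropped = len(genes.members) - len(annotated)
    if dropped:
        logger.info(
            "dropped %d/%d genes of %r outside the background universe",
            dropped,
            len(genes.members),
            genes.name,
        )
    N = len(universe)
    K = len(annotated)
    bg_prop = K / N
    records: List[ModuleEnrichment] = []
    for label, members in sorted(partition.modules().items()):
        module_in = members & universe
        n = len(module_in)
        if n == 0:
            logger.debug("module %d has no members in the universe; skipped", label)
            continue
        k = len(module_in & annotated)
        p = hypergeom_upper_tail(k, K, n, N)
        prop = k / n
        records.append(
            ModuleEnrichment(
                module=label,
                input=EnrichmentInput(N=N, K=K, n=n, k=k),
                p_value=p,
                proportion=prop,
                background_proportion=bg_prop,
                is_potential=k >= 1,
                passes_p=p < alpha,
                passes_rr=prop >= rr_multiplier * bg_prop,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.module))
    return records


def select_disease_modules(
    records: Sequence[ModuleEnrichment],
    alpha: float = 0.01,
    rr_multiplier: float = 3.0,
) -> List[ModuleEnrichment]:
    """Joint rule: p-value below *alpha* AND module proportion at least
    *rr_multiplier* times the background proportion. Either criterion can be
    relaxed (alpha=1 leaves only the relative-risk rule; rr_multiplier=0
    leaves only the p rule). Input order is preserved."""
    return [
        r
        for r in records
        if r.p_value < alpha
        and r.proportion >= rr_multiplier * r.background_proportion
    ]


def select_syndrome_modules(
    symptom_records: Sequence[ModuleEnrichment],
    disease_modules: Iterable[int],
    alpha: float = 0.01,
) -> List[ModuleEnrichment]:
    """Symptom-enriched records (p < alpha) restricted to modules that are
    already disease modules."""
    allowed = set(disease_modules)
    return [
        r for r in symptom_records if r.p_value < alpha and r.module in allowed
    ]
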
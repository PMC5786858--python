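"""Over-representation analysis of a query gene list against an annotation
collection, with Bonferroni correction.

The correction factor counts only terms with nonzero annotated size inside
the background universe, i.e. the number of tests actually performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

from modenrich.enrichment import Background, EnrichmentInput, hypergeom_upper_tail
from modenrich.graph_io import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    term: str
    input: EnrichmentInput
    p_value: float
    cpv: float  # Bonferroni-corrected p-value, capped at 1
    significant: bool


def ora(
    query: GeneSet,
    collection: Sequence[GeneSet],
    background: Background,
    alpha: float = 0.01,
) -> List[OraResult]:
    """Hypergeometric ORA of *query* against every term in *collection*.

    Query and terms are restricted to the background universe first; terms
    left with zero overlap are still tested (k=0 gives p=1). Results are
    sorted by ascending corrected p-value, ties by term name.
    """
    universe = background.universe
    if not universe:
        raise ValueError("background universe is empty")
    if not collection:
        logger.warning("empty annotation collection; nothing to test")
        return []
    q = query.members & universe
    N = len(universe)
    n = len(q)
    annotated_sizes = {t.name: len(t.members & universe) for t in collection}
    n_tests = sum(1 for size in annotated_sizes.values() if size > 0)
    results: List[OraResult] = []
    for term in collection:
        K = annotated_sizes[term.name]
        k = len(term.members & q)
        p = hypergeom_upper_tail(k, K, n, N)
        cpv = min(1.0, p * max(n_tests, 1))
        results.append(
            OraResult(
                term=term.name,
                input=EnrichmentInput(N=N, K=K, n=n, k=k),
                p_value=p,
                cpv=cpv,
                significant=cpv < alpha,
            )
        )
    results.sort(key=lambda r: (r.cpv, r.term))
    return results
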
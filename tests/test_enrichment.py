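from __future__ import annotations

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modenrich.community import Partition
from modenrich.enrichment import (
    Background,
    EnrichmentInput,
    ModuleEnrichment,
    covered_background,
    enrich_modules,
    hypergeom_upper_tail,
    select_disease_modules,
    select_potential_modules,
    select_syndrome_modules,
)
from modenrich.graph_io import GeneSet


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Independent enumeration oracle: exact tail sum over the pmf."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(total, denom)


def make_partition(blocks: dict) -> Partition:
    assignment = {}
    for label, members in blocks.items():
        for m in members:
            assignment[m] = label
    return Partition(assignment=assignment, modularity=0.0, seed=0)


def gene_set(members, name="gs", source="disease") -> GeneSet:
    return GeneSet(name=name, source=source, members=frozenset(members))


class TestEnrichmentInput:
    def test_valid(self):
        EnrichmentInput(N=10, K=5, n=4, k=4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=10, K=11, n=4, k=0),
            dict(N=10, K=5, n=11, k=0),
            dict(N=10, K=5, n=4, k=5),
            dict(N=10, K=3, n=8, k=4),
            dict(N=-1, K=0, n=0, k=0),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            EnrichmentInput(**kwargs)


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0
        assert hypergeom_upper_tail(0, 0, 0, 1) == 1.0

    def test_exact_small_case(self):
        # C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-15)

    def test_matches_enumeration_all_k(self):
        N, K, n = 30, 10, 8
        for k in range(0, 9):
            exact = float(exact_upper_tail(k, K, n, N))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(exact, abs=1e-12)

    def test_matches_scipy_sf(self):
        from scipy.stats import hypergeom

        rng = random.Random(0)
        for _ in range(50):
            N = rng.randint(2, 500)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k = rng.randint(0, min(K, n))
            ours = hypergeom_upper_tail(k, K, n, N)
            theirs = float(hypergeom.sf(k - 1, N, K, n))
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-300)

    def test_pmf_sums_to_one(self):
        rng = random.Random(2)
        for _ in range(30):
            N = rng.randint(1, 60)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            lo = max(0, n - (N - K))
            assert hypergeom_upper_tail(lo, K, n, N) == pytest.approx(1.0, abs=1e-12)

    @given(
        data=st.tuples(st.integers(2, 40), st.integers(0, 40), st.integers(0, 40))
    )
    @settings(max_examples=60, deadline=None)
    def test_non_increasing_in_k(self, data):
        N, K, n = data[0], min(data[1], data[0]), min(data[2], data[0])
        prev = 1.0 + 1e-12
        for k in range(0, min(K, n) + 1):
            p = hypergeom_upper_tail(k, K, n, N)
            assert p <= prev + 1e-12
            prev = p

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 10, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 4, 11, 10)

    def test_in_unit_interval_extreme(self):
        p = hypergeom_upper_tail(100, 100, 100, 10000)
        assert 0.0 < p <= 1.0


class TestSelectPotentialModules:
    def test_hits_modules_0_and_2(self):
        part = make_partition(
            {0: ["a", "b"], 1: ["c", "d"], 2: ["e", "f"]}
        )
        genes = gene_set({"a", "e"})
        result = select_potential_modules(part, genes)
        assert result.labels == [0, 2]
        assert result.universe == frozenset({"a", "b", "e", "f"})

    def test_disjoint_gene_set(self, caplog):
        part = make_partition({0: ["a"], 1: ["b"]})
        with caplog.at_level("WARNING"):
            result = select_potential_modules(part, gene_set({"zzz"}))
        assert result.labels == []

    def test_matches_brute_force_on_random_instance(self):
        rng = random.Random(8)
        blocks = {i: [f"n{i}_{j}" for j in range(rng.randint(2, 10))] for i in range(12)}
        part = make_partition(blocks)
        all_nodes = [n for members in blocks.values() for n in members]
        genes = gene_set(rng.sample(all_nodes, 15))
        result = select_potential_modules(part, genes)
        oracle = sorted(
            label
            for label, members in blocks.items()
            if set(members) & set(genes.members)
        )
        assert result.labels == oracle


class TestEnrichModules:
    def test_counts_and_p_against_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        part = make_partition({0: universe[:5], 1: universe[5:]})
        annotated = gene_set(universe[:4] + universe[10:14])  # 4 in module 0
        bg = Background(policy="custom", universe=frozenset(universe))
        records = enrich_modules(part, annotated, bg)
        rec0 = next(r for r in records if r.module == 0)
        assert (rec0.input.N, rec0.input.K, rec0.input.n, rec0.input.k) == (20, 8, 5, 4)
        assert rec0.p_value == pytest.approx(float(exact_upper_tail(4, 8, 5, 20)), abs=1e-12)

    def test_saturated_gene_set(self):
        universe = [f"g{i}" for i in range(10)]
        part = make_partition({0: universe[:4], 1: universe[4:]})
        bg = Background(policy="custom", universe=frozenset(universe))
        records = enrich_modules(part, gene_set(universe), bg)
        for r in records:
            assert r.input.k == r.input.n
            assert r.p_value == pytest.approx(1.0)

    def test_background_proportion_is_K_over_N(self):
        universe = [f"g{i}" for i in range(50)]
        part = make_partition({0: universe[:25], 1: universe[25:]})
        genes = gene_set(universe[::5])
        bg = Background(policy="custom", universe=frozenset(universe))
        records = enrich_modules(part, genes, bg)
        for r in records:
            assert r.background_proportion == pytest.approx(r.input.K / r.input.N)
            assert r.proportion == pytest.approx(r.input.k / r.input.n)

    def test_genes_outside_universe_dropped(self, caplog):
        universe = ["a", "b", "c", "d"]
        part = make_partition({0: ["a", "b"], 1: ["c", "d"]})
        bg = Background(policy="custom", universe=frozenset(universe))
        records = enrich_modules(part, gene_set({"a", "zzz"}), bg)
        assert all(r.input.K == 1 for r in records)

    def test_sorted_by_ascending_p(self):
        rng = random.Random(4)
        universe = [f"g{i}" for i in range(60)]
        part = make_partition(
            {0: universe[:20], 1: universe[20:40], 2: universe[40:]}
        )
        genes = gene_set(universe[:12] + universe[55:])
        bg = Background(policy="custom", universe=frozenset(universe))
        records = enrich_modules(part, genes, bg)
        ps = [r.p_value for r in records]
        assert ps == sorted(ps)

    def test_empty_universe_rejected(self):
        part = make_partition({0: ["a"]})
        with pytest.raises(ValueError):
            enrich_modules(
                part, gene_set({"a"}), Background(policy="custom", universe=frozenset())
            )

    def test_covered_background_excludes_unhit_modules(self):
        part = make_partition({0: ["a", "b"], 1: ["c", "d"], 2: ["e", "f"]})
        genes = gene_set({"a", "c"})
        bg = covered_background(part, genes)
        assert bg.universe == frozenset({"a", "b", "c", "d"})
        records = enrich_modules(part, genes, bg)
        assert sorted(r.module for r in records) == [0, 1]


# Table of printed per-module enrichment figures used by the selection-rule
# tests: (k, n) gene counts and the published disease/symptom p-values.
PUBLISHED_RATIOS = [
    (10, 24), (12, 31), (76, 204), (21, 59), (22, 62), (12, 37), (23, 77), (44, 149)
]
PUBLISHED_DISEASE_P = [2.55e-4, 1.11e-4, 1.45e-29, 1.17e-6, 6.57e-7, 4.23e-4, 4.21e-6, 2.21e-13]
PUBLISHED_SYMPTOM_P = [1.08e-4, 0.183, 1.83e-7, 0.033, 0.040, 0.015, 0.037, 0.227]
PUBLISHED_K, PUBLISHED_N = 997, 11380


def published_records(p_values):
    records = []
    for module, ((k, n), p) in enumerate(zip(PUBLISHED_RATIOS, p_values)):
        records.append(
            ModuleEnrichment(
                module=module,
                input=EnrichmentInput(N=PUBLISHED_N, K=PUBLISHED_K, n=n, k=k),
                p_value=p,
                proportion=k / n,
                background_proportion=PUBLISHED_K / PUBLISHED_N,
                is_potential=True,
                passes_p=p < 0.01,
                passes_rr=k / n >= 3 * PUBLISHED_K / PUBLISHED_N,
            )
        )
    return records


class TestSelectDiseaseModules:
    def test_published_ratios_all_pass(self):
        records = published_records(PUBLISHED_DISEASE_P)
        selected = select_disease_modules(records, alpha=0.01, rr_multiplier=3.0)
        assert len(selected) == 8
        threshold = 3 * PUBLISHED_K / PUBLISHED_N
        for r in selected:
            assert r.proportion >= threshold

    def test_low_proportion_fails_rr_regardless_of_p(self):
        rec = ModuleEnrichment(
            module=0,
            input=EnrichmentInput(N=11380, K=997, n=100, k=20),
            p_value=1e-10,
            proportion=0.20,
            background_proportion=0.0876,
            is_potential=True,
            passes_p=True,
            passes_rr=False,
        )
        assert select_disease_modules([rec]) == []

    def test_vacuous_filter_returns_all(self):
        records = published_records(PUBLISHED_DISEASE_P)
        assert select_disease_modules(records, alpha=1.0, rr_multiplier=0.0) == records

    def test_rr_zero_reduces_to_p_rule(self):
        records = published_records([0.5] * 4 + [1e-5] * 4)
        selected = select_disease_modules(records, rr_multiplier=0.0)
        assert [r.module for r in selected] == [4, 5, 6, 7]

    def test_alpha_one_reduces_to_rr_rule(self):
        records = published_records([0.9999] * 8)
        selected = select_disease_modules(records, alpha=1.0)
        assert len(selected) == 8  # all printed ratios exceed 3x background


class TestSelectSyndromeModules:
    def test_published_symptom_p_selects_two(self):
        records = published_records(PUBLISHED_SYMPTOM_P)
        selected = select_syndrome_modules(records, disease_modules=range(8), alpha=0.01)
        assert sorted(r.p_value for r in selected) == [1.83e-7, 1.08e-4]
        assert len(selected) == 2

    def test_excluded_when_not_disease_module(self):
        records = published_records(PUBLISHED_SYMPTOM_P)
        assert select_syndrome_modules(records, disease_modules=[], alpha=0.01) == []

    def test_joint_criterion(self):
        records = published_records(PUBLISHED_SYMPTOM_P)
        # module 0 has symptom p 1.08e-4 < 0.01 but is not a disease module
        selected = select_syndrome_modules(records, disease_modules=[1, 2], alpha=0.01)
        assert [r.module for r in selected] == [2]


class TestCalibrationAndPower:
    def test_null_rate_matches_exact_discrete_level(self):
        """Under uniform draws the empirical p<alpha rate must match the
        exact attainable level of the discrete test (within binomial noise)
        and never exceed alpha."""
        rng = np.random.default_rng(123)
        N, K, n, alpha = 400, 40, 50, 0.01
        universe = np.arange(N)
        # exact attainable level: P(p-value < alpha) under the null
        k_star = next(
            k for k in range(n + 2) if hypergeom_upper_tail(min(k, min(K, n)), K, n, N) < alpha
        )
        exact_level = hypergeom_upper_tail(k_star, K, n, N)
        draws = 2000
        hits = 0
        for _ in range(draws):
            annotated = rng.choice(universe, size=K, replace=False)
            k = int(np.sum(annotated < n))  # module = first n genes
            if hypergeom_upper_tail(k, K, n, N) < alpha:
                hits += 1
        rate = hits / draws
        se = math.sqrt(exact_level * (1 - exact_level) / draws)
        assert abs(rate - exact_level) <= 1.96 * se + 1e-9
        assert exact_level <= alpha

    def test_power_under_strong_planting(self):
        """Modules planted at 5x the background rate are detected at
        alpha=0.01 with power >= 0.9 for module size 50."""
        rng = np.random.default_rng(7)
        N, n = 2000, 50
        q_bg, q_in = 0.0876, 5 * 0.0876
        detected = 0
        reps = 200
        for _ in range(reps):
            in_module = rng.random(n) < q_in
            outside = rng.random(N - n) < q_bg
            k = int(in_module.sum())
            K = k + int(outside.sum())
            if hypergeom_upper_tail(k, K, n, N) < 0.01:
                detected += 1
        assert detected / reps >= 0.9
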
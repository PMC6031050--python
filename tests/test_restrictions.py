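"""DAG-of-restrictions semantics, reduction, distances, representability."""

import itertools

import numpy as np
import pytest

from oncodag import (
    FitnessLandscape,
    RestrictionDAG,
    compatible_genotypes,
    dag_distance,
    is_representable,
    read_dag,
    transitive_reduction,
    write_dag,
)
from oncodag.generate import GenParams, dag_derived_landscape, random_restriction_dag
from oncodag.restrictions import ROOT, from_edges

from helpers_oracles import (
    brute_compatible,
    is_minimal_with_same_reachability,
    reachability,
    random_fitness,
)


def idx(dag, name):
    return dag.genes.index(name)


class TestCompatibility:
    def test_direct_dependency(self):
        dag = from_edges(("A", "B"), [(ROOT, "A"), ("A", "B")])
        compat = compatible_genotypes(dag)
        assert compat == {0b00, 0b01, 0b11}  # WT, {A}, {A,B}; not {B}

    def test_conjunction_requires_both_parents(self, conjunction_pair):
        dag, _ = conjunction_pair
        compat = compatible_genotypes(dag)
        a, b, c, d = (1 << idx(dag, g) for g in "ABCD")
        assert a | b | d in compat
        assert a | b | c | d in compat
        assert a | d not in compat

    def test_unrestricted_dag_admits_all_genotypes(self):
        dag = from_edges(("A", "B", "C"), [])
        assert compatible_genotypes(dag) == set(range(8))

    def test_matches_naive_parent_check(self, rng):
        for _ in range(20):
            m = 4
            dag = random_restriction_dag(GenParams(m=m), rng)
            parents = {
                k: {idx(dag, p) for p in dag.gene_parents(g)}
                for k, g in enumerate(dag.genes)
            }
            assert compatible_genotypes(dag) == brute_compatible(
                dag.genes, parents, m
            )

    def test_downward_closed_to_wildtype(self, rng):
        # every compatible genotype has a compatible chain down to WT
        for _ in range(10):
            dag = random_restriction_dag(GenParams(m=5), rng)
            compat = compatible_genotypes(dag)
            for g in compat - {0}:
                preds = [g & ~(1 << k) for k in range(5) if g >> k & 1]
                assert any(p in compat for p in preds)


class TestConstructionInvariants:
    def test_rejects_cycles(self):
        with pytest.raises(ValueError, match="cycle"):
            RestrictionDAG(("A", "B"), frozenset({(ROOT, "A"), ("A", "B"), ("B", "A")}))

    def test_rejects_unreachable_gene(self):
        with pytest.raises(ValueError, match="reachable"):
            RestrictionDAG(("A", "B"), frozenset({(ROOT, "A")}))

    def test_rejects_edges_into_root_and_self_edges(self):
        with pytest.raises(ValueError):
            RestrictionDAG(("A",), frozenset({(ROOT, "A"), ("A", ROOT)}))
        with pytest.raises(ValueError):
            RestrictionDAG(("A",), frozenset({(ROOT, "A"), ("A", "A")}))


class TestTransitiveReduction:
    def test_removes_shortcut_edge(self):
        dag = from_edges(("F", "G", "H"), [("F", "G"), ("G", "H"), ("F", "H")])
        red = transitive_reduction(dag)
        assert red.edges == frozenset({(ROOT, "F"), ("F", "G"), ("G", "H")})

    def test_idempotent(self, rng):
        for _ in range(20):
            dag = random_restriction_dag(GenParams(m=5), rng)
            red = transitive_reduction(dag)
            assert transitive_reduction(red).edges == red.edges

    def test_preserves_reachability_and_is_minimal(self, rng):
        for _ in range(20):
            m = int(rng.integers(3, 7))
            dag = random_restriction_dag(GenParams(m=m), rng)
            # add some redundant shortcut edges
            g = dag.to_networkx()
            import networkx as nx

            closure_edges = [
                (u, v)
                for u in dag.genes
                for v in nx.descendants(g, u)
                if v != u
            ]
            if closure_edges:
                extra = [closure_edges[int(rng.integers(len(closure_edges)))]]
            else:
                extra = []
            fat = from_edges(
                dag.genes,
                [(u, v) for u, v in dag.edges if u != ROOT] + extra,
            )
            red = transitive_reduction(fat)
            gene_edges_fat = {(u, v) for u, v in fat.edges if u != ROOT}
            gene_edges_red = {(u, v) for u, v in red.edges if u != ROOT}
            assert reachability(dag.genes, gene_edges_red) == reachability(
                dag.genes, gene_edges_fat
            )
            assert is_minimal_with_same_reachability(dag.genes, gene_edges_red)

    def test_root_edges_recomputed(self):
        dag = from_edges(("A", "B"), [(ROOT, "A"), (ROOT, "B"), ("A", "B")])
        red = transitive_reduction(dag)
        assert (ROOT, "B") not in red.edges


class TestDagDistance:
    def test_identity(self, rng):
        dag = random_restriction_dag(GenParams(m=4), rng)
        assert dag_distance(dag, dag) == (0, 0.0)

    def test_forced_small_example(self):
        d1 = from_edges(("A", "B"), [(ROOT, "A"), ("A", "B")])
        d2 = from_edges(("A", "B"), [(ROOT, "A"), (ROOT, "B")])
        count, rel = dag_distance(d1, d2)
        assert count == 2
        assert rel == pytest.approx(2 / 3)

    def test_matches_set_algebra(self, rng):
        for _ in range(20):
            d1 = random_restriction_dag(GenParams(m=5), rng)
            d2 = random_restriction_dag(GenParams(m=5), rng)
            e1, e2 = set(d1.edges), set(d2.edges)  # generator output is reduced
            count, rel = dag_distance(d1, d2)
            assert count == len(e1 ^ e2)
            if e1 | e2:
                assert rel == pytest.approx(len(e1 ^ e2) / len(e1 | e2))

    def test_metric_properties(self, rng):
        dags = [random_restriction_dag(GenParams(m=4), rng) for _ in range(6)]
        for a, b in itertools.combinations(dags, 2):
            ab = dag_distance(a, b)[0]
            assert ab == dag_distance(b, a)[0]
            assert ab >= 0
        for a, b, c in itertools.combinations(dags, 3):
            assert (
                dag_distance(a, c)[0]
                <= dag_distance(a, b)[0] + dag_distance(b, c)[0]
            )

    def test_root_edge_inclusion_flag(self):
        d1 = from_edges(("A", "B"), [(ROOT, "A"), ("A", "B")])
        d2 = from_edges(("A", "B"), [(ROOT, "A"), (ROOT, "B")])
        assert dag_distance(d1, d2, include_root_edges=False) == (1, 1.0)

    def test_rejects_gene_mismatch(self):
        d1 = from_edges(("A", "B"), [])
        d2 = from_edges(("A", "C"), [])
        with pytest.raises(ValueError):
            dag_distance(d1, d2)


class TestRepresentability:
    def test_generated_landscape_matches_its_dag(self, rng):
        for _ in range(10):
            dag = random_restriction_dag(GenParams(m=5), rng)
            L = dag_derived_landscape(dag, GenParams(m=5), rng)
            assert is_representable(L, dag)

    def test_knockout_breaks_representability(self, fixtures):
        dag, knocked = fixtures["conjunction_knockout"]
        assert not is_representable(knocked, dag)

    def test_gene_count_mismatch_rejected(self, rng):
        dag = from_edges(("A", "B"), [])
        L = FitnessLandscape(("A", "B", "C"), random_fitness(rng, 3))
        with pytest.raises(ValueError):
            is_representable(L, dag)


class TestEdgeListIO:
    def test_round_trip(self, tmp_path, rng):
        dag = random_restriction_dag(GenParams(m=5), rng)
        path = tmp_path / "dag.txt"
        write_dag(dag, path)
        back = read_dag(path)
        assert back.edges == dag.edges
        assert set(back.genes) == set(dag.genes)

    def test_simple_file(self, tmp_path):
        path = tmp_path / "dag.txt"
        path.write_text("Root A\nA B\n")
        dag = read_dag(path)
        assert dag.edges == frozenset({(ROOT, "A"), ("A", "B")})

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Root A\nA B\nB A\n")
        with pytest.raises(ValueError, match="cycle"):
            read_dag(path)

    def test_unknown_gene_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Root A\nA B\n")
        with pytest.raises(ValueError, match="unknown gene"):
            read_dag(path, genes=("A",))

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Root A\nA B C\n")
        with pytest.raises(ValueError, match=":2:"):
            read_dag(path)
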
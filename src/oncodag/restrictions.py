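"""DAGs of restrictions with conjunctive (AND) parent semantics.

A DAG of restrictions is a directed acyclic graph over a gene set plus a
distinguished ``Root`` node.  An edge ``i -> j`` means a mutation in gene
``j`` can only occur once gene ``i`` is mutated; a gene with several gene
parents requires *all* of them (AND semantics).  Genes whose only parent is
Root are unconstrained.  Such DAGs are the output format of cancer
progression models like CBN and CAPRI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .genotypes import FitnessLandscape, accessible_genotypes

__all__ = [
    "ROOT",
    "RestrictionDAG",
    "compatible_genotypes",
    "transitive_reduction",
    "dag_distance",
    "is_representable",
    "read_dag",
    "write_dag",
]

ROOT = "Root"


@dataclass(frozen=True)
class RestrictionDAG:
    """Genes plus Root with directed restriction edges.

    Invariants enforced at construction: the graph is acyclic, Root has no
    incoming edges and no self-edges exist, and every gene is reachable from
    Root (directly or through other genes).
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset(map(tuple, self.edges)))
        if ROOT in genes:
            raise ValueError(f"{ROOT!r} is reserved and cannot be a gene name")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene names")
        known = set(genes) | {ROOT}
        for u, v in self.edges:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u!r}, {v!r}) uses unknown node")
            if v == ROOT:
                raise ValueError("edges into Root are not allowed")
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("restriction graph contains a cycle")
        reachable = nx.descendants(g, ROOT)
        missing = set(genes) - reachable
        if missing:
            raise ValueError(f"genes not reachable from Root: {sorted(missing)}")

    @property
    def m(self) -> int:
        return len(self.genes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(ROOT)
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g

    def gene_parents(self, gene: str) -> set[str]:
        """Non-Root parents of ``gene`` (the conjunctive requirements)."""
        return {u for u, v in self.edges if v == gene and u != ROOT}

    def gene_index(self) -> dict[str, int]:
        return {name: k for k, name in enumerate(self.genes)}


def from_edges(
    genes: Sequence[str], edges: Iterable[tuple[str, str]], complete_root: bool = True
) -> RestrictionDAG:
    """Build a DAG, optionally attaching parentless genes to Root."""
    edges = set(map(tuple, edges))
    if complete_root:
        with_parent = {v for _, v in edges}
        edges |= {(ROOT, g) for g in genes if g not in with_parent}
    return RestrictionDAG(tuple(genes), frozenset(edges))


def compatible_genotypes(dag: RestrictionDAG) -> set[int]:
    """All genotypes satisfying the DAG: every mutated gene has all its
    gene parents mutated.  WT (0) is trivially compatible."""
    idx = dag.gene_index()
    parent_masks = []
    for k, gene in enumerate(dag.genes):
        mask = 0
        for p in dag.gene_parents(gene):
            mask |= 1 << idx[p]
        parent_masks.append(mask)
    out = set()
    for g in range(2**dag.m):
        ok = True
        for k in range(dag.m):
            if g >> k & 1 and (g & parent_masks[k]) != parent_masks[k]:
                ok = False
                break
        if ok:
            out.add(g)
    return out


def transitive_reduction(dag: RestrictionDAG) -> RestrictionDAG:
    """Unique minimal edge set with the same reachability over the genes.

    Root edges are recomputed afterwards: exactly the genes left with no
    gene parent are attached to Root.  Idempotent.
    """
    g = nx.DiGraph()
    g.add_nodes_from(dag.genes)
    g.add_edges_from((u, v) for u, v in dag.edges if u != ROOT)
    red = nx.transitive_reduction(g)
    return from_edges(dag.genes, red.edges(), complete_root=True)


def dag_distance(
    d1: RestrictionDAG, d2: RestrictionDAG, include_root_edges: bool = True
) -> tuple[int, float]:
    """Edge distance between the transitive reductions of two DAGs.

    Returns ``(count, relative)``: the size of the symmetric difference of
    the reduced edge sets and that count divided by the size of their union.
    Identical reductions give ``(0, 0.0)``.  Root edges participate by
    default; with ``include_root_edges=False`` only gene-gene edges are
    compared.
    """
    if set(d1.genes) != set(d2.genes):
        raise ValueError("DAGs must share the same gene set")
    e1 = set(transitive_reduction(d1).edges)
    e2 = set(transitive_reduction(d2).edges)
    if not include_root_edges:
        e1 = {(u, v) for u, v in e1 if u != ROOT}
        e2 = {(u, v) for u, v in e2 if u != ROOT}
    diff = len(e1 ^ e2)
    union = len(e1 | e2)
    return diff, (diff / union if union else 0.0)


def is_representable(landscape: FitnessLandscape, dag: RestrictionDAG) -> bool:
    """True iff the landscape's accessible set equals the DAG's compatible set.

    Both sets include WT, so the comparison is consistent either way.  Gene
    names must match between the two objects (same genes, same order).
    """
    if tuple(landscape.gene_names) != tuple(dag.genes):
        raise ValueError(
            f"gene sets differ: {landscape.gene_names} vs {dag.genes}"
        )
    return accessible_genotypes(landscape) == compatible_genotypes(dag)


# ---------------------------------------------------------------------- I/O
# Edge-list dialect: one "parent child" pair per line, whitespace separated,
# the literal "Root" for the root node; '#' starts a comment.  The same
# format is used for fixtures and for importing DAGs inferred externally.


def write_dag(dag: RestrictionDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genes: {' '.join(dag.genes)}\n")
        for u, v in sorted(dag.edges):
            fh.write(f"{u} {v}\n")


def read_dag(path, genes: Sequence[str] | None = None) -> RestrictionDAG:
    """Read the edge-list dialect; malformed lines are reported with numbers.

    ``genes`` fixes the gene set (and order); when omitted it is taken from
    a ``# genes:`` header line if present, else from the edge endpoints in
    order of first appearance.
    """
    edges: list[tuple[str, str]] = []
    seen_genes: list[str] = []
    header_genes: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("genes:"):
                    header_genes = body[len("genes:"):].split()
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'parent child', got {line!r}"
                )
            u, v = parts
            for node in (u, v):
                if node != ROOT and node not in seen_genes:
                    seen_genes.append(node)
            edges.append((u, v))
    gene_order = list(genes) if genes is not None else (header_genes or seen_genes)
    unknown = {n for e in edges for n in e} - set(gene_order) - {ROOT}
    if unknown:
        raise ValueError(f"{path}: unknown gene names {sorted(unknown)}")
    dag = from_edges(gene_order, edges, complete_root=True)
    return dag
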
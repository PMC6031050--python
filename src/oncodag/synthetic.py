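"""Synthetic fixtures: canonical small landscapes and stand-in cohorts.

Everything the pipeline needs is generated programmatically, with no
external downloads:

* :func:`fig1_fixtures` builds the two canonical small DAG/landscape pairs
  used throughout the documentation and tests — a 5-gene DAG combining a
  direct dependency (A -> B) with an indirect chain (F -> G -> H), and a
  4-gene DAG with a conjunction (D requires both A and B) — plus a
  non-representable variant with one pairwise synthetic lethal knocked in.
* :func:`synthetic_cohort` simulates cross-sectional cohorts that stand in
  for empirical patient-by-gene matrices (e.g. pancreatic / colorectal /
  glioblastoma cohorts of 90 / 90 / 67 patients with at least one mutation
  in 7-8 genes).  The generating landscape is returned alongside, so
  ground truth stays available for recovery tests; the cohorts are
  synthetic stand-ins, not resamples of any published matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohorts import CohortMatrix
from .generate import (
    GenParams,
    dag_derived_landscape,
    generate_family,
    random_restriction_dag,
)
from .genotypes import FitnessLandscape
from .restrictions import ROOT, RestrictionDAG, from_edges
from .simulate import SimParams, simulate_to_detection, whole_tumor_sample, gene_mutation_rates

__all__ = ["CohortSpec", "fig1_fixtures", "synthetic_cohort"]


def fig1_fixtures() -> dict[str, tuple[RestrictionDAG, FitnessLandscape]]:
    """Canonical small DAG/landscape pairs at a fixed seed.

    Returns a mapping with three entries:

    * ``"chain"`` — genes A, B, F, G, H with edges Root->A, A->B, Root->F,
      F->G, G->H: a direct dependency plus an indirect chain.  Genotype
      {B} alone violates the restrictions; {A} and {A, B} satisfy them.
    * ``"conjunction"`` — genes A, B, C, D with Root->A, Root->B, Root->C,
      A->D, B->D: gene D requires both A and B, so {A, B, D} satisfies the
      restrictions while {A, D} does not.
    * ``"conjunction_knockout"`` — the conjunction landscape with genotype
      {A, C} made effectively lethal: a reciprocal-sign (synthetic-lethal)
      interaction no DAG of restrictions can represent.
    """
    rng = np.random.default_rng(20171018)
    chain_genes = ("A", "B", "F", "G", "H")
    chain = from_edges(
        chain_genes, [(ROOT, "A"), ("A", "B"), (ROOT, "F"), ("F", "G"), ("G", "H")]
    )
    chain_params = GenParams(m=5, gene_names=chain_genes)
    chain_landscape = dag_derived_landscape(chain, chain_params, rng)

    conj_genes = ("A", "B", "C", "D")
    conj = from_edges(
        conj_genes, [(ROOT, "A"), (ROOT, "B"), (ROOT, "C"), ("A", "D"), ("B", "D")]
    )
    conj_params = GenParams(m=4, gene_names=conj_genes)
    conj_landscape = dag_derived_landscape(conj, conj_params, rng)

    # knock out {A, C}: bits 0 (A) and 2 (C)
    ac = (1 << 0) | (1 << 2)
    knocked = conj_landscape.with_fitness({ac: conj_params.lethal_fitness})

    return {
        "chain": (chain, chain_landscape),
        "conjunction": (conj, conj_landscape),
        "conjunction_knockout": (conj, knocked),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic stand-in cohort.

    ``n_patients`` samples over ``m`` genes are simulated from ``source``
    (a generating landscape; drawn at random from ``family`` when omitted).
    With ``require_nonzero`` (default, matching the empirical cohorts'
    "at least one mutation" inclusion rule) all-zero samples are discarded
    and redrawn.
    """

    n_patients: int = 90
    m: int = 7
    family: str = "nonrepresentable"
    require_nonzero: bool = True
    seed: int | None = None


def synthetic_cohort(
    spec: CohortSpec,
    source: FitnessLandscape | None = None,
    sim_params: SimParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CohortMatrix, FitnessLandscape, RestrictionDAG | None]:
    """Simulate a stand-in patient cohort with its ground truth.

    Returns ``(cohort, landscape, generating_dag)``; the DAG is None when
    the source landscape was supplied or is not DAG-derived.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sim_params = sim_params or SimParams()
    dag = None
    if source is None:
        params = GenParams(m=spec.m)
        ((source, dag),) = generate_family(spec.family, 1, params, rng)
    rates = gene_mutation_rates(source.m, sim_params.mutation_scheme, rng)
    genotypes: list[int] = []
    max_draws = 20 * spec.n_patients
    draws = 0
    while len(genotypes) < spec.n_patients:
        if draws >= max_draws:
            raise RuntimeError(
                "could not collect enough samples with >= 1 mutation: "
                f"{len(genotypes)}/{spec.n_patients} after {draws} draws"
            )
        draws += 1
        pop = simulate_to_detection(source, sim_params, rng, rates=rates)
        g = whole_tumor_sample(pop, sim_params.sample_threshold)
        if g == 0 and spec.require_nonzero:
            continue
        genotypes.append(g)
    cohort = CohortMatrix.from_genotype_ints(source.gene_names, genotypes)
    return cohort, source, dag
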
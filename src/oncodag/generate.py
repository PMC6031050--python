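"""Random fitness-landscape generators.

Three families over ``m`` biallelic driver genes:

* **DAG-derived, representable** — a random transitively reduced DAG of
  restrictions; genotypes satisfying the DAG get a multiplicative fitness
  ``prod_i (1 + s_i)`` over their mutated genes (per-gene effects drawn
  uniformly), genotypes violating it get a lethal fitness.  By construction
  the accessible set equals the DAG's compatible set.
* **DAG-derived, non-representable** — a representable landscape in which a
  random subset of accessible multi-mutant genotypes is knocked out
  (synthetic lethals), introducing reciprocal sign epistasis.
* **Rough Mount Fuji (RMF)** — an additive slope away from a random
  reference genotype plus i.i.d. house-of-cards noise, spanning close-to
  -additive through fully uncorrelated landscapes.

A fourth, cohort-matched RMF family guarantees that every genotype observed
in an empirical cohort is accessible, for the landscape-matching loop.

Every generated landscape is checked so that each gene appears in at least
one accessible genotype; draws failing the check are rejected and retried.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .cohorts import CohortMatrix
from .genotypes import FitnessLandscape, accessible_genotypes, popcount
from .restrictions import (
    ROOT,
    RestrictionDAG,
    compatible_genotypes,
    from_edges,
    transitive_reduction,
)

__all__ = [
    "GenParams",
    "default_gene_names",
    "random_restriction_dag",
    "dag_derived_landscape",
    "make_non_representable",
    "rmf_landscape",
    "matched_rmf_landscape",
    "generate_family",
]


def default_gene_names(m: int) -> tuple[str, ...]:
    letters = string.ascii_uppercase
    if m <= len(letters):
        return tuple(letters[:m])
    return tuple(f"G{k}" for k in range(m))


@dataclass(frozen=True)
class GenParams:
    """Parameters of the landscape generators.

    ``s_range`` is the uniform support of per-gene multiplicative fitness
    effects of the DAG-derived family.  ``edge_prob`` is the probability of
    including each forward edge when drawing a random DAG.  The RMF fields
    control the Rough Mount Fuji family: the per-landscape distance slope is
    drawn uniformly from ``rmf_slope_range`` while the house-of-cards noise
    is standard normal scaled by ``rmf_noise_scale``; ``rmf_birth_scale`` is
    the rank-preserving exponential scale mapping raw RMF values to positive
    birth rates (WT normalized to 1).
    """

    m: int = 7
    gene_names: tuple[str, ...] | None = None
    s_range: tuple[float, float] = (0.1, 0.7)
    lethal_fitness: float = 1e-9
    edge_prob: float = 0.3
    rmf_slope_range: tuple[float, float] = (0.0, 1.25)
    rmf_noise_scale: float = 1.0
    rmf_birth_scale: float = 0.3
    knockout_frac_range: tuple[float, float] = (0.12, 1.0)
    matched_bump_range: tuple[float, float] = (0.01, 0.1)
    max_retries: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be positive")
        if not (0 < self.s_range[0] <= self.s_range[1]):
            raise ValueError("s_range must lie in (0, inf)")
        if not (0 < self.lethal_fitness < 1):
            raise ValueError("lethal_fitness must be in (0, 1)")
        if self.gene_names is not None and len(self.gene_names) != self.m:
            raise ValueError("gene_names length must equal m")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.gene_names or default_gene_names(self.m)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_file(cls, path) -> "GenParams":
        """Load parameters from a YAML or JSON mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("s_range", "rmf_slope_range", "matched_bump_range", "gene_names"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _resolve_rng(
    params: GenParams, rng: np.random.Generator | None
) -> np.random.Generator:
    return rng if rng is not None else params.rng()


def random_restriction_dag(
    params: GenParams, rng: np.random.Generator | None = None
) -> RestrictionDAG:
    """Draw a random transitively reduced DAG of restrictions.

    Construction: draw a uniform random topological order of the genes,
    include each forward edge independently with probability ``edge_prob``,
    attach parentless genes to Root, and transitively reduce.  This spans
    structures from fully independent genes through dense conjunctions.
    """
    if params.m < 2:
        raise ValueError("random_restriction_dag needs m >= 2")
    rng = _resolve_rng(params, rng)
    genes = params.genes
    order = rng.permutation(params.m)
    edges = []
    for a in range(params.m):
        for b in range(a + 1, params.m):
            if rng.random() < params.edge_prob:
                edges.append((genes[order[a]], genes[order[b]]))
    return transitive_reduction(from_edges(genes, edges, complete_root=True))


def dag_derived_landscape(
    dag: RestrictionDAG,
    params: GenParams | None = None,
    rng: np.random.Generator | None = None,
) -> FitnessLandscape:
    """Representable landscape from a DAG via a multiplicative fitness model.

    Genotypes compatible with the DAG get ``prod_i (1 + s_i)`` over their
    mutated genes with ``s_i ~ U(s_range)``; incompatible genotypes get
    ``lethal_fitness`` so they are effectively never visited.  The result
    satisfies ``is_representable(landscape, dag)``.
    """
    params = params or GenParams(m=dag.m, gene_names=dag.genes)
    rng = _resolve_rng(params, rng)
    m = dag.m
    s = rng.uniform(*params.s_range, size=m)
    compat = compatible_genotypes(dag)
    fit = np.full(2**m, params.lethal_fitness)
    log1s = np.log1p(s)
    for g in compat:
        acc = 0.0
        for k in range(m):
            if g >> k & 1:
                acc += log1s[k]
        fit[g] = np.exp(acc)
    return FitnessLandscape(dag.genes, fit, lethal_threshold=params.lethal_fitness)


def _gene_coverage_ok(landscape: FitnessLandscape) -> bool:
    """Every gene mutated in at least one accessible genotype."""
    acc = accessible_genotypes(landscape)
    mask = 0
    for g in acc:
        mask |= g
    return mask == (1 << landscape.m) - 1


def make_non_representable(
    landscape: FitnessLandscape,
    dag: RestrictionDAG,
    params: GenParams | None = None,
    rng: np.random.Generator | None = None,
) -> FitnessLandscape:
    """Knock out a random subset of accessible multi-mutants (synthetic lethals).

    The subset is drawn from genotypes with two or more mutations that are
    accessible in the input landscape; its size is uniform over
    ``knockout_frac_range`` times the number of eligible genotypes (at least
    one).  The draw is rejected and retried if any gene would no longer
    appear in an accessible genotype.  A non-empty removal always breaks
    representability against the generating DAG.  For some DAG shapes (e.g.
    pure chains) no knockout preserves gene coverage; a RuntimeError is then
    raised and callers should redraw the DAG/landscape pair.
    """
    params = params or GenParams(m=landscape.m, gene_names=landscape.gene_names)
    rng = _resolve_rng(params, rng)
    eligible = sorted(
        g for g in accessible_genotypes(landscape) if popcount(g) >= 2
    )
    if not eligible:
        return landscape
    lo_f, hi_f = params.knockout_frac_range
    lo = max(1, int(np.ceil(len(eligible) * lo_f)))
    hi = max(lo, int(len(eligible) * hi_f))
    for _ in range(params.max_retries):
        size = int(rng.integers(lo, hi + 1))
        removed = rng.choice(len(eligible), size=size, replace=False)
        knocked = landscape.with_fitness(
            {eligible[i]: params.lethal_fitness for i in removed}
        )
        if _gene_coverage_ok(knocked):
            return knocked
    raise RuntimeError(
        "could not find a knockout subset keeping every gene accessible "
        f"after {params.max_retries} retries"
    )


def rmf_landscape(
    params: GenParams | None = None, rng: np.random.Generator | None = None
) -> FitnessLandscape:
    """Draw a Rough Mount Fuji landscape.

    Raw value ``F(g) = -c * d(g, reference) + eps_g`` with the reference
    genotype uniform over all ``2**m`` genotypes, slope
    ``c ~ U(rmf_slope_range)`` and ``eps_g`` i.i.d. normal with standard
    deviation ``rmf_noise_scale``.  Raw values are mapped to positive birth
    rates by ``exp(rmf_birth_scale * (F - F(WT)))`` — a strictly monotone
    transform, so accessibility, peaks and epistasis sign classes depend
    only on the RMF ranks — giving WT fitness exactly 1.  Draws where some
    gene appears in no accessible genotype are rejected and retried.
    """
    params = params or GenParams()
    rng = _resolve_rng(params, rng)
    m = params.m
    n = 2**m
    for _ in range(params.max_retries):
        ref = int(rng.integers(n))
        c = rng.uniform(*params.rmf_slope_range)
        dist = np.array([popcount(g ^ ref) for g in range(n)], dtype=float)
        raw = -c * dist + rng.normal(0.0, params.rmf_noise_scale, size=n)
        fit = np.exp(params.rmf_birth_scale * (raw - raw[0]))
        landscape = FitnessLandscape(
            params.genes, fit, lethal_threshold=params.lethal_fitness
        )
        if _gene_coverage_ok(landscape):
            return landscape
    raise RuntimeError(
        f"no RMF draw passed the gene-coverage check in {params.max_retries} tries"
    )


def generate_family(
    family: str,
    n: int,
    params: GenParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[FitnessLandscape, RestrictionDAG | None]]:
    """Draw ``n`` landscapes from one of the three study families.

    ``family`` is one of ``"representable"`` (DAG-derived),
    ``"nonrepresentable"`` (DAG-derived with knockouts) or ``"rmf"``.  For
    the DAG-derived families the generating DAG is returned alongside each
    landscape (``None`` for RMF).  Draws for which no valid knockout exists
    are transparently redrawn.
    """
    params = params or GenParams()
    rng = _resolve_rng(params, rng)
    knock_params = replace(params, max_retries=100)
    out: list[tuple[FitnessLandscape, RestrictionDAG | None]] = []
    while len(out) < n:
        if family == "rmf":
            out.append((rmf_landscape(params, rng), None))
            continue
        dag = random_restriction_dag(params, rng)
        landscape = dag_derived_landscape(dag, params, rng)
        if family == "representable":
            out.append((landscape, dag))
        elif family == "nonrepresentable":
            try:
                out.append((make_non_representable(landscape, dag, knock_params, rng), dag))
            except RuntimeError:
                continue  # chain-like DAG with no coverage-preserving knockout
        else:
            raise ValueError(f"unknown landscape family {family!r}")
    return out


def _random_chain(g: int, m: int, rng: np.random.Generator) -> list[int]:
    """A uniformly random maximal chain WT -> ... -> g adding one locus at a time."""
    loci = [k for k in range(m) if g >> k & 1]
    rng.shuffle(loci)
    chain = [0]
    cur = 0
    for k in loci:
        cur |= 1 << k
        chain.append(cur)
    return chain


def matched_rmf_landscape(
    observed: CohortMatrix,
    params: GenParams | None = None,
    rng: np.random.Generator | None = None,
) -> FitnessLandscape:
    """RMF landscape in which every observed cohort genotype is accessible.

    Starts from a plain RMF draw over the cohort's genes, then, for each
    distinct non-WT genotype in the cohort, picks one uniformly random
    maximal chain WT -> ... -> g and raises any non-increasing step to
    ``previous * (1 + delta)`` with ``delta ~ U(matched_bump_range)``.
    Because bumps on one chain can in principle disturb another, the full
    accessibility constraint is re-verified and the draw retried on failure.
    """
    if observed.n_samples == 0:
        raise ValueError("observed cohort is empty")
    params = params or GenParams(m=observed.m, gene_names=observed.gene_names)
    if params.m != observed.m:
        params = replace(params, m=observed.m, gene_names=observed.gene_names)
    rng = _resolve_rng(params, rng)
    targets = sorted(set(observed.genotype_ints()) - {0})
    for _ in range(params.max_retries):
        base = rmf_landscape(params, rng)
        fit = base.fitness.copy()
        for g in targets:
            chain = _random_chain(int(g), params.m, rng)
            for prev, nxt in zip(chain, chain[1:]):
                if fit[nxt] <= fit[prev]:
                    fit[nxt] = fit[prev] * (1.0 + rng.uniform(*params.matched_bump_range))
        landscape = FitnessLandscape(
            params.genes, fit, lethal_threshold=params.lethal_fitness
        )
        acc = accessible_genotypes(landscape)
        if all(g in acc for g in targets) and _gene_coverage_ok(landscape):
            return landscape
    raise RuntimeError(
        "matched RMF generation failed: observed genotypes could not all be "
        f"made accessible in {params.max_retries} tries"
    )
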
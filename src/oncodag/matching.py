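"""Finding fitness landscapes that reproduce an observed cohort.

Empirical cross-sectional datasets do not come with their true fitness
landscape.  The matching loop searches for (landscape, simulation-setting)
pairs whose simulated genotype frequencies are statistically
indistinguishable from the observed ones: candidate cohort-matched RMF
landscapes are drawn, each simulated several times at the observed sample
size, and a candidate is accepted when enough repetitions produce a large
chi-squared p-value (both the asymptotic reference distribution and a
permutation test, guarding against low-count cells) while every gene is
observed mutated.  Accepted landscapes are typically *very* different from
one another even though they match the same data — the many-to-one side of
the many-to-many phenomenon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohorts import CohortMatrix
from .generate import GenParams, matched_rmf_landscape
from .genotypes import FitnessLandscape
from .simulate import (
    DETECTION_REGIMES,
    MUTATION_SCHEMES,
    SimParams,
    simulate_to_detection,
    whole_tumor_sample,
    gene_mutation_rates,
)

__all__ = [
    "MatchCriteria",
    "genotype_chi2_test",
    "simulate_mutated_cohort",
    "find_matched_landscapes",
    "MatchedLandscape",
]


@dataclass(frozen=True)
class MatchCriteria:
    """Acceptance thresholds of the matching loop.

    A candidate is accepted when at least ``min_pass`` of ``n_reps``
    simulated datasets have both chi-squared p-values above ``p_threshold``
    and (if ``require_all_genes``) every gene mutated in at least one
    simulated sample.
    """

    n_reps: int = 10
    min_pass: int = 3
    p_threshold: float = 0.6
    n_perm: int = 1000
    require_all_genes: bool = True

    def __post_init__(self) -> None:
        # min_pass = 0 with p_threshold = 0 is allowed as the vacuous
        # accept-everything setting (useful for plumbing tests)
        if not (0 <= self.min_pass <= self.n_reps):
            raise ValueError("need 0 <= min_pass <= n_reps")
        if not (0 <= self.p_threshold < 1):
            raise ValueError("p_threshold must be in [0, 1)")


def _chi2_stat(table: np.ndarray) -> float:
    """Pearson chi-squared statistic of a 2 x k count table (no correction)."""
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def genotype_chi2_test(
    observed: CohortMatrix,
    simulated: CohortMatrix,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Compare two cohorts' genotype distributions.

    Builds a 2 x k contingency table over the distinct genotypes present in
    either cohort and returns ``(p_asymptotic, p_permutation)``: the
    chi-squared reference p-value and a label-shuffling permutation p-value
    computed with the add-one estimator ``(1 + #{stat* >= stat}) /
    (n_perm + 1)``.  The permutation test is the remedy for sparse cells;
    no pooling of low-count categories is done.
    """
    if observed.n_samples == 0 or simulated.n_samples == 0:
        raise ValueError("both cohorts must be non-empty")
    if observed.gene_names != simulated.gene_names:
        raise ValueError("cohorts must share the same genes")
    g_obs = observed.genotype_ints()
    g_sim = simulated.genotype_ints()
    cats = np.unique(np.concatenate([g_obs, g_sim]))
    cat_index = {g: k for k, g in enumerate(cats)}
    k = len(cats)
    table = np.zeros((2, k))
    for g in g_obs:
        table[0, cat_index[g]] += 1
    for g in g_sim:
        table[1, cat_index[g]] += 1
    stat = _chi2_stat(table)
    dof = k - 1
    if dof == 0:
        return 1.0, 1.0
    p_asym = float(stats.chi2.sf(stat, dof)) if stat > 0 else 1.0

    rng = rng if rng is not None else np.random.default_rng()
    pooled = np.concatenate([g_obs, g_sim])
    n1 = len(g_obs)
    codes = np.array([cat_index[g] for g in pooled])
    hits = 0
    total_counts = np.bincount(codes, minlength=k).astype(float)
    for _ in range(n_perm):
        rng.shuffle(codes)
        c1 = np.bincount(codes[:n1], minlength=k).astype(float)
        t = np.stack([c1, total_counts - c1])
        if _chi2_stat(t) >= stat - 1e-12:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return p_asym, p_perm


def simulate_mutated_cohort(
    landscape: FitnessLandscape,
    params: SimParams,
    n_samples: int,
    rng: np.random.Generator,
    max_draws: int | None = None,
) -> CohortMatrix:
    """Simulate tumors until ``n_samples`` samples with >= 1 mutation.

    The empirical cohorts contain only patients with at least one mutation,
    so whole-tumor samples that call no mutation (WT consensus) are
    discarded and redrawn.
    """
    max_draws = max_draws or 20 * n_samples
    rates = gene_mutation_rates(landscape.m, params.mutation_scheme, rng)
    out: list[int] = []
    for _ in range(max_draws):
        if len(out) >= n_samples:
            break
        pop = simulate_to_detection(landscape, params, rng, rates=rates)
        g = whole_tumor_sample(pop, params.sample_threshold)
        if g != 0:
            out.append(g)
    if len(out) < n_samples:
        raise RuntimeError(
            f"only {len(out)}/{n_samples} mutated samples in {max_draws} draws"
        )
    return CohortMatrix.from_genotype_ints(landscape.gene_names, out)


@dataclass
class MatchedLandscape:
    """One accepted candidate with its settings and per-repetition log."""

    landscape: FitnessLandscape
    sim_params: SimParams
    p_values: list[tuple[float, float]]
    all_genes_seen: list[bool]
    n_passed: int


def _random_sim_params(rng: np.random.Generator, base: SimParams) -> SimParams:
    """Random mutation scheme and detection regime from the study menu."""
    from dataclasses import replace

    return replace(
        base,
        mutation_scheme=str(rng.choice(MUTATION_SCHEMES)),
        detection_regime=str(rng.choice(DETECTION_REGIMES)),
    )


def find_matched_landscapes(
    observed: CohortMatrix,
    criteria: MatchCriteria | None = None,
    n_target: int = 5,
    gen_params: GenParams | None = None,
    base_sim_params: SimParams | None = None,
    rng: np.random.Generator | None = None,
    max_candidates: int | None = None,
) -> list[MatchedLandscape]:
    """Search for landscapes producing data similar to ``observed``.

    Repeatedly draws cohort-matched RMF landscapes with randomly selected
    mutation/detection settings, simulates ``criteria.n_reps`` cohorts of
    the observed size, and keeps candidates meeting the acceptance
    criteria, until ``n_target`` are accepted.  The acceptance decision is
    a deterministic function of the logged p-values and gene-coverage
    flags.  Aborts with diagnostics when more than ``max_candidates``
    candidates have been tried (default ``50 * n_target``), i.e. when the
    acceptance rate is too low for the search to be viable.
    """
    criteria = criteria or MatchCriteria()
    rng = rng if rng is not None else np.random.default_rng()
    gen_params = gen_params or GenParams(
        m=observed.m, gene_names=observed.gene_names
    )
    base_sim_params = base_sim_params or SimParams()
    max_candidates = max_candidates or 50 * n_target
    n_obs = observed.drop_wildtype().n_samples
    accepted: list[MatchedLandscape] = []
    tried = 0
    while len(accepted) < n_target:
        if tried >= max_candidates:
            raise RuntimeError(
                f"acceptance rate too low: {len(accepted)}/{tried} candidates "
                f"accepted (target {n_target})"
            )
        tried += 1
        landscape = matched_rmf_landscape(observed, gen_params, rng)
        sim_params = _random_sim_params(rng, base_sim_params)
        p_values: list[tuple[float, float]] = []
        genes_seen: list[bool] = []
        n_passed = 0
        for _ in range(criteria.n_reps):
            try:
                sim = simulate_mutated_cohort(landscape, sim_params, n_obs, rng)
            except RuntimeError:
                p_values.append((0.0, 0.0))
                genes_seen.append(False)
                continue
            p_a, p_p = genotype_chi2_test(
                observed.drop_wildtype(), sim, criteria.n_perm, rng
            )
            seen = bool(sim.matrix.any(axis=0).all())
            p_values.append((p_a, p_p))
            genes_seen.append(seen)
            ok = p_a > criteria.p_threshold and p_p > criteria.p_threshold
            if criteria.require_all_genes:
                ok = ok and seen
            if ok:
                n_passed += 1
        if n_passed >= criteria.min_pass:
            accepted.append(
                MatchedLandscape(landscape, sim_params, p_values, genes_seen, n_passed)
            )
    return accepted
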
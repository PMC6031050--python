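"""Continuous-time clonal birth-death simulation of tumor progression.

The model follows the logistic-like McFarland-style parameterization used
throughout the cancer progression literature:

* each cell of genotype ``g`` divides at rate ``f(g)`` — the landscape
  fitness *is* the birth rate, WT = 1;
* every cell dies at the density-dependent rate
  ``D(N) = log(1 + N / K)`` with ``K = N0 / (e - 1)``, so that
  ``D(N0) = 1`` and the initial WT population starts at equilibrium;
* at each division the daughter independently acquires a mutation in every
  still-unmutated gene ``i`` with probability ``u_i`` (no back mutation);
* the tumor is screened every ``check_interval`` time units (default 20)
  and detected with probability ``p(N) = 1 - exp(-k * max(0, N / N0 - 1))``,
  increasing in tumor size; ``k`` is calibrated so that ``p(2 N0)`` is 0.1
  under the "fast" detection regime and 0.01 under "slow".  Populations
  reaching ``max_size`` are returned immediately (p is numerically 1 there).

At detection a whole-tumor sample is taken: a gene is called mutated when
the fraction of cells carrying it reaches a threshold (default 0.5), giving
a single consensus genotype per tumor — the cross-sectional observation a
cancer progression model consumes.

Two stochastic backends are provided: an exact clone-level Gillespie
simulation and a tau-leaping approximation; simulations switch from exact
to tau-leaping once the population exceeds a size threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .cohorts import CohortMatrix
from .genotypes import FitnessLandscape

__all__ = [
    "SimParams",
    "TumorPopulation",
    "gene_mutation_rates",
    "simulate_to_detection",
    "simulate_fixed_time",
    "whole_tumor_sample",
    "simulate_dataset",
    "MUTATION_SCHEMES",
    "DETECTION_REGIMES",
]

MUTATION_SCHEMES = ("common_1e-5", "common_1e-6", "variable")
DETECTION_REGIMES = ("fast", "slow")

# detection probability at N = 2*N0 for each regime
_DETECTION_ANCHOR = {"fast": 0.1, "slow": 0.01}


@dataclass(frozen=True)
class SimParams:
    """Parameters of one evolutionary run.

    ``mutation_scheme`` selects the per-gene mutation rates (see
    :func:`gene_mutation_rates`); ``detection_regime`` sets how aggressively
    growing tumors are screened.  ``sample_threshold`` is the cell fraction
    at which a mutation is called in the whole-tumor sample.
    ``exact_below`` is the population size under which the exact Gillespie
    backend is used before switching to tau-leaping (0 = always tau-leap).
    """

    N0: int = 2000
    mutation_scheme: str = "common_1e-5"
    detection_regime: str = "fast"
    sample_threshold: float = 0.5
    max_attempts: int = 100
    max_time: float = 20000.0
    max_size: float = 5e6
    tau: float = 0.1
    exact_below: int = 0
    check_interval: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if not (0 < self.sample_threshold <= 1):
            raise ValueError("sample_threshold must be in (0, 1]")
        if self.mutation_scheme not in MUTATION_SCHEMES:
            raise ValueError(f"unknown mutation scheme {self.mutation_scheme!r}")
        if self.detection_regime not in DETECTION_REGIMES:
            raise ValueError(f"unknown detection regime {self.detection_regime!r}")

    @property
    def K(self) -> float:
        """Carrying-capacity scale of the death rate; D(N0) = 1."""
        return self.N0 / (math.e - 1.0)

    @property
    def detection_k(self) -> float:
        """Hazard coefficient forcing p(detect | N = 2 N0) to the regime anchor."""
        return -math.log1p(-_DETECTION_ANCHOR[self.detection_regime])

    def death_rate(self, N: float) -> float:
        return math.log1p(N / self.K)

    def detection_prob(self, N: float) -> float:
        return 1.0 - math.exp(-self.detection_k * max(0.0, N / self.N0 - 1.0))


@dataclass
class TumorPopulation:
    """Set of clones (genotype -> cell count) at a moment in time."""

    gene_names: tuple[str, ...]
    clones: dict[int, int]
    t: float = 0.0
    attempts: int = 1  # extinction restarts consumed, including this run

    @property
    def N(self) -> int:
        return sum(self.clones.values())

    def mutation_fractions(self) -> np.ndarray:
        """Per-gene fraction of cells carrying the mutation."""
        m = len(self.gene_names)
        counts = np.zeros(m)
        total = 0
        for g, n in self.clones.items():
            total += n
            for k in range(m):
                if g >> k & 1:
                    counts[k] += n
        if total == 0:
            raise ValueError("empty population")
        return counts / total


def gene_mutation_rates(
    m: int, scheme: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-gene mutation rates for one of the three schemes.

    ``common_1e-5`` and ``common_1e-6`` are constant vectors.  ``variable``
    returns ``m`` gene-specific rates geometrically spaced from 2e-6 to 5e-5
    inclusive — maximum spread between successive values within those
    bounds, with geometric mean exactly 1e-5 (``sqrt(2e-6 * 5e-5)``) —
    randomly assigned to genes when an ``rng`` is supplied.
    """
    if scheme == "common_1e-5":
        return np.full(m, 1e-5)
    if scheme == "common_1e-6":
        return np.full(m, 1e-6)
    if scheme == "variable":
        rates = np.geomspace(2e-6, 5e-5, num=m)
        if rng is not None:
            rates = rng.permutation(rates)
        return rates
    raise ValueError(f"unknown mutation scheme {scheme!r}")


def _spawn_mutants(
    g: int,
    n_births: int,
    rates: np.ndarray,
    free_mask: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Mutated daughters among ``n_births`` divisions of clone ``g``.

    Each daughter mutates each still-unmutated gene independently; because
    per-gene probabilities are tiny, at most one new mutation per division
    is drawn (multiple simultaneous hits are negligible at these rates).
    """
    m = rates.shape[0]
    free = [k for k in range(m) if free_mask >> k & 1]
    if not free or n_births == 0:
        return {}
    u = np.array([rates[k] for k in free])
    total_u = float(u.sum())
    n_mut = rng.binomial(n_births, min(1.0, total_u))
    if n_mut == 0:
        return {}
    out: dict[int, int] = {}
    picks = rng.choice(len(free), size=n_mut, p=u / total_u)
    for idx in picks:
        h = g | (1 << free[idx])
        out[h] = out.get(h, 0) + 1
    return out


def _step_tau(
    clones: dict[int, int],
    fit: np.ndarray,
    rates: np.ndarray,
    params: SimParams,
    tau: float,
    rng: np.random.Generator,
    full_mask: int,
) -> None:
    """One tau-leap update of ``clones`` in place."""
    N = sum(clones.values())
    if N == 0:
        return
    D = params.death_rate(N)
    deltas: dict[int, int] = {}
    for g, n in clones.items():
        births = int(rng.poisson(n * fit[g] * tau))
        deaths = min(int(rng.poisson(n * D * tau)), n + births)
        mutants = _spawn_mutants(g, births, rates, full_mask & ~g, rng)
        n_mut = sum(mutants.values())
        deltas[g] = deltas.get(g, 0) + births - n_mut - deaths
        for h, c in mutants.items():
            deltas[h] = deltas.get(h, 0) + c
    for g, d in deltas.items():
        n = clones.get(g, 0) + d
        if n > 0:
            clones[g] = n
        else:
            clones.pop(g, None)


def _step_exact(
    clones: dict[int, int],
    fit: np.ndarray,
    rates: np.ndarray,
    params: SimParams,
    t: float,
    t_end: float,
    rng: np.random.Generator,
    full_mask: int,
) -> float:
    """Exact Gillespie events until ``t_end`` (or extinction); returns time."""
    while t < t_end:
        genos = list(clones.keys())
        counts = np.array([clones[g] for g in genos], dtype=float)
        N = counts.sum()
        if N == 0:
            return t_end
        D = params.death_rate(N)
        birth_rates = counts * fit[genos]
        death_rates = counts * D
        total = float(birth_rates.sum() + death_rates.sum())
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            return t_end
        r = rng.uniform(0, total)
        cum = 0.0
        for i, g in enumerate(genos):
            cum += birth_rates[i]
            if r < cum:
                # division; the daughter may acquire one new mutation
                mutants = _spawn_mutants(g, 1, rates, full_mask & ~g, rng)
                if mutants:
                    ((h, _),) = mutants.items()
                    clones[h] = clones.get(h, 0) + 1
                else:
                    clones[g] += 1
                break
            cum += death_rates[i]
            if r < cum:
                clones[g] -= 1
                if clones[g] == 0:
                    del clones[g]
                break
    return t_end


def _run_once(
    landscape: FitnessLandscape,
    rates: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    stop: Literal["detection", "time"],
    t_end: float,
) -> TumorPopulation | None:
    """One trajectory; returns None on extinction (caller restarts)."""
    fit = landscape.fitness
    full_mask = (1 << landscape.m) - 1
    clones: dict[int, int] = {0: params.N0}
    t = 0.0
    horizon = t_end if stop == "time" else params.max_time
    while t < horizon:
        t_next = min(horizon, t + params.check_interval)
        N = sum(clones.values())
        if N == 0:
            return None
        if N < params.exact_below:
            t = _step_exact(clones, fit, rates, params, t, t_next, rng, full_mask)
        else:
            # sub-steps sized so the net growth within a leap stays modest
            # (aggregated clone birth/death counts are exactly Poisson given
            # constant rates; the leap error comes from holding D(N) fixed)
            seg = t_next - t
            fmax = max(float(fit[g]) for g in clones)
            growth = max(abs(fmax - params.death_rate(N)), 1.0)
            tau = min(params.tau, 0.1 / growth)
            n_sub = max(1, int(math.ceil(seg / tau)))
            tau = seg / n_sub
            for _ in range(n_sub):
                _step_tau(clones, fit, rates, params, tau, rng, full_mask)
                if not clones:
                    return None
                if (
                    stop == "detection"
                    and sum(clones.values()) >= params.max_size
                ):
                    # p(detection) is indistinguishable from 1 at this size
                    return TumorPopulation(landscape.gene_names, clones, t=t)
            t = t_next
        if not clones:
            return None
        if stop == "detection":
            if rng.random() < params.detection_prob(sum(clones.values())):
                return TumorPopulation(landscape.gene_names, clones, t=t)
    if stop == "time":
        return TumorPopulation(landscape.gene_names, clones, t=horizon)
    raise RuntimeError(
        f"tumor not detected within max_time={params.max_time}; "
        "landscape may have no beneficial mutation reachable from WT"
    )


def simulate_to_detection(
    landscape: FitnessLandscape,
    params: SimParams,
    rng: np.random.Generator | None = None,
    rates: np.ndarray | None = None,
) -> TumorPopulation:
    """Run one tumor from ``N0`` WT cells until stochastic detection.

    The returned population carries the elapsed time, the clone composition
    at detection, and the number of extinction restarts consumed.  Raises
    after ``max_attempts`` extinctions.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if rates is None:
        rates = gene_mutation_rates(landscape.m, params.mutation_scheme, rng)
    for attempt in range(1, params.max_attempts + 1):
        pop = _run_once(landscape, rates, params, rng, "detection", params.max_time)
        if pop is not None:
            pop.attempts = attempt
            return pop
    raise RuntimeError(
        f"population went extinct in all {params.max_attempts} attempts"
    )


def simulate_fixed_time(
    landscape: FitnessLandscape,
    params: SimParams,
    t_end: float,
    rng: np.random.Generator | None = None,
    rates: np.ndarray | None = None,
    allow_extinction: bool = True,
) -> TumorPopulation:
    """Run one trajectory to a fixed horizon with no detection.

    Used for diagnostics (neutral-equilibrium checks) and for comparing the
    exact and tau-leaping backends in distribution.  Extinct populations
    come back with an empty clone map when ``allow_extinction`` is set.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if rates is None:
        rates = gene_mutation_rates(landscape.m, params.mutation_scheme, rng)
    pop = _run_once(landscape, rates, params, rng, "time", t_end)
    if pop is None:
        if allow_extinction:
            return TumorPopulation(landscape.gene_names, {}, t=t_end)
        raise RuntimeError("population went extinct")
    return pop


def whole_tumor_sample(pop: TumorPopulation, threshold: float = 0.5) -> int:
    """Consensus genotype of a whole-tumor sample.

    Gene ``i`` is called mutated iff the fraction of cells carrying the
    mutation is at least ``threshold``.
    """
    if pop.N == 0:
        raise ValueError("cannot sample an empty population")
    fracs = pop.mutation_fractions()
    g = 0
    for k, frac in enumerate(fracs):
        if frac >= threshold:
            g |= 1 << k
    return g


def simulate_dataset(
    landscape: FitnessLandscape,
    params: SimParams,
    n_samples: int,
    rng: np.random.Generator | None = None,
    return_log: bool = False,
):
    """Draw ``n_samples`` independent tumors, sampling each at detection.

    Returns a :class:`CohortMatrix`; with ``return_log`` also a per-sample
    provenance table (detection time, final size, restart count) as a list
    of dicts.  Under the ``variable`` mutation scheme the random assignment
    of rates to genes is drawn once per dataset, not per tumor.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rates = gene_mutation_rates(landscape.m, params.mutation_scheme, rng)
    genotypes = []
    log = []
    for i in range(n_samples):
        pop = simulate_to_detection(landscape, params, rng, rates=rates)
        g = whole_tumor_sample(pop, params.sample_threshold)
        genotypes.append(g)
        if return_log:
            log.append(
                {
                    "sample": i,
                    "genotype": g,
                    "detection_time": pop.t,
                    "final_size": pop.N,
                    "attempts": pop.attempts,
                }
            )
    cohort = CohortMatrix.from_genotype_ints(landscape.gene_names, genotypes)
    return (cohort, log) if return_log else cohort
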
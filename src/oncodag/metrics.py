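"""Performance and variability measures relating DAGs and landscapes.

Genotype misprediction of a DAG of restrictions against the true fitness
landscape is summarized by two fractions (WT is excluded from every set,
since only genotypes *with* mutations are predictions):

* **PFD** (proportion of false discoveries, 1 - precision): genotypes the
  DAG predicts to exist that are not accessible in the landscape, over all
  genotypes the DAG predicts to exist.
* **PND** (proportion of negative discoveries, 1 - recall): accessible
  genotypes the DAG fails to predict, over the accessible reference set.
  Because a genotype may be accessible yet essentially unobservable under a
  given mutation rate and detection regime, the reference set is restricted
  to accessible genotypes observed above a frequency floor in a large
  simulated cohort (:func:`observable_accessible`).

Replicate-to-replicate DAG variability is summarized by the Gini-Simpson
diversity of the inferred DAG multiset and by the mean relative pairwise
edge distance between transitive reductions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortMatrix
from .genotypes import FitnessLandscape, accessible_genotypes
from .restrictions import RestrictionDAG, compatible_genotypes, dag_distance, transitive_reduction

__all__ = [
    "MetricsReport",
    "observable_accessible",
    "pfd",
    "pnd",
    "gini_simpson",
    "mean_pairwise_relative_distance",
    "dag_variability",
    "accessible_set_difference",
]


def observable_accessible(
    landscape: FitnessLandscape,
    big_cohort: CohortMatrix,
    min_freq: float = 0.005,
) -> set[int]:
    """Accessible genotypes observed above ``min_freq`` in a large cohort.

    The floor (default 5 in 1000, strict inequality) is chosen so that a
    genotype at the minimal qualifying frequency is missed by a sample of
    1000 genotypes with probability ``0.995**1000 < 1%``; rarer genotypes
    should not count against a DAG as false negatives.  WT is excluded.
    """
    freqs = big_cohort.genotype_frequencies()
    acc = accessible_genotypes(landscape) - {0}
    return {g for g in acc if freqs.get(g, 0.0) > min_freq}


def _check_same_genes(a, b) -> None:
    ga = tuple(a.gene_names if hasattr(a, "gene_names") else a.genes)
    gb = tuple(b.gene_names if hasattr(b, "gene_names") else b.genes)
    if ga != gb:
        raise ValueError(f"gene sets differ: {ga} vs {gb}")


def pfd(dag: RestrictionDAG, landscape: FitnessLandscape) -> float:
    """Proportion of false discoveries (1 - precision); NaN if the DAG
    predicts no non-WT genotype (never the case for a valid DAG, where the
    single mutants of Root-attached genes are always compatible)."""
    _check_same_genes(dag, landscape)
    compat = compatible_genotypes(dag) - {0}
    if not compat:
        return float("nan")
    acc = accessible_genotypes(landscape) - {0}
    return len(compat - acc) / len(compat)


def pnd(
    dag: RestrictionDAG,
    landscape: FitnessLandscape,
    observable: set[int] | None = None,
) -> float:
    """Proportion of negative discoveries (1 - recall) over the observable
    reference set; the full accessible set is used when ``observable`` is
    None.  NaN when the reference set is empty."""
    _check_same_genes(dag, landscape)
    acc = accessible_genotypes(landscape) - {0}
    if observable is None:
        observable = acc
    elif not observable <= acc:
        raise ValueError("observable set must be a subset of accessible genotypes")
    if not observable:
        return float("nan")
    compat = compatible_genotypes(dag) - {0}
    return len(observable - compat) / len(observable)


def _reduced_key(dag: RestrictionDAG) -> frozenset:
    return frozenset(transitive_reduction(dag).edges)


def gini_simpson(dags: Sequence[RestrictionDAG], bias_corrected: bool = False) -> float:
    """Probability that two DAGs drawn from the list differ.

    ``1 - sum(p_k**2)`` over the frequencies of distinct transitively
    reduced edge sets (plug-in estimator).  ``bias_corrected`` applies the
    ``n / (n - 1)`` small-sample correction (probability that two DAGs
    drawn *without* replacement differ).
    """
    if len(dags) < 2:
        raise ValueError("gini_simpson needs at least two DAGs")
    n = len(dags)
    counts: dict[frozenset, int] = {}
    for d in dags:
        k = _reduced_key(d)
        counts[k] = counts.get(k, 0) + 1
    p2 = sum((c / n) ** 2 for c in counts.values())
    g = 1.0 - p2
    if bias_corrected:
        g *= n / (n - 1)
    return g


def mean_pairwise_relative_distance(dags: Sequence[RestrictionDAG]) -> float:
    """Average relative edge distance over all unordered pairs."""
    if len(dags) < 2:
        raise ValueError("need at least two DAGs")
    vals = [
        dag_distance(a, b)[1] for a, b in itertools.combinations(dags, 2)
    ]
    return float(np.mean(vals))


def cross_pairwise_relative_distance(
    dags_a: Sequence[RestrictionDAG], dags_b: Sequence[RestrictionDAG]
) -> float:
    """Average relative edge distance over all cross pairs of two replicate
    sets (used for between-landscape DAG comparisons)."""
    vals = [dag_distance(a, b)[1] for a in dags_a for b in dags_b]
    return float(np.mean(vals))


def dag_variability(
    grouped: Mapping[object, Sequence[RestrictionDAG]],
) -> pd.DataFrame:
    """Within- and across-condition variability of inferred DAGs.

    ``grouped`` maps a condition label (e.g. mutation scheme x detection
    regime) to the replicate DAGs inferred under it.  Returns one row per
    condition plus a pooled ``"all"`` row, each with the mean relative
    pairwise distance and the Gini-Simpson diversity of that group.
    """
    rows = []
    pooled: list[RestrictionDAG] = []
    for label, dags in grouped.items():
        dags = list(dags)
        pooled.extend(dags)
        rows.append(
            {
                "condition": label,
                "n_dags": len(dags),
                "mean_relative_distance": mean_pairwise_relative_distance(dags),
                "gini_simpson": gini_simpson(dags),
            }
        )
    if len(grouped) > 1:
        rows.append(
            {
                "condition": "all",
                "n_dags": len(pooled),
                "mean_relative_distance": mean_pairwise_relative_distance(pooled),
                "gini_simpson": gini_simpson(pooled),
            }
        )
    return pd.DataFrame(rows)


def accessible_set_difference(
    l1: FitnessLandscape, l2: FitnessLandscape
) -> tuple[int, float]:
    """Pairwise difference between the accessible sets of two landscapes.

    Returns the size of the symmetric difference (genotypes accessible
    under exactly one landscape, WT excluded) and that count divided by the
    number of distinct accessible genotypes in the two landscapes combined.
    """
    _check_same_genes(l1, l2)
    a1 = accessible_genotypes(l1) - {0}
    a2 = accessible_genotypes(l2) - {0}
    diff = len(a1 ^ a2)
    union = len(a1 | a2)
    return diff, (diff / union if union else 0.0)


@dataclass
class MetricsReport:
    """Misprediction and variability summary for one experimental cell."""

    landscape_id: str
    family: str
    mutation_scheme: str
    detection_regime: str
    learner: str
    pfd: float
    pnd: float
    observable_reference_size: int
    gini_simpson: float
    mean_relative_dag_distance: float
    n_replicates: int
    accessible_set_relative_difference: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)
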
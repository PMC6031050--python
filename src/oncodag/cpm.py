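"""Obtaining DAGs of restrictions from cohort matrices.

Two routes are supported:

* :func:`import_dag` reads DAGs inferred by external cancer progression
  model software (e.g. CBN or CAPRI) from the shared edge-list dialect,
  transitively reducing on import since some tools emit redundant indirect
  edges.
* A deliberately simple baseline **conjunctive learner** so the whole
  metrics pipeline runs end to end without external binaries.  It proposes
  an edge ``i -> j`` when gene ``j`` is (almost) never mutated without
  ``i`` and ``i`` is at least as frequent as ``j`` (a temporal-priority
  tie-break in the spirit of CAPRI's heuristic, with no claim of
  equivalence).  It is *not* CBN or CAPRI; all downstream metrics accept
  any :class:`~oncodag.restrictions.RestrictionDAG` regardless of origin.

The learner is also exposed in a statsmodels-like shape:
``ConjunctiveRestrictionsModel(cohort).fit()`` returns a results object
carrying the inferred DAG, the per-edge violation diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import CohortMatrix
from .restrictions import ROOT, RestrictionDAG, from_edges, transitive_reduction
from . import restrictions as _restrictions

__all__ = [
    "LearnerConfig",
    "learn_conjunctive_dag",
    "import_dag",
    "ConjunctiveRestrictionsModel",
    "ConjunctiveRestrictionsResults",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Baseline-learner thresholds.

    ``epsilon`` is the tolerated fraction of samples violating a candidate
    dependency (samples with the child mutated but the parent not);
    ``min_count`` is the minimum number of occurrences of a gene before
    dependencies on it are assessed.
    """

    epsilon: float = 0.005
    min_count: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def learn_conjunctive_dag(
    cohort: CohortMatrix, config: LearnerConfig | None = None
) -> RestrictionDAG:
    """Infer a conjunctive DAG of restrictions from a binary cohort.

    An edge ``i -> j`` is proposed when the fraction of ``j``-mutated
    samples lacking ``i`` is at most ``epsilon`` and the marginal frequency
    of ``i`` is at least that of ``j`` (temporal priority: a required
    parent cannot be rarer than its child).  Mutual proposals are resolved
    by keeping the higher-frequency gene as parent.  The proposal graph is
    transitively reduced and parentless genes are attached to Root.
    """
    config = config or LearnerConfig()
    if cohort.n_samples == 0 or not cohort.matrix.any():
        raise ValueError("cohort contains no mutations to learn from")
    mat = cohort.matrix.astype(bool)
    genes = cohort.gene_names
    m = cohort.m
    counts = mat.sum(axis=0)
    freq = counts / cohort.n_samples

    proposed: set[tuple[int, int]] = set()
    for i, j in itertools.permutations(range(m), 2):
        if counts[j] < config.min_count:
            continue
        violations = np.count_nonzero(mat[:, j] & ~mat[:, i])
        if violations / counts[j] <= config.epsilon and freq[i] >= freq[j]:
            proposed.add((i, j))
    # mutual proposals (genes that always co-occur): keep the
    # higher-marginal-frequency parent; ties broken by gene order
    for i, j in list(proposed):
        if (j, i) in proposed and (i, j) in proposed:
            if (freq[i], -i) >= (freq[j], -j):
                proposed.discard((j, i))
            else:
                proposed.discard((i, j))
    edges = [(genes[i], genes[j]) for i, j in proposed]
    return transitive_reduction(from_edges(genes, edges, complete_root=True))


def import_dag(path, genes=None) -> RestrictionDAG:
    """Read an externally inferred DAG and transitively reduce it.

    External CPM output (notably CAPRI) may contain both direct and
    indirect edges; every comparison downstream is defined on transitive
    reductions, so reduction always happens on import.  Cyclic or malformed
    files are rejected with line diagnostics from the parser.
    """
    return transitive_reduction(_restrictions.read_dag(path, genes=genes))


class ConjunctiveRestrictionsModel:
    """Statsmodels-style wrapper around the baseline conjunctive learner."""

    def __init__(self, cohort: CohortMatrix, config: LearnerConfig | None = None):
        self.cohort = cohort
        self.config = config or LearnerConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ConjunctiveRestrictionsModel":
        return cls(CohortMatrix.from_frame(df), **kwargs)

    def fit(self) -> "ConjunctiveRestrictionsResults":
        dag = learn_conjunctive_dag(self.cohort, self.config)
        return ConjunctiveRestrictionsResults(self, dag)


class ConjunctiveRestrictionsResults:
    """Inferred DAG plus per-edge diagnostics.

    ``edge_table`` reports, for every inferred gene-gene edge, the child's
    count, the number of samples violating the dependency and the marginal
    frequencies that drove the temporal-priority direction.
    """

    def __init__(self, model: ConjunctiveRestrictionsModel, dag: RestrictionDAG):
        self.model = model
        self.dag = dag

    @property
    def edge_table(self) -> pd.DataFrame:
        cohort = self.model.cohort
        mat = cohort.matrix.astype(bool)
        idx = {g: k for k, g in enumerate(cohort.gene_names)}
        rows = []
        for u, v in sorted(self.dag.edges):
            if u == ROOT:
                rows.append(
                    {"parent": u, "child": v, "child_count": int(mat[:, idx[v]].sum()),
                     "violations": 0, "parent_freq": np.nan,
                     "child_freq": float(mat[:, idx[v]].mean())}
                )
                continue
            i, j = idx[u], idx[v]
            rows.append(
                {
                    "parent": u,
                    "child": v,
                    "child_count": int(mat[:, j].sum()),
                    "violations": int(np.count_nonzero(mat[:, j] & ~mat[:, i])),
                    "parent_freq": float(mat[:, i].mean()),
                    "child_freq": float(mat[:, j].mean()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cohort = self.model.cohort
        lines = [
            "Conjunctive DAG of restrictions (baseline learner)",
            f"samples: {cohort.n_samples}   genes: {cohort.m}   "
            f"epsilon: {self.model.config.epsilon}",
            "",
            self.edge_table.to_string(index=False),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ConjunctiveRestrictionsResults: {len(self.dag.edges)} edges "
            f"over {self.dag.m} genes>"
        )
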
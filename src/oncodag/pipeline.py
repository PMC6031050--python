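"""Orchestration of the factorial landscape study and the cohort study.

The landscape study crosses random fitness landscapes from the three
families with mutation-rate schemes and detection regimes.  For every cell
it simulates a large set of tumors, splits them into replicate cohorts,
fits a DAG of restrictions to each replicate, and scores misprediction
(PFD/PND against the true landscape) and replicate-to-replicate DAG
variability.  The cohort study runs the landscape-matching loop on an
observed cohort and measures how different the accepted landscapes — all
of which reproduce the observed genotype frequencies — are from each
other, and how different the DAGs inferred from them are.

Defaults are desk scale (minutes on a laptop); the published factorial
design (500 landscapes x 3 mutation schemes x 2 detection regimes,
20 000 simulated tumors per cell split into 20 x 1000) is available as the
``paper_scale`` preset and differs only in row counts, never in schema.

Every random draw is attributable: each (landscape, condition) cell gets a
seed derived deterministically from the study seed, recorded in the output
tables, so any cell can be replayed in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortMatrix
from .cpm import LearnerConfig, learn_conjunctive_dag
from .generate import GenParams, generate_family
from .genotypes import FitnessLandscape, accessible_genotypes, peaks, rse_fraction
from .matching import MatchCriteria, find_matched_landscapes, simulate_mutated_cohort
from .metrics import (
    cross_pairwise_relative_distance,
    accessible_set_difference,
    dag_variability,
    gini_simpson,
    mean_pairwise_relative_distance,
    observable_accessible,
    pfd,
    pnd,
)
from .restrictions import RestrictionDAG, dag_distance
from .simulate import (
    DETECTION_REGIMES,
    MUTATION_SCHEMES,
    SimParams,
    simulate_dataset,
)

__all__ = ["ExperimentConfig", "run_landscape_study", "run_cancer_study"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Size and settings of one study run.

    ``sims_per_condition`` must be divisible by ``n_replicates``; each cell
    simulates that many tumors and splits them into replicate cohorts of
    equal size for CPM fitting.
    """

    n_representable: int = 4
    n_nonrepresentable: int = 8
    n_rmf: int = 8
    mutation_schemes: tuple[str, ...] = MUTATION_SCHEMES
    detection_regimes: tuple[str, ...] = DETECTION_REGIMES
    sims_per_condition: int = 120
    n_replicates: int = 4
    seed: int = 0
    gen_params: GenParams = field(default_factory=GenParams)
    sim_params: SimParams = field(default_factory=SimParams)
    learner_config: LearnerConfig = field(default_factory=LearnerConfig)
    observable_min_freq: float = 0.005
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.sims_per_condition % self.n_replicates:
            raise ValueError(
                f"sims_per_condition={self.sims_per_condition} not divisible "
                f"by n_replicates={self.n_replicates}"
            )
        for s in self.mutation_schemes:
            if s not in MUTATION_SCHEMES:
                raise ValueError(f"unknown mutation scheme {s!r}")
        for r in self.detection_regimes:
            if r not in DETECTION_REGIMES:
                raise ValueError(f"unknown detection regime {r!r}")

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        """The published factorial design: 100 + 200 + 200 landscapes,
        20 000 tumors per cell split into 20 x 1000."""
        kwargs = dict(
            n_representable=100,
            n_nonrepresentable=200,
            n_rmf=200,
            sims_per_condition=20_000,
            n_replicates=20,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _cell_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _landscape_summary(
    lid: str, family: str, landscape: FitnessLandscape
) -> dict:
    acc = accessible_genotypes(landscape)
    return {
        "landscape_id": lid,
        "family": family,
        "m": landscape.m,
        "n_accessible": len(acc) - 1,  # WT excluded
        "rse_fraction": rse_fraction(landscape),
        "n_peaks_accessible": len(peaks(landscape, gains_only=True)),
    }


def run_landscape_study(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Run the full generate -> simulate -> learn -> score factorial study.

    Returns tidy tables: ``landscapes`` (per-landscape characteristics),
    ``metrics`` (one row per landscape x condition x learner, including a
    ``true_dag`` scoring row for DAG-derived landscapes), and
    ``variability`` (within-condition and over-condition DAG variability
    per landscape).  With ``config.out_dir`` set, the tables are written as
    CSV alongside a JSON provenance record.
    """
    families = (
        ("representable", config.n_representable),
        ("nonrepresentable", config.n_nonrepresentable),
        ("rmf", config.n_rmf),
    )
    landscapes: list[tuple[str, str, FitnessLandscape, RestrictionDAG | None]] = []
    for fi, (family, n) in enumerate(families):
        rng = _cell_rng(config.seed, 0, fi)
        for k, (landscape, dag) in enumerate(
            generate_family(family, n, config.gen_params, rng)
        ):
            landscapes.append((f"{family}_{k:03d}", family, landscape, dag))

    landscape_rows = [
        _landscape_summary(lid, family, L) for lid, family, L, _ in landscapes
    ]
    metric_rows: list[dict] = []
    variability_rows: list[dict] = []

    rep_size = config.sims_per_condition // config.n_replicates
    for li, (lid, family, landscape, true_dag) in enumerate(landscapes):
        dags_over_conditions: list[RestrictionDAG] = []
        for ci, scheme in enumerate(config.mutation_schemes):
            for ri, regime in enumerate(config.detection_regimes):
                cell_seed_key = (1, li, ci, ri)
                rng = _cell_rng(config.seed, *cell_seed_key)
                sim_params = replace(
                    config.sim_params,
                    mutation_scheme=scheme,
                    detection_regime=regime,
                )
                big = simulate_dataset(
                    landscape, sim_params, config.sims_per_condition, rng
                )
                observable = observable_accessible(
                    landscape, big, config.observable_min_freq
                )
                # replicate cohorts: consecutive slices of the big cohort
                rep_dags: list[RestrictionDAG] = []
                for r in range(config.n_replicates):
                    chunk = CohortMatrix(
                        landscape.gene_names,
                        big.matrix[r * rep_size : (r + 1) * rep_size],
                    )
                    try:
                        d = learn_conjunctive_dag(chunk, config.learner_config)
                    except ValueError:
                        continue  # all-WT replicate: nothing to learn from
                    rep_dags.append(d)
                dags_over_conditions.extend(rep_dags)

                scored: list[tuple[str, RestrictionDAG]] = [
                    ("conjunctive", d) for d in rep_dags
                ]
                if true_dag is not None:
                    scored.append(("true_dag", true_dag))
                by_learner: dict[str, list[float]] = {}
                for learner, d in scored:
                    metric_rows.append(
                        {
                            "landscape_id": lid,
                            "family": family,
                            "mutation_scheme": scheme,
                            "detection_regime": regime,
                            "learner": learner,
                            "pfd": pfd(d, landscape),
                            "pnd": pnd(d, landscape, observable)
                            if observable
                            else float("nan"),
                            "observable_reference_size": len(observable),
                            "cell_seed": json.dumps([config.seed, *cell_seed_key]),
                        }
                    )
                if len(rep_dags) >= 2:
                    variability_rows.append(
                        {
                            "landscape_id": lid,
                            "family": family,
                            "grouping": "same_mut_dtct",
                            "mutation_scheme": scheme,
                            "detection_regime": regime,
                            "n_dags": len(rep_dags),
                            "mean_relative_distance": mean_pairwise_relative_distance(
                                rep_dags
                            ),
                            "gini_simpson": gini_simpson(rep_dags),
                        }
                    )
        if len(dags_over_conditions) >= 2:
            variability_rows.append(
                {
                    "landscape_id": lid,
                    "family": family,
                    "grouping": "over_mut_dtct",
                    "mutation_scheme": "all",
                    "detection_regime": "all",
                    "n_dags": len(dags_over_conditions),
                    "mean_relative_distance": mean_pairwise_relative_distance(
                        dags_over_conditions
                    ),
                    "gini_simpson": gini_simpson(dags_over_conditions),
                }
            )

    tables = {
        "landscapes": pd.DataFrame(landscape_rows),
        "metrics": pd.DataFrame(metric_rows),
        "variability": pd.DataFrame(variability_rows),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        provenance = {
            "seed": config.seed,
            "sims_per_condition": config.sims_per_condition,
            "n_replicates": config.n_replicates,
            "families": {f: n for f, n in families},
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return tables


def run_cancer_study(
    observed: CohortMatrix,
    config: ExperimentConfig,
    criteria: MatchCriteria | None = None,
    n_matched: int = 4,
    sims_per_landscape: int = 200,
) -> dict[str, pd.DataFrame]:
    """Matching loop plus downstream variability analysis for one cohort.

    Finds ``n_matched`` landscapes that reproduce the observed genotype
    frequencies, then, for each, simulates ``sims_per_landscape`` tumors,
    fits replicate DAGs at the observed sample size, and tabulates (a)
    pairwise accessible-set differences between accepted landscapes, (b)
    within-landscape DAG variability, and (c) between-landscape DAG
    distances averaged over all cross pairs of replicate DAGs.
    """
    criteria = criteria or MatchCriteria()
    rng = _cell_rng(config.seed, 2)
    matched = find_matched_landscapes(
        observed,
        criteria,
        n_target=n_matched,
        gen_params=replace(
            config.gen_params, m=observed.m, gene_names=observed.gene_names
        ),
        base_sim_params=config.sim_params,
        rng=rng,
    )
    n_obs = observed.drop_wildtype().n_samples
    rep_size = n_obs
    n_reps = max(2, sims_per_landscape // max(1, rep_size))

    landscape_rows = []
    rep_dags: list[list[RestrictionDAG]] = []
    for k, match in enumerate(matched):
        lid = f"matched_{k:03d}"
        landscape_rows.append(
            _landscape_summary(lid, "matched_rmf", match.landscape)
            | {
                "mutation_scheme": match.sim_params.mutation_scheme,
                "detection_regime": match.sim_params.detection_regime,
                "n_passed": match.n_passed,
            }
        )
        dags = []
        for r in range(n_reps):
            try:
                cohort = simulate_mutated_cohort(
                    match.landscape, match.sim_params, rep_size, rng
                )
                dags.append(learn_conjunctive_dag(cohort, config.learner_config))
            except (RuntimeError, ValueError):
                # detection timeout on a barely-growing landscape, or an
                # uninformative replicate; record the landscape without it
                continue
        rep_dags.append(dags)

    within_rows = [
        {
            "landscape_id": f"matched_{k:03d}",
            "n_dags": len(dags),
            "mean_relative_distance": mean_pairwise_relative_distance(dags)
            if len(dags) >= 2
            else float("nan"),
            "gini_simpson": gini_simpson(dags) if len(dags) >= 2 else float("nan"),
        }
        for k, dags in enumerate(rep_dags)
    ]
    between_rows = []
    for a in range(len(matched)):
        for b in range(a + 1, len(matched)):
            count, rel = accessible_set_difference(
                matched[a].landscape, matched[b].landscape
            )
            row = {
                "landscape_a": f"matched_{a:03d}",
                "landscape_b": f"matched_{b:03d}",
                "accessible_diff_count": count,
                "accessible_diff_relative": rel,
            }
            if rep_dags[a] and rep_dags[b]:
                row["mean_cross_dag_distance"] = cross_pairwise_relative_distance(
                    rep_dags[a], rep_dags[b]
                )
            between_rows.append(row)

    tables = {
        "matched_landscapes": pd.DataFrame(landscape_rows),
        "within_landscape": pd.DataFrame(within_rows),
        "between_landscapes": pd.DataFrame(between_rows),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
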
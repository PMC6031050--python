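#!/usr/bin/env python
"""Regenerate the small text fixtures shipped under tests/data/.

The fixtures are the canonical DAG/landscape pairs from
``oncodag.synthetic.fig1_fixtures`` (fixed seed) plus one small simulated
stand-in cohort; everything is plain text and reproducible by rerunning
this script.
"""

from pathlib import Path

from oncodag.restrictions import write_dag
from oncodag.synthetic import CohortSpec, fig1_fixtures, synthetic_cohort

OUT = Path(__file__).resolve().parent.parent / "tests" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fixtures = fig1_fixtures()
    for name in ("chain", "conjunction"):
        dag, landscape = fixtures[name]
        write_dag(dag, OUT / f"{name}.dag")
        landscape.to_csv(OUT / f"{name}_landscape.csv")
    _, knocked = fixtures["conjunction_knockout"]
    knocked.to_csv(OUT / "conjunction_knockout_landscape.csv")
    cohort, _, _ = synthetic_cohort(
        CohortSpec(n_patients=30, m=4, family="representable", seed=8)
    )
    cohort.to_csv(OUT / "synthetic_cohort_30x4.csv")
    print(f"wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
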
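# Methods

This note documents the models implemented in `oncodag`, the parameter
choices that matter, and what the synthetic data do and do not capture.

## Genotype space and accessibility

Genotypes over `m` biallelic driver loci are integers in `[0, 2^m)`; bit
`k` is the state of gene `k` and the wild type (WT) is 0. Back mutation is
excluded throughout, as is crossing a fitness valley in a single
multi-mutation step. A genotype is *accessible* if some chain of
single-mutation gains from WT increases fitness strictly at every step.

Two peak notions are exposed. `peaks()` defaults to the strict local
maximum over all Hamming-1 neighbors (gain and loss directions). With
`gains_only=True` a peak is a genotype with no strictly fitter
single-mutation-gain neighbor — the natural notion in a no-back-mutation
model, since a clone at such a genotype has no beneficial mutation
available; every gain-direction local maximum under the strict definition
is also a gain-only peak, and the gain-only count is the one reported in
the per-family statistics and by the acceptance script.

Two-locus epistasis on a square `{b, b+i, b+j, b+ij}` is classified from
the signs of the conditional effects. Exact zero differences count as "no
sign change": with continuous random fitness, ties are measure-zero, and
this choice avoids spurious sign classes on degenerate hand-built
fixtures. The reciprocal-sign-epistasis (RSE) fraction aggregates per
square over all `m(m-1)/2 * 2^(m-2)` (pair, background) combinations,
matching standard landscape-statistics practice; a per-locus-pair
aggregation (a pair counts if *any* background square is reciprocal-sign)
is available via a flag.

## DAGs of restrictions

`RestrictionDAG` carries genes plus a Root node and conjunctive (AND)
parent semantics; XOR/OR semantics are out of scope. All comparisons
operate on transitive reductions (externally inferred DAGs may contain
redundant indirect edges and are reduced on import). Root edges are
recomputed after reduction — exactly the genes left without a gene parent
attach to Root — and are *included* in edge distances by default: two DAGs
differing only in which genes hang off Root encode genuinely different
restriction structures. A flag excludes them. The relative distance is the
symmetric difference over the union of the two reduced edge sets, 0 for
identical reductions.

## Landscape generators

All families default to `m = 7` genes.

**DAG-derived, representable.** A random DAG is drawn by sampling a
uniform topological order and including each forward edge independently
with probability 0.3 (spanning sparse tree-like to dense conjunctive
structures), then reduced. Genotypes compatible with the DAG get
multiplicative fitness `prod (1 + s_i)` with `s_i ~ U(0.1, 0.7)`;
incompatible genotypes get a lethal fitness of 1e-9, which makes them
unreachable in practice. The accessible set then equals the compatible set
by construction, and these landscapes contain no RSE.

**DAG-derived, non-representable.** A representable landscape is modified
by setting a random subset of its accessible genotypes with ≥ 2 mutations
to the lethal fitness (synthetic lethals). The subset size is uniform over
`[0.12 n_elig, n_elig]`; this range was calibrated once so that the family
reproduces the target summary statistics (mean RSE fraction ≈ 0.02, mean
accessible gain-only peaks ≈ 2.8 over 200 draws) and then frozen. Draws
are rejected until every gene appears in at least one accessible genotype;
for DAG shapes where no knockout can preserve that (e.g. pure chains,
where any knocked-out genotype disconnects everything above it) the
family-level generator redraws the DAG/landscape pair.

**Rough Mount Fuji.** Raw value `F(g) = -c·d(g, r) + eps_g` with reference
genotype `r` uniform over all `2^m` genotypes, slope `c ~ U(0, 1.25)` and
`eps_g` i.i.d. standard normal. `c = 0` is the House-of-Cards limit; large
`c` is nearly additive toward the reference. Raw values map to birth rates
via `exp(0.3 (F - F(WT)))` — strictly monotone, so accessibility, peaks
and epistasis sign classes depend only on the RMF ranks — normalizing WT
to 1 and keeping the largest birth rates of order tens rather than
thousands (relevant only to simulation dynamics). The slope support was
likewise calibrated once against the family targets (mean RSE ≈ 0.27, mean
accessible peaks ≈ 11.5) and frozen. The same gene-coverage rejection
applies; it is what discards, for instance, every noise-free draw whose
reference is not the fully mutated genotype.

**Cohort-matched RMF.** Starting from a plain RMF draw over the cohort's
genes, each distinct observed genotype gets one uniformly random maximal
chain WT → … → g; any non-increasing step is raised to
`previous × (1 + delta)`, `delta ~ U(0.01, 0.1)` — the minimal
intervention preserving the RMF character. Because a bump on one chain can
disturb another, full accessibility of all observed genotypes is
re-verified and the draw retried on failure.

## Evolutionary simulation

The simulator follows the McFarland-style logistic parameterization:
birth rate of a cell is its genotype's landscape fitness; the common death
rate is `D(N) = log(1 + N/K)` with `K = N0/(e - 1)` so that the initial
`N0 = 2000` WT cells start at equilibrium (`D(N0) = 1`). At division the
daughter acquires each still-unmutated gene's mutation independently; with
per-gene rates of 1e-6–5e-5 at most one new mutation per division is
drawn, the probability of simultaneous double hits being negligible. The
three mutation schemes are: common 1e-5, common 1e-6, and gene-specific
rates geometrically spaced over [2e-6, 5e-5] (geometric mean exactly 1e-5,
maximum spread between successive values) randomly assigned to genes.

Detection is evaluated every 20 time units with probability
`p(N) = 1 - exp(-k·max(0, N/N0 - 1))`, `k` fixed by the regime anchors
`p(2 N0) = 0.1` (fast) or 0.01 (slow). The 20-unit cadence matches the
default screening cadence of the reference stochastic-simulation tooling
for this model class and yields pooled detection-size quartiles of roughly
5k / 18k / 67k cells across families and conditions — a heavy-tailed
distribution with median in the low tens of thousands. Populations
reaching 5e6 cells return immediately (detection probability is
numerically 1 there), which keeps explosive high-fitness landscapes
finite. Runs going extinct before detection restart with the attempt count
logged; runs exceeding `max_time` raise, which callers in the matching
loop treat as a failed repetition.

Two backends are provided: exact clone-level Gillespie, and tau-leaping in
which each clone's aggregated births and deaths over a sub-step are Poisson
draws. Aggregated counts are exactly Poisson when rates are constant, so
the leap error comes from holding `D(N)` fixed within a step; sub-steps
are sized so the net growth per step stays below ~10%. The suite checks
the two backends agree in distribution on 3-gene fixtures using
per-replicate statistics (final size, mutant-cell fraction, per-genotype
presence) — pooled cell counts are clonally correlated and would make any
two-sample test anti-conservative.

Whole-tumor sampling calls gene `i` mutated when its cell fraction reaches
the threshold (default 0.5), producing one consensus genotype per tumor.

## Baseline conjunctive learner

The learner exists so the metrics pipeline runs end to end without
external CPM binaries; it is deliberately *not* CBN or CAPRI, and every
downstream metric accepts imported DAGs from those tools instead. An edge
`i → j` is proposed when at most a fraction `epsilon` (default 0.005) of
`j`-mutated samples lack `i` and `i`'s marginal frequency is at least
`j`'s (a temporal-priority tie-break: a required parent cannot be rarer
than its child). Mutual proposals keep the more frequent parent; the
proposal graph is transitively reduced. On a noiseless cohort containing
every compatible genotype of a representable landscape equally often, the
learner provably recovers the generating reduced DAG, which the suite
verifies exhaustively for m ≤ 5.

## Misprediction and variability metrics

WT is excluded from every genotype set: only genotypes with mutations are
predictions, and a shared WT element would dilute all ratios. PFD is
`|compatible \ accessible| / |compatible|`; PND is
`|observable \ compatible| / |observable|` where the observable reference
is the accessible genotypes observed at frequency strictly greater than
5/1000 in a large simulated cohort. That floor makes the probability of
missing a minimally-qualifying genotype in a 1000-genotype sample
`0.995^1000 ≈ 0.0067 < 1%`, so rare-but-accessible genotypes do not count
against a DAG. Both are NaN-flagged when their denominator is empty.
Replicate variability uses the plug-in Gini–Simpson index over distinct
reduced edge sets (the `n/(n-1)` correction is available via a flag) and
the mean relative pairwise distance, within each mutation × detection cell
and pooled over all cells.

## Cohort matching

Candidates are cohort-matched RMF landscapes with mutation scheme and
detection regime drawn uniformly from the study menu. Each candidate is
simulated `n_reps = 10` times at the observed sample size (WT consensus
samples are discarded and redrawn, since the empirical cohorts contain
only patients with ≥ 1 mutation) and compared with the observed cohort via
a 2 × k χ² test over the union of observed genotype categories — no
low-count pooling; the label-permutation test (add-one estimator) is the
stated remedy for sparse cells. Acceptance requires `min_pass = 3`
repetitions with both p-values above 0.6 and every gene observed; the
decision is a deterministic function of the logged p-values and coverage
flags. Whether WT samples join the χ² categories is resolved by excluding
them, matching cohorts defined by "at least one mutation".

## Problem sizes

Desk-scale defaults are used everywhere so a full run takes minutes: the
factorial study default is 4 + 8 + 8 landscapes × 3 schemes × 2 regimes
with 120 simulated tumors per cell split into 4 replicate cohorts; the
published design (100 + 200 + 200 landscapes, 20 000 tumors per cell split
20 × 1000, 150 matched landscapes per cohort) is available as the
`paper_scale` preset and differs only in row counts. The test suite's
simulator checks use 10 landscapes × 6 conditions × 4 tumors for the
detection-size distribution (with a 6000-time-unit budget per tumor,
censoring the < 10% of runs on barely-growing landscapes) and small 3–4
gene cohorts for the matching loop. The acceptance script uses 200
landscapes per family, the size at which the family statistics were
defined.

## Known limitations

* The baseline learner is a stand-in: quantitative CPM-specific results
  (e.g. method-by-landscape interactions of CBN vs CAPRI) require the
  external tools, whose DAGs can be imported for scoring.
* No passenger mutations, observational errors, spatial structure or
  treatment; drivers are assumed known.
* Tau-leaping slightly distorts trajectories of clones of size O(1); the
  exact backend is available below a configurable size threshold.
* The synthetic stand-in cohorts are simulated from known landscapes (no
  published per-genotype frequencies exist to resample), so tests
  demonstrate internal consistency of the pipeline, not agreement with any
  particular empirical dataset.
* Downstream mixed-effects modelling of the emitted tables is left to
  standard statistics tooling; the tables are tidy CSV by design.
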
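"""Genotype space of a fitness landscape: accessibility, peaks, epistasis.

Genotypes over ``m`` biallelic loci (mutated / not mutated) are encoded as
integers in ``[0, 2**m)``: bit ``k`` is the state of gene ``k``, gene order
being the ``gene_names`` order of the enclosing landscape.  The wild type
(WT) is ``0``.  A fitness landscape maps every one of the ``2**m`` genotypes
to a positive birth rate, normalized so that WT has fitness 1.

Accessibility follows the standard fitness-graph convention for systems
without back mutation: a genotype is *accessible* when it can be reached
from WT through single mutation *gains*, each step strictly increasing
fitness.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitnessLandscape",
    "accessible_genotypes",
    "peaks",
    "classify_square",
    "rse_fraction",
    "genotype_label",
    "popcount",
]

NO_EPISTASIS = "no_epistasis"
MAGNITUDE = "magnitude"
SIGN = "sign"
RECIPROCAL_SIGN = "reciprocal_sign"


def popcount(g: int) -> int:
    """Number of mutated loci in genotype ``g``."""
    return int(g).bit_count()


def genotype_label(g: int, gene_names: Sequence[str]) -> str:
    """Human-readable label, e.g. ``'AB'`` for genes A and B mutated; 'WT' for 0."""
    if g == 0:
        return "WT"
    return "".join(n for k, n in enumerate(gene_names) if g >> k & 1)


@dataclass(frozen=True)
class FitnessLandscape:
    """Complete genotype -> fitness map over ``2**m`` biallelic genotypes.

    Parameters
    ----------
    gene_names
        Ordered gene labels; gene ``k`` is bit ``k`` of the genotype index.
    fitness
        Array of length ``2**m`` of positive birth rates, ``fitness[0] == 1``
        (WT) after normalization.
    lethal_threshold
        Fitness at or below which a genotype is treated as effectively
        non-viable (used by generators to mark knocked-out genotypes).
    """

    gene_names: tuple[str, ...]
    fitness: np.ndarray
    lethal_threshold: float = 1e-9

    def __post_init__(self) -> None:
        fit = np.asarray(self.fitness, dtype=float)
        object.__setattr__(self, "fitness", fit)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if fit.ndim != 1 or fit.shape[0] != 2 ** len(self.gene_names):
            raise ValueError(
                f"fitness must have length 2**m = {2 ** len(self.gene_names)}, "
                f"got {fit.shape}"
            )
        if not np.all(fit > 0):
            raise ValueError("all fitness values must be positive")
        fit.setflags(write=False)

    @property
    def m(self) -> int:
        return len(self.gene_names)

    @property
    def n_genotypes(self) -> int:
        return 2**self.m

    def __getitem__(self, g: int) -> float:
        return float(self.fitness[g])

    def genotypes(self) -> range:
        return range(self.n_genotypes)

    def label(self, g: int) -> str:
        return genotype_label(g, self.gene_names)

    def neighbors(self, g: int) -> Iterator[int]:
        """All Hamming-distance-1 neighbors (both gain and loss directions)."""
        for k in range(self.m):
            yield g ^ (1 << k)

    def normalized(self) -> "FitnessLandscape":
        """Return a copy rescaled so WT fitness is exactly 1."""
        return FitnessLandscape(
            self.gene_names, self.fitness / self.fitness[0], self.lethal_threshold
        )

    def with_fitness(self, updates: dict[int, float]) -> "FitnessLandscape":
        fit = self.fitness.copy()
        for g, f in updates.items():
            fit[g] = f
        return FitnessLandscape(self.gene_names, fit, self.lethal_threshold)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """One row per genotype: m 0/1 gene columns plus a ``fitness`` column."""
        bits = np.array(
            [[g >> k & 1 for k in range(self.m)] for g in self.genotypes()],
            dtype=int,
        )
        df = pd.DataFrame(bits, columns=list(self.gene_names))
        df["fitness"] = self.fitness
        return df

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, lethal_threshold: float = 1e-9
    ) -> "FitnessLandscape":
        if "fitness" not in df.columns:
            raise ValueError("landscape table needs a 'fitness' column")
        genes = [c for c in df.columns if c != "fitness"]
        m = len(genes)
        if len(df) != 2**m:
            raise ValueError(f"expected {2 ** m} rows for {m} genes, got {len(df)}")
        fit = np.empty(2**m)
        seen = np.zeros(2**m, dtype=bool)
        for _, row in df.iterrows():
            g = 0
            for k, name in enumerate(genes):
                b = int(row[name])
                if b not in (0, 1):
                    raise ValueError(f"non-binary genotype entry {row[name]!r}")
                g |= b << k
            if seen[g]:
                raise ValueError(f"duplicate genotype row for index {g}")
            seen[g] = True
            fit[g] = float(row["fitness"])
        return cls(tuple(genes), fit, lethal_threshold)

    @classmethod
    def from_csv(cls, path_or_buf, lethal_threshold: float = 1e-9) -> "FitnessLandscape":
        return cls.from_frame(pd.read_csv(path_or_buf), lethal_threshold)


def accessible_genotypes(landscape: FitnessLandscape) -> set[int]:
    """Genotypes reachable from WT by fitness-increasing single mutation gains.

    Returns the set of genotypes lying on at least one accessible mutational
    path: a chain WT -> g1 -> ... -> g where each step adds exactly one
    mutation and strictly increases fitness.  WT itself is included;
    downstream metrics exclude it explicitly.
    """
    fit = landscape.fitness
    m = landscape.m
    reached = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for g in frontier:
            fg = fit[g]
            for k in range(m):
                if not g >> k & 1:
                    h = g | (1 << k)
                    if h not in reached and fit[h] > fg:
                        reached.add(h)
                        nxt.append(h)
        frontier = nxt
    return reached


def peaks(
    landscape: FitnessLandscape,
    restrict_to_accessible: bool = True,
    gains_only: bool = False,
) -> set[int]:
    """Local fitness maxima of the landscape.

    By default a peak is strictly fitter than every Hamming-1 neighbor (both
    gain and loss directions).  With ``gains_only`` a peak is a genotype
    with no strictly fitter single-mutation-*gain* neighbor — the natural
    notion when back mutation is excluded, since a clone sitting there has
    no beneficial mutation available; this is the definition used for the
    per-family accessible-peak statistics.

    With ``restrict_to_accessible`` (the default) the result is intersected
    with the accessible genotype set, i.e. only peaks that evolution
    starting from WT could actually reach are reported.
    """
    fit = landscape.fitness
    m = landscape.m
    if gains_only:
        out = {
            g
            for g in landscape.genotypes()
            if all(
                fit[g | (1 << k)] <= fit[g] for k in range(m) if not g >> k & 1
            )
        }
    else:
        out = {
            g
            for g in landscape.genotypes()
            if all(fit[g] > fit[h] for h in landscape.neighbors(g))
        }
    if restrict_to_accessible:
        out &= accessible_genotypes(landscape)
    return out


def _sign(x: float) -> int:
    # exact zeros count as "no sign change"; ties are measure-zero for
    # continuous random fitness and must not create spurious epistasis classes
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def classify_square(
    landscape: FitnessLandscape, locus_i: int, locus_j: int, background: int
) -> str:
    """Classify the two-locus epistasis of the square on ``background``.

    The square is the four genotypes ``{b, b+i, b+j, b+ij}`` where ``b`` has
    loci ``i`` and ``j`` unmutated.  With effect differences
    ``di(b) = f(b+i) - f(b)`` and ``di(b+j) = f(b+ij) - f(b+j)`` (likewise
    for ``j``):

    * ``reciprocal_sign`` — both loci reverse the sign of their effect in the
      other's background (e.g. individually beneficial, jointly deleterious:
      the synthetic-lethality pattern);
    * ``sign`` — exactly one locus reverses sign;
    * ``magnitude`` — no reversal but the joint effect is non-additive;
    * ``no_epistasis`` — exactly additive on this square.
    """
    if locus_i == locus_j:
        raise ValueError("locus_i and locus_j must differ")
    bi, bj = 1 << locus_i, 1 << locus_j
    if background & bi or background & bj:
        raise ValueError("background must have loci i and j unmutated")
    f = landscape.fitness
    b = background
    di_b = f[b | bi] - f[b]
    di_bj = f[b | bi | bj] - f[b | bj]
    dj_b = f[b | bj] - f[b]
    dj_bi = f[b | bi | bj] - f[b | bi]
    i_flips = _sign(di_b) != 0 and _sign(di_b) == -_sign(di_bj)
    j_flips = _sign(dj_b) != 0 and _sign(dj_b) == -_sign(dj_bi)
    if i_flips and j_flips:
        return RECIPROCAL_SIGN
    if i_flips or j_flips:
        return SIGN
    if di_bj != di_b:  # equivalently dj_bi != dj_b
        return MAGNITUDE
    return NO_EPISTASIS


def _iter_squares(m: int) -> Iterator[tuple[int, int, int]]:
    for i, j in itertools.combinations(range(m), 2):
        mask = (1 << i) | (1 << j)
        for b in range(2**m):
            if not b & mask:
                yield i, j, b


def rse_fraction(landscape: FitnessLandscape, per_locus_pair: bool = False) -> float:
    """Fraction of two-locus squares with reciprocal sign epistasis.

    By default aggregates per square — all ``m(m-1)/2 * 2**(m-2)`` (locus
    pair, background) combinations — which is the standard landscape
    statistic.  With ``per_locus_pair`` a pair of loci counts once if *any*
    of its backgrounds shows reciprocal sign epistasis, and the denominator
    is ``m(m-1)/2``.
    """
    m = landscape.m
    if m < 2:
        raise ValueError("rse_fraction needs at least two loci")
    if per_locus_pair:
        hits = 0
        for i, j in itertools.combinations(range(m), 2):
            mask = (1 << i) | (1 << j)
            if any(
                classify_square(landscape, i, j, b) == RECIPROCAL_SIGN
                for b in range(2**m)
                if not b & mask
            ):
                hits += 1
        return hits / (m * (m - 1) // 2)
    total = 0
    hits = 0
    for i, j, b in _iter_squares(m):
        total += 1
        if classify_square(landscape, i, j, b) == RECIPROCAL_SIGN:
            hits += 1
    return hits / total
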
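"""Independent brute-force oracles, written without reusing library internals.

These deliberately use the most naive formulation of each definition —
explicit path enumeration, exhaustive neighbor scans, raw set algebra — so
they stay independent of the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def bits_on(g: int, m: int) -> list[int]:
    return [k for k in range(m) if g >> k & 1]


def brute_accessible(fitness, m: int) -> set[int]:
    """Accessible set by explicit enumeration of monotone add-one chains."""
    accessible = {0}
    # genotypes in order of mutation count; a genotype is accessible if some
    # single-locus-removal predecessor is accessible with lower fitness
    order = sorted(range(2**m), key=lambda g: bin(g).count("1"))
    for g in order:
        if g == 0:
            continue
        for k in bits_on(g, m):
            pred = g & ~(1 << k)
            if pred in accessible and fitness[pred] < fitness[g]:
                accessible.add(g)
                break
    return accessible


def brute_accessible_paths(fitness, m: int) -> set[int]:
    """Same set via full recursive path enumeration (exponential; m <= 5)."""
    out = {0}

    def walk(g):
        for k in range(m):
            if not g >> k & 1:
                h = g | (1 << k)
                if fitness[h] > fitness[g]:
                    out.add(h)
                    walk(h)

    walk(0)
    return out


def brute_peaks(fitness, m: int, gains_only: bool = False) -> set[int]:
    out = set()
    for g in range(2**m):
        if gains_only:
            gains = [g | (1 << k) for k in range(m) if not g >> k & 1]
            if all(fitness[h] <= fitness[g] for h in gains):
                out.add(g)
        else:
            nb = [g ^ (1 << k) for k in range(m)]
            if all(fitness[h] < fitness[g] for h in nb):
                out.add(g)
    return out


def brute_classify(f00: float, f10: float, f01: float, f11: float) -> str:
    """Epistasis class of one square from the raw four-genotype sign table."""

    def s(x):
        return int(x > 0) - int(x < 0)

    di_b, di_bj = f10 - f00, f11 - f01
    dj_b, dj_bi = f01 - f00, f11 - f10
    flip_i = s(di_b) != 0 and s(di_bj) == -s(di_b)
    flip_j = s(dj_b) != 0 and s(dj_bi) == -s(dj_b)
    if flip_i and flip_j:
        return "reciprocal_sign"
    if flip_i or flip_j:
        return "sign"
    if (f11 - f01) != (f10 - f00):
        return "magnitude"
    return "no_epistasis"


def brute_rse_fraction(fitness, m: int) -> float:
    hits = total = 0
    for i, j in itertools.combinations(range(m), 2):
        for b in range(2**m):
            if b & ((1 << i) | (1 << j)):
                continue
            total += 1
            cls = brute_classify(
                fitness[b],
                fitness[b | (1 << i)],
                fitness[b | (1 << j)],
                fitness[b | (1 << i) | (1 << j)],
            )
            if cls == "reciprocal_sign":
                hits += 1
    return hits / total


def reachability(nodes, edges) -> set[tuple[str, str]]:
    """Transitive closure pairs of a digraph by repeated expansion."""
    reach = set(edges)
    changed = True
    while changed:
        changed = False
        for (a, b), (c, d) in itertools.product(list(reach), repeat=2):
            if b == c and (a, d) not in reach:
                reach.add((a, d))
                changed = True
    return reach


def is_minimal_with_same_reachability(nodes, edges) -> bool:
    """No single edge can be dropped without changing reachability."""
    full = reachability(nodes, edges)
    for e in edges:
        if reachability(nodes, edges - {e}) == full:
            return False
    return True


def brute_compatible(genes, gene_parents, m: int) -> set[int]:
    """Compatible set from a parent map {gene_index: set of parent indices}."""
    out = set()
    for g in range(2**m):
        ok = True
        for k in range(m):
            if g >> k & 1:
                for p in gene_parents.get(k, ()):
                    if not g >> p & 1:
                        ok = False
        if ok:
            out.add(g)
    return out


def random_fitness(rng: np.random.Generator, m: int) -> np.ndarray:
    """A random positive landscape with WT = 1 (continuous, no ties)."""
    f = np.exp(rng.normal(0, 1, size=2**m))
    return f / f[0]
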
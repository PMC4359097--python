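"""Genotype fitness under hybrid incompatibility selection.

Fitness of a diploid genotype at one incompatibility pair is built from a
dominance-dose product.  Writing ``g(n; h)`` for the dose of an allele
carried in ``n`` copies (0, ``h`` or 1) the fitness of the genotype with
``nA1`` parent-1 alleles at locus A and ``nB1`` at locus B is::

    w = A(nA1, nB1)
        * (1 - s1 * g(nA1; hA)   * g(2 - nB1; hB))   # derived x derived
        * (1 - s2 * g(2-nA1; hA) * g(nB1; hB))       # ancestral x ancestral

where ``A`` is an adaptive-advantage factor (1 except for ``bdm_adaptive``
pairs, where each derived allele multiplies fitness by ``1 + s_adv`` at full
dose).  Pure parental genotypes incur no cross-parent combination, so their
fitness is maximal within the pair.  Total fitness across pairs is
multiplicative and is interpreted downstream as a survival probability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .architecture import Architecture, IncompatibilityPair

__all__ = [
    "dominance_dose",
    "pair_fitness_table",
    "pair_fitness",
    "underdominant_fitness",
    "individual_fitness",
    "expected_f1_fitness",
    "calibrate_s_for_f1",
    "architecture_tables",
]


def dominance_dose(n: int, h: float) -> float:
    """Dose of an allele present in ``n`` copies: 0, ``h`` or 1."""
    if n == 0:
        return 0.0
    if n == 1:
        return float(h)
    if n == 2:
        return 1.0
    raise ValueError(f"allele count must be 0, 1 or 2, got {n}")


def pair_fitness_table(pair: IncompatibilityPair) -> np.ndarray:
    """3x3 fitness table for one pair, indexed ``[nA1, nB1]``.

    For underdominant pairs the table depends only on the first index
    (heterokaryotypes have fitness ``1 - s1``); the second axis is padded so
    the same lookup code serves every kind.
    """
    w = np.empty((3, 3), dtype=np.float64)
    if pair.kind == "underdominant":
        for n1 in range(3):
            w[n1, :] = 1.0 - pair.s1 if n1 == 1 else 1.0
        return w
    for nA1 in range(3):
        for nB1 in range(3):
            # derived allele at A is parent 1's; derived at B is parent 2's
            d_a = dominance_dose(nA1, pair.hA)
            d_b = dominance_dose(2 - nB1, pair.hB)
            a_a = dominance_dose(2 - nA1, pair.hA)
            a_b = dominance_dose(nB1, pair.hB)
            val = (1.0 - pair.s1 * d_a * d_b) * (1.0 - pair.s2 * a_a * a_b)
            if pair.kind == "bdm_adaptive":
                val *= 1.0 + pair.s_adv * dominance_dose(nA1, pair.h_adv)
                val *= 1.0 + pair.s_adv * dominance_dose(2 - nB1, pair.h_adv)
            w[nA1, nB1] = val
    return np.maximum(w, 0.0)


def pair_fitness(pair: IncompatibilityPair, nA1: int, nB1: int) -> float:
    """Fitness of the genotype with ``nA1``/``nB1`` parent-1 alleles at the
    pair's two loci."""
    if nA1 not in (0, 1, 2) or nB1 not in (0, 1, 2):
        raise ValueError(f"allele counts must be in {{0,1,2}}, got ({nA1}, {nB1})")
    if pair.kind == "underdominant" and nB1 != nA1:
        raise ValueError("underdominant pairs have a single locus: nB1 must equal nA1")
    return float(pair_fitness_table(pair)[nA1, nB1])


def underdominant_fitness(pair: IncompatibilityPair, n1: int) -> float:
    """Fitness of a karyotype carrying ``n1`` parent-1 rearrangements."""
    if pair.kind != "underdominant":
        raise TypeError(f"pair {pair.id!r} has kind {pair.kind!r}, not underdominant")
    if n1 not in (0, 1, 2):
        raise ValueError(f"allele count must be 0, 1 or 2, got {n1}")
    return 1.0 - pair.s1 if n1 == 1 else 1.0


def individual_fitness(
    genotype: Sequence[tuple[int, int] | int],
    architecture: Architecture,
) -> float:
    """Product of pair fitnesses over the architecture.

    ``genotype`` holds one entry per pair, in architecture order: a
    ``(nA1, nB1)`` tuple, or a single count for underdominant pairs.
    """
    if len(genotype) != architecture.n_pairs:
        raise ValueError(
            f"genotype has {len(genotype)} entries for "
            f"{architecture.n_pairs} pairs"
        )
    w = 1.0
    for pair, g in zip(architecture.pairs, genotype):
        if isinstance(g, (int, np.integer)):
            g = (int(g), int(g))
        w *= pair_fitness(pair, g[0], g[1])
    return w


def expected_f1_fitness(architecture: Architecture) -> float:
    """Fitness of a first-generation hybrid: heterozygous at every locus."""
    return individual_fitness([(1, 1)] * architecture.n_pairs, architecture)


def calibrate_s_for_f1(n_pairs: int, h: float, target_w: float) -> float:
    """Symmetric selection coefficient giving a prescribed F1 fitness.

    Solves ``(1 - s * h**2) ** (2 * n_pairs) = target_w`` for ``s``, the
    common coefficient of ``n_pairs`` coevolving pairs with dominance ``h``
    at both loci.  Used to compare architectures of different sizes at equal
    total selection on F1 hybrids.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if not (0.0 < target_w <= 1.0):
        raise ValueError("target F1 fitness must lie in (0, 1]")
    if h <= 0.0:
        raise ValueError("calibration requires h > 0")
    s = (1.0 - target_w ** (1.0 / (2 * n_pairs))) / (h * h)
    if not (0.0 <= s <= 1.0):
        raise ValueError(
            f"no selection coefficient in [0, 1] achieves F1 fitness "
            f"{target_w} with {n_pairs} pairs at h={h} (would need s={s:.4g})"
        )
    return s


def architecture_tables(
    architecture: Architecture,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compile an architecture for array-based fitness evaluation.

    Returns ``(idxA, idxB, tables)``: per-pair indices into the sorted locus
    list (underdominant pairs repeat their single locus) and the stacked
    ``(n_pairs, 3, 3)`` fitness tables.
    """
    pl = architecture.pair_locus_indices()
    idxA = np.array([a for a, _ in pl], dtype=np.int64)
    idxB = np.array([b for _, b in pl], dtype=np.int64)
    if architecture.n_pairs:
        tables = np.stack([pair_fitness_table(p) for p in architecture.pairs])
    else:
        tables = np.empty((0, 3, 3), dtype=np.float64)
    return idxA, idxB, tables


def genotype_array_fitness(
    counts: np.ndarray,
    idxA: np.ndarray,
    idxB: np.ndarray,
    tables: np.ndarray,
) -> np.ndarray:
    """Vectorized fitness of many genotypes.

    ``counts`` is an ``(n, L)`` array of parent-1 allele counts at the sorted
    tracked loci.
    """
    if tables.shape[0] == 0:
        return np.ones(counts.shape[0])
    p = np.arange(tables.shape[0])
    w = tables[p[None, :], counts[:, idxA], counts[:, idxB]]
    return w.prod(axis=1)
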
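"""Jitted inner loops of the individual-based simulator.

Genomes are ``(n, 2, L)`` uint8 arrays of ancestry alleles (1 = parent 1,
0 = parent 2) at the tracked loci, sorted by (chromosome, position).
``seg_start``/``seg_end`` delimit the runs of loci sharing a chromosome.
Meiosis follows the one-obligate-crossover rule: per chromosome, a random
starting haplotype and a single crossover at a Uniform(0, 1) map position.

All randomness flows through a ``numpy.random.Generator`` passed in
explicitly, so replicate streams stay independent and reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BITCAP = 62  # usable coin-flip bits per 63-bit integer draw


@njit(cache=True, inline="always")
def _gamete_into(geno, parent, seg_start, seg_end, pos, rng, out, row, hap):
    """Write one gamete of ``parent`` into ``out[row, hap, :]``."""
    bits = rng.integers(0, 4611686018427387903)
    avail = _BITCAP
    for c in range(seg_start.shape[0]):
        if avail == 0:
            bits = rng.integers(0, 4611686018427387903)
            avail = _BITCAP
        start = int(bits & 1)
        bits >>= 1
        avail -= 1
        s = seg_start[c]
        e = seg_end[c]
        if e - s == 1:
            # single tracked locus: the crossover position is irrelevant
            out[row, hap, s] = geno[parent, start, s]
        else:
            x = rng.random()
            for l in range(s, e):
                if pos[l] < x:
                    out[row, hap, l] = geno[parent, start, l]
                else:
                    out[row, hap, l] = geno[parent, 1 - start, l]


@njit(cache=True)
def reproduce_once(
    geno,
    sex,
    n,
    capacity,
    seg_start,
    seg_end,
    pos,
    idxA,
    idxB,
    tables,
    brood_mean,
    max_broods,
    alpha,
    max_mate_trials,
    next_geno,
    next_sex,
    cnt,
    rng,
):
    """One non-overlapping generation: mating, viability selection and
    carrying-capacity regulation.

    Mating is exclusive pair formation: each female takes one unmated male
    (a uniform random matching; surplus individuals of the majority sex go
    unmated), optionally subject to assortative rejection at strength
    ``alpha``.  Brood sizes are Poisson with mean ``brood_mean`` in the
    first round and ``(capacity - survivors) / n_mated_females`` in top-up
    rounds from the same pairings, for at most ``max_broods`` broods per
    female.  Offspring survive with
    probability ``min(w, 1)`` where ``w`` is multiplicative incompatibility
    fitness.  Survivors are written into ``next_geno``/``next_sex``;
    per-locus parent-1 allele counts of the survivors accumulate in ``cnt``.

    Returns ``(n_survivors, fitness_sum)`` where ``fitness_sum`` is the sum
    of survivor fitnesses (for the mean-fitness census).
    """
    L = geno.shape[2]
    P = idxA.shape[0]
    for l in range(L):
        cnt[l] = 0
    nf = 0
    nm = 0
    females = np.empty(n, np.int64)
    males = np.empty(n, np.int64)
    for i in range(n):
        if sex[i] == 0:
            females[nf] = i
            nf += 1
        else:
            males[nm] = i
            nm += 1
    if nf == 0 or nm == 0:
        return 0, 0.0
    # shuffle both sexes: females so truncation at capacity is exchangeable,
    # males so exclusive pair formation is a uniform random matching
    for i in range(nf - 1, 0, -1):
        j = rng.integers(0, i + 1)
        t = females[i]
        females[i] = females[j]
        females[j] = t
    for i in range(nm - 1, 0, -1):
        j = rng.integers(0, i + 1)
        t = males[i]
        males[i] = males[j]
        males[j] = t
    # exclusive pair formation: each female takes one unmated male, for all
    # her broods; surplus individuals of the majority sex stay unmated
    mates = np.empty(nf, np.int64)
    if alpha > 0.0:
        # ancestry class: 0 hybrid, 1 pure parent 1, 2 pure parent 2
        cls = np.empty(n, np.int8)
        for i in range(n):
            all1 = True
            all0 = True
            for l in range(L):
                a = geno[i, 0, l]
                b = geno[i, 1, l]
                if a == 0 or b == 0:
                    all1 = False
                if a == 1 or b == 1:
                    all0 = False
                if not all1 and not all0:
                    break
            cls[i] = 1 if all1 else (2 if all0 else 0)
        n_mated = 0
        for k in range(nf):
            if n_mated >= nm:
                break
            f = females[k]
            chosen = n_mated
            if cls[f] != 0:
                # parental-classed female: scan the unmated males, rejecting
                # other-class candidates w.p. alpha, accepting the last
                # candidate once her trials are exhausted
                j = n_mated
                trials = 1
                while j < nm - 1 and trials < max_mate_trials:
                    m = males[j]
                    if cls[m] == cls[f] or rng.random() >= alpha:
                        break
                    j += 1
                    trials += 1
                chosen = j
            t = males[chosen]
            males[chosen] = males[n_mated]
            males[n_mated] = t
            mates[k] = males[n_mated]
            n_mated += 1
    else:
        n_mated = nf if nf < nm else nm
        for k in range(n_mated):
            mates[k] = males[k]

    total = 0
    fit_sum = 0.0
    mean_b = brood_mean
    for _round in range(max_broods):
        for k in range(n_mated):
            mother = females[k]
            father = mates[k]
            kids = rng.poisson(mean_b)
            for _ in range(kids):
                _gamete_into(geno, mother, seg_start, seg_end, pos, rng, next_geno, total, 0)
                _gamete_into(geno, father, seg_start, seg_end, pos, rng, next_geno, total, 1)
                w = 1.0
                for p in range(P):
                    nA = next_geno[total, 0, idxA[p]] + next_geno[total, 1, idxA[p]]
                    nB = next_geno[total, 0, idxB[p]] + next_geno[total, 1, idxB[p]]
                    w *= tables[p, nA, nB]
                if w >= 1.0 or rng.random() < w:
                    next_sex[total] = 0 if rng.random() < 0.5 else 1
                    fit_sum += w if w < 1.0 else 1.0
                    for l in range(L):
                        cnt[l] += next_geno[total, 0, l] + next_geno[total, 1, l]
                    total += 1
                    if total >= capacity:
                        return total, fit_sum
        if capacity - total <= 0:
            break
        mean_b = (capacity - total) / n_mated
    return total, fit_sum


@njit(cache=True)
def run_swarm(
    geno,
    sex,
    n0,
    capacity,
    seg_start,
    seg_end,
    pos,
    idxA,
    idxB,
    tables,
    brood_mean,
    max_broods,
    alpha,
    max_mate_trials,
    mig1,
    mig2,
    stop_when_fixed,
    freq,
    fit,
    size,
    rng,
):
    """Full replicate of a single hybrid swarm with optional pure-parental
    immigration.

    ``mig1``/``mig2`` hold the per-generation counts of pure parent-1 /
    parent-2 immigrants (pre-drawn Binomial counts; zeros for an isolated
    swarm).  Census arrays ``freq`` (parent-1 allele frequency per locus),
    ``fit`` (mean fitness of members) and ``size`` have ``n_gen + 1`` rows;
    row 0 is the founding census.

    Returns ``(extinct_generation, last_simulated_generation)`` with -1 for
    "never extinct".  When ``stop_when_fixed`` and every locus is fixed the
    remaining census rows are filled with the absorbed state.
    """
    G = mig1.shape[0]
    L = geno.shape[2]
    P = idxA.shape[0]
    next_geno = np.empty_like(geno)
    next_sex = np.empty_like(sex)
    cnt = np.empty(L, np.int64)
    n = n0

    # founding census
    for l in range(L):
        cnt[l] = 0
    w0 = 0.0
    for i in range(n):
        w = 1.0
        for p in range(P):
            nA = geno[i, 0, idxA[p]] + geno[i, 1, idxA[p]]
            nB = geno[i, 0, idxB[p]] + geno[i, 1, idxB[p]]
            w *= tables[p, nA, nB]
        w0 += w if w < 1.0 else 1.0
        for l in range(L):
            cnt[l] += geno[i, 0, l] + geno[i, 1, l]
    size[0] = n
    if n > 0:
        fit[0] = w0 / n
        for l in range(L):
            freq[0, l] = cnt[l] / (2.0 * n)
    else:
        fit[0] = np.nan
        for l in range(L):
            freq[0, l] = np.nan

    for g in range(1, G + 1):
        for _ in range(mig1[g - 1]):
            for l in range(L):
                geno[n, 0, l] = 1
                geno[n, 1, l] = 1
            sex[n] = 0 if rng.random() < 0.5 else 1
            n += 1
        for _ in range(mig2[g - 1]):
            for l in range(L):
                geno[n, 0, l] = 0
                geno[n, 1, l] = 0
            sex[n] = 0 if rng.random() < 0.5 else 1
            n += 1
        n2, fsum = reproduce_once(
            geno, sex, n, capacity, seg_start, seg_end, pos, idxA, idxB,
            tables, brood_mean, max_broods, alpha, max_mate_trials,
            next_geno, next_sex, cnt, rng,
        )
        tmp = geno
        geno = next_geno
        next_geno = tmp
        tmps = sex
        sex = next_sex
        next_sex = tmps
        n = n2
        size[g] = n
        if n == 0:
            for gg in range(g, G + 1):
                size[gg] = 0
                fit[gg] = np.nan
                for l in range(L):
                    freq[gg, l] = np.nan
            return g, g
        fit[g] = fsum / n
        for l in range(L):
            freq[g, l] = cnt[l] / (2.0 * n)
        if stop_when_fixed:
            fixed = True
            for l in range(L):
                if cnt[l] != 0 and cnt[l] != 2 * n:
                    fixed = False
                    break
            if fixed:
                for gg in range(g + 1, G + 1):
                    size[gg] = n
                    fit[gg] = fit[g]
                    for l in range(L):
                        freq[gg, l] = freq[g, l]
                return -1, g
    return -1, G
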
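# Methods

## The model

Two parental species are separated by a set of genetic incompatibilities:
pairs of loci whose cross-species allele combinations reduce fitness
(Bateson–Dobzhansky–Muller epistasis), or single underdominant
rearrangements.  A hybrid swarm founded by both species segregates for all
of these pairs simultaneously.  Selection against the cross-species
combinations drives each pair toward fixation of one parental combination
or the other; which parent wins at a given pair is decided by the founding
admixture proportion, dominance, and drift.  When at least one pair fixes
for each parent, backcrosses to *both* species suffer incompatibility
selection and the swarm is reproductively isolated from both — the
beginning of a hybrid species.  The package measures how often and how fast
this happens.

### Fitness construction

Each locus carries a parent-1 and a parent-2 ancestry allele.  By
convention the derived allele at locus A is parent 1's and the derived
allele at locus B is parent 2's.  With `g(n; h) ∈ {0, h, 1}` the dominance
dose of an allele carried in `n` copies, the fitness of the genotype with
`nA1` parent-1 alleles at A and `nB1` at B is

    w = A(nA1, nB1)
        × (1 − s1·g(nA1; hA)·g(2−nB1; hB))      # derived × derived
        × (1 − s2·g(2−nA1; hA)·g(nB1; hB))      # ancestral × ancestral

The kinds differ only in their parameters: coevolving pairs have `s1, s2 >
0`; neutral BDM pairs have `s2 = 0` (the ancestral combination is
compatible with both species); adaptive BDM pairs additionally multiply
fitness by `(1 + s_adv·g(n_derived; h_adv))` per locus, which is what
prevents fixation of the ancestral genotype under drift.  Underdominant
rearrangements are single loci with heterokaryotype fitness `1 − s1`.
Fitness across pairs is multiplicative and is interpreted as a survival
probability (capped at 1 in the individual-based simulator; no
renormalization when adaptive advantages push `w` above 1).

The exact numeric fitness tables are a reconstruction from the published
qualitative schemes; the double heterozygote deliberately incurs *both*
penalty terms, `(1 − s1·hA·hB)(1 − s2·hA·hB)`.  Under this constructor the
mean F1 fitness of random 20-pair architectures (s ~ Exponential, h ~
Uniform(0,1)) has the closed form `E[w_pair]^20` with
`E[w_pair] = 1 − 2·E[s]/4 + E[s]²/9`, giving ≈ 0.37 at mean s = 0.1 and
≈ 0.14 at mean s = 0.2 — close to, but not exactly, the published 0.38 and
0.1, which is the residual uncertainty of reconstructing an unpublished
matrix.

### Exact two-locus engine

Gamete frequencies `x1..x4` (gamete 1 = parent-1 allele at both loci)
follow the classical selection–recombination recursion

    xi' = xi·wi*/w̄ + εi·r·D·w14/w̄ ,   ε = (−1, +1, +1, −1)

with marginal fitnesses `wi* = Σj xj·wij`, mean fitness `w̄`, linkage
disequilibrium `D = x1x4 − x2x3` and recombination fraction `r`.  The
implementation is validated against a brute-force oracle that enumerates
all 16 ordered mating gamete pairs and applies Mendelian segregation
(agreement to 1e-12).  Because fitness depends on genotype, not phase, the
model requires `w14 = w23` and rejects matrices violating it.

Drift is a multinomial resample of `2N` gametes after the deterministic
step — the standard Wright–Fisher construction on the recursion's state
space.  A diploid-pair sampling variant (`diploid_sampling=True`) exists
for sensitivity checks; at these population sizes the two are
indistinguishable.

### Individual-based simulator

Diploid, sexual, non-overlapping generations; genomes are ancestry vectors
over the tracked loci only (no neutral sequence, no mutation — the model's
timescale is hundreds of generations).  Meiosis uses one obligate crossover
per chromosome at a Uniform(0,1) map position, so same-chromosome loci
recombine at their map distance and different chromosomes assort freely.

Life cycle per deme and generation: immigrants arrive (counts ~
Binomial(N_source, m); pure parental individuals when the source is a
fixed parental pool, sampled members otherwise); each female forms an
**exclusive pair** with one randomly chosen unmated male; broods are
Poisson(mean 2); offspring survive with probability `min(w, 1)`; if the
deme is below its carrying capacity `N`, top-up broods with Poisson mean
`(N − current)/n_mated_females` are drawn **from the same pairings**, at
most 10 broods per female; offspring replace parents and the census records
per-locus parent-1 allele frequency, mean fitness and deme size.

Exclusive pairing is a deliberate design choice.  With males sampled with
replacement (polygyny), male offspring-number variance is ~6 rather than
~2 and the one-generation drift variance implies Ne ≈ 0.53·N; the
simulator then disagrees with the `N`-parameterized two-locus Wright–Fisher
model it must match (single-pair benchmark) and depresses the two-pair
isolation probability to ~0.40.  With exclusive pairing the measured Ne is
≈ N (993 at N = 1000) and the two-pair baseline reproduces the published
47±2%.  Order within a generation is migration → mating/selection →
replacement → census; migrants join the mating pool and capacity is
enforced on the offspring generation (add-then-regulate).

### Detecting isolation

A pair is fixed for parent 1 at a census if the parent-1 allele frequency
is at or above the threshold at both of its loci (symmetrically for parent
2).  A replicate is isolated at the first census with at least one pair
fixed each way.  Outcomes {isolated_both, parent1_fixed, parent2_fixed,
mixed_unfixed, extinct} are exhaustive and exclusive; time to isolation is
averaged over isolated replicates only.

The threshold is exact fixation (1.0) for closed swarms.  Under ongoing
migration exact fixation is impossible: with immigrant fraction `m_tot`
against heterozygote selection `s·h`, a "fixed" locus equilibrates near
major-allele frequency `1 − m_tot/(s·h)` — about 0.96 at 4Nm = 8 per
parent with s = 0.1, h = 0.5.  The with-migration default is therefore
0.9: safely below the equilibrium, far above segregating frequencies.  (A
cutoff of 0.99 sits above the equilibrium and detects nothing in this
regime.)  The threshold is a reported config knob in all outputs.

## Synthetic scenario generators

`random_architecture` draws selection coefficients (fixed or exponential
with a given mean, redrawing values above 1 so fitness stays non-negative,
independently for s1/s2 or symmetric), dominance (fixed or Uniform(0,1))
and genomic placement (one locus per chromosome for "unlinked"; uniform
chromosome and position over a default 24-chromosome map — a typical fish
karyotype — for "random").  Demography presets: `isolated_swarm`,
`swarm_with_migration` (fixed parental pools feeding one swarm),
`stepping_stone`, and `twin_hybrids` (two swarms from the same parents,
optionally exchanging migrants).  The generator's defaults are the study
conditions: N = 1000 diploids, f = 0.5 founding admixture, 2000-generation
horizon, s = 0.1 and h = 0.5 for fixed architectures.

What the generator does *not* emulate: real genetic maps (all chromosomes
have unit map length and exactly one crossover), neutral diversity within
the parental species (founders are entirely homozygous), mutation,
inbreeding, selfing, and ecological or sexual selection beyond the optional
assortative-rejection knob.  Passing tests therefore show that the
*selection–drift–migration mechanism* behaves as published, not that any
particular natural hybrid zone will follow it.

## Numerical choices

- Randomness: every run consumes a single `numpy` SeedSequence; replicate
  streams are spawned children, so results are independent of scheduling
  and reproducible bit-for-bit from (config, master seed).
- The per-generation inner loops are numba-jitted; the one-swarm case
  (optionally with fixed parental immigration) runs an entire replicate
  inside one kernel, with immigrant counts pre-drawn.  Isolated runs stop
  early once every locus is fixed (the state is then absorbing) and the
  census is padded.
- Deterministic iteration stops at `fix_tol = 1e-9` (a gamete above
  `1 − fix_tol` or a step smaller than `fix_tol`); drift runs stop only at
  exact absorption.
- Capacity truncation mid-brood uses a shuffled female order, so the cut
  is exchangeable across families.
- Degenerate inputs: demes lacking either sex, or with zero surviving
  offspring, are extinct (a recorded outcome, not an error); an
  all-zero-fitness population raises an inviability error only in the
  deterministic engine, where the recursion is undefined.

## Problem sizes

The bundled test suite uses reduced sizes (N = 100–1000, 80–500
replicates) chosen so the whole suite runs in a few minutes while every
binomial comparison retains a 3-standard-error margin.
`scripts/acceptance.py` re-runs the headline ensembles at the study scale
(500 replicates of N = 1000 over 2000 generations for the fixed
architectures; 100 replicates with a fresh random architecture per
replicate for the 20-pair ensembles at mean s = 0.05 and 0.1, 500 at mean
s = 0.2; 10^5 Monte-Carlo draws for the F1-fitness expectations).

## Known limitations

- The fitness tables are reconstructions; see above.
- The skewed-founding case (f = 0.65, two pairs, N = 1000, s = 0.1):
  both the exact two-locus ensemble and the simulator give essentially 0%
  isolation — drift at Ne ≈ 1000 cannot overcome the deterministic pull to
  the major parent at these parameters.  Published supplementary analyses
  report a small nonzero probability under related conditions (smaller
  populations, dominance variation); those conditions are not fully
  specified, so this package reports the honest value for the stated
  parameters.
- Mean time to isolation for the two-pair baseline is ~250 generations
  here; published summaries quote a range up to 258 ± 38 for the weakest
  selection studied, with "~200" as round-number prose.
- The cross-population (twin-swarm) isolation criterion implemented — at
  least one pair fixed for opposite parents in the two swarms — is the
  natural reading, but published percentages for that experiment imply a
  stricter unstated criterion; the two are not comparable and no
  quantitative claim is made for it.
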
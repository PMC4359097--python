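"""Individual-based forward simulator of hybrid populations.

Diploid, sexual, non-overlapping generations.  Each generation of a deme:
immigrants arrive, every female forms an exclusive pair with one randomly
chosen unmated male (so offspring-number variance is Poisson for both sexes
and the effective size tracks the carrying capacity), broods
are Poisson-distributed, offspring survive with probability equal to their
multiplicative incompatibility fitness, and top-up broods from the same
pairings refill the deme to carrying capacity (at most ``max_broods`` broods
per female).  Offspring replace their parents; allele frequencies at every
tracked locus, mean fitness and deme size are censused each generation.

Genomes are ancestry vectors over the tracked incompatibility loci (1 =
parent-1 allele); no neutral sequence is carried.  Meiosis draws one
obligate crossover per chromosome at a Uniform(0, 1) map position, so two
loci on one chromosome recombine at a fraction equal to their map distance
and loci on different chromosomes assort independently (r = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernels
from .architecture import Architecture
from .demography import Demography, MigrationEdge
from .fitness import architecture_tables, genotype_array_fitness

__all__ = [
    "LifeCycleConfig",
    "Individual",
    "Deme",
    "Scenario",
    "ReplicateRecord",
    "CompiledArchitecture",
    "compile_architecture",
    "make_gamete",
    "initialize_hybrid_deme",
    "initialize_parental_deme",
    "reproduce_deme",
    "apply_migration",
    "run_replicate",
]

FEMALE, MALE = 0, 1


@dataclass(frozen=True)
class LifeCycleConfig:
    """Mating and brood parameters of the life cycle.

    ``brood_mean`` is the Poisson mean of the first brood; up to
    ``max_broods`` broods per female top the deme up to capacity.
    ``assort_reject_prob`` is the probability that a parental-classed female
    rejects a male of a different ancestry class (0 = random mating),
    redrawing at most ``max_mate_trials`` times.
    """

    brood_mean: float = 2.0
    max_broods: int = 10
    assort_reject_prob: float = 0.0
    max_mate_trials: int = 10

    def __post_init__(self) -> None:
        if self.brood_mean <= 0:
            raise ValueError("brood_mean must be > 0")
        if self.max_broods < 1 or self.max_mate_trials < 1:
            raise ValueError("max_broods and max_mate_trials must be >= 1")
        if not (0.0 <= self.assort_reject_prob <= 1.0):
            raise ValueError("assort_reject_prob must lie in [0, 1]")


@dataclass(frozen=True)
class Individual:
    """A diploid individual: two ancestry haplotypes over the tracked loci."""

    maternal: np.ndarray
    paternal: np.ndarray
    sex: int = FEMALE

    def __post_init__(self) -> None:
        if len(self.maternal) != len(self.paternal):
            raise ValueError("haplotypes must have equal length")


@dataclass
class Deme:
    """A population: genotype array ``(n, 2, L)`` plus sexes and capacity."""

    label: str
    capacity: int
    genomes: np.ndarray
    sex: np.ndarray
    role: str = "hybrid"

    @property
    def n(self) -> int:
        return self.genomes.shape[0]

    def allele_freq(self) -> np.ndarray:
        """Parent-1 allele frequency at every tracked locus (NaN if empty)."""
        if self.n == 0:
            return np.full(self.genomes.shape[2], np.nan)
        return self.genomes.mean(axis=(0, 1))

    def counts(self, compiled: "CompiledArchitecture") -> np.ndarray:
        """(n, L) parent-1 allele counts per individual."""
        return self.genomes.sum(axis=1, dtype=np.int64)

    def mean_fitness(self, compiled: "CompiledArchitecture") -> float:
        if self.n == 0:
            return float("nan")
        w = genotype_array_fitness(
            self.counts(compiled), compiled.idxA, compiled.idxB, compiled.tables
        )
        return float(np.minimum(w, 1.0).mean())

    def individuals(self) -> list[Individual]:
        return [
            Individual(self.genomes[i, 0].copy(), self.genomes[i, 1].copy(), int(self.sex[i]))
            for i in range(self.n)
        ]


@dataclass(frozen=True)
class CompiledArchitecture:
    """Array form of an architecture for the kernels.

    Loci are sorted by (chromosome, position); ``seg_start``/``seg_end``
    delimit same-chromosome runs; ``idxA``/``idxB``/``tables`` drive fitness.
    """

    architecture: Architecture
    chrom_of: np.ndarray
    pos: np.ndarray
    seg_start: np.ndarray
    seg_end: np.ndarray
    idxA: np.ndarray
    idxB: np.ndarray
    tables: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.pos.shape[0]


def compile_architecture(architecture: Architecture) -> CompiledArchitecture:
    loci = architecture.loci
    chrom_of = np.array([l.chromosome for l in loci], dtype=np.int64)
    pos = np.array([l.position for l in loci], dtype=np.float64)
    seg_start, seg_end = [], []
    for i, c in enumerate(chrom_of):
        if i == 0 or c != chrom_of[i - 1]:
            seg_start.append(i)
            if i > 0:
                seg_end.append(i)
    if len(chrom_of):
        seg_end.append(len(chrom_of))
    idxA, idxB, tables = architecture_tables(architecture)
    return CompiledArchitecture(
        architecture,
        chrom_of,
        pos,
        np.array(seg_start, dtype=np.int64),
        np.array(seg_end, dtype=np.int64),
        idxA,
        idxB,
        tables,
    )


def make_gamete(
    individual: Individual,
    compiled: CompiledArchitecture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Meiosis: one gamete, with one obligate crossover per chromosome.

    Per chromosome the starting haplotype is a fair coin and the crossover
    position is Uniform(0, 1); loci left of the crossover come from the
    starting haplotype, loci right of it from the other.
    """
    haps = np.stack([np.asarray(individual.maternal), np.asarray(individual.paternal)])
    out = np.empty(compiled.n_loci, dtype=haps.dtype)
    for s, e in zip(compiled.seg_start, compiled.seg_end):
        start = int(rng.integers(0, 2))
        x = rng.random()
        take_other = compiled.pos[s:e] >= x
        out[s:e] = np.where(take_other, haps[1 - start, s:e], haps[start, s:e])
    return out


def initialize_hybrid_deme(
    N: int,
    f: float,
    compiled: CompiledArchitecture,
    rng: np.random.Generator,
    label: str = "H",
) -> Deme:
    """Found a hybrid swarm: round(f*N) pure parent-1 individuals and the
    rest pure parent-2, sexes random."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("admixture proportion f must lie in [0, 1]")
    n1 = int(round(f * N))
    L = compiled.n_loci
    genomes = np.zeros((N, 2, L), dtype=np.uint8)
    genomes[:n1] = 1
    sex = (rng.random(N) < 0.5).astype(np.uint8)
    return Deme(label, N, genomes, sex, role="hybrid")


def initialize_parental_deme(
    N: int,
    parent: int,
    compiled: CompiledArchitecture,
    rng: np.random.Generator,
    label: str | None = None,
) -> Deme:
    if parent not in (1, 2):
        raise ValueError("parent must be 1 or 2")
    L = compiled.n_loci
    allele = 1 if parent == 1 else 0
    genomes = np.full((N, 2, L), allele, dtype=np.uint8)
    sex = (rng.random(N) < 0.5).astype(np.uint8)
    return Deme(label or f"P{parent}", N, genomes, sex, role=f"parental{parent}")


def _pure_individuals(
    count: int, parent: int, L: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    allele = 1 if parent == 1 else 0
    genomes = np.full((count, 2, L), allele, dtype=np.uint8)
    sex = (rng.random(count) < 0.5).astype(np.uint8)
    return genomes, sex


def reproduce_deme(
    deme: Deme,
    compiled: CompiledArchitecture,
    lifecycle: LifeCycleConfig,
    rng: np.random.Generator,
) -> Deme:
    """One generation of mating, viability selection and regulation.

    Returns the offspring generation (an empty deme is extinction).
    """
    c = compiled
    L = c.n_loci
    next_geno = np.empty((deme.capacity, 2, L), dtype=np.uint8)
    next_sex = np.empty(deme.capacity, dtype=np.uint8)
    cnt = np.empty(max(L, 1), dtype=np.int64)
    n_new, _ = _kernels.reproduce_once(
        np.ascontiguousarray(deme.genomes),
        np.ascontiguousarray(deme.sex),
        deme.n,
        deme.capacity,
        c.seg_start,
        c.seg_end,
        c.pos,
        c.idxA,
        c.idxB,
        c.tables,
        float(lifecycle.brood_mean),
        int(lifecycle.max_broods),
        float(lifecycle.assort_reject_prob),
        int(lifecycle.max_mate_trials),
        next_geno,
        next_sex,
        cnt,
        rng,
    )
    return Deme(deme.label, deme.capacity, next_geno[:n_new].copy(), next_sex[:n_new].copy(), deme.role)


def apply_migration(
    demes: Mapping[str, Deme],
    demography: Demography,
    compiled: CompiledArchitecture,
    rng: np.random.Generator,
) -> dict[str, Deme]:
    """Move migrants along every edge; counts are Binomial(N_source, m).

    Fixed (non-explicit) parental sources emit manufactured pure
    individuals; explicit demes emit sampled members, which leave the
    source.  Draws are based on pre-migration states, then applied at once.
    """
    L = compiled.n_loci
    incoming: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {k: [] for k in demes}
    leaving: dict[str, list[np.ndarray]] = {k: [] for k in demes}
    for edge in demography.edges:
        src_spec = demography.deme(edge.source)
        if src_spec.role != "hybrid" and not src_spec.explicit:
            count = int(rng.binomial(src_spec.capacity, edge.rate))
            if count and edge.dest in demes:
                parent = 1 if src_spec.role == "parental1" else 2
                incoming[edge.dest].append(_pure_individuals(count, parent, L, rng))
        else:
            src = demes[edge.source]
            count = int(rng.binomial(src_spec.capacity, edge.rate))
            count = min(count, src.n)
            if count:
                idx = rng.choice(src.n, size=count, replace=False)
                incoming[edge.dest].append(
                    (src.genomes[idx].copy(), src.sex[idx].copy())
                )
                leaving[edge.source].append(idx)
    out: dict[str, Deme] = {}
    for label, deme in demes.items():
        genomes, sex = deme.genomes, deme.sex
        if leaving[label]:
            gone = np.unique(np.concatenate(leaving[label]))
            keep = np.setdiff1d(np.arange(deme.n), gone, assume_unique=True)
            genomes, sex = genomes[keep], sex[keep]
        if incoming[label]:
            genomes = np.concatenate([genomes] + [g for g, _ in incoming[label]])
            sex = np.concatenate([sex] + [s for _, s in incoming[label]])
        out[label] = Deme(label, deme.capacity, genomes, sex, deme.role)
    return out


@dataclass
class Scenario:
    """Everything one replicate needs: architecture, demography, life cycle
    and the simulation horizon."""

    architecture: Architecture
    demography: Demography
    lifecycle: LifeCycleConfig = field(default_factory=LifeCycleConfig)
    generations: int = 2000
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "architecture": self.architecture.to_dict(),
            "demography": self.demography.to_dict(),
            "lifecycle": {
                "brood_mean": self.lifecycle.brood_mean,
                "max_broods": self.lifecycle.max_broods,
                "assort_reject_prob": self.lifecycle.assort_reject_prob,
                "max_mate_trials": self.lifecycle.max_mate_trials,
            },
            "run": {"generations": self.generations},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            architecture=Architecture.from_dict(d["architecture"]),
            demography=Demography.from_dict(d["demography"]),
            lifecycle=LifeCycleConfig(**d.get("lifecycle", {})),
            generations=int(d.get("run", {}).get("generations", 2000)),
            label=d.get("label", ""),
        )


@dataclass
class ReplicateRecord:
    """Per-generation census of one replicate.

    ``freq[label]`` is a ``(generations + 1, L)`` array of parent-1 allele
    frequencies at the sorted tracked loci (row 0 = founding census; NaN
    after extinction), with matching ``mean_fitness`` and ``size`` series.
    """

    architecture: Architecture
    generations: int
    freq: dict[str, np.ndarray]
    mean_fitness: dict[str, np.ndarray]
    size: dict[str, np.ndarray]
    extinct_generation: dict[str, int | None]
    seed: object = None

    @property
    def deme_labels(self) -> list[str]:
        return list(self.freq)

    def hybrid_label(self) -> str:
        return self.deme_labels[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: (generation, deme, locus_id, p1_freq, mean_fitness,
        pop_size)."""
        loci = self.architecture.loci
        rows = []
        for label in self.deme_labels:
            f = self.freq[label]
            for g in range(f.shape[0]):
                for li, locus in enumerate(loci):
                    rows.append(
                        (
                            g,
                            label,
                            f"chr{locus.chromosome}:{locus.position:.6f}",
                            f[g, li],
                            self.mean_fitness[label][g],
                            self.size[label][g],
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["generation", "deme", "locus_id", "p1_freq", "mean_fitness", "pop_size"],
        )


def _fast_path_edges(scenario: Scenario) -> tuple[bool, list[MigrationEdge]]:
    """Whether the fused single-swarm kernel applies, and the feeding edges."""
    demo = scenario.demography
    hybrids = demo.hybrid_demes
    if len(hybrids) != 1:
        return False, []
    target = hybrids[0].label
    feeding = []
    for e in demo.edges:
        src = demo.deme(e.source)
        if src.role == "hybrid" or src.explicit:
            return False, []
        if e.dest != target:
            continue  # migration into a fixed source is a no-op
        feeding.append(e)
    for d in demo.demes:
        if d.role != "hybrid" and d.explicit:
            return False, []
    return True, feeding


def run_replicate(scenario: Scenario, seed) -> ReplicateRecord:
    """Simulate one replicate; identical seeds give identical records."""
    rng = np.random.default_rng(seed)
    compiled = compile_architecture(scenario.architecture)
    fast, feeding = _fast_path_edges(scenario)
    if fast:
        return _run_fast(scenario, compiled, feeding, rng, seed)
    return _run_general(scenario, compiled, rng, seed)


def _run_fast(scenario, compiled, feeding, rng, seed) -> ReplicateRecord:
    demo = scenario.demography
    hyb = demo.hybrid_demes[0]
    G = scenario.generations
    L = compiled.n_loci
    mig1 = np.zeros(G, dtype=np.int64)
    mig2 = np.zeros(G, dtype=np.int64)
    for e in feeding:
        src = demo.deme(e.source)
        counts = rng.binomial(src.capacity, e.rate, size=G).astype(np.int64)
        if src.role == "parental1":
            mig1 += counts
        else:
            mig2 += counts
    total_mig = mig1 + mig2
    headroom = int(total_mig.max()) if G else 0
    absorbing = int(total_mig.sum()) == 0 if G else True
    cap = hyb.capacity
    geno = np.zeros((cap + headroom, 2, L), dtype=np.uint8)
    sex = np.zeros(cap + headroom, dtype=np.uint8)
    founders = initialize_hybrid_deme(cap, hyb.founding_f, compiled, rng, hyb.label)
    geno[:cap] = founders.genomes
    sex[:cap] = founders.sex
    freq = np.empty((G + 1, L), dtype=np.float64)
    fit = np.empty(G + 1, dtype=np.float64)
    size = np.empty(G + 1, dtype=np.int64)
    lc = scenario.lifecycle
    extinct, _last = _kernels.run_swarm(
        geno,
        sex,
        cap,
        cap,
        compiled.seg_start,
        compiled.seg_end,
        compiled.pos,
        compiled.idxA,
        compiled.idxB,
        compiled.tables,
        float(lc.brood_mean),
        int(lc.max_broods),
        float(lc.assort_reject_prob),
        int(lc.max_mate_trials),
        mig1,
        mig2,
        absorbing,  # fixation is absorbing only without immigration
        freq,
        fit,
        size,
        rng,
    )
    return ReplicateRecord(
        architecture=scenario.architecture,
        generations=G,
        freq={hyb.label: freq},
        mean_fitness={hyb.label: fit},
        size={hyb.label: size},
        extinct_generation={hyb.label: None if extinct < 0 else int(extinct)},
        seed=seed,
    )


def _run_general(scenario, compiled, rng, seed) -> ReplicateRecord:
    demo = scenario.demography
    G = scenario.generations
    L = compiled.n_loci
    tracked = [d for d in demo.demes if d.role == "hybrid" or d.explicit]
    demes: dict[str, Deme] = {}
    for d in tracked:
        if d.role == "hybrid":
            demes[d.label] = initialize_hybrid_deme(
                d.capacity, d.founding_f, compiled, rng, d.label
            )
        else:
            parent = 1 if d.role == "parental1" else 2
            demes[d.label] = initialize_parental_deme(
                d.capacity, parent, compiled, rng, d.label
            )
    freq = {d.label: np.full((G + 1, L), np.nan) for d in tracked}
    fit = {d.label: np.full(G + 1, np.nan) for d in tracked}
    size = {d.label: np.zeros(G + 1, dtype=np.int64) for d in tracked}
    extinct: dict[str, int | None] = {d.label: None for d in tracked}

    def census(g: int) -> None:
        for label, deme in demes.items():
            freq[label][g] = deme.allele_freq()
            fit[label][g] = deme.mean_fitness(compiled)
            size[label][g] = deme.n

    census(0)
    for g in range(1, G + 1):
        demes = apply_migration(demes, demo, compiled, rng)
        for label in list(demes):
            demes[label] = reproduce_deme(
                demes[label], compiled, scenario.lifecycle, rng
            )
            if demes[label].n == 0 and extinct[label] is None:
                extinct[label] = g
        census(g)
    return ReplicateRecord(
        architecture=scenario.architecture,
        generations=G,
        freq=freq,
        mean_fitness=fit,
        size=size,
        extinct_generation=extinct,
        seed=seed,
    )
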
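"""Architecture generators and demography presets.

Everything the experiments need is constructed here from parameters, so no
external data ships with the package: random incompatibility architectures
(exponentially distributed selection coefficients, uniform dominance,
random genomic placement) and the standard deme layouts (isolated swarm,
swarm fed by both parents, stepping-stone chain, twin hybrid swarms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import (
    Architecture,
    GenomeMap,
    IncompatibilityPair,
    LocusRef,
    unlinked_coevolving_architecture,
)
from .demography import Demography, DemeSpec, MigrationEdge
from .fitness import calibrate_s_for_f1
from .simulator import Scenario

__all__ = [
    "ArchitectureSpec",
    "random_architecture",
    "preset_demography",
    "example_scenario",
    "EXAMPLE_SCENARIOS",
]

#: default chromosome count for random placement (a typical fish karyotype)
DEFAULT_N_CHROMOSOMES = 24


@dataclass(frozen=True)
class ArchitectureSpec:
    """Recipe for a random architecture.

    ``s_mode`` is ``"fixed"`` (use ``s``) or ``"exponential"`` (draw from an
    exponential with mean ``s``, resampling draws above 1 so fitness stays
    non-negative).  ``symmetric_s`` reuses one draw for ``s1`` and ``s2``;
    otherwise the two are drawn independently ("variation in asymmetry").
    ``h_mode`` is ``"fixed"`` (use ``h``) or ``"uniform"``.  ``placement``
    is ``"unlinked"`` (every locus on its own chromosome), ``"random"``
    (uniform chromosome and position) or ``"explicit"`` (use ``loci``).
    """

    n_pairs: int
    kind: str = "coevolving"
    s_mode: str = "fixed"
    s: float = 0.1
    h_mode: str = "fixed"
    h: float = 0.5
    placement: str = "unlinked"
    symmetric_s: bool = True
    loci: tuple[LocusRef, ...] = ()
    s_adv: float = 0.01
    h_adv: float = 0.5

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.s_mode not in ("fixed", "exponential"):
            raise ValueError(f"unknown s_mode {self.s_mode!r}")
        if self.h_mode not in ("fixed", "uniform"):
            raise ValueError(f"unknown h_mode {self.h_mode!r}")
        if self.placement not in ("unlinked", "random", "explicit"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.s_mode == "exponential" and self.s <= 0:
            raise ValueError("exponential s_mode needs a positive mean")


def _draw_s(spec: ArchitectureSpec, rng: np.random.Generator) -> float:
    if spec.s_mode == "fixed":
        return spec.s
    while True:
        v = float(rng.exponential(spec.s))
        if v <= 1.0:
            return v


def random_architecture(
    spec: ArchitectureSpec,
    genome_map: GenomeMap | None = None,
    rng: np.random.Generator | None = None,
) -> Architecture:
    """Draw an architecture from the recipe; deterministic under a seeded rng."""
    rng = np.random.default_rng() if rng is None else rng
    loci_per_pair = 1 if spec.kind == "underdominant" else 2
    n_loci = loci_per_pair * spec.n_pairs
    if genome_map is None:
        if spec.placement == "unlinked":
            genome_map = GenomeMap(max(1, n_loci))
        else:
            genome_map = GenomeMap(DEFAULT_N_CHROMOSOMES)

    if spec.placement == "unlinked":
        if genome_map.n_chromosomes < n_loci:
            raise ValueError(
                f"unlinked placement of {n_loci} loci needs at least "
                f"{n_loci} chromosomes, genome map has {genome_map.n_chromosomes}"
            )
        loci = [LocusRef(c, 0.5) for c in range(n_loci)]
    elif spec.placement == "random":
        placed: set[tuple[int, float]] = set()
        loci = []
        while len(loci) < n_loci:
            c = int(rng.integers(0, genome_map.n_chromosomes))
            p = float(rng.random())
            if (c, p) not in placed:
                placed.add((c, p))
                loci.append(LocusRef(c, p))
    else:
        if len(spec.loci) != n_loci:
            raise ValueError(
                f"explicit placement needs {n_loci} loci, got {len(spec.loci)}"
            )
        loci = list(spec.loci)

    pairs = []
    for i in range(spec.n_pairs):
        s1 = _draw_s(spec, rng)
        s2 = s1 if spec.symmetric_s else _draw_s(spec, rng)
        hA = spec.h if spec.h_mode == "fixed" else float(rng.random())
        hB = spec.h if spec.h_mode == "fixed" else float(rng.random())
        kwargs = dict(s1=s1, s2=s2, hA=hA, hB=hB)
        if spec.kind == "underdominant":
            kwargs.update(locusA=loci[i], locusB=None, s2=0.0)
        else:
            kwargs.update(locusA=loci[2 * i], locusB=loci[2 * i + 1])
        if spec.kind in ("bdm_neutral", "bdm_adaptive"):
            kwargs["s2"] = 0.0
        if spec.kind == "bdm_adaptive":
            kwargs.update(s_adv=spec.s_adv, h_adv=spec.h_adv)
        pairs.append(IncompatibilityPair(id=f"pair{i}", kind=spec.kind, **kwargs))
    return Architecture(genome_map, pairs)


PRESETS = ("isolated_swarm", "swarm_with_migration", "stepping_stone", "twin_hybrids")


def preset_demography(
    name: str,
    N: int = 1000,
    f: float = 0.5,
    m1: float = 0.0,
    m2: float = 0.0,
    n_hybrid_demes: int = 3,
    m_between: float = 0.0,
) -> Demography:
    """Standard deme layouts.

    ``isolated_swarm``: one hybrid deme, no migration.
    ``swarm_with_migration``: one hybrid deme fed by fixed parental sources
    at per-generation fractions ``m1`` (parent 1) and ``m2`` (parent 2).
    ``stepping_stone``: a chain of ``n_hybrid_demes`` hybrid demes between
    parental ends, neighbours exchanging migrants at rate ``m_between``.
    ``twin_hybrids``: two hybrid swarms each fed by both parents, optionally
    exchanging migrants at rate ``m_between``.
    """
    p1 = DemeSpec("P1", N, role="parental1")
    p2 = DemeSpec("P2", N, role="parental2")
    if name == "isolated_swarm":
        return Demography(demes=[DemeSpec("H", N, founding_f=f)])
    if name == "swarm_with_migration":
        return Demography(
            demes=[p1, DemeSpec("H", N, founding_f=f), p2],
            edges=[MigrationEdge("P1", "H", m1), MigrationEdge("P2", "H", m2)],
        )
    if name == "stepping_stone":
        if n_hybrid_demes < 1:
            raise ValueError("need at least one hybrid deme")
        hybrids = [
            DemeSpec(f"H{i + 1}", N, founding_f=f) for i in range(n_hybrid_demes)
        ]
        edges = [
            MigrationEdge("P1", "H1", m1),
            MigrationEdge("P2", f"H{n_hybrid_demes}", m2),
        ]
        for i in range(n_hybrid_demes - 1):
            edges.append(MigrationEdge(f"H{i + 1}", f"H{i + 2}", m_between))
            edges.append(MigrationEdge(f"H{i + 2}", f"H{i + 1}", m_between))
        return Demography(demes=[p1, *hybrids, p2], edges=edges)
    if name == "twin_hybrids":
        ha = DemeSpec("H1", N, founding_f=f)
        hb = DemeSpec("H2", N, founding_f=f)
        edges = []
        for h in ("H1", "H2"):
            if m1 > 0:
                edges.append(MigrationEdge("P1", h, m1))
            if m2 > 0:
                edges.append(MigrationEdge("P2", h, m2))
        if m_between > 0:
            edges.append(MigrationEdge("H1", "H2", m_between))
            edges.append(MigrationEdge("H2", "H1", m_between))
        return Demography(demes=[p1, ha, hb, p2], edges=edges)
    raise ValueError(f"unknown demography preset {name!r}; choose from {PRESETS}")


def _baseline(n_pairs: int, s: float, **kw) -> Scenario:
    return Scenario(
        architecture=unlinked_coevolving_architecture(n_pairs, s=s, h=0.5),
        demography=preset_demography("isolated_swarm", **kw),
        label=f"{n_pairs}-pair isolated swarm, s={s}",
    )


def example_scenario(name: str, seed: int = 0) -> Scenario:
    """Named example configurations used throughout the documentation and
    experiments.  Random architectures are drawn with the given seed."""
    rng = np.random.default_rng(seed)
    if name == "two_pair_baseline":
        return _baseline(2, 0.1)
    if name == "two_pair_f1_080":
        s = calibrate_s_for_f1(2, 0.5, 0.8)
        return _baseline(2, s)
    if name == "two_pair_migration":
        m = Demography.rate_from_four_Nm(8.0, 1000)
        return Scenario(
            architecture=unlinked_coevolving_architecture(2, s=0.1, h=0.5),
            demography=preset_demography("swarm_with_migration", m1=m, m2=m),
            label="2-pair swarm with 4Nm=8 immigration from each parent",
        )
    if name == "twenty_pair_smean005":
        arch = random_architecture(
            ArchitectureSpec(
                n_pairs=20,
                s_mode="exponential",
                s=0.05,
                h_mode="uniform",
                placement="random",
                symmetric_s=False,
            ),
            rng=rng,
        )
        return Scenario(
            architecture=arch,
            demography=preset_demography("isolated_swarm"),
            label="20 random pairs, exponential s (mean 0.05)",
        )
    if name == "inversion_s005":
        arch = random_architecture(
            ArchitectureSpec(n_pairs=2, kind="underdominant", s=0.05), rng=rng
        )
        return Scenario(
            architecture=arch,
            demography=preset_demography("isolated_swarm"),
            label="two underdominant rearrangements, s=0.05",
        )
    raise ValueError(f"unknown example scenario {name!r}")


EXAMPLE_SCENARIOS = (
    "two_pair_baseline",
    "two_pair_f1_080",
    "two_pair_migration",
    "twenty_pair_smean005",
    "inversion_s005",
)
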
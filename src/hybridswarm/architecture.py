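"""Genetic architectures of hybrid incompatibility.

An :class:`Architecture` describes how two parental species differ: a genome
map (chromosome count; positions live in crossover-map units) and an ordered
list of :class:`IncompatibilityPair` objects.  Each pair is a two-locus
epistatic interaction (or a single underdominant rearrangement) with its own
selection coefficients ``s1``/``s2`` and per-locus dominance ``hA``/``hB``.

Four kinds of incompatibility are supported:

``coevolving``
    Both cross-parent allele combinations are deleterious (``s1 > 0`` and
    ``s2 > 0``): the two loci co-adapted within each lineage.
``bdm_neutral``
    A classic Bateson–Dobzhansky–Muller pair built from neutral
    substitutions; only the derived–derived combination is deleterious
    (``s2 = 0``), and the ancestral combination is compatible with both
    species.
``bdm_adaptive``
    As ``bdm_neutral`` but each derived allele carries a (weak) fitness
    advantage ``s_adv``, which prevents fixation of the ancestral genotype.
``underdominant``
    A single-locus rearrangement whose heterozygous carriers have fitness
    ``1 - s1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "KINDS",
    "LocusRef",
    "GenomeMap",
    "IncompatibilityPair",
    "Architecture",
]

KINDS = ("coevolving", "bdm_neutral", "bdm_adaptive", "underdominant")


@dataclass(frozen=True, order=True)
class LocusRef:
    """A tracked genomic position: chromosome index and map position in [0, 1)."""

    chromosome: int
    position: float

    def __post_init__(self) -> None:
        if self.chromosome < 0:
            raise ValueError(f"chromosome index must be >= 0, got {self.chromosome}")
        if not (0.0 <= self.position < 1.0):
            raise ValueError(f"position must lie in [0, 1), got {self.position}")


@dataclass(frozen=True)
class GenomeMap:
    """Number of chromosomes; every chromosome has unit map length."""

    n_chromosomes: int

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("a genome needs at least one chromosome")

    def contains(self, locus: LocusRef) -> bool:
        return 0 <= locus.chromosome < self.n_chromosomes


@dataclass(frozen=True)
class IncompatibilityPair:
    """One epistatic incompatibility between the two parental lineages.

    Allele orientation is fixed by convention: at locus A the derived allele
    is parent 1's, at locus B it is parent 2's.  The derived-by-derived
    penalty is ``s1`` and the ancestral-by-ancestral penalty is ``s2`` (zero
    for the BDM kinds).  ``underdominant`` pairs use only ``locusA`` and
    ``s1``.
    """

    id: str
    kind: str
    locusA: LocusRef
    locusB: LocusRef | None
    s1: float
    s2: float = 0.0
    hA: float = 0.5
    hB: float = 0.5
    s_adv: float = 0.0
    h_adv: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown incompatibility kind {self.kind!r}")
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("hA", "hB", "h_adv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.s_adv < 0:
            raise ValueError("s_adv must be >= 0")
        if self.kind == "underdominant":
            if self.locusB is not None:
                raise ValueError("underdominant pairs use a single locus (locusB=None)")
            if self.s2 != 0.0 or self.s_adv != 0.0:
                raise ValueError("underdominant pairs use only s1")
        else:
            if self.locusB is None:
                raise ValueError(f"{self.kind} pairs need two loci")
            if self.locusA == self.locusB:
                raise ValueError("locusA and locusB must differ")
        if self.kind in ("bdm_neutral", "bdm_adaptive") and self.s2 != 0.0:
            raise ValueError(f"{self.kind} requires s2 = 0 (asymmetry lives in s1)")
        if self.kind == "bdm_neutral" and self.s_adv != 0.0:
            raise ValueError("bdm_neutral requires s_adv = 0")
        if self.kind == "bdm_adaptive" and self.s_adv <= 0.0:
            raise ValueError("bdm_adaptive requires s_adv > 0")
        if self.kind == "coevolving" and self.s_adv != 0.0:
            raise ValueError("coevolving pairs carry no adaptive advantage")

    @property
    def loci(self) -> tuple[LocusRef, ...]:
        if self.locusB is None:
            return (self.locusA,)
        return (self.locusA, self.locusB)


@dataclass
class Architecture:
    """A genome map plus an ordered list of incompatibility pairs."""

    genome_map: GenomeMap
    pairs: list[IncompatibilityPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[LocusRef] = set()
        for pair in self.pairs:
            for locus in pair.loci:
                if not self.genome_map.contains(locus):
                    raise ValueError(
                        f"pair {pair.id!r}: locus {locus} outside the genome map"
                    )
                if locus in seen:
                    raise ValueError(f"pair {pair.id!r}: locus {locus} used twice")
                seen.add(locus)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def loci(self) -> list[LocusRef]:
        """All tracked loci, sorted by (chromosome, position)."""
        return sorted(l for pair in self.pairs for l in pair.loci)

    @property
    def n_loci(self) -> int:
        return sum(len(p.loci) for p in self.pairs)

    def locus_index(self) -> dict[LocusRef, int]:
        return {locus: i for i, locus in enumerate(self.loci)}

    def pair_locus_indices(self) -> list[tuple[int, int]]:
        """(index of locus A, index of locus B) per pair, in sorted-locus order.

        Underdominant pairs report their single locus twice.
        """
        index = self.locus_index()
        out = []
        for pair in self.pairs:
            a = index[pair.locusA]
            b = index[pair.locusB] if pair.locusB is not None else a
            out.append((a, b))
        return out

    def is_unlinked(self) -> bool:
        chroms = [l.chromosome for l in self.loci]
        return len(set(chroms)) == len(chroms)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genome_map": {"n_chromosomes": self.genome_map.n_chromosomes},
            "pairs": [_pair_to_dict(p) for p in self.pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Architecture":
        gm = GenomeMap(int(d["genome_map"]["n_chromosomes"]))
        pairs = [_pair_from_dict(p) for p in d["pairs"]]
        return cls(gm, pairs)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "Architecture":
        return cls.from_dict(json.loads(s))


def _pair_to_dict(pair: IncompatibilityPair) -> dict:
    d = asdict(pair)
    if d["locusB"] is None:
        del d["locusB"]
    return d


def _pair_from_dict(d: dict) -> IncompatibilityPair:
    d = dict(d)
    d["locusA"] = LocusRef(**d["locusA"])
    if d.get("locusB") is not None:
        d["locusB"] = LocusRef(**d["locusB"])
    else:
        d["locusB"] = None
    return IncompatibilityPair(**d)


def unlinked_coevolving_architecture(
    n_pairs: int,
    s: float | Sequence[float] = 0.1,
    h: float = 0.5,
) -> Architecture:
    """The workhorse architecture: ``n_pairs`` coevolving pairs, every locus
    on its own chromosome (pairwise recombination fraction 0.5), symmetric
    selection ``s1 = s2 = s`` and dominance ``hA = hB = h``.
    """
    svals = [float(s)] * n_pairs if isinstance(s, (int, float)) else [float(v) for v in s]
    if len(svals) != n_pairs:
        raise ValueError("need one s per pair")
    gm = GenomeMap(max(1, 2 * n_pairs))
    pairs = [
        IncompatibilityPair(
            id=f"pair{i}",
            kind="coevolving",
            locusA=LocusRef(2 * i, 0.5),
            locusB=LocusRef(2 * i + 1, 0.5),
            s1=svals[i],
            s2=svals[i],
            hA=h,
            hB=h,
        )
        for i in range(n_pairs)
    ]
    return Architecture(gm, pairs)
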
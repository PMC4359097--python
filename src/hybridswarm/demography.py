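"""Deme graphs: population labels, capacities, roles and migration edges."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DemeSpec", "MigrationEdge", "Demography"]

ROLES = ("parental1", "parental2", "hybrid")


@dataclass(frozen=True)
class DemeSpec:
    """One population.

    Parental demes default to fixed pure sources: they do not evolve, and
    migrants drawn from them are manufactured as pure parental individuals.
    Set ``explicit=True`` to simulate a parental deme as a real population.
    ``founding_f`` is the admixture proportion (fraction of founders from
    parent species 1) and applies to hybrid demes only.
    """

    label: str
    capacity: int
    role: str = "hybrid"
    founding_f: float = 0.5
    explicit: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown deme role {self.role!r}")
        if self.capacity < 1:
            raise ValueError("deme capacity must be >= 1")
        if not (0.0 <= self.founding_f <= 1.0):
            raise ValueError("founding admixture proportion must lie in [0, 1]")


@dataclass(frozen=True)
class MigrationEdge:
    """Directed per-generation migration at fraction ``rate`` of the source.

    The migrant count each generation is Binomial(source capacity, rate).
    """

    source: str
    dest: str
    rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("migration rate must lie in [0, 1]")
        if self.source == self.dest:
            raise ValueError("migration edge must join two distinct demes")


@dataclass
class Demography:
    """A deme graph with directed migration edges."""

    demes: list[DemeSpec] = field(default_factory=list)
    edges: list[MigrationEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [d.label for d in self.demes]
        if len(set(labels)) != len(labels):
            raise ValueError("deme labels must be unique")
        known = set(labels)
        for e in self.edges:
            if e.source not in known or e.dest not in known:
                raise ValueError(f"migration edge {e} references an unknown deme")

    def deme(self, label: str) -> DemeSpec:
        for d in self.demes:
            if d.label == label:
                return d
        raise KeyError(label)

    @property
    def hybrid_demes(self) -> list[DemeSpec]:
        return [d for d in self.demes if d.role == "hybrid"]

    def edges_into(self, label: str) -> list[MigrationEdge]:
        return [e for e in self.edges if e.dest == label]

    def four_Nm(self, edge: MigrationEdge) -> float:
        """Population-scaled migration rate 4*N*m of an edge (N of the
        destination deme)."""
        return 4.0 * self.deme(edge.dest).capacity * edge.rate

    @staticmethod
    def rate_from_four_Nm(four_nm: float, N: int) -> float:
        """Per-generation migrant fraction m with 4*N*m = ``four_nm``."""
        if four_nm < 0:
            raise ValueError("4Nm must be >= 0")
        return four_nm / (4.0 * N)

    def to_dict(self) -> dict:
        return {
            "demes": [
                {
                    "label": d.label,
                    "capacity": d.capacity,
                    "role": d.role,
                    "founding_f": d.founding_f,
                    "explicit": d.explicit,
                }
                for d in self.demes
            ],
            "edges": [
                {"source": e.source, "dest": e.dest, "rate": e.rate}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Demography":
        return cls(
            demes=[DemeSpec(**spec) for spec in d["demes"]],
            edges=[MigrationEdge(**e) for e in d.get("edges", [])],
        )
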
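"""Outcome detection and ensemble summaries.

A hybrid population counts as reproductively isolated from both parental
species once at least one incompatibility pair is fixed for the parent-1
allele combination and at least one other pair is fixed for parent 2: any
backcross to either parent then suffers incompatibility selection.  The
fixation threshold defaults to exact fixation; runs with ongoing migration
use a slightly lower cutoff because recurrent immigrant alleles preclude
exact fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import ReplicateRecord, Scenario, run_replicate

__all__ = [
    "OUTCOME_CLASSES",
    "IsolationResult",
    "pair_fixation_state",
    "fixation_codes",
    "detect_isolation",
    "classify_outcome",
    "isolation_probability",
    "bootstrap_mean",
    "mean_fitness_series",
    "cross_population_isolation",
    "replicate_seeds",
    "run_ensemble",
    "sweep",
]

OUTCOME_CLASSES = (
    "isolated_both",
    "parent1_fixed",
    "parent2_fixed",
    "mixed_unfixed",
    "extinct",
)

#: default fixation threshold when a deme receives ongoing migration.  Under
#: recurrent immigration at rate m against heterozygote selection s*h, a
#: "fixed" locus equilibrates near major-allele frequency 1 - m_tot/(s*h)
#: (about 0.96 at 4Nm = 8 per parent, s = 0.1, h = 0.5), so the cutoff must
#: sit well below that equilibrium while staying far from segregation.
MIGRATION_THRESHOLD = 0.9


def _check_threshold(threshold: float) -> None:
    if not (0.5 < threshold <= 1.0):
        raise ValueError("fixation threshold must lie in (0.5, 1]")


def fixation_codes(
    record: ReplicateRecord, threshold: float = 1.0, deme: str | None = None
) -> np.ndarray:
    """Per-generation, per-pair fixation code: +1 (parent 1 fixed at both
    loci), -1 (parent 2), 0 (segregating)."""
    _check_threshold(threshold)
    deme = deme or record.hybrid_label()
    freq = record.freq[deme]
    pl = record.architecture.pair_locus_indices()
    idxA = np.array([a for a, _ in pl], dtype=np.intp)
    idxB = np.array([b for _, b in pl], dtype=np.intp)
    fa, fb = freq[:, idxA], freq[:, idxB]
    with np.errstate(invalid="ignore"):
        p1 = (fa >= threshold) & (fb >= threshold)
        p2 = (fa <= 1.0 - threshold) & (fb <= 1.0 - threshold)
    return p1.astype(np.int8) - p2.astype(np.int8)


def pair_fixation_state(
    record: ReplicateRecord,
    generation: int,
    pair: int | str,
    threshold: float = 1.0,
    deme: str | None = None,
) -> str:
    """Fixation state of one pair at one census: ``fixed_P1`` iff the
    parent-1 allele frequency exceeds the threshold at both loci of the
    pair, ``fixed_P2`` symmetrically, else ``segregating``."""
    if isinstance(pair, str):
        ids = [p.id for p in record.architecture.pairs]
        if pair not in ids:
            raise KeyError(f"unknown pair id {pair!r}")
        pair = ids.index(pair)
    code = fixation_codes(record, threshold, deme)[generation, pair]
    return {1: "fixed_P1", -1: "fixed_P2", 0: "segregating"}[int(code)]


@dataclass(frozen=True)
class IsolationResult:
    isolated: bool
    generation: int | None
    pairs_fixed_P1: int
    pairs_fixed_P2: int


def detect_isolation(
    record: ReplicateRecord, threshold: float = 1.0, deme: str | None = None
) -> IsolationResult:
    """First census at which the deme is fixed for at least one pair toward
    each parental species; pair counts are reported at the horizon."""
    codes = fixation_codes(record, threshold, deme)
    joint = (codes == 1).any(axis=1) & (codes == -1).any(axis=1)
    c1 = int((codes[-1] == 1).sum())
    c2 = int((codes[-1] == -1).sum())
    if joint.any():
        return IsolationResult(True, int(np.argmax(joint)), c1, c2)
    return IsolationResult(False, None, c1, c2)


def classify_outcome(
    record: ReplicateRecord, threshold: float = 1.0, deme: str | None = None
) -> str:
    """Mutually exclusive replicate outcome at the horizon."""
    deme = deme or record.hybrid_label()
    iso = detect_isolation(record, threshold, deme)
    if iso.isolated:
        return "isolated_both"
    if record.extinct_generation.get(deme) is not None:
        return "extinct"
    n_pairs = record.architecture.n_pairs
    if n_pairs and iso.pairs_fixed_P1 == n_pairs:
        return "parent1_fixed"
    if n_pairs and iso.pairs_fixed_P2 == n_pairs:
        return "parent2_fixed"
    return "mixed_unfixed"


def isolation_probability(isolated) -> tuple[float, float]:
    """Fraction of isolated replicates and its two-standard-error band."""
    flags = np.asarray(
        [r if isinstance(r, (bool, np.bool_, int, np.integer)) else r.isolated for r in isolated],
        dtype=bool,
    )
    n = flags.size
    if n == 0:
        raise ValueError("need at least one replicate")
    p = flags.mean()
    return float(p), float(2.0 * np.sqrt(p * (1.0 - p) / n))


def bootstrap_mean(
    values, B: int = 1000, rng: np.random.Generator | None = None
) -> tuple[float, np.ndarray]:
    """Sample mean plus ``B`` means of with-replacement resamples."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("need at least one value")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, values.size, size=(B, values.size))
    return float(values.mean()), values[idx].mean(axis=1)


def mean_fitness_series(
    records: list[ReplicateRecord],
    normalize_to_parental: bool = False,
    deme: str | None = None,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cross-replicate mean fitness per generation, with a bootstrap band.

    With ``normalize_to_parental`` the series is divided by the mean fitness
    of pure parental individuals under the same architecture (exactly 1 for
    coevolving architectures; computed from the fitness tables otherwise).
    """
    if not records:
        raise ValueError("need at least one record")
    rng = np.random.default_rng() if rng is None else rng
    deme = deme or records[0].hybrid_label()
    horizon = records[0].generations
    if any(r.generations != horizon for r in records):
        raise ValueError("records must share a horizon")
    W = np.stack([r.mean_fitness[deme] for r in records])  # (R, G+1)
    if normalize_to_parental:
        from .fitness import individual_fitness

        arch = records[0].architecture
        w1 = individual_fitness([(2, 2)] * arch.n_pairs, arch)
        w2 = individual_fitness([(0, 0)] * arch.n_pairs, arch)
        W = W / ((min(w1, 1.0) + min(w2, 1.0)) / 2.0)
    mean = np.nanmean(W, axis=0)
    idx = rng.integers(0, W.shape[0], size=(B, W.shape[0]))
    boot = np.nanmean(W[idx], axis=1)  # (B, G+1)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "generation": np.arange(horizon + 1),
            "mean_fitness": mean,
            "boot_lo": lo,
            "boot_hi": hi,
        }
    )


def cross_population_isolation(
    recordA: ReplicateRecord,
    recordB: ReplicateRecord,
    threshold: float = 1.0,
    demeA: str | None = None,
    demeB: str | None = None,
) -> tuple[bool, list[int]]:
    """Whether two hybrid populations are isolated from each other: at least
    one pair fixed for opposite parental types at the horizon.  Returns the
    flag and the supporting pair indices."""
    if recordA.architecture.to_dict() != recordB.architecture.to_dict():
        raise ValueError("records must share an architecture")
    ca = fixation_codes(recordA, threshold, demeA)[-1]
    cb = fixation_codes(recordB, threshold, demeB)[-1]
    supporting = np.nonzero((ca * cb) == -1)[0]
    return bool(supporting.size), supporting.tolist()


def replicate_seeds(master_seed, reps: int) -> list[np.random.SeedSequence]:
    """Independent, scheduling-invariant per-replicate seed sequences."""
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed.spawn(reps)
    return np.random.SeedSequence(master_seed).spawn(reps)


def run_ensemble(
    scenario: Scenario,
    reps: int,
    master_seed: int,
    threshold: float = 1.0,
    census_at: tuple[int, ...] = (),
    keep_records: bool = False,
    collect_fitness: bool = False,
    deme: str | None = None,
):
    """Run ``reps`` replicates and tabulate per-replicate outcomes.

    Returns ``(table, records)``; ``records`` is None unless requested (or
    a stacked mean-fitness array when ``collect_fitness``).  The table has
    one row per replicate: outcome class, isolation generation and pair
    counts, plus ``pairs_P1_at_<g>``/``pairs_P2_at_<g>`` columns for every
    requested census generation.
    """
    _check_threshold(threshold)
    rows = []
    records = [] if keep_records else None
    fitness = [] if collect_fitness else None
    for i, ss in enumerate(replicate_seeds(master_seed, reps)):
        rec = run_replicate(scenario, ss)
        iso = detect_isolation(rec, threshold, deme)
        row = {
            "replicate": i,
            "outcome": classify_outcome(rec, threshold, deme),
            "isolated": iso.isolated,
            "isolation_generation": iso.generation,
            "n_pairs_P1": iso.pairs_fixed_P1,
            "n_pairs_P2": iso.pairs_fixed_P2,
        }
        if census_at:
            codes = fixation_codes(rec, threshold, deme)
            for g in census_at:
                row[f"pairs_P1_at_{g}"] = int((codes[g] == 1).sum())
                row[f"pairs_P2_at_{g}"] = int((codes[g] == -1).sum())
        rows.append(row)
        if keep_records:
            records.append(rec)
        if collect_fitness:
            fitness.append(rec.mean_fitness[deme or rec.hybrid_label()])
    table = pd.DataFrame(rows)
    if collect_fitness:
        return table, np.stack(fitness)
    return table, records


def sweep(
    scenarios: dict[str, Scenario] | list[tuple[str, Scenario]],
    reps: int,
    master_seed: int,
    threshold: float = 1.0,
    B: int = 1000,
) -> pd.DataFrame:
    """One summary row per scenario: isolation probability with 2-SE
    whiskers, mean isolation time among isolated replicates with a bootstrap
    band, and the outcome breakdown.

    Per-replicate seeds are derived from ``master_seed`` and the scenario
    name, so results do not depend on evaluation order.
    """
    items = list(scenarios.items()) if isinstance(scenarios, dict) else list(scenarios)
    rows = []
    for j, (name, scenario) in enumerate(items):
        cell_seed = np.random.SeedSequence([master_seed, j])
        table, _ = run_ensemble(scenario, reps, cell_seed, threshold)
        p, two_se = isolation_probability(table["isolated"].to_numpy())
        times = table.loc[table["isolated"], "isolation_generation"].to_numpy(float)
        if times.size:
            boot_rng = np.random.default_rng(np.random.SeedSequence([master_seed, j]))
            mean_t, boot = bootstrap_mean(times, B=B, rng=boot_rng)
            t_lo, t_hi = np.percentile(boot, [2.5, 97.5])
        else:
            mean_t = t_lo = t_hi = np.nan
        counts = table["outcome"].value_counts()
        row = {
            "scenario": name,
            "n_reps": reps,
            "threshold": threshold,
            "p_isolated": p,
            "two_se": two_se,
            "mean_isolation_time": mean_t,
            "boot_time_lo": t_lo,
            "boot_time_hi": t_hi,
        }
        for cls in OUTCOME_CLASSES:
            row[f"n_{cls}"] = int(counts.get(cls, 0))
        rows.append(row)
    return pd.DataFrame(rows)
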
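"""Exact two-locus selection–recombination dynamics, with optional drift.

State is the vector of gamete frequencies ``x = (x1, x2, x3, x4)`` where
gamete 1 carries the parent-1 allele at both loci, gametes 2 and 3 are the
recombinant types (P1 at A only, P2 at A only) and gamete 4 carries the
parent-2 allele at both loci.  One generation of random mating, viability
selection by a symmetric gamete-pair fitness matrix ``w`` and recombination
at fraction ``r`` gives

    xi' = xi * wi_star / w_bar + eps_i * r * D * w14 / w_bar

with marginal fitness ``wi_star = sum_j xj * wij``, mean fitness
``w_bar = sum_ij xi xj wij``, linkage disequilibrium ``D = x1*x4 - x2*x3``
and sign vector ``eps = (-1, +1, +1, -1)``.

A finite population of ``N`` diploids is modelled by resampling the
post-selection gamete pool: a multinomial draw of ``2N`` gametes (the
standard Wright–Fisher construction; a diploid-pair sampling variant is
available for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import IncompatibilityPair
from .fitness import pair_fitness_table

__all__ = [
    "EPSILON",
    "GameteFrequencies",
    "TwoLocusModel",
    "gamete_fitness_matrix",
    "selection_recombination_step",
    "iterate_deterministic",
    "wright_fisher_step",
    "fixation_ensemble",
]

#: fixed sign vector of the recombination term
EPSILON = np.array([-1.0, 1.0, 1.0, -1.0])

#: parent-1 allele count at locus A carried by each gamete class
_GAMETE_A1 = np.array([1, 1, 0, 0])
#: parent-1 allele count at locus B carried by each gamete class
_GAMETE_B1 = np.array([1, 0, 1, 0])


@dataclass(frozen=True)
class GameteFrequencies:
    """Frequencies of the four gamete classes; must sum to one."""

    x: np.ndarray

    def __init__(self, x1, x2=None, x3=None, x4=None):
        if x2 is None:
            arr = np.asarray(x1, dtype=np.float64)
        else:
            arr = np.array([x1, x2, x3, x4], dtype=np.float64)
        if arr.shape != (4,):
            raise ValueError("need four gamete frequencies")
        if np.any(arr < -1e-12):
            raise ValueError(f"gamete frequencies must be non-negative: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"gamete frequencies must sum to 1: {arr}")
        arr = np.clip(arr, 0.0, None)
        arr = arr / arr.sum()
        object.__setattr__(self, "x", arr)

    @property
    def D(self) -> float:
        """Linkage disequilibrium ``x1*x4 - x2*x3``."""
        x = self.x
        return float(x[0] * x[3] - x[1] * x[2])

    @property
    def pA(self) -> float:
        """Parent-1 allele frequency at locus A."""
        return float(self.x[0] + self.x[1])

    @property
    def pB(self) -> float:
        """Parent-1 allele frequency at locus B."""
        return float(self.x[0] + self.x[2])

    @classmethod
    def from_admixture(cls, f: float) -> "GameteFrequencies":
        """Founding state of a hybrid swarm: coupling gametes only."""
        if not (0.0 <= f <= 1.0):
            raise ValueError("admixture proportion must lie in [0, 1]")
        return cls(f, 0.0, 0.0, 1.0 - f)


def gamete_fitness_matrix(pair: IncompatibilityPair) -> np.ndarray:
    """Symmetric 4x4 gamete-pair fitness matrix for one incompatibility pair."""
    table = pair_fitness_table(pair)
    w = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            nA1 = _GAMETE_A1[i] + _GAMETE_A1[j]
            nB1 = _GAMETE_B1[i] + _GAMETE_B1[j]
            w[i, j] = table[nA1, nB1]
    return w


@dataclass(frozen=True)
class TwoLocusModel:
    """Parameters of the recursion: fitness matrix, recombination, size."""

    w: np.ndarray
    r: float = 0.5
    N: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if w.shape != (4, 4):
            raise ValueError("w must be a 4x4 matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("w must be symmetric (w_ij = w_ji)")
        if abs(w[0, 3] - w[1, 2]) > 1e-12:
            raise ValueError(
                "coupling and repulsion double heterozygotes must share one "
                "fitness (w14 = w23): fitness depends on genotype, not phase"
            )
        if np.any(w < 0):
            raise ValueError("fitness values must be non-negative")
        if not (0.0 <= self.r <= 0.5):
            raise ValueError("recombination fraction must lie in [0, 0.5]")
        if self.N is not None and self.N < 1:
            raise ValueError("population size must be >= 1")
        object.__setattr__(self, "w", w)

    @classmethod
    def from_pair(
        cls, pair: IncompatibilityPair, r: float = 0.5, N: int | None = None
    ) -> "TwoLocusModel":
        return cls(gamete_fitness_matrix(pair), r=r, N=N)


def _step_vec(X: np.ndarray, w: np.ndarray, r: float) -> np.ndarray:
    """One deterministic step applied to rows of gamete-frequency states."""
    wstar = X @ w                             # (R, 4) marginal fitnesses
    wbar = np.einsum("ri,ri->r", X, wstar)    # (R,) mean fitnesses
    if np.any(wbar <= 0):
        raise ZeroDivisionError("mean population fitness is zero: population inviable")
    D = X[:, 0] * X[:, 3] - X[:, 1] * X[:, 2]
    Xn = (X * wstar + EPSILON[None, :] * (r * w[0, 3]) * D[:, None]) / wbar[:, None]
    Xn = np.clip(Xn, 0.0, None)
    return Xn / Xn.sum(axis=1, keepdims=True)


def selection_recombination_step(
    x: GameteFrequencies, model: TwoLocusModel
) -> GameteFrequencies:
    """One generation of deterministic selection and recombination."""
    return GameteFrequencies(_step_vec(x.x[None, :], model.w, model.r)[0])


def iterate_deterministic(
    x0: GameteFrequencies,
    model: TwoLocusModel,
    max_generations: int = 2000,
    fix_tol: float = 1e-9,
) -> np.ndarray:
    """Iterate the recursion; returns the trajectory as a (T+1, 4) array.

    Stops early once a gamete class exceeds ``1 - fix_tol`` or the state
    changes by less than ``fix_tol`` in one generation.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    traj = [x0.x.copy()]
    X = x0.x[None, :]
    for _ in range(max_generations):
        Xn = _step_vec(X, model.w, model.r)
        traj.append(Xn[0].copy())
        if Xn.max() > 1.0 - fix_tol or np.abs(Xn - X).max() < fix_tol:
            break
        X = Xn
    return np.array(traj)


def _drift_sample(
    X: np.ndarray, N: int, rng: np.random.Generator, diploid: bool
) -> np.ndarray:
    if diploid:
        # sample N ordered diploid gamete pairs and count transmitted gametes
        P = X[:, :, None] * X[:, None, :]
        counts = rng.multinomial(N, P.reshape(X.shape[0], 16))
        counts = counts.reshape(X.shape[0], 4, 4)
        gam = counts.sum(axis=2) + counts.sum(axis=1)
        return gam / (2.0 * N)
    counts = rng.multinomial(2 * N, X)
    return counts / (2.0 * N)


def wright_fisher_step(
    x: GameteFrequencies,
    model: TwoLocusModel,
    rng: np.random.Generator,
    diploid_sampling: bool = False,
) -> GameteFrequencies:
    """Deterministic step followed by multinomial resampling of 2N gametes."""
    if model.N is None:
        raise ValueError("wright_fisher_step needs a finite population size N")
    Xn = _step_vec(x.x[None, :], model.w, model.r)
    return GameteFrequencies(_drift_sample(Xn, model.N, rng, diploid_sampling)[0])


OUTCOMES = ("fix_gamete1", "fix_gamete2", "fix_gamete3", "fix_gamete4", "unfixed")


def fixation_ensemble(
    model: TwoLocusModel,
    x0: GameteFrequencies,
    reps: int,
    max_gen: int,
    rng: np.random.Generator,
    diploid_sampling: bool = False,
):
    """Run ``reps`` Wright–Fisher replicates to absorption (or ``max_gen``).

    Returns a dict mapping outcome labels to ``(count, fraction, se)``, the
    binomial standard error attached to each fraction, plus the vector of
    absorption generations (-1 where unfixed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model.N is None:
        raise ValueError("fixation_ensemble needs a finite population size N")
    X = np.tile(x0.x, (reps, 1))
    absorbed = np.full(reps, -1, dtype=np.int64)
    outcome = np.full(reps, 4, dtype=np.int64)  # 4 = unfixed
    active = np.arange(reps)
    for gen in range(1, max_gen + 1):
        if active.size == 0:
            break
        Xa = _step_vec(X[active], model.w, model.r)
        Xa = _drift_sample(Xa, model.N, rng, diploid_sampling)
        X[active] = Xa
        fixed_class = np.argmax(Xa, axis=1)
        is_fixed = Xa[np.arange(Xa.shape[0]), fixed_class] >= 1.0
        newly = active[is_fixed]
        outcome[newly] = fixed_class[is_fixed]
        absorbed[newly] = gen
        active = active[~is_fixed]
    result = {}
    for k, label in enumerate(OUTCOMES):
        count = int((outcome == k).sum())
        frac = count / reps
        se = np.sqrt(frac * (1.0 - frac) / reps)
        result[label] = (count, frac, se)
    return result, absorbed
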
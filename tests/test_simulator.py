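"""Individual-based simulator: meiosis, life cycle, migration, replicates."""

import numpy as np
import pytest

from hybridswarm.architecture import (
    Architecture,
    GenomeMap,
    IncompatibilityPair,
    LocusRef,
    unlinked_coevolving_architecture,
)
from hybridswarm.demography import Demography, DemeSpec, MigrationEdge
from hybridswarm.scenarios import preset_demography
from hybridswarm.simulator import (
    Deme,
    Individual,
    LifeCycleConfig,
    Scenario,
    apply_migration,
    compile_architecture,
    initialize_hybrid_deme,
    initialize_parental_deme,
    make_gamete,
    reproduce_deme,
    run_replicate,
)


def _linked_architecture(p: float, q: float) -> Architecture:
    """Two loci of one pair on the same chromosome at positions p < q."""
    pair = IncompatibilityPair(
        id="p", kind="coevolving", locusA=LocusRef(0, p), locusB=LocusRef(0, q),
        s1=0.1, s2=0.1,
    )
    return Architecture(GenomeMap(1), [pair])


class TestMakeGamete:
    def test_homozygote_transmits_its_haplotype(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        hap = np.array([1, 0, 1, 0], dtype=np.uint8)
        ind = Individual(hap, hap.copy())
        for _ in range(5):
            assert (make_gamete(ind, compiled, rng) == hap).all()

    def test_unlinked_loci_recombine_freely(self, rng, two_pair_architecture):
        """Loci on different chromosomes: recombination fraction ~ 0.5."""
        compiled = compile_architecture(two_pair_architecture)
        ind = Individual(
            np.ones(4, dtype=np.uint8), np.zeros(4, dtype=np.uint8)
        )
        n = 20000
        gametes = np.array([make_gamete(ind, compiled, rng) for _ in range(n)])
        recomb = (gametes[:, 0] != gametes[:, 1]).mean()
        assert abs(recomb - 0.5) < 3 * np.sqrt(0.25 / n)

    @pytest.mark.parametrize("p,q", [(0.2, 0.5), (0.1, 0.9)])
    def test_linked_loci_recombine_at_map_distance(self, rng, p, q):
        """One obligate crossover per chromosome: the recombination fraction
        between two loci equals their map distance."""
        compiled = compile_architecture(_linked_architecture(p, q))
        ind = Individual(np.ones(2, dtype=np.uint8), np.zeros(2, dtype=np.uint8))
        n = 20000
        gametes = np.array([make_gamete(ind, compiled, rng) for _ in range(n)])
        recomb = (gametes[:, 0] != gametes[:, 1]).mean()
        d = q - p
        assert abs(recomb - d) < 3 * np.sqrt(d * (1 - d) / n)


class TestInitialization:
    def test_equal_admixture_counts(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_hybrid_deme(1000, 0.5, compiled, rng)
        assert deme.n == 1000
        n_pure1 = (deme.genomes.min(axis=(1, 2)) == 1).sum()
        assert n_pure1 == 500
        assert set(np.unique(deme.genomes)) <= {0, 1}

    def test_single_parent_founding(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_hybrid_deme(1000, 1.0, compiled, rng)
        assert (deme.genomes == 1).all()

    def test_first_generation_f1_fraction(self, rng, two_pair_architecture):
        """Random mating at f = 0.5 yields ~50% F1 hybrids in generation 1
        (slightly fewer among survivors, because F1s carry the double-
        heterozygote penalty at both pairs)."""
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_hybrid_deme(1000, 0.5, compiled, rng)
        offspring = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)
        geno = offspring.genomes
        is_f1 = ((geno[:, 0] == 1).all(axis=1) & (geno[:, 1] == 0).all(axis=1)) | (
            (geno[:, 0] == 0).all(axis=1) & (geno[:, 1] == 1).all(axis=1)
        )
        w_f1 = 0.950625**2
        expected = 0.5 * w_f1 / (0.5 + 0.5 * w_f1)  # survival-weighted
        # offspring share brood pairings, so the effective sample is the
        # ~500 pairings rather than the 1000 survivors
        assert abs(is_f1.mean() - expected) < 3 * np.sqrt(0.25 / 500)


class TestReproduceDeme:
    def test_capacity_reached_when_fitness_is_one(self, rng):
        arch = unlinked_coevolving_architecture(2, s=0.0)
        compiled = compile_architecture(arch)
        deme = initialize_hybrid_deme(500, 0.5, compiled, rng)
        out = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)
        assert out.n == 500

    def test_population_never_exceeds_capacity(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_hybrid_deme(300, 0.5, compiled, rng)
        for _ in range(5):
            deme = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)
            assert deme.n <= 300

    def test_zero_fitness_extinguishes_deme(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        compiled.tables[:] = 0.0  # lethal for every genotype
        deme = initialize_hybrid_deme(100, 0.5, compiled, rng)
        out = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)
        assert out.n == 0

    def test_single_sex_deme_goes_extinct(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_hybrid_deme(50, 0.5, compiled, rng)
        deme.sex[:] = 0  # females only
        out = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)
        assert out.n == 0

    def test_single_brood_survivor_mean_is_thinned_poisson(self, rng):
        """With one brood round, survivors per female ~ brood_mean x fitness."""
        pair = IncompatibilityPair(
            id="p", kind="coevolving", locusA=LocusRef(0, 0.5),
            locusB=LocusRef(1, 0.5), s1=0.2, s2=0.2,
        )
        arch = Architecture(GenomeMap(2), [pair])
        compiled = compile_architecture(arch)
        # every individual homozygous P1 at A, P2 at B: every offspring has
        # the same genotype and fitness 1 - s1 = 0.8
        n = 2000
        genomes = np.zeros((n, 2, 2), dtype=np.uint8)
        genomes[:, :, 0] = 1
        sex = (rng.random(n) < 0.5).astype(np.uint8)
        deme = Deme("H", 10**6, genomes, sex)
        n_pairs = min(int((sex == 0).sum()), int((sex == 1).sum()))
        lc = LifeCycleConfig(brood_mean=2.0, max_broods=1)
        out = reproduce_deme(deme, compiled, lc, rng)
        expected = n_pairs * 2.0 * 0.8
        sd = np.sqrt(n_pairs * 2.0 * 0.8)  # thinned-Poisson variance
        assert abs(out.n - expected) < 4 * sd

    def test_parental_deme_mean_fitness_is_one(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        deme = initialize_parental_deme(200, 1, compiled, rng)
        for _ in range(3):
            assert deme.mean_fitness(compiled) == 1.0
            deme = reproduce_deme(deme, compiled, LifeCycleConfig(), rng)


class TestMigration:
    def _demes(self, rng, compiled, N=200):
        return {
            "H": initialize_hybrid_deme(N, 0.5, compiled, rng, "H"),
        }

    def test_zero_migration_leaves_demes_unchanged(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        demo = preset_demography("swarm_with_migration", N=200, m1=0.0, m2=0.0)
        demes = self._demes(rng, compiled)
        out = apply_migration(demes, demo, compiled, rng)
        assert (out["H"].genomes == demes["H"].genomes).all()

    def test_migrant_count_mean_matches_binomial(self, rng, two_pair_architecture):
        """4Nm = 8 at N = 1000 means m = 0.002 and ~2 migrants/generation."""
        compiled = compile_architecture(two_pair_architecture)
        m = Demography.rate_from_four_Nm(8.0, 1000)
        assert m == pytest.approx(0.002)
        demo = preset_demography("swarm_with_migration", N=1000, m1=m, m2=0.0)
        demes = {"H": initialize_hybrid_deme(1000, 0.5, compiled, rng, "H")}
        draws = 3000
        total = 0
        for _ in range(draws):
            out = apply_migration(demes, demo, compiled, rng)
            total += out["H"].n - 1000
        mean = total / draws
        se = np.sqrt(1000 * m * (1 - m) / draws)
        assert abs(mean - 2.0) < 3 * se

    def test_migrants_from_fixed_source_are_pure(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        demo = preset_demography("swarm_with_migration", N=50, m1=0.5, m2=0.0)
        demes = {"H": initialize_hybrid_deme(50, 0.0, compiled, rng, "H")}
        out = apply_migration(demes, demo, compiled, rng)
        newcomers = out["H"].genomes[50:]
        assert newcomers.shape[0] > 0
        assert (newcomers == 1).all()

    def test_explicit_source_loses_its_migrants(self, rng, two_pair_architecture):
        compiled = compile_architecture(two_pair_architecture)
        demo = Demography(
            demes=[
                DemeSpec("H1", 100, role="hybrid"),
                DemeSpec("H2", 100, role="hybrid"),
            ],
            edges=[MigrationEdge("H1", "H2", 0.1)],
        )
        demes = {
            "H1": initialize_hybrid_deme(100, 0.5, compiled, rng, "H1"),
            "H2": initialize_hybrid_deme(100, 0.5, compiled, rng, "H2"),
        }
        out = apply_migration(demes, demo, compiled, rng)
        moved = out["H2"].n - 100
        assert moved > 0
        assert out["H1"].n == 100 - moved


class TestRunReplicate:
    def test_same_seed_gives_identical_records(self, two_pair_architecture):
        sc = Scenario(
            architecture=two_pair_architecture,
            demography=preset_demography("isolated_swarm", N=200),
            generations=100,
        )
        a = run_replicate(sc, 42)
        b = run_replicate(sc, 42)
        for label in a.freq:
            assert np.array_equal(a.freq[label], b.freq[label], equal_nan=True)
            assert np.array_equal(a.size[label], b.size[label])

    def test_neutral_fixation_probability_equals_founding_frequency(self):
        """Drift only: each locus fixes parent 1 with probability f."""
        arch = unlinked_coevolving_architecture(1, s=0.0)
        f = 0.3
        sc = Scenario(
            architecture=arch,
            demography=preset_demography("isolated_swarm", N=100, f=f),
            generations=3000,
        )
        reps = 200
        fixed_p1 = []
        for seed in range(reps):
            rec = run_replicate(sc, seed)
            final = rec.freq["H"][-1]
            fixed_p1.extend(final == 1.0)
        frac = np.mean(fixed_p1)
        se = np.sqrt(f * (1 - f) / (2 * reps))
        assert abs(frac - f) < 3 * se

    def test_census_shape_and_founding_row(self, two_pair_architecture):
        sc = Scenario(
            architecture=two_pair_architecture,
            demography=preset_demography("isolated_swarm", N=400),
            generations=50,
        )
        rec = run_replicate(sc, 7)
        assert rec.freq["H"].shape == (51, 4)
        assert np.allclose(rec.freq["H"][0], 0.5)
        assert rec.size["H"][0] == 400
        # founders are pure parentals, so founding mean fitness is 1
        assert rec.mean_fitness["H"][0] == pytest.approx(1.0)

    def test_general_driver_handles_twin_hybrid_demes(self, two_pair_architecture):
        sc = Scenario(
            architecture=two_pair_architecture,
            demography=preset_demography("twin_hybrids", N=150, m_between=0.01),
            generations=30,
        )
        rec = run_replicate(sc, 3)
        assert set(rec.freq) == {"H1", "H2"}
        for label in ("H1", "H2"):
            assert rec.size[label][-1] <= 150

    def test_record_frame_is_tidy(self, two_pair_architecture):
        sc = Scenario(
            architecture=two_pair_architecture,
            demography=preset_demography("isolated_swarm", N=100),
            generations=10,
        )
        df = run_replicate(sc, 1).to_frame()
        assert list(df.columns) == [
            "generation", "deme", "locus_id", "p1_freq", "mean_fitness", "pop_size",
        ]
        assert len(df) == 11 * 4
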
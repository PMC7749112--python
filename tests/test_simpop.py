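"""Tests for the forward simulator: mutation-effect draws, reproduction
modes, gene conversion, equilibrium initialisation, determinism, and the
hybrid scenario."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from clonescan import _kernels
from clonescan.simpop import (
    PAPER_PRESET,
    SCALED_PRESET,
    Population,
    SimConfig,
    advance_generation,
    apply_conversion,
    draw_dfe_effect,
    equilibrium_population,
    run_simulation,
    simulate_hybrid_scenario,
)

TINY = SimConfig(
    pop_size=60,
    genome_length=2000,
    mutation_rate=3e-5,
    crossover_rate=3e-5,
    n_generations=400,
    sample_size=8,
    seed=7,
)


@pytest.fixture(scope="module")
def tiny_sample():
    return run_simulation(TINY)


class TestConfig:
    def test_presets_preserve_population_scaled_rates(self):
        assert PAPER_PRESET.theta_bp == pytest.approx(0.01)
        assert SCALED_PRESET.theta_bp == pytest.approx(0.01)
        assert SCALED_PRESET.rho_bp == pytest.approx(0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cloning_rate": 1.5},
            {"mutation_rate": -1e-9},
            {"pop_size": 1},
            {"dfe_shape": 0.0},
            {"sample_size": 100, "pop_size": 50},
            {"sites_model": "finite4", "init": "equilibrium"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDfe:
    def test_deleterious_draws_are_nonpositive(self):
        rng = np.random.default_rng(0)
        cfg = replace(TINY, deleterious_fraction=1.0)
        draws = [draw_dfe_effect(cfg, rng) for _ in range(500)]
        assert all(s <= 0 for s in draws)

    def test_mean_effect_matches_dfe(self):
        rng = np.random.default_rng(1)
        cfg = replace(TINY, deleterious_fraction=1.0)
        draws = np.array([draw_dfe_effect(cfg, rng) for _ in range(60_000)])
        # sd of one draw = |mean|/sqrt(shape); MC error ~ 4e-4
        assert draws.mean() == pytest.approx(-0.01, abs=8e-4)

    def test_neutral_fraction(self):
        rng = np.random.default_rng(2)
        draws = np.array([draw_dfe_effect(TINY, rng) for _ in range(20_000)])
        frac_zero = (draws == 0).mean()
        assert frac_zero == pytest.approx(1 - 0.4 / 1.4, abs=0.02)

    def test_all_neutral_when_fraction_zero(self):
        rng = np.random.default_rng(3)
        cfg = replace(TINY, deleterious_fraction=0.0)
        assert all(draw_dfe_effect(cfg, rng) == 0.0 for _ in range(200))


class TestConversion:
    def test_alpha_zero_identity(self):
        rng = np.random.default_rng(0)
        pair = rng.integers(0, 2, size=(2, 50)).astype(np.int8)
        assert np.array_equal(apply_conversion(pair, 0.0, rng), pair)

    def test_alpha_one_removes_all_heterozygosity(self):
        rng = np.random.default_rng(1)
        pair = rng.integers(0, 2, size=(2, 200)).astype(np.int8)
        out = apply_conversion(pair, 1.0, rng)
        assert np.all(out[0] == out[1])
        # homozygous sites unchanged
        hom = pair[0] == pair[1]
        assert np.array_equal(out[0][hom], pair[0][hom])

    def test_donor_balance(self):
        rng = np.random.default_rng(2)
        pair = np.array([[0], [1]], dtype=np.int8)
        wins_hap1 = 0
        n = 20_000
        for _ in range(n):
            out = apply_conversion(pair, 1.0, rng)
            wins_hap1 += out[0, 0] == 0 and out[1, 0] == 0
        assert wins_hap1 / n == pytest.approx(0.5, abs=0.02)

    def test_allele_frequency_conserved_in_expectation(self):
        rng = np.random.default_rng(3)
        n_rep, n_sites = 4000, 30
        deltas = np.empty(n_rep)
        for k in range(n_rep):
            pair = rng.integers(0, 2, size=(2, n_sites)).astype(np.int8)
            out = apply_conversion(pair, 0.5, rng)
            deltas[k] = out.mean() - pair.mean()
        se = deltas.std(ddof=1) / np.sqrt(n_rep)
        assert abs(deltas.mean()) < 3 * se + 1e-12


class TestReproduction:
    def test_pure_clonal_offspring_resample_parent_pairs(self):
        cfg = replace(TINY, cloning_rate=1.0, mutation_rate=0.0, conversion_rate=0.0)
        rng = np.random.default_rng(5)
        pop = equilibrium_population(replace(cfg, init="equilibrium",
                                             sites_model="infinite"), rng)
        parent_pairs = {
            (pop.haplotypes[2 * i].tobytes(), pop.haplotypes[2 * i + 1].tobytes())
            for i in range(cfg.pop_size)
        }
        child = advance_generation(pop, cfg, rng)
        for i in range(cfg.pop_size):
            pair = (child.haplotypes[2 * i].tobytes(), child.haplotypes[2 * i + 1].tobytes())
            assert pair in parent_pairs

    def test_neutral_parent_selection_uniform(self):
        # with all fitness effects absent, parent usage is multinomial(Ne, 1/Ne);
        # identify clonal parents by unique genotype patterns
        ne = 16
        cfg = SimConfig(pop_size=ne, genome_length=100, mutation_rate=0.0,
                        crossover_rate=0.0, cloning_rate=1.0, n_generations=1,
                        sample_size=4)
        # base-4 identity patterns over 2 columns
        haps = np.zeros((2 * ne, 2), dtype=np.int8)
        for i in range(ne):
            haps[2 * i] = haps[2 * i + 1] = [i // 4, i % 4]
        counts = np.zeros(ne)
        rng = np.random.default_rng(11)
        pop = Population(config=cfg, haplotypes=haps, positions=np.array([10.0, 20.0]),
                         eff_allele=np.zeros(2, np.int8), eff_s=np.zeros(2))
        n_rounds = 60
        for _ in range(n_rounds):
            child = advance_generation(pop, cfg, rng)
            for i in range(ne):
                pat = child.haplotypes[2 * i]
                counts[int(pat[0]) * 4 + int(pat[1])] += 1
        chi2, p = stats.chisquare(counts)
        assert p > 0.001

    def test_determinism(self):
        a = run_simulation(TINY)
        b = run_simulation(TINY)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.global_positions, b.global_positions)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert a.genotypes.individuals == b.genotypes.individuals

    def test_genotypes_consistent_with_truth_haplotypes(self, tiny_sample):
        from clonescan.core import genotypes_from_haplotypes

        assert np.array_equal(
            tiny_sample.genotypes.genotypes,
            genotypes_from_haplotypes(tiny_sample.haplotypes),
        )

    def test_meselson_effect_under_strict_clonality(self):
        cfg = SimConfig(pop_size=60, genome_length=2000, mutation_rate=4e-5,
                        crossover_rate=0.0, cloning_rate=1.0, n_generations=600,
                        sample_size=8, seed=3)
        ss = run_simulation(cfg)
        g = ss.genotypes.genotypes
        het = g[:, :, 0] != g[:, :, 1]
        frac_all_het = het.all(axis=1).mean()
        assert frac_all_het > 0.4


class TestEquilibriumInit:
    def test_diversity_and_site_count_match_neutral_theory(self):
        cfg = SimConfig(pop_size=200, genome_length=20_000, mutation_rate=1.25e-5,
                        n_generations=0, init="equilibrium", n_contigs=20)
        n = 2 * cfg.pop_size
        pis, ss = [], []
        for seed in range(5):
            pop = equilibrium_population(cfg, np.random.default_rng(seed))
            f = pop.haplotypes.mean(axis=0)
            pis.append((2 * f * (1 - f) * n / (n - 1)).sum() / cfg.genome_length)
            ss.append(pop.n_sites)
        theta = cfg.theta_bp
        a_n = (1.0 / np.arange(1, n)).sum()
        assert np.mean(pis) == pytest.approx(theta, rel=0.2)
        assert np.mean(ss) == pytest.approx(theta * cfg.genome_length * a_n, rel=0.2)

    def test_matches_msprime_oracle_sfs(self):
        # independent coalescent oracle: compare folded SFS shape and
        # segregating-site counts on matched parameters
        msprime = pytest.importorskip("msprime")
        n_tips, theta_locus, reps = 40, 8.0, 40
        mine, oracle = [], []
        cfg = SimConfig(pop_size=n_tips // 2, genome_length=1000,
                        mutation_rate=theta_locus / (4 * (n_tips // 2) * 1000),
                        n_generations=0, init="equilibrium", n_contigs=1)
        for seed in range(reps):
            pop = equilibrium_population(cfg, np.random.default_rng(seed))
            mine.append(pop.n_sites)
            # haploid-copies model: pairwise coalescence rate 1/(2*Ne), so the
            # msprime haploid population holds 2*Ne copies
            ts = msprime.sim_ancestry(
                samples=n_tips, ploidy=1, population_size=n_tips,
                random_seed=seed + 1,
            )
            mts = msprime.sim_mutations(
                ts, rate=theta_locus / (4 * (n_tips // 2)), random_seed=seed + 1,
                discrete_genome=False,
            )
            oracle.append(mts.num_sites)
        t, p = stats.ttest_ind(mine, oracle)
        assert p > 0.01, (np.mean(mine), np.mean(oracle))


class TestKernelEquivalence:
    def test_numba_and_numpy_paths_agree(self, monkeypatch):
        rng = np.random.default_rng(0)
        haps = rng.integers(0, 2, size=(40, 25)).astype(np.int8)
        src = rng.integers(0, 40, size=40)
        cols = np.arange(0, 25, 3)
        ea = np.ones(cols.size, np.int8)
        es = -rng.gamma(0.1, 0.1, cols.size)
        positions = np.sort(rng.uniform(0, 1000, 25))
        fixups = [(3, 4, 5, np.array([200.0, 700.0])), (7, 10, 11, np.array([500.0]))]

        def run_all():
            out = np.empty((40, 28), np.int8)
            out[:, 25:] = 0
            _kernels.offspring_copy(haps, src, out)
            _kernels.apply_crossovers(haps, positions, out, fixups)
            w = _kernels.fitness_multiplicative(haps, cols, ea, es)
            return out.copy(), w

        out_nb, w_nb = run_all()
        monkeypatch.setattr(_kernels, "HAVE_NUMBA", False)
        out_np, w_np = run_all()
        assert np.array_equal(out_nb, out_np)
        assert np.allclose(w_nb, w_np, rtol=1e-12)


@pytest.fixture(scope="module")
def hybrid_sample():
    cfg = SimConfig(pop_size=80, genome_length=5000, mutation_rate=2.5e-5,
                    crossover_rate=2.5e-5, n_generations=300, sample_size=8,
                    seed=21, init="equilibrium", n_contigs=5)
    return simulate_hybrid_scenario(
        cfg, replace(cfg, seed=22), split_generations=1600, n_hybrids=3,
        burnin_generations=300, n_sample_a=6, n_sample_b=6,
    )


class TestHybridScenario:
    def test_no_divergence_hybrids_look_ordinary(self):
        cfg = SimConfig(pop_size=60, genome_length=4000, mutation_rate=2.5e-5,
                        crossover_rate=2.5e-5, n_generations=200, sample_size=6,
                        seed=31, init="equilibrium", n_contigs=4)
        ss = simulate_hybrid_scenario(cfg, replace(cfg, seed=32), 0, 3,
                                      burnin_generations=400, n_sample_a=6)
        g = ss.genotypes.genotypes
        het = (g[:, :, 0] != g[:, :, 1]).mean(axis=0)
        hyb = [i for i, l in enumerate(ss.individuals) if l.startswith("H")]
        rest = [i for i in range(len(ss.individuals)) if i not in hyb]
        t, p = stats.ttest_ind(het[hyb], het[rest])
        assert p > 0.01

    def test_long_split_hybrids_more_heterozygous(self, hybrid_sample):
        ss = hybrid_sample
        g = ss.genotypes.genotypes
        het = (g[:, :, 0] != g[:, :, 1]).mean(axis=0)
        hyb = [i for i, l in enumerate(ss.individuals) if l.startswith("H")]
        rest = [i for i in range(len(ss.individuals)) if i not in hyb]
        assert het[hyb].mean() > 1.5 * het[rest].mean()

    def test_hybrid_haplotypes_nearest_in_different_populations(self, hybrid_sample):
        ss = hybrid_sample
        h = ss.haplotypes
        origins = np.array(ss.origins)
        labels = [l for l in ss.individuals]
        for k, lab in enumerate(labels):
            if not lab.startswith("H"):
                continue
            for hap_k in (0, 1):
                row = 2 * k + hap_k
                d = (h != h[row]).sum(axis=1).astype(float)
                d[2 * k] = d[2 * k + 1] = np.inf  # exclude own individual
                nearest = int(np.argmin(d))
                assert origins[nearest] == origins[row]


class TestWriteSample:
    def test_unphased_export_drops_phase(self, tiny_sample, tmp_path):
        from clonescan.simpop import write_sample

        paths = write_sample(tiny_sample, tmp_path, phased=False)
        text = paths["vcf"].read_text()
        body = [l for l in text.splitlines() if not l.startswith("#")]
        assert body and all("|" not in l for l in body)
        assert "PS" not in text.split("#CHROM")[0] or "Phase set" not in text

    def test_monomorphic_sample_writes_valid_empty_vcf(self, tmp_path):
        import warnings
        from clonescan import io as cio
        from clonescan.simpop import write_sample

        cfg = replace(TINY, mutation_rate=0.0, n_generations=5, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ss = run_simulation(cfg)
        assert ss.is_empty()
        paths = write_sample(ss, tmp_path)
        m, haps, ps = cio.read_vcf(paths["vcf"])
        assert m.n_sites == 0 and m.individuals == ss.individuals
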
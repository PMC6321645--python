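"""Synthetic-data generator: parents, homoeology, pedigree, read sampling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genome, make_truth
from wheatbsa.simulate import (
    BULK_NAMES,
    PARENT_A,
    PARENT_B,
    ConfigurationError,
    DepthModel,
    GenomeConfig,
    HomoeologConfig,
    HomoeologModel,
    PedigreeConfig,
    add_homoeology,
    expected_homozygosity,
    sample_allele_counts,
    simulate_parents,
    simulate_pedigree,
    simulate_selfing_series,
    simulate_tetraploid_counts,
)


class TestSimulateParents:
    def test_site_count_conserved(self):
        cfg = GenomeConfig(allelic_sites_per_chromosome=500)
        genome = simulate_parents(cfg, seed=3)
        assert genome.n_sites == 7 * 500
        # biallelic with distinct parental bases, strictly increasing positions
        assert (genome.sites["parent_a"] != genome.sites["parent_b"]).all()
        for chrom, _ in cfg.chromosomes:
            pos = genome.sites_on(chrom)["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()

    def test_deterministic_under_seed(self):
        cfg = GenomeConfig(allelic_sites_per_chromosome=50)
        assert simulate_parents(cfg, seed=11).equals(simulate_parents(cfg, seed=11))
        assert not simulate_parents(cfg, seed=11).equals(simulate_parents(cfg, seed=12))

    def test_zero_sites_on_noncausal_chromosome_is_valid(self):
        cfg = GenomeConfig(
            allelic_sites_per_chromosome={"1D": 0, "2D": 10, "3D": 5},
            chromosomes=(("1D", 10**6), ("2D", 10**6), ("3D", 10**6)),
            causal_pos=500_000,
        )
        genome = simulate_parents(cfg, seed=0)
        assert len(genome.sites_on("1D")) == 0
        assert len(genome.sites_on("2D")) == 10

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_parents(
                GenomeConfig(chromosomes=(("2D", 0),), allelic_sites_per_chromosome=5,
                             causal_pos=1), seed=0
            )
        with pytest.raises(ConfigurationError):
            simulate_parents(
                GenomeConfig(
                    chromosomes=(("1D", 10**6), ("2D", 10**6)),
                    allelic_sites_per_chromosome={"1D": 5, "2D": 0},
                    causal_pos=500_000,
                ),
                seed=0,
            )


class TestHomoeology:
    def test_rho_bounds_and_divergent_bases(self):
        gcfg = GenomeConfig(allelic_sites_per_chromosome=60, homoeolog_sites_per_chromosome=120)
        genome = simulate_parents(gcfg, seed=5)
        genome, hom = add_homoeology(genome, gcfg, HomoeologConfig(), seed=6)
        assert genome.n_sites == 7 * 180
        assert (hom.rho >= 0).all() and (hom.rho <= 1).all()
        homsites = genome.sites["kind"] == "homoeolog"
        # at homoeolog-divergent sites the parents agree and the homoeolog differs
        assert (genome.sites.loc[homsites, "parent_a"] == genome.sites.loc[homsites, "parent_b"]).all()
        assert (hom.homoeolog_base[homsites] != genome.sites.loc[homsites, "parent_a"]).all()
        assert (hom.rho[homsites.to_numpy()] > 0).all()

    def test_matches_reference_derivation(self, toy_genome):
        hom = HomoeologModel(
            rho=np.zeros(3), homoeolog_base=np.array(["A", "T", "T"]),
            tetraploid_expressed=np.zeros(3, dtype=bool),
        )
        assert hom.matches_reference(toy_genome, PARENT_A).tolist() == [True, False, False]
        assert hom.matches_reference(toy_genome, PARENT_B).tolist() == [False, True, True]


class TestPedigree:
    def test_bulk_structure_and_causal_fixation(self, toy_genome):
        cfg = PedigreeConfig(bulk_size=10)
        truth = simulate_pedigree(toy_genome, cfg, seed=7)
        assert sorted(truth.individuals) == sorted(BULK_NAMES)
        assert all(len(m) == 10 for m in truth.individuals.values())
        assert len(truth.bulk_membership) == 40
        # selection forces fixation at the causal site (site index 0)
        for p in (1, 2):
            assert truth.bulk_frequency(f"carrier-SP{p}")[0] == 1.0
            assert truth.bulk_frequency(f"noncarrier-SP{p}")[0] == 0.0
        geno = truth.bulk_membership.set_index("bulk")["causal_genotype"]
        assert (geno.loc["carrier-SP1"] == 2).all()
        assert (geno.loc["noncarrier-SP2"] == 0).all()

    def test_unlinked_chromosome_frequency_near_half(self, toy_genome):
        # Monte-Carlo over replicate pedigrees: the donor-allele frequency at
        # a site on an unlinked chromosome has mean 1/2
        freqs = []
        for rep in range(200):
            truth = simulate_pedigree(toy_genome, PedigreeConfig(bulk_size=5), seed=1000 + rep)
            freqs.append(truth.bulk_frequency("carrier-SP1")[2])  # 5D site
        freqs = np.asarray(freqs)
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - 0.5) < 4 * se + 1e-9

    def test_selection_must_stop_before_final_generation(self, toy_genome):
        with pytest.raises(ConfigurationError):
            simulate_pedigree(
                toy_genome,
                PedigreeConfig(final_generation=3, select_het_at_causal_through=3),
                seed=0,
            )


class TestExpectedHomozygosity:
    def test_closed_form(self):
        assert expected_homozygosity(4) == 0.875
        assert expected_homozygosity(1) == 0.0
        assert expected_homozygosity(2) == 0.5

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_homozygosity(0)

    def test_monotone_in_generation(self):
        values = [expected_homozygosity(g) for g in range(1, 10)]
        assert values == sorted(values)
        assert values[-1] < 1.0

    def test_simulation_oracle_generation_three(self):
        fractions = simulate_selfing_series(2000, 3, 150, seed=13)
        se = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - expected_homozygosity(3)) < 4 * se


class TestAlleleCountSampling:
    def _clean_homoeolog(self, genome, rho=0.0, base=None):
        n = genome.n_sites
        hbase = genome.sites["parent_a"].to_numpy() if base is None else np.repeat(base, n)
        return HomoeologModel(
            rho=np.full(n, rho), homoeolog_base=hbase,
            tetraploid_expressed=np.full(n, rho > 0),
        )

    def test_fixed_allele_without_contamination(self, toy_genome):
        truth = make_truth(toy_genome, {b: [1.0, 1.0, 1.0] for b in BULK_NAMES})
        hom = self._clean_homoeolog(toy_genome)
        table = sample_allele_counts(
            truth, toy_genome, hom, "carrier-SP1", PARENT_A, DepthModel(50, np.inf), seed=3
        )
        covered = table["depth"] > 0
        assert (table.loc[covered, "alt_depth"] == table.loc[covered, "depth"]).all()
        # mirrored against the donor reference: no alternate reads at all
        table_b = sample_allele_counts(
            truth, toy_genome, hom, "carrier-SP1", PARENT_B, DepthModel(50, np.inf), seed=3
        )
        assert (table_b["alt_depth"] == 0).all()

    def test_half_contamination_mixture_expectation(self):
        # rho = 0.5, homoeolog base equals the reference base, donor allele
        # fixed: E[K/D] = 0.5 (half the reads are non-alternate homoeologs)
        spec = [("2D", 1000 + 7 * i, "A", "G") for i in range(400)]
        genome = make_genome(spec, ("2D", 1001), [("2D", 10**6)])
        truth = make_truth(genome, {b: np.ones(400) for b in BULK_NAMES})
        hom = HomoeologModel(
            rho=np.full(400, 0.5),
            homoeolog_base=genome.sites["parent_a"].to_numpy(),
            tetraploid_expressed=np.ones(400, dtype=bool),
        )
        table = sample_allele_counts(
            truth, genome, hom, "carrier-SP1", PARENT_A, DepthModel(200, np.inf), seed=4
        )
        frac = (table["alt_depth"] / table["depth"]).mean()
        assert abs(frac - 0.5) < 0.01

    def test_count_conservation(self, toy_genome):
        truth = make_truth(toy_genome, {b: [0.5, 0.2, 0.9] for b in BULK_NAMES})
        hom = self._clean_homoeolog(toy_genome, rho=0.3)
        for seed in range(5):
            t = sample_allele_counts(
                truth, toy_genome, hom, "carrier-SP2", PARENT_B, DepthModel(), seed=seed
            )
            assert (t["alt_depth"] <= t["depth"]).all()
            assert (t["alt_depth"] >= 0).all()


class TestTetraploidCounts:
    def test_pure_homoeolog_reads(self):
        spec = [("2D", 100, "A", "A"), ("2D", 200, "C", "C")]
        genome = make_genome(spec, ("2D", 100), [("2D", 10**4)])
        hom = HomoeologModel(
            rho=np.array([0.4, 0.4]),
            homoeolog_base=np.array(["A", "T"]),  # matches ref / differs
            tetraploid_expressed=np.array([True, True]),
        )
        t = simulate_tetraploid_counts(hom, genome, DepthModel(40, np.inf), PARENT_A, seed=0)
        assert t.loc[0, "alt_depth"] == 0
        assert t.loc[1, "alt_depth"] == t.loc[1, "depth"] > 0

    def test_unexpressed_homoeolog_has_no_coverage(self):
        spec = [("2D", 100, "A", "G")]
        genome = make_genome(spec, ("2D", 100), [("2D", 10**4)])
        hom = HomoeologModel(
            rho=np.array([0.5]), homoeolog_base=np.array(["T"]),
            tetraploid_expressed=np.array([False]),
        )
        t = simulate_tetraploid_counts(hom, genome, DepthModel(40, np.inf), PARENT_A, seed=0)
        assert (t["depth"] == 0).all()
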
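"""Simulator correctness: analytic genotype frequencies, mating calibration,
structure closed forms, missingness, and seed determinism."""

import numpy as np
import pytest
from scipy import stats

from assortcheck.errors import FeasibilityError, ValidationError
from assortcheck.genosim import (
    MatingSimConfig,
    StructureSimConfig,
    inject_missingness,
    simulate_assortative_population,
    simulate_hw_genotypes,
    simulate_structured_population,
)
from assortcheck.inbreeding import counts_for_variants, estimate_f_multi


class TestHwGenotypes:
    def test_full_inbreeding_has_no_heterozygotes(self):
        geno = simulate_hw_genotypes(np.array([0.5]), f=1.0, n=100, seed=0)
        assert not np.any(geno.dosages == 1)

    def test_hwe_limit_proportions(self):
        geno = simulate_hw_genotypes(np.array([0.5]), f=0.0, n=100_000, seed=1)
        freqs = np.array([(geno.dosages == k).mean() for k in (0, 1, 2)])
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=3 * 0.5 / np.sqrt(100_000))

    def test_derived_class_frequencies(self):
        # p=0.3, f=0.2 -> (AA, Aa, aa) = (0.132, 0.336, 0.532)
        n = 100_000
        geno = simulate_hw_genotypes(np.array([0.3]), f=0.2, n=n, seed=2)
        for k, expect in ((2, 0.132), (1, 0.336), (0, 0.532)):
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs((geno.dosages == k).mean() - expect) < 3 * se

    def test_chi_square_goodness_of_fit_grid(self):
        """Class frequencies match the analytic values across a (p, f) grid."""
        n = 100_000
        for i, (p, f) in enumerate([(0.1, 0.0), (0.3, 0.2), (0.5, -0.3), (0.4, 0.6)]):
            geno = simulate_hw_genotypes(np.array([p]), f=f, n=n, seed=100 + i)
            q = 1 - p
            expected = n * np.array([q * q * (1 - f) + q * f, 2 * p * q * (1 - f),
                                     p * p * (1 - f) + p * f])
            observed = np.array([(geno.dosages == k).sum() for k in (0, 1, 2)])
            keep = expected > 0
            stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            assert stats.chi2.sf(stat, df=keep.sum() - 1) > 0.01

    def test_allele_frequency_invariant_to_f(self):
        """Mean dosage / 2 recovers p regardless of the inbreeding level."""
        p = 0.3
        for f in (-0.2, 0.0, 0.5):
            geno = simulate_hw_genotypes(np.full(50, p), f=f, n=5000, seed=int(10 * f) + 7)
            assert np.mean(geno.allele1_freq()) == pytest.approx(p, abs=0.01)

    def test_infeasible_combination_names_locus(self):
        with pytest.raises(FeasibilityError, match="locus 1"):
            simulate_hw_genotypes(np.array([0.5, 0.1]), f=-0.5, n=10, seed=0)

    def test_seed_determinism(self):
        a = simulate_hw_genotypes(np.full(20, 0.3), 0.1, 50, seed=5)
        b = simulate_hw_genotypes(np.full(20, 0.3), 0.1, 50, seed=5)
        c = simulate_hw_genotypes(np.full(20, 0.3), 0.1, 50, seed=6)
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_round_robin_chromosomes(self):
        geno = simulate_hw_genotypes(np.full(45, 0.3), 0.0, 5, seed=0)
        chroms = geno.variants["chromosome"].astype(int)
        assert set(chroms) == set(range(1, 23))
        assert list(chroms[:3]) == [1, 2, 3]


class TestAssortativePopulation:
    def test_random_mating_null(self):
        cfg = MatingSimConfig(n_parent_pairs=2000, m_trait=10, m_neutral=50,
                              rho_spouse=0.0, seed=3)
        geno, pheno, truth = simulate_assortative_population(cfg)
        assert abs(truth.realized_rho[0]) < 3 / np.sqrt(cfg.n_parent_pairs)
        counts = counts_for_variants(geno)
        f_trait = estimate_f_multi(counts[:10]).f_m_hat
        f_neutral = estimate_f_multi(counts[10:]).f_m_hat
        assert abs(f_trait - f_neutral) < 0.02

    def test_perfect_assortment_depletes_heterozygotes(self):
        cfg = MatingSimConfig(n_parent_pairs=3000, m_trait=1, m_neutral=1,
                              maf_range=(0.5, 0.5), h2=1.0, rho_spouse=1.0, seed=4)
        geno, pheno, truth = simulate_assortative_population(cfg)
        assert truth.realized_rho[0] > 0.95
        d = geno.dosages[:, 0]
        p = d.mean() / 2
        het = (d == 1).mean()
        assert het < 2 * p * (1 - p)

    def test_derived_trait_locus_f_with_pedigree_oracle(self):
        """Offspring trait-locus f matches rho*h2/(2 m) and the brute-force
        transmitted-allele covariance computed from the simulated parents."""
        cfg = MatingSimConfig(n_parent_pairs=20_000, m_trait=20, m_neutral=10,
                              maf_range=(0.5, 0.5), h2=0.8, rho_spouse=0.5,
                              n_generations=1, offspring_per_pair=1, seed=6)
        geno, pheno, truth = simulate_assortative_population(cfg)
        assert truth.expected_f[0] == pytest.approx(0.01)
        counts = counts_for_variants(geno)
        f_hat = estimate_f_multi(counts[:20]).f_m_hat
        # oracle: uniting-gamete correlation from parent genotype covariance
        dos_a, dos_b = truth.extras["parent_dosages"]
        oracle = []
        for j in range(20):
            ga = dos_a[:, j].astype(float)
            gb = dos_b[:, j].astype(float)
            p = np.concatenate([ga, gb]).mean() / 2
            oracle.append(np.cov(ga, gb, ddof=1)[0, 1] / 4 / (p * (1 - p)))
        oracle_f = float(np.mean(oracle))
        assert f_hat == pytest.approx(oracle_f, abs=0.004)
        assert f_hat == pytest.approx(0.01, abs=0.005)

    def test_rho_calibration_warning(self):
        cfg = MatingSimConfig(n_parent_pairs=6, m_trait=1, m_neutral=1,
                              rho_spouse=0.9, h2=0.5, seed=1)
        # tiny cohort: realized r is noisy, warning allowed but not fatal
        geno, pheno, truth = simulate_assortative_population(cfg)
        assert geno.n_samples == 12

    def test_seed_reproducibility(self):
        cfg = MatingSimConfig(n_parent_pairs=50, m_trait=5, m_neutral=5, seed=9)
        g1, p1, _ = simulate_assortative_population(cfg)
        g2, p2, _ = simulate_assortative_population(cfg)
        assert np.array_equal(g1.dosages, g2.dosages)
        assert np.array_equal(p1, p2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            MatingSimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValidationError):
            MatingSimConfig(h2=1.5)
        with pytest.raises(ValidationError):
            MatingSimConfig(rho_spouse=1.2)


class TestStructuredPopulation:
    def test_identical_subpops_give_zero_f(self):
        cfg = StructureSimConfig(
            subpop_freqs=np.vstack([np.full(10, 0.4), np.full(10, 0.4)]),
            mixing_proportions=[0.5, 0.5], mode="pooled", n_individuals=100, seed=0,
        )
        _, truth = simulate_structured_population(cfg)
        assert np.allclose(truth.expected_f, 0.0)

    def test_wahlund_closed_form(self):
        cfg = StructureSimConfig(
            subpop_freqs=np.vstack([np.full(400, 0.3), np.full(400, 0.7)]),
            mixing_proportions=[0.5, 0.5], mode="pooled", n_individuals=4000, seed=1,
        )
        geno, truth = simulate_structured_population(cfg)
        assert truth.expected_f[0] == pytest.approx(0.16)
        est = estimate_f_multi(counts_for_variants(geno)).f_m_hat
        assert est == pytest.approx(0.16, abs=0.01)

    def test_f1_cross_closed_form(self):
        cfg = StructureSimConfig(
            subpop_freqs=np.vstack([np.full(400, 0.3), np.full(400, 0.7)]),
            mixing_proportions=[0.5, 0.5], mode="f1_cross", n_individuals=4000, seed=2,
        )
        geno, truth = simulate_structured_population(cfg)
        assert truth.expected_f[0] == pytest.approx(-0.16)
        est = estimate_f_multi(counts_for_variants(geno)).f_m_hat
        assert est == pytest.approx(-0.16, abs=0.01)

    def test_f1_cross_requires_two_subpops(self):
        with pytest.raises(ValidationError, match="2 subpopulations"):
            StructureSimConfig(
                subpop_freqs=np.vstack([np.full(5, 0.3)] * 3),
                mixing_proportions=[0.4, 0.3, 0.3], mode="f1_cross",
            )

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            StructureSimConfig(
                subpop_freqs=np.vstack([np.full(5, 0.3), np.full(5, 0.7)]),
                mixing_proportions=[0.5, 0.6],
            )


class TestInjectMissingness:
    def test_zero_rate_identity(self, tiny_geno):
        out = inject_missingness(tiny_geno, 0.0, seed=1)
        assert np.array_equal(out.dosages, tiny_geno.dosages)

    def test_realized_rate_binomial(self):
        geno = simulate_hw_genotypes(np.full(200, 0.3), 0.0, 500, seed=1)
        out = inject_missingness(geno, 0.5, seed=2)
        realized = (out.dosages == -1).mean()
        n_calls = geno.dosages.size
        assert abs(realized - 0.5) < 3 * np.sqrt(0.25 / n_calls)

    def test_call_rate_filter_fraction_matches_binomial_tail(self):
        """With 6% missingness, the fraction of variants failing CR >= 0.95
        matches the binomial tail P(X > 0.05 n) at the given sample size."""
        n, m, rate = 200, 2000, 0.06
        geno = simulate_hw_genotypes(np.full(m, 0.3), 0.0, n, seed=3)
        out = inject_missingness(geno, rate, seed=4)
        failing = (out.call_rate() < 0.95).mean()
        k_max = int(np.floor(0.05 * n))  # fails when missing count > k_max
        expected = float(stats.binom.sf(k_max, n, rate))
        se = np.sqrt(expected * (1 - expected) / m)
        assert abs(failing - expected) < 4 * se

    def test_invalid_rate(self, tiny_geno):
        with pytest.raises(ValidationError):
            inject_missingness(tiny_geno, 1.0)
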
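"""QC chain: exact HWE test vs full enumeration, filters with strict
thresholds, LD pruning, kinship exclusion, PC outliers."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest

from assortcheck.errors import ValidationError
from assortcheck.genosim import (
    StructureSimConfig,
    inject_missingness,
    simulate_hw_genotypes,
    simulate_structured_population,
)
from assortcheck.inbreeding import VariantCounts
from assortcheck.qc import (
    QCThresholds,
    exclude_related,
    filter_samples,
    filter_variants,
    hwe_chisq_pvalue,
    hwe_exact_pvalue,
    hwe_test,
    kinship_matrix,
    ld_prune,
    pc_outlier_filter,
)
from conftest import make_geno


def hwe_exact_oracle(n0, n1, n2):
    """Exact-rational enumeration of the conditional het-count distribution."""
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    if rare == 0:
        return Fraction(1)
    probs = {}
    denom = comb(2 * n, rare)
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hc < 0:
            continue
        # multinomial configuration count x 2^h over C(2n, rare)
        num = 2**h * Fraction(
            factorial(n), factorial(h) * factorial(hr) * factorial(hc)
        )
        probs[h] = Fraction(num, denom)
    p_obs = probs[n1]
    return sum(p for p in probs.values() if p <= p_obs)


class TestHweExact:
    def test_perfect_hwe_proportions(self):
        c = VariantCounts(25, 50, 25)
        assert hwe_chisq_pvalue(c) == pytest.approx(1.0)
        assert hwe_exact_pvalue(c) == pytest.approx(float(hwe_exact_oracle(25, 50, 25)))

    def test_all_heterozygote_tail(self):
        c = VariantCounts(0, 20, 0)
        assert hwe_exact_pvalue(c) == pytest.approx(float(hwe_exact_oracle(0, 20, 0)), rel=1e-9)

    def test_monomorphic_convention(self):
        assert hwe_exact_pvalue(VariantCounts(0, 0, 30)) == 1.0

    def test_exhaustive_oracle_sweep(self):
        """Exact test equals full rational enumeration for all counts n <= 50."""
        for n in range(1, 51):
            for n2 in range(n + 1):
                for n1 in range(n - n2 + 1):
                    n0 = n - n2 - n1
                    got = hwe_exact_pvalue(VariantCounts(n0, n1, n2))
                    want = float(hwe_exact_oracle(n0, n1, n2))
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (n0, n1, n2)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            hwe_test(VariantCounts(1, 1, 1), method="bayes")


class TestVariantFilters:
    def test_low_call_rate_removed(self):
        geno = simulate_hw_genotypes(np.full(50, 0.3), 0.0, 200, seed=0)
        geno = inject_missingness(geno, 0.0, seed=0)
        dos = geno.dosages.copy()
        dos[:12, 0] = -1  # 6% missing on variant 0
        bad = make_geno(dos)
        out, report = filter_variants(bad)
        assert "v0" not in out.variant_ids
        assert report.steps[0]["filter"] == "call_rate"
        assert "v0" in report.steps[0]["removed"]

    def test_maf_threshold_strict(self):
        """MAF exactly at the threshold is retained (strict < removal)."""
        n = 100
        dos = np.zeros((n, 2), dtype=np.int8)
        dos[0, 0] = 2  # MAF exactly 0.01 at variant 0... and keep v1 polymorphic
        dos[:30, 1] = 1
        geno = make_geno(dos)
        out, _ = filter_variants(geno)
        assert "v0" in list(out.variant_ids)
        dos2 = dos.copy()
        dos2[0, 0] = 1  # MAF 0.005 < 0.01 -> removed
        out2, _ = filter_variants(make_geno(dos2))
        assert "v0" not in list(out2.variant_ids)

    def test_extreme_inbreeding_fails_hwe(self):
        geno = simulate_hw_genotypes(np.full(3, 0.5), 0.9, 10_000, seed=1)
        dos = np.hstack([geno.dosages, simulate_hw_genotypes(
            np.full(3, 0.5), 0.0, 10_000, seed=2).dosages])
        full = make_geno(dos)
        out, report = filter_variants(full)
        hwe_step = [s for s in report.steps if s["filter"] == "hwe"][0]
        assert set(hwe_step["removed"]) == {"v0", "v1", "v2"}
        assert out.n_variants == 3

    def test_all_removed_raises(self):
        dos = np.zeros((100, 1), dtype=np.int8)  # monomorphic -> MAF 0
        with pytest.raises(ValidationError, match="all variants"):
            filter_variants(make_geno(dos))


class TestSampleFilter:
    def test_boundary_missingness(self):
        dos = np.ones((3, 10), dtype=np.int8)
        dos[0, 0] = -1  # 10.0% missing -> retained (strict >)
        dos[1, :2] = -1  # 20% -> removed
        geno = make_geno(dos)
        out, report = filter_samples(geno)
        assert list(out.sample_ids) == ["s0", "s2"]

    def test_clean_matrix_unchanged(self):
        geno = make_geno([[0, 1, 2], [1, 1, 0], [2, 0, 1]])
        out, report = filter_samples(geno)
        assert out.n_samples == geno.n_samples
        assert all(step["n_removed"] == 0 for step in report.steps)


class TestLdPrune:
    def test_duplicate_column_resolved(self):
        rng = np.random.default_rng(0)
        col = rng.choice([0, 1, 2], size=300, p=[0.49, 0.42, 0.09]).astype(np.int8)
        other = rng.choice([0, 1, 2], size=300).astype(np.int8)
        geno = make_geno(np.column_stack([col, col, other]))
        kept = ld_prune(geno, r2_max=0.1)
        assert len([v for v in kept if v in ("v0", "v1")]) == 1
        assert "v2" in kept

    def test_uncorrelated_loci_all_retained(self):
        geno = simulate_hw_genotypes(np.full(20, 0.4), 0.0, 2000, seed=3)
        kept = ld_prune(geno, r2_max=0.1)
        assert len(kept) == 20

    def test_greedy_hand_trace(self):
        """3 loci with pairwise r2 ~ (0.5, 0.5, 0.0): the shared locus loses
        to both higher-MAF partners exactly as the greedy hand trace says."""
        rng = np.random.default_rng(1)
        n = 4000
        base = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25]).astype(np.int8)
        noisy = lambda: np.clip(base + rng.integers(-1, 2, n) * (rng.random(n) < 0.35), 0, 2)
        v0 = base  # MAF highest
        v1 = noisy().astype(np.int8)
        v2 = rng.choice([0, 1, 2], size=n, p=[0.36, 0.48, 0.16]).astype(np.int8)
        geno = make_geno(np.column_stack([v0, v1, v2]))
        r01 = np.corrcoef(v0, v1)[0, 1] ** 2
        assert r01 > 0.1
        kept = ld_prune(geno, r2_max=0.1, keep="higher_maf")
        maf = geno.maf()
        expected_drop = "v0" if maf[0] < maf[1] else "v1"
        assert expected_drop not in kept and "v2" in kept

    def test_random_keep_is_seeded(self):
        rng = np.random.default_rng(2)
        col = rng.choice([0, 1, 2], size=500).astype(np.int8)
        geno = make_geno(np.column_stack([col, col]))
        k1 = ld_prune(geno, keep="random", seed=11)
        k2 = ld_prune(geno, keep="random", seed=11)
        assert k1 == k2

    def test_sample_order_invariance(self):
        geno = simulate_hw_genotypes(np.full(30, 0.3), 0.0, 500, seed=5)
        perm = np.random.default_rng(6).permutation(geno.n_samples)
        shuffled = geno.subset(sample_idx=perm)
        assert ld_prune(geno) == ld_prune(shuffled)


class TestKinship:
    def test_duplicate_individual_detected(self):
        geno = simulate_hw_genotypes(np.full(3000, 0.3), 0.0, 50, seed=7)
        dos = np.vstack([geno.dosages, geno.dosages[0]])
        dup = make_geno(dos)
        K = kinship_matrix(dup)
        assert K[0, -1] > 0.9
        retained = exclude_related(K, dup.sample_ids, cutoff=0.025)
        assert ("s0" in retained) != ("s50" in retained)

    def test_unrelated_offdiagonals_near_zero_and_diag_near_one(self):
        geno = simulate_hw_genotypes(
            np.random.default_rng(8).uniform(0.1, 0.5, 5000), 0.0, 200, seed=9
        )
        K = kinship_matrix(geno)
        assert np.allclose(K, K.T)
        off = K[np.triu_indices_from(K, 1)]
        # with in-sample frequencies the rows center, so E[offdiag] = -1/(n-1)
        n = geno.n_samples
        assert off.mean() == pytest.approx(-1.0 / (n - 1), abs=0.002)
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.05)

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(10)
        m = 4000
        p = rng.uniform(0.2, 0.5, m)
        parents = simulate_hw_genotypes(p, 0.0, 40, seed=11).dosages
        # child of parents 0 and 1; second trio from parents 2 and 3
        def child(a, b):
            return (rng.binomial(1, parents[a] / 2) + rng.binomial(1, parents[b] / 2)).astype(np.int8)
        dos = np.vstack([parents, child(0, 1), child(2, 3)])
        geno = make_geno(dos)
        K = kinship_matrix(geno)
        assert K[0, 40] == pytest.approx(0.5, abs=0.08)
        assert K[2, 41] == pytest.approx(0.5, abs=0.08)
        retained = exclude_related(K, geno.sample_ids, cutoff=0.3)
        # each trio loses members until no related pair remains
        assert not {"s40", "s0", "s1"}.issubset(set(retained))


class TestPcOutliers:
    def test_homogeneous_population_keeps_everyone(self):
        geno = simulate_hw_genotypes(np.full(300, 0.3), 0.0, 150, seed=12)
        retained, scores = pc_outlier_filter(geno, n_pcs=2, sd_mult=6.0)
        assert len(retained) == 150
        assert scores.shape == (150, 2)

    def test_minority_cluster_flagged(self):
        cfg = StructureSimConfig(
            subpop_freqs=np.vstack([np.full(400, 0.1), np.full(400, 0.9)]),
            mixing_proportions=[0.95, 0.05], mode="pooled", n_individuals=400, seed=13,
        )
        geno, truth = simulate_structured_population(cfg)
        retained, scores = pc_outlier_filter(geno, n_pcs=2, sd_mult=3.0)
        removed = set(geno.sample_ids) - set(retained)
        minority = set(geno.sample_ids[truth.subpop_labels == 1])
        assert minority and minority.issubset(removed)
        # removing the flagged samples shrinks the PC1 variance share
        keep_idx = np.flatnonzero(np.isin(geno.sample_ids, list(retained)))
        sub = geno.subset(sample_idx=keep_idx)
        _, scores2 = pc_outlier_filter(sub, n_pcs=2, sd_mult=6.0)
        share = lambda s: s[:, 0].var() / s.var(axis=0).sum()
        assert share(scores2) < share(scores)

    def test_rank_deficiency_rejected(self, tiny_geno):
        with pytest.raises(ValidationError, match="n_pcs"):
            pc_outlier_filter(tiny_geno, n_pcs=10)
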
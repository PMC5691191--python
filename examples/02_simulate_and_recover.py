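"""Forward-simulate one generation of assortative mating and recover the
analytic trait-locus inbreeding coefficient.

With spousal phenotype correlation rho, heritability h2 and m equally
contributing trait loci, the offspring generation is expected to show
f = rho * h2 / (2 m) at each trait locus and f = 0 at neutral loci.
"""

from assortcheck import (
    MatingSimConfig,
    estimate_f_multi,
    simulate_assortative_population,
)
from assortcheck.inbreeding import counts_for_variants

cfg = MatingSimConfig(
    n_parent_pairs=5000, m_trait=20, m_neutral=500, maf_range=(0.1, 0.5),
    h2=0.8, rho_spouse=0.5, n_generations=1, offspring_per_pair=2, seed=7,
)
geno, phenotype, truth = simulate_assortative_population(cfg)
print(f"simulated {geno.n_samples} offspring x {geno.n_variants} SNPs")
print(f"realized spousal correlation: {truth.realized_rho[0]:.3f} (target {cfg.rho_spouse})")

counts = counts_for_variants(geno)
f_trait = estimate_f_multi(counts[: cfg.m_trait]).f_m_hat
f_neutral = estimate_f_multi(counts[cfg.m_trait :]).f_m_hat
expected = cfg.rho_spouse * cfg.h2 / (2 * cfg.m_trait)
print(f"trait-locus f_M   = {f_trait:+.4f}  (analytic expectation {expected:+.4f})")
print(f"neutral-locus f_M = {f_neutral:+.4f}  (expected ~0)")
print(
    "Only trait loci acquire a heterozygote deficit: assortative mating is "
    "locus-specific, unlike inbreeding or structure."
)
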
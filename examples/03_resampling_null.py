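"""Test a trait SNP set against a frequency-matched resampling null.

The null distribution of f_M is built by repeatedly re-estimating it on
random SNP sets of matched size and minor-allele frequency; genome-wide
confounders shift the null and the observation alike, so the empirical
p-value isolates the trait-specific signal.
"""

import numpy as np

from assortcheck import MatingSimConfig, null_distribution, simulate_assortative_population

cfg = MatingSimConfig(
    n_parent_pairs=5000, m_trait=20, m_neutral=2000, h2=0.8, rho_spouse=0.5, seed=11,
)
geno, phenotype, truth = simulate_assortative_population(cfg)
trait_ids = list(geno.variant_ids[: cfg.m_trait])
pool_ids = list(geno.variant_ids[cfg.m_trait :])

nd = null_distribution(geno, trait_ids, pool_ids, B=1000, seed=2)
print(f"observed trait f_M = {nd.obs:+.4f}")
print(f"null over B={nd.B} matched resamples: mean {np.mean(nd.values):+.5f}, "
      f"sd {np.std(nd.values, ddof=1):.5f}")
print(f"empirical p = {nd.p_empirical:.4g}  (floor at 1/(B+1) = {1/(nd.B+1):.4g})")
print(
    "A p-value near the floor means the observed f_M exceeds essentially "
    "every frequency-matched null set: trait-specific heterozygote deficit."
)
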
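"""Estimate the inbreeding coefficient at a single locus from genotype counts.

The count triple (n0 aa, n1 Aa, n2 AA) is the sufficient statistic; the
maximum-likelihood f has the closed form 1 - observed/expected heterozygosity.
"""

from assortcheck import VariantCounts, estimate_f_single, estimate_f_multi

for counts in [(25, 50, 25), (30, 40, 30), (50, 0, 50), (40, 55, 5)]:
    est = estimate_f_single(VariantCounts(*counts))
    print(
        f"counts {counts}: p-hat = {est.p_hat:.3f}, f-hat = {est.f_hat:+.4f}, "
        f"loglik = {est.loglik:.2f}, feasible f in [{est.feasible_range[0]:.3f}, 1]"
    )

# joint estimate over several loci sharing one f
joint = estimate_f_multi([VariantCounts(30, 40, 30), VariantCounts(28, 42, 30)])
print(f"\njoint f_M over 2 loci = {joint.f_m_hat:+.4f} (loglik {joint.loglik:.2f})")
print(
    "f-hat = 0 means heterozygosity exactly matches Hardy-Weinberg; positive "
    "values are a heterozygote deficit (inbreeding/assortative mating), "
    "negative values an excess."
)
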
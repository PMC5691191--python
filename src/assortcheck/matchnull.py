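"""Frequency-matched resampling null for the multi-locus inbreeding
coefficient, and single-locus distribution comparisons.

The test logic: genome-wide confounders (population structure, cryptic
relatedness, finite-sample bias) shift the inbreeding coefficient at EVERY
locus, while trait-driven assortative mating shifts only trait-associated
loci. So the null distribution of the multi-locus estimate f_M is built by
repeatedly drawing, from the post-QC pruned genome, random SNP sets of the
same size and matched minor-allele frequencies as the trait set, and
re-estimating f_M on each. The empirical p-value is the upper-tail rank
(1 + #{null >= observed}) / (B + 1) — with B = 1000 resamples the smallest
attainable p is 1/1001, i.e. the familiar "p = 0.001" floor.

Single-locus comparisons (Welch t and two-sample KS on the per-locus f
estimates of the trait set vs one matched set) complement the resampling
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from assortcheck.errors import ValidationError
from assortcheck.genio import GenotypeMatrix
from assortcheck.inbreeding import counts_for_variants, estimate_f_multi

__all__ = [
    "MatchSpec",
    "NullDistribution",
    "match_frequencies",
    "null_distribution",
    "empirical_pvalue",
    "compare_single_locus",
]


@dataclass(frozen=True)
class MatchSpec:
    """How null SNP sets are frequency-matched to the trait set.

    ``maf_bin_width`` partitions [0, 0.5] into bins; each trait SNP is
    matched by a pool SNP from the same bin, sampled without replacement
    within a resample and independently across resamples.
    """

    maf_bin_width: float = 0.01
    exclude_ids: tuple = ()
    with_replacement_across_resamples: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_bin_width <= 0.5:
            raise ValidationError("maf_bin_width must be in (0, 0.5]")


@dataclass
class NullDistribution:
    """B resampled f_M values plus the observed value and empirical p."""

    values: np.ndarray
    B: int
    matched_sets: list
    seed: int
    obs: float
    p_empirical: float


def _bin_index(maf: np.ndarray, width: float) -> np.ndarray:
    return np.floor(np.asarray(maf, dtype=np.float64) / width).astype(int)


def match_frequencies(
    target_mafs, pool_ids, pool_mafs, spec: MatchSpec = MatchSpec(), seed: int = 0
) -> list:
    """Sample one pool variant per target from the same MAF bin.

    Sampling is uniform without replacement within this call. An empty bin
    is widened once to its two adjacent bins with a warning; if still
    empty, an error names the offending MAF.
    """
    rng = np.random.default_rng(seed)
    pool_ids = np.asarray(pool_ids, dtype=object)
    pool_mafs = np.asarray(pool_mafs, dtype=np.float64)
    if spec.exclude_ids:
        keep = ~np.isin(pool_ids, np.asarray(spec.exclude_ids, dtype=object))
        pool_ids, pool_mafs = pool_ids[keep], pool_mafs[keep]
    target_mafs = np.asarray(target_mafs, dtype=np.float64)
    pool_bins = _bin_index(pool_mafs, spec.maf_bin_width)
    target_bins = _bin_index(target_mafs, spec.maf_bin_width)

    by_bin: dict[int, list[int]] = {}
    for i, b in enumerate(pool_bins):
        by_bin.setdefault(int(b), []).append(i)

    used = np.zeros(len(pool_ids), dtype=bool)
    chosen: list = []
    # fill scarcer bins first so without-replacement sampling cannot strand them
    order = np.argsort([len(by_bin.get(int(b), [])) for b in target_bins], kind="stable")
    picks = np.empty(len(target_mafs), dtype=object)
    for t in order:
        b = int(target_bins[t])
        candidates = [i for i in by_bin.get(b, []) if not used[i]]
        if not candidates:
            widened = [i for bb in (b - 1, b + 1) for i in by_bin.get(bb, []) if not used[i]]
            if widened:
                warnings.warn(
                    f"MAF bin {b} empty for target MAF {target_mafs[t]:.4f}; "
                    "widened to adjacent bins",
                    stacklevel=2,
                )
                candidates = widened
            else:
                raise ValidationError(
                    f"no pool variant available near MAF {target_mafs[t]:.4f} "
                    f"(bin width {spec.maf_bin_width})"
                )
        pick = candidates[int(rng.integers(len(candidates)))]
        used[pick] = True
        picks[t] = pool_ids[pick]
    chosen = list(picks)
    return chosen


def empirical_pvalue(obs: float, null_values) -> float:
    """Upper-tail empirical p with the +1 convention: (1 + #{null >= obs}) / (B + 1)."""
    null_values = np.asarray(null_values, dtype=np.float64)
    if null_values.size == 0:
        raise ValidationError("empty null distribution")
    return float((1 + np.sum(null_values >= obs)) / (null_values.size + 1))


def null_distribution(
    geno: GenotypeMatrix,
    trait_ids,
    pool_ids,
    B: int = 1000,
    spec: MatchSpec = MatchSpec(),
    seed: int = 0,
) -> NullDistribution:
    """Resampled null of f_M from frequency-matched SNP sets.

    ``geno`` should already be post-QC and LD-pruned so the independence
    assumption of the product likelihood holds. Trait SNPs are implicitly
    excluded from the pool; B matched sets are drawn (without replacement
    within a set, independently across sets) and f_M re-estimated on each.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    trait_ids = list(trait_ids)
    pool_ids = [v for v in pool_ids if v not in set(trait_ids)]
    if not pool_ids:
        raise ValidationError("empty resampling pool after excluding trait SNPs")

    maf = geno.maf()
    vid_to_idx = {v: i for i, v in enumerate(geno.variant_ids)}
    target_mafs = np.array([maf[vid_to_idx[v]] for v in trait_ids])
    pool_mafs = np.array([maf[vid_to_idx[v]] for v in pool_ids])

    counts_all = counts_for_variants(geno)
    obs = estimate_f_multi([counts_all[vid_to_idx[v]] for v in trait_ids]).f_m_hat

    rng = np.random.default_rng(seed)
    values = np.empty(B)
    matched_sets = []
    for b in range(B):
        ids = match_frequencies(
            target_mafs, pool_ids, pool_mafs, spec=spec,
            seed=int(rng.integers(2**31)),
        )
        matched_sets.append(ids)
        values[b] = estimate_f_multi([counts_all[vid_to_idx[v]] for v in ids]).f_m_hat
    return NullDistribution(
        values=values,
        B=B,
        matched_sets=matched_sets,
        seed=seed,
        obs=obs,
        p_empirical=empirical_pvalue(obs, values),
    )


def compare_single_locus(f_trait, f_matched) -> dict:
    """Welch t-test and two-sample KS test on per-locus f estimates.

    Returns a dict shaped like one comparison-table row: group means and
    SDs, the two p-values, and a ``t_degenerate`` flag when both groups
    have zero variance (the t statistic is then undefined).
    """
    f_trait = np.asarray(f_trait, dtype=np.float64)
    f_matched = np.asarray(f_matched, dtype=np.float64)
    if f_trait.size < 2 or f_matched.size < 2:
        raise ValidationError("both groups need at least 2 loci")
    def _constant(v):
        return v.std() <= 1e-12 * max(1.0, abs(v.mean()))

    degenerate = _constant(f_trait) and _constant(f_matched)
    if degenerate:
        t_p = 1.0 if f_trait.mean() == f_matched.mean() else 0.0
    else:
        t_p = float(stats.ttest_ind(f_trait, f_matched, equal_var=False).pvalue)
    ks_p = float(stats.ks_2samp(f_trait, f_matched).pvalue)
    return {
        "mean_trait": float(f_trait.mean()),
        "sd_trait": float(f_trait.std(ddof=1)),
        "mean_matched": float(f_matched.mean()),
        "sd_matched": float(f_matched.std(ddof=1)),
        "t_p": t_p,
        "ks_p": ks_p,
        "t_degenerate": bool(degenerate),
        "n_trait": int(f_trait.size),
        "n_matched": int(f_matched.size),
    }
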
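"""Genotype quality control: variant/sample filters, exact HWE test,
LD pruning, kinship-based relative exclusion, PC outlier removal.

The default thresholds are the conventional GWAS values: variants are
dropped when call rate < 0.95, MAF < 0.01 or exact-HWE P < 5e-7 (all strict
inequalities); samples when their missing rate exceeds 0.1. Pruning keeps
the panel approximately independent (pairwise r^2 <= 0.1, 50-variant
windows stepping by 5); one member of every pair with estimated kinship
above 0.025 is excluded greedily, most-connected first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.decomposition import PCA

from assortcheck.errors import ValidationError
from assortcheck.genio import MISSING, GenotypeMatrix
from assortcheck.inbreeding import VariantCounts

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_test",
    "hwe_exact_pvalue",
    "filter_variants",
    "filter_samples",
    "ld_prune",
    "kinship_matrix",
    "exclude_related",
    "pc_outlier_filter",
]


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_floor: float = 5e-7
    max_sample_missing: float = 0.1
    prune_r2: float = 0.1
    kinship_cutoff: float = 0.025
    pc_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.prune_r2 <= 1.0:
            raise ValidationError("prune_r2 must be in (0, 1]")
        if self.pc_outlier_sd <= 0:
            raise ValidationError("pc_outlier_sd must be positive")


@dataclass
class QCReport:
    """Itemized record of what each filter removed."""

    steps: list = field(default_factory=list)  # (filter_name, n_removed, removed_ids)
    retained_ids: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add(self, name: str, removed_ids) -> None:
        removed_ids = list(removed_ids)
        self.steps.append({"filter": name, "n_removed": len(removed_ids), "removed": removed_ids})

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "n_retained": len(self.retained_ids),
            "retained": list(self.retained_ids),
            "params": dict(self.params),
        }


# ----------------------------------------------------------------------
# Hardy-Weinberg tests
# ----------------------------------------------------------------------

def hwe_exact_pvalue(counts: VariantCounts) -> float:
    """Exact HWE test by enumeration of heterozygote counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    standard SNP exact test). Monomorphic loci return 1.0 by convention.
    """
    n = counts.n
    n_het = counts.n1
    rare = min(2 * counts.n0 + counts.n1, 2 * counts.n2 + counts.n1)
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele total
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_pvalue(counts: VariantCounts) -> float:
    """1-df chi-square HWE test (asymptotic alternative to the exact test)."""
    n = counts.n
    p = counts.p_hat
    if p <= 0.0 or p >= 1.0:
        return 1.0
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([counts.n0, counts.n1, counts.n2], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def hwe_test(counts: VariantCounts, method: str = "exact") -> float:
    """HWE p-value for one locus; ``method`` is 'exact' or 'chisq'."""
    if counts.n <= 0:
        raise ValidationError("empty genotype counts")
    if method == "exact":
        return hwe_exact_pvalue(counts)
    if method == "chisq":
        return hwe_chisq_pvalue(counts)
    raise ValidationError(f"unknown HWE method {method!r}")


# ----------------------------------------------------------------------
# Variant / sample filters
# ----------------------------------------------------------------------

def _variant_counts_arrays(geno: GenotypeMatrix):
    d = geno.dosages
    return (d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0)


def filter_variants(
    geno: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants with low call rate, low MAF, or extreme HWE departure.

    Inequalities are strict: CR < min_call_rate removed (CR exactly at the
    threshold retained), MAF < min_maf removed, HWE P < hwe_p_floor removed.
    Variant order is preserved.
    """
    report = QCReport(params={"min_call_rate": thresholds.min_call_rate,
                             "min_maf": thresholds.min_maf,
                             "hwe_p_floor": thresholds.hwe_p_floor})
    vids = geno.variant_ids
    cr = geno.call_rate()
    keep = cr >= thresholds.min_call_rate
    report.add("call_rate", vids[~keep])

    maf = geno.maf()
    low_maf = np.isnan(maf) | (maf < thresholds.min_maf)
    report.add("maf", vids[keep & low_maf])
    keep &= ~low_maf

    n0, n1, n2 = _variant_counts_arrays(geno)
    hwe_fail = np.zeros(geno.n_variants, dtype=bool)
    for j in np.flatnonzero(keep):
        p = hwe_exact_pvalue(VariantCounts(int(n0[j]), int(n1[j]), int(n2[j])))
        hwe_fail[j] = p < thresholds.hwe_p_floor
    report.add("hwe", vids[keep & hwe_fail])
    keep &= ~hwe_fail

    if not keep.any():
        raise ValidationError("all variants removed by QC filters")
    report.retained_ids = list(vids[keep])
    return geno.subset(variant_idx=np.flatnonzero(keep)), report


def filter_samples(
    geno: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose missing-genotype rate strictly exceeds the threshold."""
    report = QCReport(params={"max_sample_missing": thresholds.max_sample_missing})
    rate = geno.sample_missing_rate()
    keep = rate <= thresholds.max_sample_missing
    report.add("sample_missing", geno.sample_ids[~keep])
    if not keep.any():
        raise ValidationError("all samples removed by missingness filter")
    report.retained_ids = list(geno.sample_ids[keep])
    return geno.subset(sample_idx=np.flatnonzero(keep)), report


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def _imputed_standardized(geno: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, centered dosage columns (unit operations for r^2)."""
    d = geno.dosage_float()
    col_mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(col_mean, idx[1])
    return d - d.mean(axis=0)


def ld_prune(
    geno: GenotypeMatrix,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 5,
    keep: str = "higher_maf",
    seed: int = 0,
) -> list:
    """Sliding-window LD pruning; returns retained variant ids in order.

    Within each window, any pair of retained variants with squared dosage
    correlation above ``r2_max`` is resolved by dropping the lower-MAF
    member (``keep='higher_maf'``; position tie-break keeps the earlier
    variant) or a seeded random member (``keep='random'``). Missing calls
    are mean-imputed for the correlation only.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValidationError("r2_max must be in (0, 1]")
    if keep not in ("higher_maf", "random"):
        raise ValidationError(f"unknown keep policy {keep!r}")
    rng = np.random.default_rng(seed)
    m = geno.n_variants
    x = _imputed_standardized(geno)
    norms = np.sqrt((x**2).sum(axis=0))
    maf = geno.maf()
    alive = np.ones(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, m)
        idx = [j for j in range(start, stop) if alive[j]]
        changed = True
        while changed:
            changed = False
            idx = [j for j in idx if alive[j]]
            for a_pos in range(len(idx)):
                i = idx[a_pos]
                if not alive[i]:
                    continue
                for j in idx[a_pos + 1 :]:
                    if not alive[j]:
                        continue
                    denom = norms[i] * norms[j]
                    if denom == 0:
                        continue
                    r = float(x[:, i] @ x[:, j]) / denom
                    if r * r > r2_max:
                        if keep == "random":
                            drop = i if rng.random() < 0.5 else j
                        elif maf[i] == maf[j]:
                            drop = j
                        else:
                            drop = i if maf[i] < maf[j] else j
                        alive[drop] = False
                        changed = True
                        if drop == i:
                            break
        if stop >= m:
            break
        start += step
    return list(geno.variant_ids[alive])


# ----------------------------------------------------------------------
# Kinship
# ----------------------------------------------------------------------

def kinship_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Genetic relationship matrix from standardized dosages.

    A_jk = (1/m) * sum_i (g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i q_i) over
    loci non-missing in both samples; monomorphic loci are skipped with a
    warning. Diagonal averages ~1 for an outbred HWE sample; off-diagonal
    ~0 for unrelateds, ~0.5 for parent-offspring.
    """
    if geno.n_samples < 2:
        raise ValidationError("kinship requires at least 2 samples")
    p = geno.allele1_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValidationError("no polymorphic variants for kinship estimation")
    if (~poly).sum():
        warnings.warn(f"skipping {(~poly).sum()} monomorphic loci in kinship", stacklevel=2)
    d = geno.dosage_float()[:, poly]
    p = p[poly]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    observed = ~np.isnan(z)
    z = np.where(observed, z, 0.0)
    pair_m = observed.astype(np.float64) @ observed.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (z @ z.T) / pair_m


def exclude_related(K: np.ndarray, sample_ids, cutoff: float = 0.025) -> list:
    """Greedy relative exclusion: drop the most-connected sample first.

    Repeatedly removes the individual participating in the most pairs with
    kinship above ``cutoff`` (ties broken by sample order) until no pair
    remains; returns the retained ids in input order.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    n = len(sample_ids)
    over = (np.asarray(K) > cutoff).astype(bool)
    np.fill_diagonal(over, False)
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        worst = int(np.argmax(deg))
        if deg[worst] == 0:
            break
        alive[worst] = False
    return list(sample_ids[alive])


# ----------------------------------------------------------------------
# PC outliers
# ----------------------------------------------------------------------

def _pca_standardized(geno: GenotypeMatrix) -> np.ndarray:
    """Center 2p, scale sqrt(2pq), zero-fill missing after centering."""
    p = geno.allele1_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    d = geno.dosage_float()[:, poly]
    p = p[poly]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return np.where(np.isnan(z), 0.0, z)


def pc_outlier_filter(
    geno: GenotypeMatrix, n_pcs: int = 2, sd_mult: float = 6.0
) -> tuple[list, np.ndarray]:
    """Remove samples beyond mean +/- sd_mult * SD on any of the first PCs.

    Returns ``(retained_sample_ids, scores)`` where scores are the
    n_samples x n_pcs PC coordinates of ALL input samples (so flagged
    points can be plotted).
    """
    z = _pca_standardized(geno)
    max_rank = min(z.shape)
    if n_pcs > max_rank:
        raise ValidationError(f"n_pcs={n_pcs} exceeds matrix rank bound {max_rank}")
    pca = PCA(n_components=n_pcs, svd_solver="full" if max_rank < 500 else "randomized",
              random_state=0)
    scores = pca.fit_transform(z)
    center = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    ok = np.all(np.abs(scores - center) <= sd_mult * sd, axis=1)
    return list(geno.sample_ids[ok]), scores
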
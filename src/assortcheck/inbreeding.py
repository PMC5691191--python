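"""Maximum-likelihood estimation of the inbreeding coefficient.

Under inbreeding or assortative mating, genotype frequencies at a biallelic
locus with allele-1 frequency p (q = 1 - p) deviate from Hardy-Weinberg as

    AA: p^2 (1-f) + p f
    Aa: 2 p q (1-f)
    aa: q^2 (1-f) + q f

where f is the inbreeding coefficient: positive f means heterozygote
deficit, negative f heterozygote excess. The allele frequency itself is
unaffected, so p is plugged in at its sample estimate (profile likelihood)
and f is the single free parameter.

Single-locus estimation maximizes the multinomial log-likelihood of the
genotype counts (n0, n1, n2); the maximizer has the closed form
``f = 1 - n1 / (2 n p q)``, clipped to the feasible range
``[-min(p,q)/max(p,q), 1]`` within which all three class probabilities are
non-negative. The multi-locus estimator maximizes the product likelihood
over M independent loci sharing a common f, by bounded scalar optimization
(the log-likelihood is concave in f, being a sum of logs of affine
functions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from assortcheck.errors import MonomorphicError, ValidationError
from assortcheck.genio import MISSING, GenotypeMatrix

__all__ = [
    "VariantCounts",
    "FEstimate",
    "MultiFEstimate",
    "genotype_counts",
    "single_locus_loglik",
    "estimate_f_single",
    "estimate_f_multi",
    "f_profile",
    "feasible_lower_bound",
]

_XATOL = 1e-8  # scalar-optimizer tolerance on f


@dataclass(frozen=True)
class VariantCounts:
    """Genotype counts at one locus: (n0 aa, n1 Aa, n2 AA).

    The sufficient statistic for inbreeding-coefficient inference.
    """

    n0: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2) < 0:
            raise ValidationError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValidationError("at least one observed genotype required")

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def p_hat(self) -> float:
        """Sample allele-1 frequency (2 n2 + n1) / 2n."""
        return (2 * self.n2 + self.n1) / (2 * self.n)


@dataclass(frozen=True)
class FEstimate:
    """Single-locus ML estimate of the inbreeding coefficient."""

    f_hat: float
    p_hat: float
    loglik: float
    n: int
    feasible_range: tuple[float, float]


@dataclass(frozen=True)
class MultiFEstimate:
    """Common inbreeding coefficient jointly estimated over M loci."""

    f_m_hat: float
    p_hats: np.ndarray
    m: int
    loglik: float
    feasible_range: tuple[float, float]


def feasible_lower_bound(p: float) -> float:
    """Smallest f for which all genotype-class probabilities are >= 0."""
    q = 1.0 - p
    return -min(p, q) / max(p, q)


def genotype_counts(geno: GenotypeMatrix, variant_id: str) -> VariantCounts:
    """Tally (n0, n1, n2) for one variant, dropping missing calls."""
    col = geno.dosages[:, geno.variant_index(variant_id)]
    col = col[col != MISSING]
    if col.size == 0:
        raise ValidationError(f"variant {variant_id!r} has no observed genotypes")
    return VariantCounts(int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))


def _class_probs(f, p):
    """Genotype class probabilities (aa, Aa, AA); may be negative outside the feasible range."""
    q = 1.0 - p
    return (q * q * (1 - f) + q * f, 2 * p * q * (1 - f), p * p * (1 - f) + p * f)


def single_locus_loglik(f: float, p: float, counts: VariantCounts) -> float:
    """Multinomial log-likelihood of counts at inbreeding coefficient f.

    Returns -inf when a class with positive observed count has probability
    zero (e.g. heterozygotes at f = 1).
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"allele frequency p={p} must lie strictly in (0,1)")
    if f < feasible_lower_bound(p) - 1e-12 or f > 1.0 + 1e-12:
        raise ValidationError(f"(f={f}, p={p}) outside the feasible range")
    pr_aa, pr_het, pr_AA = _class_probs(f, p)
    total = 0.0
    for count, prob in ((counts.n0, pr_aa), (counts.n1, pr_het), (counts.n2, pr_AA)):
        if count == 0:
            continue
        if prob <= 0.0:
            return -np.inf
        total += count * np.log(prob)
    return total


def estimate_f_single(counts: VariantCounts) -> FEstimate:
    """ML inbreeding coefficient at one locus.

    The allele frequency is fixed at its sample value and the profile
    likelihood maximized over f. The interior maximizer is the
    observed/expected-heterozygosity identity ``1 - n1/(2 n p q)``; it is
    clipped to the feasible range (at the boundaries one genotype class has
    probability exactly zero).
    """
    p = counts.p_hat
    if p <= 0.0 or p >= 1.0:
        raise MonomorphicError(
            f"locus is monomorphic (p_hat={p}); inbreeding coefficient undefined"
        )
    q = 1.0 - p
    f_min = feasible_lower_bound(p)
    f_raw = 1.0 - counts.n1 / (2.0 * counts.n * p * q)
    f_hat = float(np.clip(f_raw, f_min, 1.0))
    return FEstimate(
        f_hat=f_hat,
        p_hat=p,
        loglik=single_locus_loglik(f_hat, p, counts),
        n=counts.n,
        feasible_range=(f_min, 1.0),
    )


def _multi_loglik_arrays(counts_list: Sequence[VariantCounts]):
    """Stack counts/frequencies into arrays for fast joint evaluation."""
    n0 = np.array([c.n0 for c in counts_list], dtype=np.float64)
    n1 = np.array([c.n1 for c in counts_list], dtype=np.float64)
    n2 = np.array([c.n2 for c in counts_list], dtype=np.float64)
    p = np.array([c.p_hat for c in counts_list], dtype=np.float64)
    return n0, n1, n2, p


def _multi_loglik(f: float, n0, n1, n2, p) -> float:
    q = 1.0 - p
    probs = np.stack([q * q * (1 - f) + q * f, 2 * p * q * (1 - f), p * p * (1 - f) + p * f])
    counts = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.maximum(probs, 0.0)), 0.0)
    if np.isneginf(terms).any() or np.isnan(terms).any():
        return -np.inf
    return float(terms.sum())


def estimate_f_multi(counts_list: Iterable[VariantCounts]) -> MultiFEstimate:
    """Common inbreeding coefficient over M independent loci.

    Each locus keeps its own sample allele frequency; the shared f
    maximizes the product of the per-locus multinomial likelihoods. The
    joint feasible range is the intersection of the per-locus ranges; the
    optimizer is bounded Brent on the (concave) joint log-likelihood, with
    ties broken toward 0.
    """
    counts_list = list(counts_list)
    if not counts_list:
        raise ValidationError("estimate_f_multi requires at least one locus")
    for i, c in enumerate(counts_list):
        if c.p_hat <= 0.0 or c.p_hat >= 1.0:
            raise MonomorphicError(f"locus at index {i} is monomorphic (p_hat={c.p_hat})")
    n0, n1, n2, p = _multi_loglik_arrays(counts_list)
    f_min = float(np.max(-np.minimum(p, 1 - p) / np.maximum(p, 1 - p)))

    if len(counts_list) == 1:
        single = estimate_f_single(counts_list[0])
        return MultiFEstimate(single.f_hat, p, 1, single.loglik, (f_min, 1.0))

    # shrink bounds by one tolerance so class probabilities stay positive
    lo, hi = f_min + _XATOL, 1.0 - _XATOL
    res = minimize_scalar(
        lambda f: -_multi_loglik(f, n0, n1, n2, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _XATOL},
    )
    f_hat = float(res.x)
    # tie-break toward 0 / snap to exact boundary when indistinguishable
    for candidate in (0.0, f_min, 1.0):
        if f_min <= candidate <= 1.0:
            ll = _multi_loglik(candidate, n0, n1, n2, p)
            if ll >= -res.fun - 1e-12 and abs(candidate - f_hat) <= 10 * _XATOL:
                f_hat = candidate
                break
    return MultiFEstimate(
        f_m_hat=f_hat,
        p_hats=p,
        m=len(counts_list),
        loglik=_multi_loglik(f_hat, n0, n1, n2, p),
        feasible_range=(f_min, 1.0),
    )


def counts_for_variants(geno: GenotypeMatrix, variant_ids=None) -> list[VariantCounts]:
    """Vectorized genotype tallies for a set of variants (missing dropped)."""
    if variant_ids is None:
        idx = np.arange(geno.n_variants)
    else:
        idx = np.array([geno.variant_index(v) for v in variant_ids])
    d = geno.dosages[:, idx]
    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    return [VariantCounts(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]


def f_profile(geno: GenotypeMatrix, variant_ids=None) -> dict:
    """Per-variant f estimates for a SNP set, with summary statistics.

    Returns a dict with ``estimates`` (list of FEstimate), ``mean``, ``sd``
    (across-locus moments of the single-locus estimates) and ``f_m`` (the
    joint multi-locus estimate over the same loci, which should closely
    track the mean).
    """
    counts = counts_for_variants(geno, variant_ids)
    estimates = [estimate_f_single(c) for c in counts]
    f_vals = np.array([e.f_hat for e in estimates])
    multi = estimate_f_multi(counts)
    return {
        "estimates": estimates,
        "f_values": f_vals,
        "mean": float(f_vals.mean()),
        "sd": float(f_vals.std(ddof=1)) if len(f_vals) > 1 else float("nan"),
        "f_m": multi.f_m_hat,
        "multi": multi,
    }
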
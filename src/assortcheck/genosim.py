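"""Forward simulation of the populations the inference assumes.

Three generative modes cover the statistical structures the pipeline must
distinguish:

``simulate_hw_genotypes``
    Direct multinomial draws from the inbreeding-parameterized genotype
    frequencies p^2(1-f)+pf / 2pq(1-f) / q^2(1-f)+qf — the ground truth for
    estimator parameter-recovery checks.

``simulate_assortative_population``
    A forward mating model: founders under HWE, an additive polygenic trait
    with heritability h2, spouses paired by phenotype rank so the realized
    spousal correlation approaches a target rho, Mendelian transmission to
    offspring. One generation of assortative mating with spousal phenotype
    correlation rho induces an expected per-trait-locus inbreeding
    coefficient of rho * h2 / (2 * m_trait) in the offspring (the
    correlation between uniting gametes), while neutral loci stay at HWE.

``simulate_structured_population``
    Two-or-more subpopulation structure. Pooling differentiated
    subpopulations produces a heterozygote deficit (Wahlund effect)
    F = var(p) / (p_bar * q_bar); an F1 cross of two subpopulations
    produces the mirror-image heterozygote excess.

All randomness flows through ``numpy.random.default_rng(seed)``; equal
seeds give byte-identical outputs.

Mate matching calibration: candidates are split into two pools, one pool is
ranked on its true phenotype and the other on phenotype plus Gaussian noise,
then paired rank-to-rank. With noise variance s2 on one side only, the
realized spousal phenotype correlation is approximately
``1 / sqrt(1 + s2 / var(P))``, which is inverted to choose s2 for a target
rho. rho = 0 falls back to random pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from assortcheck.errors import FeasibilityError, ValidationError
from assortcheck.genio import MISSING, GenotypeMatrix
from assortcheck.inbreeding import feasible_lower_bound

__all__ = [
    "MatingSimConfig",
    "StructureSimConfig",
    "SimTruth",
    "simulate_hw_genotypes",
    "simulate_assortative_population",
    "simulate_structured_population",
    "inject_missingness",
]

N_AUTOSOMES = 22


@dataclass(frozen=True)
class MatingSimConfig:
    """Parameters of the forward assortative-mating simulation.

    Defaults mirror the study conditions the analysis is designed around: a
    strongly heritable polygenic trait (h2 = 0.8, the classic full-sib
    estimate for adult height), a spousal phenotype correlation of 0.4 (the
    European-American spouse-height correlation scale), 20 trait loci so
    per-locus effects are individually small, and a genome-wide panel of
    neutral loci for the matched null.
    """

    n_parent_pairs: int = 500
    m_trait: int = 20
    m_neutral: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2: float = 0.8
    rho_spouse: float = 0.4
    n_generations: int = 1
    offspring_per_pair: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parent_pairs < 1 or self.offspring_per_pair < 1 or self.n_generations < 1:
            raise ValidationError("counts must be >= 1")
        if self.m_trait < 0 or self.m_neutral < 0 or self.m_trait + self.m_neutral < 1:
            raise ValidationError("need at least one locus; m_trait may be 0 for null runs")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range {self.maf_range} must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValidationError("h2 must be in [0, 1]")
        if abs(self.rho_spouse) > 1.0:
            raise ValidationError("|rho_spouse| must be <= 1")


@dataclass(frozen=True)
class StructureSimConfig:
    """Parameters of the subpopulation-structure simulation.

    ``subpop_freqs`` is a (k_subpops x m_loci) array of allele-1
    frequencies. ``mode='pooled'`` samples each individual's subpopulation
    once (shared across loci) by ``mixing_proportions``; ``mode='f1_cross'``
    gives every individual one parental allele from each of exactly two
    subpopulations.
    """

    subpop_freqs: np.ndarray
    mixing_proportions: np.ndarray
    mode: str = "pooled"
    n_individuals: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.atleast_2d(np.asarray(self.subpop_freqs, dtype=np.float64))
        object.__setattr__(self, "subpop_freqs", freqs)
        props = np.asarray(self.mixing_proportions, dtype=np.float64)
        object.__setattr__(self, "mixing_proportions", props)
        if props.shape[0] != freqs.shape[0]:
            raise ValidationError("one mixing proportion per subpopulation required")
        if not np.isclose(props.sum(), 1.0):
            raise ValidationError(f"mixing proportions sum to {props.sum()}, not 1")
        if (freqs <= 0).any() or (freqs >= 1).any():
            raise ValidationError("subpopulation frequencies must lie strictly in (0, 1)")
        if self.mode not in ("pooled", "f1_cross"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "f1_cross" and freqs.shape[0] != 2:
            raise ValidationError("f1_cross requires exactly 2 subpopulations")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")


@dataclass
class SimTruth:
    """Ground-truth bookkeeping emitted by the simulators."""

    true_freq: np.ndarray
    beta: np.ndarray
    expected_f: np.ndarray
    spouse_pairs: Optional[pd.DataFrame] = None
    generation: Optional[np.ndarray] = None
    realized_rho: Optional[list] = None
    subpop_labels: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.true_freq)
        if len(self.beta) != m or len(self.expected_f) != m:
            raise ValidationError("per-locus truth vectors must share one length")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("effect sizes must be finite")


def _variant_table(m: int, prefix: str = "snp") -> pd.DataFrame:
    """Round-robin chromosome assignment over autosomes 1-22, ascending positions."""
    chroms = [str(1 + (i % N_AUTOSOMES)) for i in range(m)]
    positions = [1000 * (1 + i // N_AUTOSOMES) for i in range(m)]
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i}" for i in range(m)],
            "chromosome": chroms,
            "position": positions,
            "allele1": "A",
            "allele2": "B",
        }
    )


def simulate_hw_genotypes(
    freqs: np.ndarray, f: float, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Draw genotypes directly from the f-parameterized class frequencies.

    Each locus is drawn independently with class probabilities
    aa: q^2(1-f)+qf, Aa: 2pq(1-f), AA: p^2(1-f)+pf. Raises
    :class:`FeasibilityError` when (f, p) puts any class probability below
    zero at some locus.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if (freqs <= 0).any() or (freqs >= 1).any():
        raise ValidationError("allele frequencies must lie strictly in (0, 1)")
    bounds = np.array([feasible_lower_bound(p) for p in freqs])
    bad = np.flatnonzero((f < bounds - 1e-12) | (f > 1.0 + 1e-12))
    if bad.size:
        i = int(bad[0])
        raise FeasibilityError(
            f"f={f} infeasible at locus {i} (p={freqs[i]:.4g}, "
            f"feasible range [{bounds[i]:.4g}, 1])"
        )
    rng = np.random.default_rng(seed)
    q = 1.0 - freqs
    pr_aa = q * q * (1 - f) + q * f
    pr_het = 2 * freqs * q * (1 - f)
    # cumulative thresholds per locus; one uniform per call classifies it
    u = rng.random((n, freqs.size))
    dosages = np.full((n, freqs.size), 2, dtype=np.int8)
    dosages[u < pr_aa + pr_het] = 1
    dosages[u < pr_aa] = 0
    return GenotypeMatrix(
        sample_ids=np.array([f"ind{i}" for i in range(n)], dtype=object),
        variants=_variant_table(freqs.size),
        dosages=dosages,
    )


def _trait(dosages: np.ndarray, beta: np.ndarray, h2: float, rng) -> np.ndarray:
    """Additive polygenic phenotype with environmental noise set by h2."""
    g = dosages.astype(np.float64) @ beta
    var_g = g.var()
    if h2 >= 1.0 or var_g == 0.0:
        noise_sd = 0.0 if h2 >= 1.0 else 1.0
    else:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    return g + rng.normal(0.0, noise_sd, size=g.shape[0]) if noise_sd > 0 else g.copy()


def _pair_by_phenotype(pheno: np.ndarray, rho: float, rng):
    """Split into two mate pools and pair by (noisy) phenotype rank.

    Returns index pairs (a, b) into ``pheno``. Noise with variance
    var(P) * (1/rho^2 - 1) is added to ONE side before ranking so that the
    realized spousal correlation approximates rho (see module docstring).
    Negative rho ranks one side in reverse.
    """
    n = pheno.shape[0]
    perm = rng.permutation(n)
    half = n // 2
    side_a, side_b = perm[:half], perm[half : 2 * half]
    if rho == 0.0:
        return side_a, side_b  # random pairing
    var_p = pheno.var()
    r = abs(rho)
    if r >= 1.0:
        noisy_b = pheno[side_b]
    else:
        s2 = var_p * (1.0 / (r * r) - 1.0)
        noisy_b = pheno[side_b] + rng.normal(0.0, np.sqrt(s2), size=half)
    order_a = side_a[np.argsort(pheno[side_a], kind="stable")]
    order_b = side_b[np.argsort(noisy_b, kind="stable")]
    if rho < 0:
        order_b = order_b[::-1]
    return order_a, order_b


def _mendelian_offspring(dos_a, dos_b, rng):
    """One child per row pair: one allele from each parent, independently per locus."""
    pa = rng.binomial(1, dos_a / 2.0)
    pb = rng.binomial(1, dos_b / 2.0)
    return (pa + pb).astype(np.int8)


def simulate_assortative_population(config: MatingSimConfig):
    """Forward-simulate assortative mating on a polygenic trait.

    Returns ``(geno, phenotype, truth)`` for the FINAL generation, where
    ``truth`` records per-locus true founder frequencies, effect sizes,
    the analytic per-trait-locus expected f (rho * h2 / (2 m_trait), 0 for
    neutral loci), spouse pairings of the last mating round, and the
    realized spousal phenotype correlation per generation.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_trait + config.m_neutral
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    beta = np.zeros(m)
    beta[: config.m_trait] = 1.0  # equal positive effects at trait loci

    n_founders = 2 * config.n_parent_pairs
    u = rng.random((n_founders, m))
    q = 1.0 - freqs
    dosages = np.full((n_founders, m), 2, dtype=np.int8)
    dosages[u < q * q + 2 * freqs * q] = 1
    dosages[u < q * q] = 0

    realized_rho: list[float] = []
    spouse_pairs = None
    warned = False
    for gen in range(config.n_generations):
        pheno = _trait(dosages, beta, config.h2, rng)
        side_a, side_b = _pair_by_phenotype(pheno, config.rho_spouse, rng)
        r = float(np.corrcoef(pheno[side_a], pheno[side_b])[0, 1]) if len(side_a) > 2 else np.nan
        realized_rho.append(r)
        if (
            gen == 0
            and np.isfinite(r)
            and abs(r - config.rho_spouse) > 0.05
            and not warned
        ):
            warnings.warn(
                f"realized spousal correlation {r:.3f} deviates from target "
                f"{config.rho_spouse} by more than 0.05",
                stacklevel=2,
            )
            warned = True
        spouse_pairs = pd.DataFrame(
            {"id_a": [f"g{gen}_i{i}" for i in side_a], "id_b": [f"g{gen}_i{i}" for i in side_b]}
        )
        parent_dosages = (dosages[side_a].copy(), dosages[side_b].copy())
        kids = []
        for _ in range(config.offspring_per_pair):
            kids.append(_mendelian_offspring(dosages[side_a], dosages[side_b], rng))
        dosages = np.vstack(kids)

    final_gen = config.n_generations
    sample_ids = np.array([f"g{final_gen}_i{i}" for i in range(dosages.shape[0])], dtype=object)
    pheno = _trait(dosages, beta, config.h2, rng)
    expected_f = np.zeros(m)
    if config.m_trait > 0:
        expected_f[: config.m_trait] = config.rho_spouse * config.h2 / (2.0 * config.m_trait)
    truth = SimTruth(
        true_freq=freqs,
        beta=beta,
        expected_f=expected_f,
        spouse_pairs=spouse_pairs,
        generation=np.full(dosages.shape[0], final_gen),
        realized_rho=realized_rho,
        extras={"parent_dosages": parent_dosages},  # last mating round, paired rows
    )
    geno = GenotypeMatrix(sample_ids, _variant_table(m), dosages)
    return geno, pheno, truth


def simulate_structured_population(config: StructureSimConfig):
    """Simulate pooled or F1-cross subpopulation structure.

    ``truth.expected_f`` carries the closed-form per-locus expectation:
    pooled, +var_w(p) / (p_bar q_bar) (Wahlund deficit); F1 cross,
    1 - (p1 q2 + p2 q1) / (2 p_bar q_bar) (heterozygote excess, negative
    whenever the subpopulations differ).
    """
    rng = np.random.default_rng(config.seed)
    freqs = config.subpop_freqs  # k x m
    props = config.mixing_proportions
    k, m = freqs.shape
    n = config.n_individuals

    p_bar = props @ freqs
    q_bar = 1.0 - p_bar
    if config.mode == "pooled":
        var_p = props @ (freqs - p_bar) ** 2
        expected_f = var_p / (p_bar * q_bar)
        labels = rng.choice(k, size=n, p=props)
        p_ind = freqs[labels]  # n x m
        u = rng.random((n, m))
        q_ind = 1.0 - p_ind
        dosages = np.full((n, m), 2, dtype=np.int8)
        dosages[u < q_ind * q_ind + 2 * p_ind * q_ind] = 1
        dosages[u < q_ind * q_ind] = 0
    else:  # f1_cross
        p1, p2 = freqs[0], freqs[1]
        het = p1 * (1 - p2) + p2 * (1 - p1)
        expected_f = 1.0 - het / (2.0 * p_bar * q_bar)
        a1 = rng.binomial(1, np.broadcast_to(p1, (n, m)))
        a2 = rng.binomial(1, np.broadcast_to(p2, (n, m)))
        dosages = (a1 + a2).astype(np.int8)
        labels = np.zeros(n, dtype=int)

    truth = SimTruth(
        true_freq=p_bar,
        beta=np.zeros(m),
        expected_f=np.asarray(expected_f, dtype=np.float64),
        subpop_labels=labels,
    )
    geno = GenotypeMatrix(
        sample_ids=np.array([f"ind{i}" for i in range(n)], dtype=object),
        variants=_variant_table(m),
        dosages=dosages,
    )
    return geno, truth


def inject_missingness(geno: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise ValidationError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return GenotypeMatrix(geno.sample_ids.copy(), geno.variants.copy(), geno.dosages.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(geno.dosages.shape) < rate
    dosages = geno.dosages.copy()
    dosages[mask] = MISSING
    return GenotypeMatrix(geno.sample_ids.copy(), geno.variants.copy(), dosages)
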
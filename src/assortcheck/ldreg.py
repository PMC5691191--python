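"""Cross-chromosome LD-product regression.

Assortative mating on a polygenic trait builds gametic disequilibrium
between trait loci even on different chromosomes, with magnitude
proportional to the product of their effect sizes; population structure
builds cross-chromosome LD too, but proportional to the product of the
loci's ancestry (PC) loadings. Regressing the composite disequilibrium D of
every cross-chromosome trait-SNP pair on (beta_i * beta_j, load1_i *
load1_j, load2_i * load2_j) therefore separates the two sources: a positive
effect-size-product coefficient is trait-driven mating signal that ancestry
cannot explain.

D is estimated phase-free from dosages with the composite (Burrows-type)
estimator cov(g_i, g_j) / 2, which is consistent for the gametic D under
random union of gametes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from assortcheck.errors import ValidationError
from assortcheck.genio import GenotypeMatrix
from assortcheck.qc import _pca_standardized

__all__ = [
    "LDPairRecord",
    "ProductRegressionResult",
    "composite_D",
    "snp_effect_sizes",
    "pc_loadings",
    "build_pair_records",
    "product_regression",
]


@dataclass(frozen=True)
class LDPairRecord:
    """One cross-chromosome SNP pair: the regression row."""

    id_i: str
    id_j: str
    D: float
    beta_product: float
    pc1_product: float
    pc2_product: float


@dataclass
class ProductRegressionResult:
    """Per-predictor OLS estimates for the three product terms."""

    table: pd.DataFrame  # index: predictor; columns: estimate, se, t, p
    n_pairs: int

    def coefficient(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "estimate"])

    def pvalue(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "p"])


def composite_D(g_i, g_j) -> float:
    """Composite disequilibrium between two dosage vectors: cov(g_i, g_j) / 2.

    Missing entries (NaN) are dropped pairwise; at least two complete pairs
    are required. For duplicated loci under HWE this equals var(g)/2 = pq.
    """
    g_i = np.asarray(g_i, dtype=np.float64)
    g_j = np.asarray(g_j, dtype=np.float64)
    if g_i.shape != g_j.shape:
        raise ValidationError("dosage vectors must have equal length")
    ok = ~(np.isnan(g_i) | np.isnan(g_j))
    if ok.sum() < 2:
        raise ValidationError("need at least 2 complete sample pairs for D")
    gi, gj = g_i[ok], g_j[ok]
    return float(np.cov(gi, gj, ddof=1)[0, 1] / 2.0)


def snp_effect_sizes(geno: GenotypeMatrix, phenotype, variant_ids=None) -> pd.Series:
    """Univariate OLS slope of the phenotype on each variant's dosage.

    One regression per variant with an intercept; missing dosages dropped
    per variant. Zero-variance variants are dropped with a warning.
    """
    phenotype = np.asarray(phenotype, dtype=np.float64)
    if phenotype.shape[0] != geno.n_samples:
        raise ValidationError("phenotype length must equal the number of samples")
    ids = list(geno.variant_ids) if variant_ids is None else list(variant_ids)
    d = geno.dosage_float()
    betas = {}
    dropped = []
    for v in ids:
        col = d[:, geno.variant_index(v)]
        ok = ~np.isnan(col) & ~np.isnan(phenotype)
        g, y = col[ok], phenotype[ok]
        var_g = g.var()
        if var_g == 0.0:
            dropped.append(v)
            continue
        betas[v] = float(np.cov(g, y, ddof=1)[0, 1] / g.var(ddof=1))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance variants: {dropped[:5]}",
                      stacklevel=2)
    return pd.Series(betas, name="beta")


def pc_loadings(geno: GenotypeMatrix, n_pcs: int = 2):
    """PCA of the standardized dosage matrix (center 2p, scale sqrt(2pq)).

    Returns ``(loadings, scores)``: loadings is an n_variants x n_pcs
    DataFrame of unit-norm right singular vectors indexed by variant id
    (zero rows for monomorphic variants excluded from the PCA), scores the
    n_samples x n_pcs sample coordinates. Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if geno.n_variants < 2:
        raise ValidationError("PCA needs at least 2 variants")
    p = geno.allele1_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    z = _pca_standardized(geno)
    max_rank = min(z.shape)
    if n_pcs > max_rank:
        raise ValidationError(f"n_pcs={n_pcs} exceeds rank bound {max_rank}")
    pca = PCA(n_components=n_pcs, svd_solver="full" if max_rank < 500 else "randomized",
              random_state=0)
    scores = pca.fit_transform(z)
    comps = pca.components_  # n_pcs x n_poly, unit rows
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    loadings = np.zeros((geno.n_variants, n_pcs))
    loadings[poly] = comps.T
    loadings = pd.DataFrame(
        loadings, index=geno.variant_ids, columns=[f"pc{k + 1}" for k in range(n_pcs)]
    )
    return loadings, scores


def build_pair_records(
    geno: GenotypeMatrix, trait_ids, betas: pd.Series, loadings: pd.DataFrame
) -> list[LDPairRecord]:
    """All unordered cross-chromosome pairs of trait variants with D and products."""
    trait_ids = [v for v in trait_ids if v in betas.index]
    chrom = dict(zip(geno.variant_ids, geno.variants["chromosome"]))
    if len({chrom[v] for v in trait_ids}) < 2:
        raise ValidationError("trait SNPs span fewer than 2 chromosomes; no unlinked pairs")
    d = geno.dosage_float()
    col = {v: d[:, geno.variant_index(v)] for v in trait_ids}
    records = []
    for vi, vj in combinations(trait_ids, 2):
        if chrom[vi] == chrom[vj]:
            continue
        records.append(
            LDPairRecord(
                id_i=vi,
                id_j=vj,
                D=composite_D(col[vi], col[vj]),
                beta_product=float(betas[vi] * betas[vj]),
                pc1_product=float(loadings.loc[vi, "pc1"] * loadings.loc[vj, "pc1"]),
                pc2_product=float(loadings.loc[vi, "pc2"] * loadings.loc[vj, "pc2"]),
            )
        )
    return records


def product_regression(records: list[LDPairRecord]) -> ProductRegressionResult:
    """OLS of pairwise D on effect-size and PC-loading products (plus intercept)."""
    if len(records) < 4:
        raise ValidationError("need at least 4 pair records for the regression")
    df = pd.DataFrame(
        {
            "D": [r.D for r in records],
            "beta_product": [r.beta_product for r in records],
            "pc1_product": [r.pc1_product for r in records],
            "pc2_product": [r.pc2_product for r in records],
        }
    )
    X = df[["beta_product", "pc1_product", "pc2_product"]]
    corr = X.corr().to_numpy()
    off = np.abs(corr[np.triu_indices(3, k=1)])
    if np.any(off > 1 - 1e-10):
        names = ["beta_product", "pc1_product", "pc2_product"]
        iu = np.triu_indices(3, k=1)
        k = int(np.argmax(off))
        raise ValidationError(
            f"collinear predictors: {names[iu[0][k]]} and {names[iu[1][k]]}"
        )
    model = sm.OLS(df["D"], sm.add_constant(X)).fit()
    table = pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    ).drop(index="const")
    return ProductRegressionResult(table=table, n_pairs=len(records))
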
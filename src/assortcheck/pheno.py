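"""Spousal phenotype correlations with optional age adjustment.

A high spouse-height correlation is the phenotypic face of assortative
mating; the genotypic analyses elsewhere in the package test whether it
reaches the DNA. The correlation here is the interclass Pearson r over
spouse pairs, each pair entered once with roles ordered deterministically
by sample id (a double-entry intraclass variant is available by flag), with
a Fisher-z 95% CI and a two-sided t-test p-value. Age adjustment replaces
heights by residuals of a pooled OLS of height on age over all paired
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from assortcheck.errors import ValidationError
from assortcheck.genio import PhenotypeTable

__all__ = ["SpousalResult", "pair_extraction", "spouse_correlation"]


@dataclass(frozen=True)
class SpousalResult:
    r: float
    ci: tuple[float, float]
    p: float
    n_pairs: int
    adjusted: bool


def pair_extraction(table: PhenotypeTable) -> list[tuple]:
    """Unique spouse pairs as (height_a, height_b, age_a, age_b) tuples.

    Each symmetric pair appears exactly once, roles ordered by sample id
    (so A<->B and B<->A collapse deterministically). Self-paired samples
    are rejected.
    """
    df = table.data
    if "spouse_id" not in df.columns:
        raise ValidationError("phenotype table has no spouse_id column")
    paired = df.dropna(subset=["spouse_id"])
    selfpair = paired[paired["sample_id"] == paired["spouse_id"]]
    if len(selfpair):
        raise ValidationError(f"self-paired samples: {selfpair['sample_id'].tolist()[:5]}")
    rows = paired.set_index("sample_id")
    seen = set()
    out = []
    for sid in sorted(rows.index):
        spouse = rows.loc[sid, "spouse_id"]
        key = tuple(sorted((sid, spouse)))
        if key in seen:
            continue
        seen.add(key)
        a, b = key
        age_a = rows.loc[a].get("age", np.nan)
        age_b = rows.loc[b].get("age", np.nan)
        out.append((float(rows.loc[a, "height"]), float(rows.loc[b, "height"]),
                    float(age_a), float(age_b)))
    return out


def spouse_correlation(
    table: PhenotypeTable, adjust_age: bool = False, double_entry: bool = False
) -> SpousalResult:
    """Interclass spousal correlation of height.

    With ``adjust_age``, heights are first replaced by residuals from one
    pooled OLS of height on age fitted over all paired individuals. With
    ``double_entry``, each pair contributes both orderings (the intraclass
    convention); p and CI then still use the number of distinct pairs.
    """
    pairs = pair_extraction(table)
    n_pairs = len(pairs)
    if n_pairs < 3:
        raise ValidationError(f"need >= 3 complete spouse pairs, got {n_pairs}")
    h_a = np.array([p[0] for p in pairs])
    h_b = np.array([p[1] for p in pairs])
    if adjust_age:
        age_a = np.array([p[2] for p in pairs])
        age_b = np.array([p[3] for p in pairs])
        if np.isnan(age_a).any() or np.isnan(age_b).any():
            raise ValidationError("age adjustment requested but ages are missing")
        heights = np.concatenate([h_a, h_b])
        ages = np.concatenate([age_a, age_b])
        # pooled OLS height ~ age; constant age degenerates to centering
        if ages.std() == 0.0:
            resid = heights - heights.mean()
        else:
            slope, intercept = np.polyfit(ages, heights, 1)
            resid = heights - (intercept + slope * ages)
        h_a, h_b = resid[:n_pairs], resid[n_pairs:]
    if double_entry:
        x = np.concatenate([h_a, h_b])
        y = np.concatenate([h_b, h_a])
    else:
        x, y = h_a, h_b
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError("zero-variance heights; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    # inference on the number of distinct pairs
    df = n_pairs - 2
    if abs(r) >= 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
        z = np.arctanh(r)
        zse = 1.0 / np.sqrt(n_pairs - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * zse)),
              float(np.tanh(z + 1.959963984540054 * zse)))
    return SpousalResult(r=r, ci=ci, p=p, n_pairs=n_pairs, adjusted=adjust_age)
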
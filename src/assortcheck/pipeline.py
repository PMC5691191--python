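"""End-to-end pipeline orchestration and report assembly.

``run_pipeline`` chains the stages — QC, single/multi-locus inbreeding
estimation, frequency-matched resampling null, cross-chromosome LD-product
regression, spousal correlation — and writes a JSON + TSV bundle with a
provenance block (package version, seeds, thresholds). Each stage's output
mirrors one of the analysis's standard result tables: single-locus
comparison, multi-locus f_M with empirical p, the D-product regression, and
the spousal correlations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import assortcheck
from assortcheck.errors import AssortcheckError
from assortcheck.genio import GenotypeMatrix, PhenotypeTable, read_phenotypes, read_plink
from assortcheck.inbreeding import f_profile
from assortcheck.ldreg import build_pair_records, pc_loadings, product_regression, snp_effect_sizes
from assortcheck.matchnull import MatchSpec, compare_single_locus, null_distribution
from assortcheck.pheno import spouse_correlation
from assortcheck.qc import (
    QCThresholds,
    exclude_related,
    filter_samples,
    filter_variants,
    kinship_matrix,
    ld_prune,
    pc_outlier_filter,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    bfile: str | None = None
    trait_snps: list = field(default_factory=list)
    pheno_path: str | None = None
    out_dir: str = "assortcheck_out"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    match_spec: MatchSpec = field(default_factory=MatchSpec)
    B: int = 1000
    seed: int = 0
    run_kinship: bool = True
    run_pc_outliers: bool = False
    run_ldreg: bool = True
    run_spouses: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = QCThresholds(**raw.pop("thresholds", {}))
        spec = MatchSpec(**raw.pop("match_spec", {}))
        snps_path = raw.pop("trait_snps_file", None)
        cfg = cls(thresholds=thr, match_spec=spec, **raw)
        if snps_path:
            cfg.trait_snps = Path(snps_path).read_text().split()
        return cfg


def _stage(name):
    """Wrap a stage so failures surface with the stage name."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise AssortcheckError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    geno: GenotypeMatrix | None = None,
    pheno: np.ndarray | None = None,
    pheno_table: PhenotypeTable | None = None,
) -> dict:
    """Run QC -> inbreeding -> resampling null -> LD regression -> spouses.

    ``geno`` may be passed directly (library use) or loaded from
    ``config.bfile``. Returns the report bundle as a dict and, when
    ``config.out_dir`` is set, writes ``report.json`` plus TSVs of the
    per-variant estimates and the null distribution (the histogram data
    for a null-vs-observed figure).
    """
    rng = np.random.default_rng(config.seed)
    if geno is None:
        if config.bfile is None:
            raise AssortcheckError("no genotype input: pass geno= or set config.bfile")
        geno = _stage("load")(read_plink)(config.bfile)
    if pheno_table is None and config.pheno_path:
        pheno_table = _stage("load_pheno")(read_phenotypes)(config.pheno_path)

    bundle: dict = {
        "provenance": {
            "package": "assortcheck",
            "version": assortcheck.__version__,
            "seed": config.seed,
            "B": config.B,
            "thresholds": vars(config.thresholds),
            "match_spec": {
                "maf_bin_width": config.match_spec.maf_bin_width,
                "with_replacement_across_resamples":
                    config.match_spec.with_replacement_across_resamples,
            },
        },
        "stages": {},
    }

    # ---- QC chain -----------------------------------------------------
    geno_s, samp_report = _stage("qc_samples")(filter_samples)(geno, config.thresholds)
    geno_v, var_report = _stage("qc_variants")(filter_variants)(geno_s, config.thresholds)
    geno_v = geno_v.orient_minor()
    if config.run_kinship and geno_v.n_samples >= 2:
        K = _stage("kinship")(kinship_matrix)(geno_v)
        retained = exclude_related(K, geno_v.sample_ids, config.thresholds.kinship_cutoff)
        keep_idx = np.flatnonzero(np.isin(geno_v.sample_ids, retained))
        n_rel = geno_v.n_samples - len(retained)
        geno_v = geno_v.subset(sample_idx=keep_idx)
    else:
        n_rel = 0
    if config.run_pc_outliers:
        retained, _scores = _stage("pc_outliers")(pc_outlier_filter)(
            geno_v, n_pcs=2, sd_mult=config.thresholds.pc_outlier_sd
        )
        keep_idx = np.flatnonzero(np.isin(geno_v.sample_ids, retained))
        geno_v = geno_v.subset(sample_idx=keep_idx)
    pruned_ids = _stage("ld_prune")(ld_prune)(
        geno_v, r2_max=config.thresholds.prune_r2,
        seed=int(rng.integers(2**31)),
    )
    bundle["stages"]["qc"] = {
        "samples": samp_report.to_dict(),
        "variants": var_report.to_dict(),
        "n_related_removed": n_rel,
        "n_pruned_retained": len(pruned_ids),
    }

    trait_ids = [v for v in config.trait_snps if v in set(geno_v.variant_ids)]
    if not trait_ids:
        raise AssortcheckError("stage 'estimate' failed: no trait SNPs survive QC")
    pool_ids = [v for v in pruned_ids if v not in set(trait_ids)]

    # ---- single-locus estimates (comparison-table analogue) -----------
    prof_trait = _stage("estimate")(f_profile)(geno_v, trait_ids)
    null_seed = int(rng.integers(2**31))
    nd = _stage("resample")(null_distribution)(
        geno_v, trait_ids, pool_ids, B=config.B, spec=config.match_spec, seed=null_seed
    )
    one_matched = nd.matched_sets[0]
    prof_matched = f_profile(geno_v, one_matched)
    comparison = compare_single_locus(prof_trait["f_values"], prof_matched["f_values"])
    bundle["stages"]["single_locus"] = comparison
    bundle["stages"]["multi_locus"] = {
        "f_m_trait": prof_trait["f_m"],
        "null_mean": float(nd.values.mean()),
        "null_sd": float(nd.values.std(ddof=1)),
        "p_empirical": nd.p_empirical,
        "B": nd.B,
        "M": len(trait_ids),
    }

    # ---- LD-product regression ----------------------------------------
    if config.run_ldreg and pheno is not None and len(trait_ids) >= 4:
        try:
            betas = snp_effect_sizes(geno_v, pheno, trait_ids)
            loadings, _ = pc_loadings(geno_v, n_pcs=2)
            records = build_pair_records(geno_v, trait_ids, betas, loadings)
            reg = product_regression(records)
            bundle["stages"]["ld_regression"] = {
                "n_pairs": reg.n_pairs,
                "coefficients": reg.table.reset_index()
                .rename(columns={"index": "predictor"})
                .to_dict(orient="records"),
            }
        except AssortcheckError as exc:
            warnings.warn(f"LD regression skipped: {exc}", stacklevel=2)
            bundle["stages"]["ld_regression"] = {"skipped": str(exc)}

    # ---- spousal correlation ------------------------------------------
    if config.run_spouses and pheno_table is not None and "spouse_id" in pheno_table.data:
        for adjust in (False, True):
            key = "spouses_age_adjusted" if adjust else "spouses"
            try:
                res = spouse_correlation(pheno_table, adjust_age=adjust)
                bundle["stages"][key] = {
                    "r": res.r, "ci": list(res.ci), "p": res.p, "n_pairs": res.n_pairs,
                }
            except AssortcheckError as exc:
                bundle["stages"][key] = {"skipped": str(exc)}

    # ---- emit ----------------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2, default=float))
        per_variant = pd.DataFrame(
            {
                "variant_id": trait_ids,
                "n": [e.n for e in prof_trait["estimates"]],
                "p_hat": [e.p_hat for e in prof_trait["estimates"]],
                "f_hat": [e.f_hat for e in prof_trait["estimates"]],
                "loglik": [e.loglik for e in prof_trait["estimates"]],
            }
        )
        per_variant.to_csv(out / "trait_f.tsv", sep="\t", index=False)
        pd.DataFrame({"f_m_null": nd.values}).to_csv(
            out / "null_distribution.tsv", sep="\t", index=False
        )
        (out / "report.md").write_text(make_report(bundle))
    return bundle


def make_report(bundle: dict) -> str:
    """Render the report bundle as human-readable Markdown."""
    lines = ["# assortcheck report", ""]
    prov = bundle.get("provenance", {})
    lines.append(
        f"package {prov.get('package', '?')} {prov.get('version', '?')}, "
        f"seed {prov.get('seed', '?')}, B = {prov.get('B', '?')}"
    )
    stages = bundle.get("stages", {})

    lines.append("\n## QC")
    qc = stages.get("qc")
    if qc:
        for step in qc["variants"]["steps"] + qc["samples"]["steps"]:
            lines.append(f"- {step['filter']}: removed {step['n_removed']}")
        lines.append(f"- related removed: {qc['n_related_removed']}")
        lines.append(f"- pruned panel size: {qc['n_pruned_retained']}")
    else:
        lines.append("*(absent)*")

    lines.append("\n## Single-locus comparison (trait vs matched SNPs)")
    sl = stages.get("single_locus")
    if sl:
        lines.append("| group | mean f | sd | n |")
        lines.append("|---|---|---|---|")
        lines.append(f"| trait | {sl['mean_trait']:.4g} | {sl['sd_trait']:.4g} | {sl['n_trait']} |")
        lines.append(
            f"| matched | {sl['mean_matched']:.4g} | {sl['sd_matched']:.4g} | {sl['n_matched']} |"
        )
        lines.append(f"\nWelch t p = {sl['t_p']:.3g}; KS p = {sl['ks_p']:.3g}")
    else:
        lines.append("*(absent)*")

    lines.append("\n## Multi-locus f_M vs resampling null")
    ml = stages.get("multi_locus")
    if ml:
        lines.append(
            f"f_M(trait) = {ml['f_m_trait']:.4g}; null mean {ml['null_mean']:.4g} "
            f"(sd {ml['null_sd']:.4g}); empirical p = {ml['p_empirical']:.4g} "
            f"(B = {ml['B']}, M = {ml['M']})"
        )
    else:
        lines.append("*(absent)*")

    lines.append("\n## LD-product regression (cross-chromosome pairs)")
    lr = stages.get("ld_regression")
    if lr and "coefficients" in lr:
        lines.append("| predictor | estimate | se | t | p |")
        lines.append("|---|---|---|---|---|")
        for row in lr["coefficients"]:
            lines.append(
                f"| {row['predictor']} | {row['estimate']:.4g} | {row['se']:.4g} "
                f"| {row['t']:.3g} | {row['p']:.3g} |"
            )
    elif lr:
        lines.append(f"*(skipped: {lr.get('skipped')})*")
    else:
        lines.append("*(absent)*")

    lines.append("\n## Spousal correlations")
    any_sp = False
    for key, label in (("spouses", "unadjusted"), ("spouses_age_adjusted", "age-adjusted")):
        sp = stages.get(key)
        if sp and "r" in sp:
            any_sp = True
            lines.append(
                f"- {label}: r = {sp['r']:.3f} (95% CI {sp['ci'][0]:.3f}..{sp['ci'][1]:.3f}), "
                f"p = {sp['p']:.3g}, {sp['n_pairs']} pairs"
            )
    if not any_sp:
        lines.append("*(absent)*")
    lines.append("")
    return "\n".join(lines)
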
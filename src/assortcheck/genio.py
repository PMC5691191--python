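"""Genotype and phenotype I/O plus the shared in-memory data model.

The pipeline's universal currency is :class:`GenotypeMatrix`: a samples ×
variants matrix of allele-1 dosage codes {0, 1, 2} with ``-1`` marking a
missing call, alongside per-variant metadata (id, chromosome, 1-based
position, alleles). Genotypes are read from and written to PLINK binary
(BED/BIM/FAM, SNP-major) or a plain TSV dialect; phenotypes travel as TSV
with columns ``sample_id  height  age  spouse_id`` (optional ``sex``,
``generation``).

The PLINK 2-bit codec follows the standard BED layout: 3 magic bytes
``0x6c 0x1b 0x01``, then per variant ceil(n/4) bytes, sample *i* occupying
bits ``2(i mod 4)`` of byte ``i // 4`` with codes 00 = homozygous allele 1,
01 = missing, 10 = heterozygous, 11 = homozygous allele 2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from assortcheck.errors import PlinkFormatError, ValidationError

MISSING = -1  # dosage code for a missing genotype call

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage (index 0..2, and -1 -> last slot) <-> 2-bit BED code
_DOSAGE_TO_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)  # [d0, d1, d2, missing]
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)

VARIANT_COLUMNS = ["variant_id", "chromosome", "position", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a cohort.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, length ``n_samples``.
    variants:
        DataFrame with columns ``variant_id, chromosome, position, allele1,
        allele2``; ``allele1`` is the counted allele.
    dosages:
        ``n_samples x n_variants`` int8 array of allele-1 copy counts in
        {0, 1, 2} with ``-1`` for missing.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if not isinstance(self.variants, pd.DataFrame):
            raise ValidationError("variants must be a DataFrame")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValidationError(f"variants missing columns: {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        vids = self.variants["variant_id"]
        if vids.duplicated().any():
            dups = vids[vids.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate variant ids, e.g. {dups}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosages contain codes outside {0,1,2,missing}")
        if (self.variants["position"] < 1).any():
            raise ValidationError("positions must be >= 1")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(idx[0])

    # -- derived per-variant statistics ---------------------------------
    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        out = self.dosages.astype(np.float64)
        out[self.dosages == MISSING] = np.nan
        return out

    def allele1_freq(self) -> np.ndarray:
        """Complete-case allele-1 frequency per variant (NaN if all missing)."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(self.dosages == MISSING, axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.mean(self.dosages == MISSING, axis=1)

    # -- subsetting and re-orientation ----------------------------------
    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[s],
            variants=self.variants.iloc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(s, v)],
        )

    def subset_variants_by_id(self, variant_ids) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in variant_ids]
        return self.subset(variant_idx=idx)

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip variants so allele 1 is the minor allele.

        Flipping maps dosage d -> 2 - d and swaps the allele labels; the
        swap is recorded in a ``flipped`` column of the variant table.
        Estimation downstream is invariant to orientation, but MAF-based
        matching and reporting read allele 1 as the minor allele.
        """
        p = self.allele1_freq()
        flip = p > 0.5
        dos = self.dosages.copy()
        cols = np.flatnonzero(flip)
        sub = dos[:, cols]
        keep_missing = sub == MISSING
        sub = (2 - sub).astype(np.int8)
        sub[keep_missing] = MISSING
        dos[:, cols] = sub
        var = self.variants.copy()
        a1 = var["allele1"].to_numpy().copy()
        a2 = var["allele2"].to_numpy().copy()
        a1[cols], a2[cols] = a2[cols].copy(), a1[cols].copy()
        var["allele1"] = a1
        var["allele2"] = a2
        var["flipped"] = flip
        return GenotypeMatrix(self.sample_ids, var, dos)


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes with optional spouse pairing.

    The spouse relation must be symmetric: if A lists B as spouse, B must
    list A. ``height`` is in any consistent length unit; ``age`` in years.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ["sample_id", "height"]
    OPTIONAL = ["age", "spouse_id", "sex", "generation"]

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
            raise ValidationError(f"duplicate sample ids in phenotype table: {dups}")
        self.data = df.reset_index(drop=True)
        self._check_spouse_symmetry()

    def _check_spouse_symmetry(self) -> None:
        df = self.data
        if "spouse_id" not in df.columns:
            return
        paired = df.dropna(subset=["spouse_id"])
        spouse_of = dict(zip(paired["sample_id"], paired["spouse_id"]))
        offenders = []
        for a, b in spouse_of.items():
            if spouse_of.get(b) != a:
                offenders.append((a, b))
        if offenders:
            raise ValidationError(
                f"asymmetric spouse pairs (A lists B but B does not list A): {offenders[:10]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.data)


# ----------------------------------------------------------------------
# PLINK binary
# ----------------------------------------------------------------------

def _pack_bed(dosages: np.ndarray) -> bytes:
    """Pack a samples x variants dosage matrix into SNP-major BED payload."""
    n, m = dosages.shape
    if m == 0 or n == 0:
        return b""
    # index -1 (missing) picks the last slot of the lookup table
    codes = _DOSAGE_TO_CODE[dosages]  # n x m uint8
    pad = (-n) % 4
    if pad:
        # trailing sample slots are zero-filled, as PLINK does; ignored on read
        codes = np.vstack([codes, np.zeros((pad, m), dtype=np.uint8)])
    codes = codes.T.reshape(m, -1, 4)  # per-variant byte groups
    weights = np.array([1, 4, 16, 64], dtype=np.uint8)
    packed = (codes * weights).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    return packed.tobytes()


def _unpack_bed(payload: bytes, n_samples: int, n_variants: int) -> np.ndarray:
    bytes_per_variant = (n_samples + 3) // 4
    expected = bytes_per_variant * n_variants
    if len(payload) != expected:
        raise PlinkFormatError(
            f"BED payload is {len(payload)} bytes; expected {expected} "
            f"for {n_samples} samples x {n_variants} variants"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_variants, bytes_per_variant)
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n_samples]
    return _CODE_TO_DOSAGE[codes].T.copy()  # samples x variants


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write BED/BIM/FAM files under ``prefix`` (SNP-major BED)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(_pack_bed(geno.dosages))
    bim = pd.DataFrame(
        {
            "chromosome": geno.variants["chromosome"],
            "variant_id": geno.variants["variant_id"],
            "cm": 0,
            "position": geno.variants["position"],
            "allele1": geno.variants["allele1"],
            "allele2": geno.variants["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a SNP-major PLINK BED/BIM/FAM file set."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2] != 0x01:
        raise PlinkFormatError(
            f"{prefix}.bed: only SNP-major mode (0x01) is supported, got {raw[2]:#x}"
        )
    dosages = _unpack_bed(raw[3:], len(fam), len(bim))
    variants = bim[["variant_id", "chromosome", "position", "allele1", "allele2"]].copy()
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), variants, dosages)


# ----------------------------------------------------------------------
# TSV dialects
# ----------------------------------------------------------------------

def write_tsv_genotypes(geno: GenotypeMatrix, path: str | Path, variants_path=None) -> None:
    """Wide TSV: ``sample_id`` column then one column per variant id; NA = missing."""
    d = geno.dosages.astype(object)
    wide = pd.DataFrame(d, columns=geno.variant_ids)
    wide = wide.mask(wide == MISSING, "NA")
    wide.insert(0, "sample_id", geno.sample_ids)
    wide.to_csv(path, sep="\t", index=False)
    if variants_path is not None:
        geno.variants[VARIANT_COLUMNS].to_csv(variants_path, sep="\t", index=False)


def read_tsv_genotypes(path: str | Path, variants_path=None) -> GenotypeMatrix:
    """Read the wide TSV genotype dialect.

    ``variants_path`` optionally points to a variant-metadata TSV with
    columns ``variant_id chromosome position allele1 allele2``; without it,
    placeholder metadata is synthesized (chromosome "1", ascending
    positions, alleles A/B).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: header must contain a sample_id column")
    variant_ids = [c for c in df.columns if c != "sample_id"]
    codes = df[variant_ids].to_numpy(dtype=object)
    dosages = np.empty(codes.shape, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for (i, j), val in np.ndenumerate(codes):
        try:
            dosages[i, j] = valid[str(val)]
        except KeyError:
            # +2: one for the header line, one for 1-based numbering
            raise ValidationError(
                f"{path}: line {i + 2}, variant {variant_ids[j]}: "
                f"invalid genotype code {val!r} (expected 0/1/2/NA)"
            ) from None
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chromosome": str})
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValidationError(f"{variants_path}: missing columns {missing}")
        variants = variants.set_index("variant_id").loc[variant_ids].reset_index()
    else:
        variants = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chromosome": "1",
                "position": np.arange(1, len(variant_ids) + 1),
                "allele1": "A",
                "allele2": "B",
            }
        )
    return GenotypeMatrix(df["sample_id"].to_numpy(dtype=object), variants, dosages)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the phenotype TSV (sample_id, height, age, spouse_id, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "spouse_id": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
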
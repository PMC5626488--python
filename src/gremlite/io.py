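"""Readers and writers for the standard formats the pipeline touches.

Supported dialects:

* PLINK binary genotypes (``.bed``/``.bim``/``.fam``), SNP-major mode only.
  Dosages count copies of the A1 allele, so the 2-bit codes map
  ``00`` -> 2 (homozygous A1), ``10`` -> 1 (het), ``11`` -> 0
  (homozygous A2) and ``01`` -> missing.
* GCTA binary GRMs (``.grm.bin``/``.grm.N.bin``/``.grm.id``): 32-bit
  floats over the lower triangle (diagonal included) in row-major order.
* Whitespace-delimited phenotype / covariate / annotation tables keyed by
  family and individual id (per-sample) or SNP id (per-SNP).

All round-trips are bit-exact for bed files and float32-exact for GRMs;
readers never reorder samples or SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit code -> dosage of the A1 allele (-1 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class FormatError(ValueError):
    """A file violates the dialect this package reads/writes."""


@dataclass
class GenotypeMatrix:
    """An n-samples x m-SNPs dosage matrix with sample and SNP metadata.

    ``samples`` has columns ``fid``, ``iid`` and optionally ``sex``,
    ``age``, ``status`` (0 control / 1 case), ``skin_color`` (ordinal
    1-10, NaN = missing).  ``snps`` has columns ``snp``, ``chrom``
    (string label), ``pos`` (1-based), ``a1``, ``a2``.  ``X`` holds
    A1-allele counts in {0,1,2} with -1 for missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    X: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.X.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ids = self.samples["fid"].astype(str) + "_" + self.samples["iid"].astype(str)
        if ids.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.samples["fid"].astype(str) + "_" + self.samples["iid"].astype(str)

    def allele_freq(self) -> np.ndarray:
        """A1 allele frequency per SNP from non-missing calls (NaN if all missing)."""
        obs = self.X >= 0
        counts = obs.sum(axis=0)
        dose = np.where(obs, self.X, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, dose / (2.0 * counts), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, in [0, 0.5]."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return (self.X < 0).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.X >= 0).mean(axis=1)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        si = np.arange(self.n) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.m) if snp_idx is None else np.asarray(snp_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return GenotypeMatrix(
            samples=self.samples.iloc[si].reset_index(drop=True),
            snps=self.snps.iloc[vi].reset_index(drop=True),
            X=self.X[np.ix_(si, vi)].copy(),
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snps["snp"] == snp_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])


@dataclass
class GRMatrix:
    """Symmetric genetic relatedness estimates with per-pair SNP counts.

    ``ids`` are "fid_iid" strings in matrix order; ``A`` the n x n
    relatedness values; ``N`` the per-pair counts of SNPs that were
    non-missing in both members.  ``calibration`` records the LD
    attenuation constant c and regression slope beta once the matrix has
    been adjusted (see :func:`gremlite.grm.adjust_grm`).
    """

    ids: list[str]
    A: np.ndarray
    N: np.ndarray
    n_snps: int
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.N = np.asarray(self.N, dtype=np.float64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids in GRM")
        if self.A.shape != (n, n) or self.N.shape != (n, n):
            raise ValueError("GRM value/count matrices must be n x n")
        if not np.allclose(self.A, self.A.T, atol=1e-6):
            raise ValueError("GRM is not symmetric")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("GRM contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def adjusted(self) -> bool:
        return bool(self.calibration.get("adjusted", False))

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.A[iu]


# ---------------------------------------------------------------------------
# PLINK bed / bim / fam
# ---------------------------------------------------------------------------

_SEX_CODES = {1: 1, 2: 2, 0: 0}


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix.bed/.bim/.fam`` in SNP-major PLINK binary format.

    The fam phenotype column carries case/control status as 2/1 (PLINK
    convention) with -9 for missing.
    """
    prefix = Path(prefix)
    n, m = geno.n, geno.m

    s = geno.samples
    sex = s["sex"].fillna(0).astype(int) if "sex" in s else pd.Series(0, index=s.index)
    if "status" in s:
        pheno = s["status"].map({0: 1, 1: 2}).fillna(-9).astype(int)
    else:
        pheno = pd.Series(-9, index=s.index)
    fam = pd.DataFrame(
        {
            "fid": s["fid"],
            "iid": s["iid"],
            "pat": 0,
            "mat": 0,
            "sex": sex,
            "pheno": pheno,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": geno.snps["chrom"],
            "snp": geno.snps["snp"],
            "cm": 0,
            "pos": geno.snps["pos"],
            "a1": geno.snps["a1"],
            "a2": geno.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    codes = np.empty_like(geno.X, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[geno.X == dosage] = code
    payload = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    payload[:, :n] = codes.T
    # pad slots beyond n are 0b00 per PLINK convention
    shifted = payload.reshape(m, bytes_per_snp, 4) << (2 * np.arange(4, dtype=np.uint8))
    packed = shifted[..., 0] | shifted[..., 1] | shifted[..., 2] | shifted[..., 3]
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix.bed/.bim/.fam``; only SNP-major bed files are supported."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed is not a PLINK bed file (bad magic bytes)")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(
            "sample-major bed files (mode byte 0x00) are an unsupported dialect; "
            "re-encode as SNP-major"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed has {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    codes = (packed[:, :, None] >> (2 * np.arange(4, dtype=np.uint8))) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    X = _CODE_TO_DOSAGE[codes].T.copy()

    status = fam["pheno"].map({1: 0, 2: 1})
    samples = pd.DataFrame(
        {"fid": fam["fid"], "iid": fam["iid"], "sex": fam["sex"], "status": status}
    )
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(samples=samples, snps=snps, X=X)


# ---------------------------------------------------------------------------
# GCTA binary GRM
# ---------------------------------------------------------------------------


def _tri_n(nel: int) -> int:
    """Invert nel = n(n+1)/2; raise if nel is not a triangular number."""
    n = int((np.sqrt(8.0 * nel + 1.0) - 1.0) / 2.0 + 0.5)
    if n * (n + 1) // 2 != nel:
        raise FormatError(f"{nel} float32 values is not a lower-triangle count n(n+1)/2")
    return n


def write_grm_bin(grm: GRMatrix, prefix: str | Path) -> None:
    """Write ``prefix.grm.bin/.grm.N.bin/.grm.id`` (GCTA binary dialect)."""
    prefix = Path(prefix)
    il = np.tril_indices(grm.n)
    grm.A[il].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.N[il].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.ids:
            fid, _, iid = sid.partition("_")
            fh.write(f"{fid}\t{iid or fid}\n")


def read_grm_bin(prefix: str | Path, n_snps: int | None = None) -> GRMatrix:
    """Read a GCTA binary GRM; matrix order follows the id file."""
    prefix = Path(prefix)
    ids_df = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    ids = (ids_df["fid"] + "_" + ids_df["iid"]).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in GRM id file")
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    n_from_file = _tri_n(len(vals))
    if n_from_file != n:
        raise FormatError(
            f"GRM value file implies {n_from_file} samples but id file lists {n}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if len(counts) not in (len(vals), 1):
        raise FormatError("GRM N file length matches neither 1 nor n(n+1)/2")
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    il = np.tril_indices(n)
    A[il] = vals
    N[il] = counts if len(counts) == len(vals) else counts[0]
    A = A + np.tril(A, -1).T
    N = N + np.tril(N, -1).T
    total = int(N.max()) if n_snps is None else n_snps
    return GRMatrix(ids=ids, A=A, N=N, n_snps=total)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

_MISSING_CODES = {"-9", "NA", "na", "NaN", "nan", ""}


@dataclass
class TableSchema:
    """Column contract for a whitespace-delimited input table.

    ``key_cols`` lead the file (``["fid", "iid"]`` for per-sample tables,
    ``["snp"]`` for per-SNP tables); ``value_cols`` maps the remaining
    column names to dtypes; optional per-column ``(lo, hi)`` bounds in
    ``ranges`` are enforced on non-missing values.
    """

    key_cols: list[str]
    value_cols: dict[str, type]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


PHENOTYPE_SCHEMA = TableSchema(["fid", "iid"], {"status": float}, {"status": (0, 1)})
COVARIATE_SCHEMA = TableSchema(
    ["fid", "iid"],
    {"age": float, "sex": float, "skin_color": float},
    {"skin_color": (1, 10)},
)
ANNOTATION_SCHEMA = TableSchema(["snp"], {"genic": float, "eqtl_p": float}, {"eqtl_p": (0, 1)})
SNP_LIST_SCHEMA = TableSchema(["snp"], {})


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a whitespace-delimited table against a schema.

    Missing codes (-9, NA, empty) are normalised to NaN; out-of-range
    values raise with the offending 1-based row number.  Columns listed
    in the schema but absent from the file are loaded as all-missing
    only if the file carries a header naming its columns; headerless
    files must supply every schema column in order.
    """
    path = Path(path)
    ncols = len(schema.key_cols) + len(schema.value_cols)
    names = schema.key_cols + list(schema.value_cols)
    with open(path) as fh:
        first = fh.readline().split()
    has_header = bool(first) and first[0].lower() in {c.lower() for c in names}
    if not has_header and first and len(first) != ncols:
        raise FormatError(
            f"{path}: expected {ncols} columns ({', '.join(names)}), found {len(first)}"
        )
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=0 if has_header else None,
        names=None if has_header else names,
        dtype=str,
        na_values=sorted(_MISSING_CODES),
        keep_default_na=True,
    )
    if has_header:
        df.columns = [c.lower() for c in df.columns]
        missing_keys = [c for c in schema.key_cols if c not in df.columns]
        if missing_keys:
            raise FormatError(f"{path}: missing key column(s) {missing_keys}")
        for col in schema.value_cols:
            if col not in df.columns:
                df[col] = np.nan
        df = df[names]
    elif df.shape[1] != ncols:
        raise FormatError(
            f"{path}: expected {ncols} columns ({', '.join(names)}), found {df.shape[1]}"
        )
    for col, dtype in schema.value_cols.items():
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: column {col!r} is not numeric: {exc}") from exc
        if col in schema.ranges:
            lo, hi = schema.ranges[col]
            bad = df.index[(df[col] < lo) | (df[col] > hi)]
            if len(bad):
                row = int(bad[0]) + 1 + int(has_header)
                raise FormatError(
                    f"{path} row {row}: {col}={df[col].iloc[bad[0]]} outside [{lo}, {hi}]"
                )
    n_missing = int(df[list(schema.value_cols)].isna().sum().sum()) if schema.value_cols else 0
    df.attrs["n_missing_values"] = n_missing
    return df


def match_samples(table: pd.DataFrame, geno: GenotypeMatrix) -> pd.DataFrame:
    """Align a FID/IID-keyed table to genotype sample order.

    Unknown ids are reported in ``attrs['unknown_ids']`` rather than
    silently dropped; samples absent from the table get NaN rows.
    """
    key = table["fid"].astype(str) + "_" + table["iid"].astype(str)
    table = table.set_index(key)
    geno_ids = geno.sample_ids
    unknown = sorted(set(table.index) - set(geno_ids))
    out = table.reindex(geno_ids).reset_index(drop=True)
    out.attrs["unknown_ids"] = unknown
    return out
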
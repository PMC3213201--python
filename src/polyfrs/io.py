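"""Readers and writers for PLINK, GCTA-GRM and tabular formats.

PLINK .bed files are handled in SNP-major layout only (magic bytes
``6c 1b 01``), with the standard 2-bit genotype coding: ``00`` =
homozygous A1, ``10`` = heterozygous, ``11`` = homozygous A2 and ``01``
= missing. Dosages count the A1 allele (the fifth .bim column), so code
``00`` reads as dosage 2.

GRM files follow the GCTA binary triple convention: ``.grm.bin`` holds
the lower triangle (diagonal included, row-major) as little-endian
float32, ``.grm.N.bin`` the per-pair non-missing SNP counts in the same
layout, and ``.grm.id`` a two-column family/sample id text file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage; NaN marks the missing code 01
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_SEX_FROM_FAM = {"1": "male", "2": "female"}
_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}


class PlinkFormatError(ValueError):
    """Malformed PLINK fileset (bad magic, wrong payload length...)."""


# ---------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK ``prefix.bed/.bim/.fam`` fileset into a panel.

    Sample order follows the .fam file, SNP order the .bim file.
    Only SNP-major .bed files are accepted.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["family_id", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele_a1", "allele_a2"],
        dtype={"chromosome": int, "snp_id": str, "position": int,
               "allele_a1": str, "allele_a2": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != BED_MAGIC[:2]:
        raise PlinkFormatError(f"bad .bed magic bytes {raw[:2].hex()}")
    if raw[2:3] != BED_MAGIC[2:3]:
        raise PlinkFormatError(
            "only SNP-major .bed files are supported (third byte must be 0x01)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f".bed payload is {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} SNPs"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack the four 2-bit fields of each byte, low bits = first sample
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T

    samples = pd.DataFrame(
        {
            "family_id": fam["family_id"],
            "sample_id": fam["sample_id"],
            "sex": fam["sex"].map(_SEX_FROM_FAM).fillna("unknown"),
            "batch": "A",
        }
    )
    snps = bim[["snp_id", "chromosome", "position", "allele_a1", "allele_a2"]]
    return GenotypePanel(samples=samples, snps=snps, dosages=dosages)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a SNP-major PLINK ``prefix.bed/.bim/.fam`` fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_samples, panel.n_snps

    fam_rows = [
        f"{r.family_id} {r.sample_id} 0 0 {_SEX_TO_FAM.get(r.sex, '0')} -9"
        for r in panel.samples.itertuples()
    ]
    prefix.with_suffix(".fam").write_text("\n".join(fam_rows) + "\n")

    bim_rows = [
        f"{int(r.chromosome)}\t{r.snp_id}\t0\t{int(r.position)}\t"
        f"{r.allele_a1}\t{r.allele_a2}"
        for r in panel.snps.itertuples()
    ]
    prefix.with_suffix(".bim").write_text("\n".join(bim_rows) + "\n")

    dos = panel.dosages
    codes = np.full(dos.shape, 1, dtype=np.uint8)  # missing
    codes[dos == 2.0] = 0
    codes[dos == 1.0] = 2
    codes[dos == 0.0] = 3

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------
# GCTA GRM binary triple
# ---------------------------------------------------------------------

@dataclass
class GrmFile:
    """Lower-triangular GRM payload as stored on disk.

    ``values`` and ``pair_snp_counts`` are flat arrays of length
    n(n+1)/2 in row-major lower-triangle order; ``ids`` is a DataFrame
    with family_id/sample_id columns in matrix row order.
    """

    ids: pd.DataFrame
    values: np.ndarray
    pair_snp_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        want = n * (n + 1) // 2
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.pair_snp_counts = np.asarray(self.pair_snp_counts, dtype=float).ravel()
        if self.values.size != want:
            raise ValueError(
                f"GRM has {self.values.size} values, expected {want} for n={n}"
            )
        if self.pair_snp_counts.size != want:
            raise ValueError("pair_snp_counts length mismatch")
        if (self.pair_snp_counts < 0).any():
            raise ValueError("pair SNP counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def to_square(self) -> np.ndarray:
        """Full symmetric n x n matrix of relatedness values."""
        n = self.n_samples
        a = np.zeros((n, n))
        i, j = np.tril_indices(n)
        a[i, j] = self.values
        a[j, i] = self.values
        return a

    def counts_to_square(self) -> np.ndarray:
        n = self.n_samples
        c = np.zeros((n, n))
        i, j = np.tril_indices(n)
        c[i, j] = self.pair_snp_counts
        c[j, i] = self.pair_snp_counts
        return c

    @classmethod
    def from_square(
        cls,
        matrix: np.ndarray,
        ids: pd.DataFrame,
        pair_snp_counts: np.ndarray | None = None,
    ) -> "GrmFile":
        matrix = np.asarray(matrix, dtype=float)
        n = matrix.shape[0]
        i, j = np.tril_indices(n)
        counts = (
            np.zeros(n * (n + 1) // 2)
            if pair_snp_counts is None
            else np.asarray(pair_snp_counts, dtype=float)[i, j]
        )
        return cls(ids=ids.reset_index(drop=True), values=matrix[i, j],
                   pair_snp_counts=counts)


def read_grm_bin(prefix: str | Path) -> GrmFile:
    """Read a GCTA binary GRM from ``prefix.grm.bin/.grm.N.bin/.grm.id``."""
    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None,
        names=["family_id", "sample_id"], dtype=str,
    )
    n = len(ids)
    want = n * (n + 1) // 2
    values = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if values.size != want:
        raise ValueError(
            f"{prefix}.grm.bin holds {values.size} floats, expected {want} "
            f"for the {n} ids in .grm.id"
        )
    n_file = Path(f"{prefix}.grm.N.bin")
    if n_file.exists():
        counts = np.fromfile(n_file, dtype="<f4")
        if counts.size != want:
            raise ValueError(f"{prefix}.grm.N.bin length mismatch")
    else:
        counts = np.zeros(want, dtype="<f4")
    return GrmFile(ids=ids, values=values.astype(float),
                   pair_snp_counts=counts.astype(float))


def write_grm_bin(grm: GrmFile, prefix: str | Path) -> None:
    """Write a GRM in GCTA binary triple format."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    grm.values.astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.pair_snp_counts.astype("<f4").tofile(f"{prefix}.grm.N.bin")
    grm.ids.to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------

def read_table(
    path: str | Path,
    required: list[str] | None = None,
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Read a whitespace-delimited table with header row and NA codes.

    Requires a ``sample_id`` column with unique values; ``required``
    lists further mandatory columns and ``numeric`` columns are coerced
    to float (non-coercible values are an error). Unknown columns are
    preserved untouched.
    """
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("table must contain a sample_id column")
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dupes[:5]}")
    for col in numeric or []:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the tab-delimited dialect :func:`read_table` reads."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------
# plain-text dosage dialect (test fixtures)
# ---------------------------------------------------------------------

def read_text_dosage(path: str | Path) -> GenotypePanel:
    """Read the human-readable fixture dialect.

    Header row of SNP ids; one row per sample starting with the sample
    id, followed by 0/1/2/NA dosages. SNP metadata is filled with
    placeholder chromosome 1 positions and A/C alleles.
    """
    lines = Path(path).read_text().strip().splitlines()
    snp_ids = lines[0].split()
    rows, ids = [], []
    for line in lines[1:]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    samples = pd.DataFrame(
        {"family_id": ids, "sample_id": ids, "sex": "unknown", "batch": "A"}
    )
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": 1,
            "position": np.arange(1, len(snp_ids) + 1),
            "allele_a1": "A",
            "allele_a2": "C",
        }
    )
    return GenotypePanel(samples=samples, snps=snps, dosages=np.array(rows))


def write_text_dosage(panel: GenotypePanel, path: str | Path) -> None:
    lines = [" ".join(panel.snp_ids)]
    for i, sid in enumerate(panel.sample_ids):
        vals = [
            "NA" if np.isnan(v) else str(int(v)) for v in panel.dosages[i]
        ]
        lines.append(" ".join([sid] + vals))
    Path(path).write_text("\n".join(lines) + "\n")
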
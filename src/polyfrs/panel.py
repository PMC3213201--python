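"""Core in-memory containers for genotype data.

The central object is :class:`GenotypePanel`: an ``n_samples x n_snps``
dosage matrix (counts of the A1 allele, 0/1/2, NaN for missing) together
with per-sample and per-SNP metadata. Every analysis stage consumes and
produces panels, so the container is deliberately small and strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

SAMPLE_COLUMNS = ["family_id", "sample_id", "sex", "batch"]
SNP_COLUMNS = ["snp_id", "chromosome", "position", "allele_a1", "allele_a2"]


def _as_sample_frame(samples: pd.DataFrame) -> pd.DataFrame:
    df = samples.reset_index(drop=True).copy()
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table lacks columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    if (df["sample_id"].astype(str).str.len() == 0).any():
        raise ValueError("empty sample id")
    return df


def _as_snp_frame(snps: pd.DataFrame) -> pd.DataFrame:
    df = snps.reset_index(drop=True).copy()
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"snp table lacks columns {missing}")
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate snp ids")
    chrom = df["chromosome"].astype(int)
    if ((chrom < 1) | (chrom > 22)).any():
        raise ValueError("autosomes only: chromosome must be in 1..22")
    if (df["allele_a1"] == df["allele_a2"]).any():
        raise ValueError("allele_a1 must differ from allele_a2")
    if (df["position"].astype(int) < 0).any():
        raise ValueError("positions must be non-negative")
    return df


@dataclass
class GenotypePanel:
    """Biallelic autosomal genotypes with sample/SNP metadata.

    Parameters
    ----------
    samples : DataFrame with columns family_id, sample_id, sex, batch.
        ``sex`` uses "male"/"female"/"unknown".
    snps : DataFrame with columns snp_id, chromosome, position,
        allele_a1, allele_a2 (positions 1-based, as in .bim files).
    dosages : float array (n_samples, n_snps)
        Counts of allele A1 per genotype: 0, 1, 2 or NaN for missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _as_sample_frame(self.samples)
        self.snps = _as_snp_frame(self.snps)
        dos = np.asarray(self.dosages, dtype=float)
        if dos.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        if dos.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {dos.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        if dos.shape[0] < 1 or dos.shape[1] < 1:
            raise ValueError("panel must contain at least one sample and one SNP")
        observed = dos[~np.isnan(dos)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        self.dosages = dos

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    # -- per-axis summaries --------------------------------------------
    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per SNP."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Sample frequency of allele A1 per SNP (NaN if fully missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_A1A1, n_A1A2, n_A2A2) at SNP index ``j``."""
        col = self.dosages[:, j]
        return (
            int(np.sum(col == 2.0)),
            int(np.sum(col == 1.0)),
            int(np.sum(col == 0.0)),
        )

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        snp_ids: Iterable[str] | None = None,
    ) -> "GenotypePanel":
        """Restrict to the given samples/SNPs, preserving panel order."""
        samp_mask = np.ones(self.n_samples, dtype=bool)
        snp_mask = np.ones(self.n_snps, dtype=bool)
        if sample_ids is not None:
            keep = set(sample_ids)
            samp_mask = np.array([s in keep for s in self.sample_ids])
        if snp_ids is not None:
            keep = set(snp_ids)
            snp_mask = np.array([s in keep for s in self.snp_ids])
        return GenotypePanel(
            samples=self.samples.loc[samp_mask].reset_index(drop=True),
            snps=self.snps.loc[snp_mask].reset_index(drop=True),
            dosages=self.dosages[np.ix_(samp_mask, snp_mask)],
        )

    def sample_indexer(self, ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given sample ids (in the given order)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id {exc} not in panel") from exc

    def equals(self, other: "GenotypePanel") -> bool:
        if self.dosages.shape != other.dosages.shape:
            return False
        same_dos = np.array_equal(self.dosages, other.dosages, equal_nan=True)
        return (
            same_dos
            and self.samples[SAMPLE_COLUMNS].equals(other.samples[SAMPLE_COLUMNS])
            and self.snps[SNP_COLUMNS].astype(
                {"chromosome": int, "position": int}
            ).equals(
                other.snps[SNP_COLUMNS].astype({"chromosome": int, "position": int})
            )
        )


def standardized_dosages(
    panel: GenotypePanel,
    impute_mean: bool = True,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Center by 2p and scale by sqrt(2p(1-p)) per SNP.

    Missing entries become 0 after centering when ``impute_mean`` (i.e.
    they are replaced by the SNP mean), otherwise NaN is propagated.
    Monomorphic SNPs yield NaN columns; callers must exclude them.
    """
    p = panel.allele_frequency() if freqs is None else np.asarray(freqs, float)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (panel.dosages - 2.0 * p) / scale
    if impute_mean:
        z = np.where(np.isnan(panel.dosages), 0.0, z)
    return z
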
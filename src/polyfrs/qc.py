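"""Genotype quality control: two regimes over markers and samples.

Two named presets mirror common practice for association versus
variance-component analysis. The ``gwas`` regime uses sample/marker
call rate 95%, MAF 0.01 and a Hardy-Weinberg exact-test floor of 1e-4,
with close relatives removed subject-wise at PIHAT > 0.25. The
``heritability`` regime tightens the sample call rate to 99% and the
HWE floor to 0.05, and flags pairs at relatedness > 0.025 (for that
analysis relatives are handled either by dropping subjects or by
dropping pairs; see the heritability module).

Filters run in a fixed, logged order: sample call rate, marker filters
(call rate, MAF, HWE — each marker attributed to the first criterion it
fails), heterozygosity outliers, relatedness, ancestry outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .panel import GenotypePanel


@dataclass(frozen=True)
class QcConfig:
    sample_call_rate_min: float = 0.95
    marker_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-4
    het_sd_limit: float = 3.0
    ibs_sd_limit: float = 3.0
    relatedness_subject_max: float = 0.25
    relatedness_pair_max: float = 0.025
    pihat_min_joint_snps: int = 50
    do_relatedness: bool = True
    do_ancestry: bool = True


PRESETS = {
    "gwas": QcConfig(
        sample_call_rate_min=0.95, maf_min=0.01, hwe_p_min=1e-4,
        relatedness_subject_max=0.25,
    ),
    "heritability": QcConfig(
        sample_call_rate_min=0.99, maf_min=0.01, hwe_p_min=0.05,
        relatedness_subject_max=0.025, relatedness_pair_max=0.025,
    ),
}


@dataclass
class FilterRecord:
    name: str
    threshold: float
    removed: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class QcReport:
    """Ordered log of filters with removals and the surviving panel ids."""

    filters: list[FilterRecord] = field(default_factory=list)
    surviving_samples: list[str] = field(default_factory=list)
    surviving_snps: list[str] = field(default_factory=list)

    def removed_by(self, name: str) -> list[str]:
        for rec in self.filters:
            if rec.name == name:
                return rec.removed
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "filters": [
                {"name": f.name, "threshold": f.threshold,
                 "n_removed": f.n_removed, "removed": list(f.removed)}
                for f in self.filters
            ],
            "n_samples": len(self.surviving_samples),
            "n_snps": len(self.surviving_snps),
        }


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional HWE test (Levene-Haldane distribution).

    Given genotype counts (hom-A1, het, hom-A2), sums the probabilities
    of all heterozygote counts — conditional on the allele counts —
    whose probability does not exceed that of the observed count.
    Monomorphic markers return 1.0 (a single attainable configuration).
    """
    counts = (n_aa_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa_hom1 + n_het  # A1 allele count
    n_b = 2 * n_hom2 + n_het

    # attainable het counts share the parity of the minor allele count
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)

    def logprob(h: np.ndarray) -> np.ndarray:
        hom1 = (n_a - h) // 2
        hom2 = (n_b - h) // 2
        return (
            gammaln(n + 1)
            - gammaln(hom1 + 1) - gammaln(h + 1) - gammaln(hom2 + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )

    logp = logprob(hets)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    return np.array(
        [hwe_exact_test(*panel.genotype_counts(j)) for j in range(panel.n_snps)]
    )


# ---------------------------------------------------------------------
# marker and sample filters
# ---------------------------------------------------------------------

def marker_filters(panel: GenotypePanel, config: QcConfig) -> list[FilterRecord]:
    """Remove markers failing call rate, MAF or HWE (strict less-than).

    Each removed marker is attributed to the first criterion it fails in
    that order; call rate and frequencies are computed over the panel's
    current samples.
    """
    call = panel.marker_call_rate()
    maf = panel.minor_allele_frequency()
    snp_ids = panel.snp_ids

    fail_call = call < config.marker_call_rate_min
    with np.errstate(invalid="ignore"):
        fail_maf = ~fail_call & (np.nan_to_num(maf) < config.maf_min)
    hwe_candidates = ~(fail_call | fail_maf)
    fail_hwe = np.zeros(panel.n_snps, dtype=bool)
    for j in np.nonzero(hwe_candidates)[0]:
        if hwe_exact_test(*panel.genotype_counts(j)) < config.hwe_p_min:
            fail_hwe[j] = True
    return [
        FilterRecord("marker_call_rate", config.marker_call_rate_min,
                     list(snp_ids[fail_call])),
        FilterRecord("marker_maf", config.maf_min, list(snp_ids[fail_maf])),
        FilterRecord("marker_hwe", config.hwe_p_min, list(snp_ids[fail_hwe])),
    ]


def sample_call_rate_filter(
    panel: GenotypePanel, config: QcConfig
) -> FilterRecord:
    ids = panel.sample_ids
    fail = panel.sample_call_rate() < config.sample_call_rate_min
    return FilterRecord("sample_call_rate", config.sample_call_rate_min,
                        list(ids[fail]))


def heterozygosity_filter(
    panel: GenotypePanel, config: QcConfig
) -> FilterRecord:
    """Flag heterozygosity outliers among the panel's samples.

    The statistic is the fraction of a sample's non-missing genotypes
    that are heterozygous; outliers lie more than ``het_sd_limit``
    standard deviations from the sample mean (two-sided). With fewer
    than 3 samples, or a zero standard deviation, nothing is flagged.
    """
    ids = panel.sample_ids
    nonmiss = ~np.isnan(panel.dosages)
    n_obs = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(
            n_obs > 0, (panel.dosages == 1.0).sum(axis=1) / n_obs, np.nan
        )
    removed: list[str] = []
    if len(ids) < 3:
        warnings.warn("fewer than 3 samples: heterozygosity filter skipped")
    else:
        sd = np.nanstd(het)
        if sd > 0:
            z = (het - np.nanmean(het)) / sd
            removed = list(ids[np.abs(z) > config.het_sd_limit])
    return FilterRecord("sample_heterozygosity", config.het_sd_limit, removed)


def sample_filters(panel: GenotypePanel, config: QcConfig) -> list[FilterRecord]:
    """Remove low-call-rate samples, then heterozygosity outliers.

    Heterozygosity z-scores are computed against the
    post-call-rate-filter sample.
    """
    call_rec = sample_call_rate_filter(panel, config)
    keep = [s for s in panel.sample_ids if s not in set(call_rec.removed)]
    sub = panel.subset(sample_ids=keep) if call_rec.removed else panel
    return [call_rec, heterozygosity_filter(sub, config)]


# ---------------------------------------------------------------------
# relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------

def estimate_pihat(
    panel: GenotypePanel, pair: tuple[int, int], freqs: np.ndarray | None = None,
    min_joint_snps: int = 50,
) -> float:
    """Method-of-moments PIHAT (Z1/2 + Z2) for one sample pair.

    Per-locus IBS states are counted over jointly non-missing SNPs and
    compared with their expectations under IBD 0/1/2 given the sample
    allele frequencies; the solved (Z0, Z1, Z2) are clamped to the
    probability simplex. Returns NaN (with a warning) when fewer than
    ``min_joint_snps`` SNPs are jointly observed.
    """
    i, k = pair
    xi, xk = panel.dosages[i], panel.dosages[k]
    joint = ~np.isnan(xi) & ~np.isnan(xk)
    p = (panel.allele_frequency() if freqs is None else freqs)[joint]
    ok = ~np.isnan(p) & (p > 0) & (p < 1)
    if ok.sum() < min_joint_snps:
        warnings.warn(f"pair {pair}: only {int(ok.sum())} joint SNPs, skipped")
        return float("nan")
    xi, xk, p = xi[joint][ok], xk[joint][ok], p[ok]
    q = 1.0 - p

    diff = np.abs(xi - xk)
    n_ibs0 = float(np.sum(diff == 2.0))
    n_ibs1 = float(np.sum(diff == 1.0))
    n_ibs2 = float(np.sum(diff == 0.0))
    m = len(p)

    # expected per-state counts given IBD state
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = m - e0_ibd0 - e1_ibd0
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = m - e1_ibd1

    z0 = n_ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    z1 = (n_ibs1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = (n_ibs2 - z0 * e2_ibd0 - z1 * e2_ibd1) / m
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total > 0:
        z = z / total
    return float(z[1] / 2.0 + z[2])


def pihat_matrix(panel: GenotypePanel, min_joint_snps: int = 50) -> np.ndarray:
    """Symmetric PIHAT matrix over all sample pairs (diagonal = 1)."""
    n = panel.n_samples
    freqs = panel.allele_frequency()
    out = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            out[i, k] = out[k, i] = estimate_pihat(
                panel, (i, k), freqs=freqs, min_joint_snps=min_joint_snps
            )
    return out


def prune_relatives_subjectwise(
    relatedness: np.ndarray, ids: list[str], threshold: float
) -> set[str]:
    """Greedy subject removal until no pair exceeds the threshold.

    Repeatedly drops the individual participating in the most
    over-threshold pairs (ties broken by lexicographically smallest
    id), so a hub related to several others goes before its partners.
    """
    rel = np.asarray(relatedness, dtype=float).copy()
    np.fill_diagonal(rel, 0.0)
    rel = np.nan_to_num(rel)
    active = np.ones(len(ids), dtype=bool)
    removed: set[str] = set()
    ids_arr = np.asarray(ids)
    while True:
        over = (rel > threshold) & active[:, None] & active[None, :]
        degree = over.sum(axis=1)
        if degree.max(initial=0) == 0:
            return removed
        top = degree.max()
        candidates = np.nonzero((degree == top) & active)[0]
        victim = candidates[np.argsort(ids_arr[candidates])[0]]
        active[victim] = False
        removed.add(str(ids_arr[victim]))


# ---------------------------------------------------------------------
# ancestry outliers (IBS distance)
# ---------------------------------------------------------------------

def ibs_distance_matrix(panel: GenotypePanel) -> np.ndarray:
    """Mean per-locus IBS distance |x_i - x_j| / 2 over joint SNPs."""
    n = panel.n_samples
    dos = panel.dosages
    nonmiss = ~np.isnan(dos)
    filled = np.nan_to_num(dos)
    out = np.zeros((n, n))
    for i in range(n):
        joint = nonmiss[i] & nonmiss
        diff = np.abs(filled[i] - filled) * joint
        with np.errstate(invalid="ignore"):
            out[i] = diff.sum(axis=1) / (2.0 * joint.sum(axis=1))
    np.fill_diagonal(out, 0.0)
    return out


def ibs_ancestry_outliers(
    panel: GenotypePanel, sd_limit: float = 3.0
) -> set[str]:
    """Samples unusually IBS-distant from the rest of the cohort.

    The per-sample statistic is the mean IBS distance to all other
    samples; only the one-sided upper tail (z above the limit) is
    flagged, since ancestry outliers are farther — never closer — than
    typical. Requires n >= 3.
    """
    if panel.n_samples < 3:
        raise ValueError("ancestry outlier detection needs at least 3 samples")
    dist = ibs_distance_matrix(panel)
    n = panel.n_samples
    mean_dist = dist.sum(axis=1) / (n - 1)
    sd = mean_dist.std()
    if sd == 0:
        return set()
    z = (mean_dist - mean_dist.mean()) / sd
    return set(panel.sample_ids[z > sd_limit])


# ---------------------------------------------------------------------
# full pipeline as a transformer
# ---------------------------------------------------------------------

class GenotypeQC:
    """Quality-control transformer over genotype panels.

    Parameters
    ----------
    preset : "gwas" | "heritability" | None
        Named threshold set; ``config`` overrides it when given.
    config : QcConfig, optional
        Explicit thresholds.

    After :meth:`fit`, ``report_`` holds the ordered filter log and
    :meth:`transform` subsets any panel to the surviving ids. Running
    the pipeline on its own output is a fixed point: no further
    removals occur.
    """

    def __init__(self, preset: str | None = "gwas",
                 config: QcConfig | None = None):
        self.preset = preset
        self.config = config

    def _resolved_config(self) -> QcConfig:
        if self.config is not None:
            return self.config
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return PRESETS[self.preset]

    def get_params(self, deep: bool = True) -> dict:
        return {"preset": self.preset, "config": self.config}

    def set_params(self, **params) -> "GenotypeQC":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, panel: GenotypePanel) -> "GenotypeQC":
        cfg = self._resolved_config()
        report = QcReport()
        current = panel

        rec = sample_call_rate_filter(current, cfg)
        report.filters.append(rec)
        if rec.removed:
            keep = [s for s in current.sample_ids if s not in set(rec.removed)]
            current = current.subset(sample_ids=keep)

        recs = marker_filters(current, cfg)
        report.filters.extend(recs)
        drop_snps = {s for r in recs for s in r.removed}
        if drop_snps:
            keep = [s for s in current.snp_ids if s not in drop_snps]
            current = current.subset(snp_ids=keep)

        rec = heterozygosity_filter(current, cfg)
        report.filters.append(rec)
        if rec.removed:
            keep = [s for s in current.sample_ids if s not in set(rec.removed)]
            current = current.subset(sample_ids=keep)

        if cfg.do_relatedness and current.n_samples >= 2:
            rel = pihat_matrix(
                current, min_joint_snps=cfg.pihat_min_joint_snps
            )
            removed = prune_relatives_subjectwise(
                rel, list(current.sample_ids), cfg.relatedness_subject_max
            )
            report.filters.append(
                FilterRecord("relatedness", cfg.relatedness_subject_max,
                             sorted(removed))
            )
            if removed:
                keep = [s for s in current.sample_ids if s not in removed]
                current = current.subset(sample_ids=keep)

        if cfg.do_ancestry and current.n_samples >= 3:
            outliers = ibs_ancestry_outliers(current, cfg.ibs_sd_limit)
            report.filters.append(
                FilterRecord("ancestry_ibs", cfg.ibs_sd_limit, sorted(outliers))
            )
            if outliers:
                keep = [s for s in current.sample_ids if s not in outliers]
                current = current.subset(sample_ids=keep)

        report.surviving_samples = list(current.sample_ids)
        report.surviving_snps = list(current.snp_ids)
        self.report_ = report
        return self

    def transform(self, panel: GenotypePanel) -> GenotypePanel:
        if not hasattr(self, "report_"):
            raise RuntimeError("GenotypeQC must be fitted before transform")
        return panel.subset(
            sample_ids=self.report_.surviving_samples,
            snp_ids=self.report_.surviving_snps,
        )

    def fit_transform(self, panel: GenotypePanel) -> GenotypePanel:
        return self.fit(panel).transform(panel)


def apply_qc(panel: GenotypePanel, preset: str = "gwas",
             config: QcConfig | None = None) -> tuple[GenotypePanel, QcReport]:
    """One-shot QC: returns the filtered panel and its report."""
    qc = GenotypeQC(preset=preset, config=config).fit(panel)
    return qc.transform(panel), qc.report_
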
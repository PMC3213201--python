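"""Synthetic genotype, phenotype and covariate generation.

The generator emulates the statistical structure the downstream analyses
assume: biallelic autosomal SNPs in Hardy-Weinberg equilibrium with a
configurable minor-allele-frequency spectrum, an additive polygenic
trait with known heritability, optional close relatives (duplicate and
full-sib pairs), two-population stratification under the
Balding-Nichols model, batch-structured missingness, and a clinical
covariate panel (age, sex, lipids, blood pressure, treatment, smoking,
diabetes) sufficient to drive the risk-score engine. Ground truth —
causal SNPs, per-allele effects, realized heritability, subpopulation
and relative-pair labels — is returned alongside the data so parameter
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, standardized_dosages


@dataclass
class SimConfig:
    """Knobs of the genotype simulator; defaults give a panmictic,
    fully-typed, unrelated cohort."""

    n_samples: int = 500
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_true: float = 0.5
    n_causal: int | None = None  # defaults to min(100, n_snps)
    fst: float = 0.0
    n_duplicate_pairs: int = 0
    n_sib_pairs: int = 0
    missing_rate: float = 0.0
    batch_missing_boost: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")
        if self.n_causal is None:
            self.n_causal = min(100, self.n_snps)
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.fst < 0 or self.batch_missing_boost < 0:
            raise ValueError("fst and batch_missing_boost must be >= 0")
        n_rel = 2 * (self.n_duplicate_pairs + self.n_sib_pairs)
        if n_rel > self.n_samples:
            raise ValueError("more relative-pair members than samples")


@dataclass
class SimTruth:
    """Ground truth recorded by the simulator."""

    causal_ids: set[str] = field(default_factory=set)
    effects: dict[str, float] = field(default_factory=dict)
    h2_realized: float = float("nan")
    subpop: dict[str, int] = field(default_factory=dict)
    relative_pairs: list[tuple[str, str, str]] = field(default_factory=list)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a genotype panel under HWE with optional structure.

    Per SNP an ancestral frequency is drawn uniformly on ``maf_range``;
    with ``fst > 0`` each of two equal-sized subpopulations receives its
    own frequency from the Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F)
    distribution. Genotypes are Binomial(2, p) per locus. Duplicate
    pairs copy genotypes wholesale; sib pairs share each of their two
    alleles with probability 1/2 per locus independently (expected
    relatedness 1/2, no linkage). Missingness is Bernoulli per entry,
    with the rate boosted additively for batch "B" samples.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    truth = SimTruth()

    p_anc = rng.uniform(*config.maf_range, size=m)
    subpop = np.ones(n, dtype=int)
    if config.fst > 0:
        subpop[n // 2:] = 2
        f = config.fst
        p_sub = np.stack(
            [
                rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
                for _ in range(2)
            ]
        )
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
        per_sample_p = p_sub[subpop - 1]  # (n, m)
    else:
        per_sample_p = np.broadcast_to(p_anc, (n, m))

    # sample two allele draws explicitly so sib sharing can reuse them
    alleles = rng.random((2, n, m)) < per_sample_p[None]
    dosages = alleles.sum(axis=0).astype(float)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    truth.subpop = {sid: int(sp) for sid, sp in zip(sample_ids, subpop)}

    # plant relatives at the front of the sample list: (0,1), (2,3), ...
    cursor = 0
    for _ in range(config.n_duplicate_pairs):
        a, b = cursor, cursor + 1
        dosages[b] = dosages[a]
        truth.relative_pairs.append((sample_ids[a], sample_ids[b], "duplicate"))
        cursor += 2
    for _ in range(config.n_sib_pairs):
        a, b = cursor, cursor + 1
        share = rng.random((2, m)) < 0.5
        sib = np.where(share, alleles[:, a, :], alleles[:, b, :])
        dosages[b] = sib.sum(axis=0).astype(float)
        truth.relative_pairs.append((sample_ids[a], sample_ids[b], "sib"))
        cursor += 2

    batch = np.where(rng.random(n) < 0.5, "A", "B")
    if config.missing_rate > 0 or config.batch_missing_boost > 0:
        rate = np.full(n, config.missing_rate)
        rate[batch == "B"] = np.minimum(
            rate[batch == "B"] + config.batch_missing_boost, 0.99
        )
        miss = rng.random((n, m)) < rate[:, None]
        dosages[miss] = np.nan

    samples = pd.DataFrame(
        {
            "family_id": sample_ids,
            "sample_id": sample_ids,
            "sex": rng.permuted(
                np.where(np.arange(n) % 2 == 0, "male", "female")
            ),
            "batch": batch,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j:06d}" for j in range(m)],
            "chromosome": (np.arange(m) % 22) + 1,
            "position": np.arange(m) // 22 * 1000 + 1,
            "allele_a1": "A",
            "allele_a2": "C",
        }
    )
    panel = GenotypePanel(samples=samples, snps=snps, dosages=dosages)
    return panel, truth


def simulate_phenotype(
    panel: GenotypePanel,
    truth: SimTruth | None = None,
    h2_true: float = 0.5,
    n_causal: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """Additive polygenic trait on standardized genotypes.

    Causal SNPs are sampled uniformly; effects beta_j ~ N(0, h2/n_causal)
    apply to the standardized dosage, so each causal SNP contributes
    h2/n_causal of variance regardless of allele frequency. Residuals
    are N(0, 1 - h2). Records the realized heritability
    Var(g)/Var(y) in the returned truth object.
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError("h2_true must lie in [0, 1]")
    if n_causal > panel.n_snps:
        raise ValueError("n_causal cannot exceed the panel SNP count")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SimTruth()

    z = standardized_dosages(panel)
    z = np.nan_to_num(z)  # monomorphic columns contribute nothing
    causal_idx = rng.choice(panel.n_snps, size=n_causal, replace=False)
    betas = (
        rng.normal(0.0, np.sqrt(h2_true / n_causal), size=n_causal)
        if h2_true > 0
        else np.zeros(n_causal)
    )
    g = z[:, causal_idx] @ betas
    e = rng.normal(0.0, np.sqrt(1.0 - h2_true), size=panel.n_samples)
    y = g + e

    snp_ids = panel.snp_ids
    truth.causal_ids = {snp_ids[j] for j in causal_idx}
    truth.effects = {snp_ids[j]: float(b) for j, b in zip(causal_idx, betas)}
    var_y = np.var(y)
    truth.h2_realized = float(np.var(g) / var_y) if var_y > 0 else 0.0
    return y, truth


def simulate_covariates(
    n: int,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    genetic_values: np.ndarray | None = None,
    genetic_share: float = 0.0,
) -> pd.DataFrame:
    """Clinical covariate panel for the risk-score engine.

    Distributions are chosen to resemble a middle-aged epidemiological
    cohort: age Uniform(30, 74); total cholesterol N(200, 35) mg/dL
    truncated above 100; HDL N(50, 13) truncated above 20; SBP
    N(125, 17) mmHg truncated above 90; 20% treated for hypertension,
    20% smokers, 8% diabetic; sexes balanced. All continuous values are
    strictly positive so log transforms are safe.

    By default the covariates carry no genetic signal. Passing per-sample
    ``genetic_values`` with ``genetic_share`` in (0, 1] mixes a scaled
    copy of them into total cholesterol, HDL (negatively) and SBP, making
    the derived risk score itself heritable.
    """
    rng = np.random.default_rng(seed)

    def truncated_normal(mean: float, sd: float, lower: float) -> np.ndarray:
        out = rng.normal(mean, sd, size=n)
        while (bad := out <= lower).any():
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return out

    sex = np.where(np.arange(n) % 2 == 0, "male", "female")
    df = pd.DataFrame(
        {
            "sample_id": sample_ids
            if sample_ids is not None
            else [f"S{i:05d}" for i in range(n)],
            "sex": rng.permuted(sex),
            "age": rng.uniform(30.0, 74.0, size=n),
            "total_chol": truncated_normal(200.0, 35.0, 100.0),
            "hdl": truncated_normal(50.0, 13.0, 20.0),
            "sbp": truncated_normal(125.0, 17.0, 90.0),
            "bp_treated": (rng.random(n) < 0.2).astype(int),
            "smoker": (rng.random(n) < 0.2).astype(int),
            "diabetic": (rng.random(n) < 0.08).astype(int),
        }
    )
    if genetic_values is not None and genetic_share > 0:
        g = np.asarray(genetic_values, dtype=float)
        g = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
        w = np.sqrt(genetic_share)
        for col, sd, sign in (("total_chol", 35.0, 1), ("hdl", 13.0, -1),
                              ("sbp", 17.0, 1)):
            df[col] = df[col] + sign * w * sd * g
            df[col] = df[col].clip(lower={"total_chol": 101, "hdl": 21,
                                          "sbp": 91}[col])
    return df


def planted_qc_panel() -> tuple[GenotypePanel, dict[str, dict]]:
    """Deterministic 20-sample x 30-SNP panel with planted QC violations.

    The 27 clean markers are cyclic shifts of one Hardy-Weinberg-modal
    genotype column (5 hom / 10 het / 5 hom), which keeps every clean
    sample's heterozygosity nearly constant. Planted faults:

    * sample ``Q17``: 60% call rate (fails 95% and 99% thresholds);
    * sample ``Q18``: zero heterozygosity (outlier below -3 SD);
    * samples ``Q15``/``Q16``: exact duplicates;
    * marker ``M_lowcall``: two missing entries (samples Q00/Q01);
    * marker ``M_lowmaf``: monomorphic;
    * marker ``M_hwe``: total heterozygote deficit (tiny exact-test p).

    The expected per-filter removals depend on the regime: at a 99%
    sample call-rate threshold a 30-marker sample fails with a single
    missing genotype, so under the stricter preset Q00/Q01 (the
    carriers of M_lowcall's missing entries) fall to the sample filter
    and M_lowcall itself becomes complete. Returns the panel and a map
    ``{preset: {filter: planted removals}}``.
    """
    n, m_clean = 20, 27
    base = np.array([2.0] * 5 + [1.0] * 10 + [0.0] * 5)
    # one full cycle of shifts (every sample het at exactly 10 of 20)
    # plus seven evenly spaced extras, keeping heterozygosity near-constant
    shifts = list(range(20)) + [0, 3, 6, 9, 12, 15, 18]
    dos = np.column_stack([np.roll(base, j) for j in shifts])
    # Q18: heterozygotes recoded to alternating homozygotes
    dos[18] = np.where(
        dos[18] == 1.0,
        np.where(np.arange(m_clean) % 2 == 0, 0.0, 2.0),
        dos[18],
    )
    dos[16] = dos[15]  # duplicate pair Q15/Q16
    dos[17, 0:12] = np.nan  # Q17 call rate 18/30

    m_lowcall = np.roll(base, 3).astype(float).copy()
    m_lowcall[18] = 2.0 if m_lowcall[18] == 1.0 else m_lowcall[18]
    m_lowcall[16] = m_lowcall[15]
    m_lowcall[[0, 1]] = np.nan  # call rate 17/19 once Q17 is dropped
    m_lowmaf = np.zeros(n)
    m_hwe = np.array([2.0] * 10 + [0.0] * 10)

    full = np.column_stack([dos, m_lowcall, m_lowmaf, m_hwe])
    sample_ids = [f"Q{i:02d}" for i in range(n)]
    snp_ids = [f"C{j:02d}" for j in range(m_clean)] + [
        "M_lowcall", "M_lowmaf", "M_hwe",
    ]
    samples = pd.DataFrame(
        {"family_id": sample_ids, "sample_id": sample_ids,
         "sex": "unknown", "batch": "A"}
    )
    snps = pd.DataFrame(
        {"snp_id": snp_ids, "chromosome": 1,
         "position": np.arange(1, len(snp_ids) + 1),
         "allele_a1": "A", "allele_a2": "C"}
    )
    planted = {
        "gwas": {
            "sample_call_rate": ["Q17"],
            "marker_call_rate": ["M_lowcall"],
            "marker_maf": ["M_lowmaf"],
            "marker_hwe": ["M_hwe"],
            "sample_heterozygosity": ["Q18"],
            "duplicate_pair": ["Q15", "Q16"],
        },
        "heritability": {
            "sample_call_rate": ["Q00", "Q01", "Q17"],
            "marker_call_rate": [],
            "marker_maf": ["M_lowmaf"],
            "marker_hwe": ["M_hwe"],
            "sample_heterozygosity": ["Q18"],
            "duplicate_pair": ["Q15", "Q16"],
        },
    }
    return GenotypePanel(samples=samples, snps=snps, dosages=full), planted


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypePanel, np.ndarray, SimTruth]:
    """Genotypes plus phenotype in one call (shared seed bookkeeping)."""
    panel, truth = simulate_genotypes(config)
    y, truth = simulate_phenotype(
        panel,
        truth,
        h2_true=config.h2_true,
        n_causal=config.n_causal,
        seed=config.seed + 1,
    )
    return panel, y, truth
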
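"""Single-SNP association testing under an additive linear model.

Each SNP is tested by ordinary least squares of the phenotype on its
A1-allele dosage plus covariates (conventionally age, sex, genotyping
batch dummies and the leading principal components of the standardized
genotype matrix, which absorb population stratification). Genotype
missingness is handled by per-SNP casewise deletion; mean imputation is
used only inside the PCA. P-values come from the two-sided t
distribution with ``n_used - (#covariates + 2)`` degrees of freedom; an
optional max-T permutation mode provides empirical p-values instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, standardized_dosages

LAMBDA_NULL_MEDIAN = 0.45494  # median of the 1-df chi-square


@dataclass
class PcSet:
    """Per-sample principal-component coordinates."""

    scores: np.ndarray  # (n_samples, K)
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


class GenotypePCA:
    """PCA of the mean-imputed, frequency-standardized genotype matrix.

    Genotypes are centered by twice the allele frequency and scaled by
    sqrt(2p(1-p)); missing entries are mean-imputed (zero after
    centering). Scores are the top-K left singular vectors scaled by
    their singular values, with the sign fixed so each component's
    largest-magnitude coordinate is positive. Constant SNPs are
    excluded with a warning.
    """

    def __init__(self, n_components: int = 20):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "GenotypePCA":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, panel: GenotypePanel) -> "GenotypePCA":
        k = self.n_components
        if k < 0 or k >= min(panel.n_samples, panel.n_snps):
            if k != 0:
                raise ValueError(
                    f"n_components={k} must satisfy 0 <= K < min(n, m)"
                )
        if k == 0:
            self.scores_ = np.empty((panel.n_samples, 0))
            self.eigenvalues_ = np.empty(0)
            return self
        z = standardized_dosages(panel, impute_mean=True)
        constant = np.isnan(z).any(axis=0)
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant SNPs excluded from PCA"
            )
            z = z[:, ~constant]
        z = z - z.mean(axis=0)  # exact column centering after imputation
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        u, s = u[:, :k], s[:k]
        # deterministic sign: largest-magnitude coordinate positive
        flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.scores_ = u * flip * s
        self.eigenvalues_ = s**2 / (panel.n_samples - 1)
        return self

    def transform(self, panel: GenotypePanel) -> np.ndarray:
        return self.scores_

    def fit_transform(self, panel: GenotypePanel) -> np.ndarray:
        return self.fit(panel).scores_

    def to_pcset(self) -> PcSet:
        return PcSet(scores=self.scores_, eigenvalues=self.eigenvalues_)


def compute_pcs(panel: GenotypePanel, n_components: int = 20) -> PcSet:
    """Top principal components of the standardized genotype matrix."""
    return GenotypePCA(n_components=n_components).fit(panel).to_pcset()


# ---------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------

def make_gwas_covariates(
    panel: GenotypePanel,
    covar_table: pd.DataFrame | None = None,
    covar_columns: tuple[str, ...] = ("age",),
    pcs: np.ndarray | None = None,
    include_sex: bool = True,
    include_batch: bool = True,
) -> pd.DataFrame:
    """Numeric covariate design aligned to panel sample order.

    Assembles the conventional adjustment set: numeric columns from the
    covariate table, a male indicator, genotyping-batch one-hot dummies
    with the first level dropped, and PC scores.
    """
    parts: list[pd.DataFrame] = []
    if covar_table is not None:
        tbl = covar_table.set_index("sample_id").loc[panel.sample_ids]
        keep = [c for c in covar_columns if c in tbl.columns]
        parts.append(tbl[keep].reset_index(drop=True).astype(float))
    if include_sex:
        parts.append(
            pd.DataFrame(
                {"sex_male": (panel.samples["sex"] == "male").astype(float)}
            )
        )
    if include_batch:
        dummies = pd.get_dummies(
            panel.samples["batch"], prefix="batch", drop_first=True, dtype=float
        )
        if dummies.shape[1]:
            parts.append(dummies.reset_index(drop=True))
    if pcs is not None and pcs.shape[1]:
        parts.append(
            pd.DataFrame(
                pcs, columns=[f"pc{i + 1}" for i in range(pcs.shape[1])]
            )
        )
    if not parts:
        return pd.DataFrame(index=range(panel.n_samples))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------
# association
# ---------------------------------------------------------------------

class LinearGWAS:
    """Per-SNP additive OLS association scan.

    Parameters
    ----------
    n_pcs : int
        Principal components computed from the panel and appended to
        the covariates (0 disables).
    permutations : int
        When positive, max-T permutation p-values are computed in
        addition to the asymptotic ones (column ``p_perm``).
    seed : int
        Seed for the permutation mode.

    After :meth:`fit`, ``results_`` is a DataFrame with one row per SNP:
    snp_id, chromosome, position, a1, beta, se, t_stat, p, n_used.
    SNPs whose dosage is constant in the analysed samples are reported
    with NaN statistics and flagged in ``skipped_``.
    """

    def __init__(self, n_pcs: int = 0, permutations: int = 0, seed: int = 0):
        self.n_pcs = n_pcs
        self.permutations = permutations
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_pcs": self.n_pcs, "permutations": self.permutations,
                "seed": self.seed}

    def set_params(self, **params) -> "LinearGWAS":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        panel: GenotypePanel,
        y: np.ndarray,
        covariates: pd.DataFrame | np.ndarray | None = None,
    ) -> "LinearGWAS":
        y = np.asarray(y, dtype=float)
        if y.shape[0] != panel.n_samples:
            raise ValueError("phenotype length does not match panel")
        if np.isnan(y).any():
            raise ValueError(
                "phenotype must be complete; drop samples with missing values"
            )
        cov = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if np.isnan(cov).any():
                raise ValueError("covariates must be complete")
        if self.n_pcs > 0:
            pcs = compute_pcs(panel, self.n_pcs).scores
            cov = pcs if cov is None else np.column_stack([cov, pcs])

        n = panel.n_samples
        design = (
            np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
        )
        n_cov = design.shape[1] - 1  # covariates excluding intercept

        dos = panel.dosages
        beta = np.full(panel.n_snps, np.nan)
        se = np.full(panel.n_snps, np.nan)
        tstat = np.full(panel.n_snps, np.nan)
        pval = np.full(panel.n_snps, np.nan)
        n_used = np.zeros(panel.n_snps, dtype=int)
        skipped = np.zeros(panel.n_snps, dtype=bool)

        has_missing = np.isnan(dos).any(axis=0)
        complete = np.nonzero(~has_missing)[0]

        # Frisch-Waugh fast path for SNPs observed in every sample
        q, _ = np.linalg.qr(design)
        resid_y = y - q @ (q.T @ y)
        if complete.size:
            g = dos[:, complete]
            resid_g = g - q @ (q.T @ g)
            gg = np.einsum("ij,ij->j", resid_g, resid_g)
            ok = gg > 1e-12
            gy = resid_g.T @ resid_y
            df = n - n_cov - 2
            with np.errstate(invalid="ignore", divide="ignore"):
                b = np.where(ok, gy / gg, np.nan)
                rss = resid_y @ resid_y - b**2 * gg
                s = np.sqrt(np.maximum(rss, 0.0) / df / gg)
                t = b / s
            idx = complete
            beta[idx], se[idx], tstat[idx] = b, s, t
            pval[idx] = 2.0 * stats.t.sf(np.abs(t), df)
            n_used[idx] = n
            skipped[idx[~ok]] = True
            beta[idx[~ok]] = np.nan

        # casewise deletion path for SNPs with missing genotypes
        for j in np.nonzero(has_missing)[0]:
            g = dos[:, j]
            mask = ~np.isnan(g)
            nj = int(mask.sum())
            n_used[j] = nj
            dfj = nj - n_cov - 2
            if dfj < 1 or np.nanstd(g[mask]) == 0:
                skipped[j] = True
                continue
            x = np.column_stack([design[mask], g[mask]])
            xtx = x.T @ x
            try:
                xtx_inv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                skipped[j] = True
                continue
            coef = xtx_inv @ (x.T @ y[mask])
            resid = y[mask] - x @ coef
            sigma2 = resid @ resid / dfj
            beta[j] = coef[-1]
            se[j] = np.sqrt(sigma2 * xtx_inv[-1, -1])
            tstat[j] = beta[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), dfj)

        self.results_ = pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "chromosome": panel.snps["chromosome"].to_numpy(),
                "position": panel.snps["position"].to_numpy(),
                "a1": panel.snps["allele_a1"].to_numpy(),
                "beta": beta,
                "se": se,
                "t_stat": tstat,
                "p": pval,
                "n_used": n_used,
            }
        )
        self.skipped_ = panel.snp_ids[skipped]

        if self.permutations > 0:
            self.results_["p_perm"] = self._max_t_permutation(
                panel, y, design, tstat
            )
        return self

    def _max_t_permutation(
        self, panel: GenotypePanel, y: np.ndarray, design: np.ndarray,
        tstat: np.ndarray,
    ) -> np.ndarray:
        """Family-wise empirical p by permuting covariate-residualized y."""
        rng = np.random.default_rng(self.seed)
        q, _ = np.linalg.qr(design)
        resid_y = y - q @ (q.T @ y)
        n = len(y)
        n_cov = design.shape[1] - 1
        dos = np.where(np.isnan(panel.dosages), np.nan, panel.dosages)
        g = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
        resid_g = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", resid_g, resid_g)
        ok = gg > 1e-12
        df = n - n_cov - 2

        max_t = np.empty(self.permutations)
        for r in range(self.permutations):
            perm = rng.permutation(resid_y)
            gy = resid_g.T @ perm
            with np.errstate(invalid="ignore", divide="ignore"):
                b = gy / gg
                rss = perm @ perm - b**2 * gg
                t = b / np.sqrt(np.maximum(rss, 1e-300) / df / gg)
            max_t[r] = np.nanmax(np.abs(t[ok]))
        obs = np.abs(tstat)
        return np.array(
            [
                (1.0 + np.sum(max_t >= o)) / (self.permutations + 1.0)
                if np.isfinite(o)
                else np.nan
                for o in obs
            ]
        )


def run_gwas(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_pcs: int = 0,
) -> pd.DataFrame:
    """Per-SNP additive association scan; see :class:`LinearGWAS`."""
    return LinearGWAS(n_pcs=n_pcs).fit(panel, phenotype, covariates).results_


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over 0.45494."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / LAMBDA_NULL_MEDIAN)


def significant_hits(
    results: pd.DataFrame, threshold: float = 5e-8, top_n: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide-significant SNPs plus the top-N list by p-value.

    Returns ``(hits, top)``: SNPs below the threshold and the ``top_n``
    smallest p-values regardless of it, both ascending in p with ties
    broken by snp_id.
    """
    ranked = results.dropna(subset=["p"]).sort_values(
        ["p", "snp_id"], kind="mergesort"
    )
    hits = ranked[ranked["p"] < threshold].reset_index(drop=True)
    return hits, ranked.head(top_n).reset_index(drop=True)


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected-vs-observed -log10(p) pairs for a Q-Q plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    m = len(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected),
         "observed_neglog10": -np.log10(np.maximum(p, 1e-300))}
    )
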
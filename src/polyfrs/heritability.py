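"""SNP heritability from a genetic relationship matrix.

Two estimation families are provided. GREML fits the variance-component
model y = Xb + g + e with Var(y) = sigma2_g * A + sigma2_e * I by
restricted maximum likelihood, where A is the allele-frequency-weighted
GRM; three iterative schemes are offered — Newton steps with the
average-information matrix (AI), Newton steps with the expected (Fisher)
information, and expectation-maximization updates (EM) — which share
the same optimum and differ only in path. Haseman-Elston regression
instead regresses the pairwise phenotype cross-product (or squared
difference) on the pairwise GRM entry; its slope estimates h² directly,
close-relative pairs are excluded pair-wise rather than subject-wise,
and inference comes from a subject-level bootstrap because pairs
sharing a subject are not independent.

All REML linear algebra runs in the eigenbasis of A, where
V = sigma2_g * A + sigma2_e * I is diagonal; one symmetric
eigendecomposition per fit makes each iteration O(n p²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GrmFile
from .panel import GenotypePanel, standardized_dosages
from .qc import prune_relatives_subjectwise


# ---------------------------------------------------------------------
# GRM construction
# ---------------------------------------------------------------------

def compute_grm(panel: GenotypePanel) -> GrmFile:
    """Allele-frequency-weighted GRM (GCTA convention).

    Off-diagonal entries average, over jointly non-missing SNPs, the
    product of the two samples' standardized dosages
    (x - 2p)/sqrt(2p(1-p)). Diagonal entries use the unbiased
    single-sample form 1 + (x² - (1+2p)x + 2p²)/(2p(1-p)) averaged over
    the sample's non-missing SNPs. Monomorphic SNPs are rejected.
    """
    p = panel.allele_frequency()
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("panel contains monomorphic or fully missing SNPs")
    x = panel.dosages
    nonmiss = ~np.isnan(x)
    w = standardized_dosages(panel, impute_mean=False, freqs=p)
    w = np.where(nonmiss, w, 0.0)
    m_mask = nonmiss.astype(float)

    num = w @ w.T
    counts = m_mask @ m_mask.T
    if np.any(counts == 0):
        raise ValueError("a sample pair shares no non-missing SNPs")
    a = num / counts

    denom = 2.0 * p * (1.0 - p)
    diag_terms = np.where(
        nonmiss, (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / denom, 0.0
    )
    n_obs = nonmiss.sum(axis=1)
    np.fill_diagonal(a, 1.0 + np.nansum(diag_terms, axis=1) / n_obs)

    ids = panel.samples[["family_id", "sample_id"]].reset_index(drop=True)
    return GrmFile.from_square(a, ids=ids, pair_snp_counts=counts)


def grm_prune_subjects(grm: GrmFile, threshold: float = 0.025) -> GrmFile:
    """Drop subjects greedily until no off-diagonal exceeds the threshold.

    This is the subject-wise handling of close relatives used for the
    REML arm; contrast with the pair-wise exclusion inside
    Haseman-Elston regression, which keeps every subject.
    """
    a = grm.to_square()
    ids = list(grm.ids["sample_id"])
    removed = prune_relatives_subjectwise(a, ids, threshold)
    if not removed:
        return grm
    keep = np.array([sid not in removed for sid in ids])
    counts = grm.counts_to_square()[np.ix_(keep, keep)]
    return GrmFile.from_square(
        a[np.ix_(keep, keep)],
        ids=grm.ids.loc[keep].reset_index(drop=True),
        pair_snp_counts=counts,
    )


# ---------------------------------------------------------------------
# GREML
# ---------------------------------------------------------------------

class _RotatedREML:
    """REML workspace in the eigenbasis of the GRM.

    With A = U diag(lam) U', V = sg*A + se*I rotates to the diagonal
    d = sg*lam + se, and every trace/quadratic form needed by the three
    update schemes reduces to O(n p²) expressions in the rotated
    phenotype and fixed-effect design.
    """

    def __init__(self, a: np.ndarray, y: np.ndarray, x: np.ndarray):
        lam, u = np.linalg.eigh(a)
        self.lam = lam
        self.yt = u.T @ y
        self.xt = u.T @ x
        self.n = len(y)
        self.p = x.shape[1]

    def pieces(self, sg: float, se: float):
        d = sg * self.lam + se
        if d.min() <= 0:
            return None
        dinv = 1.0 / d
        xd = self.xt * dinv[:, None]
        xtvx = self.xt.T @ xd
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return None
        b = np.linalg.inv(xtvx)
        w = dinv * self.yt - xd @ (b @ (xd.T @ self.yt))  # w = P y (rotated)
        ypy = float(self.yt @ w)
        logl = -0.5 * (np.sum(np.log(d)) + logdet_xtvx + ypy)
        return {"d": d, "dinv": dinv, "xd": xd, "b": b, "w": w,
                "ypy": ypy, "logl": logl}

    def _tr_pv(self, pc: dict, v: np.ndarray) -> float:
        # tr(P Vi) with Vi diagonal (v = lam for the genetic component,
        # ones for the residual)
        t1 = float(np.sum(v * pc["dinv"]))
        m = self.xt.T @ (self.xt * (v * pc["dinv"] ** 2)[:, None])
        return t1 - float(np.trace(pc["b"] @ m))

    def score(self, pc: dict) -> np.ndarray:
        out = np.empty(2)
        for i, v in enumerate((self.lam, np.ones(self.n))):
            ypvpy = float(np.sum(v * pc["w"] ** 2))
            out[i] = -0.5 * (self._tr_pv(pc, v) - ypvpy)
        return out

    def fisher_info(self, pc: dict) -> np.ndarray:
        vs = (self.lam, np.ones(self.n))
        dinv = pc["dinv"]
        info = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                vi, vj = vs[i], vs[j]
                t1 = float(np.sum(vi * vj * dinv**2))
                g = self.xt.T @ (self.xt * (vi * vj * dinv**3)[:, None])
                t2 = float(np.trace(pc["b"] @ g))
                hi = self.xt.T @ (self.xt * (vi * dinv**2)[:, None])
                hj = self.xt.T @ (self.xt * (vj * dinv**2)[:, None])
                t3 = float(np.trace(pc["b"] @ hi @ pc["b"] @ hj))
                info[i, j] = info[j, i] = 0.5 * (t1 - 2 * t2 + t3)
        return info

    def _apply_p(self, pc: dict, u: np.ndarray) -> np.ndarray:
        return pc["dinv"] * u - pc["xd"] @ (pc["b"] @ (pc["xd"].T @ u))

    def average_info(self, pc: dict) -> np.ndarray:
        vs = (self.lam, np.ones(self.n))
        vw = [v * pc["w"] for v in vs]
        pvw = [self._apply_p(pc, t) for t in vw]
        info = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                info[i, j] = info[j, i] = 0.5 * float(vw[i] @ pvw[j])
        return info


class GREML:
    """Restricted-maximum-likelihood variance components on a GRM.

    Parameters
    ----------
    algorithm : "ai" | "fisher" | "em"
        Update scheme: average-information Newton, expected-information
        (Fisher scoring) Newton, or expectation-maximization. The first
        iteration of the Newton schemes is an EM step, which stabilises
        the start. All schemes share the same optimum.
    max_iter, tol : iteration cap and the |delta logL| convergence
        criterion.
    constrain : project negative variance components to 1e-6 * Vp
        (flagging the fit) rather than allowing negative estimates.

    Fitted attributes: ``sigma2_g_``, ``sigma2_e_``, ``vp_``, ``h2_``,
    ``se_sigma2_g_``, ``se_sigma2_e_``, ``se_vp_``, ``se_h2_``,
    ``logL_``, ``n_iter_``, ``converged_``, ``constrained_``,
    ``n_used_``, ``history_`` (logL per iteration). Standard errors
    come from the inverse average-information matrix at the optimum for
    every algorithm, with the h² SE by the delta method.
    """

    def __init__(self, algorithm: str = "ai", max_iter: int = 200,
                 tol: float = 1e-8, constrain: bool = True):
        self.algorithm = algorithm
        self.max_iter = max_iter
        self.tol = tol
        self.constrain = constrain

    def get_params(self, deep: bool = True) -> dict:
        return {"algorithm": self.algorithm, "max_iter": self.max_iter,
                "tol": self.tol, "constrain": self.constrain}

    def set_params(self, **params) -> "GREML":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        grm: GrmFile | np.ndarray,
        y: np.ndarray,
        covariates: np.ndarray | pd.DataFrame | None = None,
    ) -> "GREML":
        if self.algorithm not in ("ai", "fisher", "em"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        a = grm.to_square() if isinstance(grm, GrmFile) else np.asarray(grm)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if a.shape != (n, n):
            raise ValueError("GRM and phenotype are not aligned")
        if n < 50:
            warnings.warn(f"n={n} is small for REML; estimates will be noisy")
        if covariates is None:
            x = np.ones((n, 1))
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            x = np.column_stack([np.ones(n), cov])

        ws = _RotatedREML(a, y, x)
        vp0 = float(np.var(y, ddof=1))
        theta = np.array([vp0 / 2.0, vp0 / 2.0])
        floor = 1e-6 * vp0

        pc = ws.pieces(*theta)
        if pc is None:
            raise np.linalg.LinAlgError("V not positive definite at start")
        history = [pc["logl"]]
        converged = False
        constrained = False
        n_iter = 0

        for it in range(self.max_iter):
            n_iter = it + 1
            use_em = self.algorithm == "em" or it == 0
            if use_em:
                # sigma_i^2 <- sigma_i^2 + sigma_i^4 (y'PViPy - tr(PVi))/n
                new = theta.copy()
                for i, v in enumerate((ws.lam, np.ones(ws.n))):
                    ypvpy = float(np.sum(v * pc["w"] ** 2))
                    new[i] = theta[i] + theta[i] ** 2 * (
                        ypvpy - ws._tr_pv(pc, v)
                    ) / ws.n
                step = new - theta
            else:
                s = ws.score(pc)
                info = (
                    ws.average_info(pc)
                    if self.algorithm == "ai"
                    else ws.fisher_info(pc)
                )
                try:
                    step = np.linalg.solve(info, s)
                except np.linalg.LinAlgError:
                    step = np.linalg.pinv(info) @ s

            # step halving on loss of positive definiteness
            pc_new = None
            for _ in range(10):
                cand = theta + step
                if self.constrain:
                    low = cand < 0
                    if low.any():
                        cand = cand.copy()
                        cand[low] = floor
                        constrained = True
                pc_new = ws.pieces(*cand)
                if pc_new is not None:
                    break
                step = step / 2.0
            if pc_new is None:
                raise np.linalg.LinAlgError(
                    "V remained non-positive-definite after 10 halvings"
                )
            theta = cand
            delta = pc_new["logl"] - history[-1]
            history.append(pc_new["logl"])
            pc = pc_new
            if abs(delta) < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"REML ({self.algorithm}) did not converge in "
                f"{self.max_iter} iterations"
            )

        ai = ws.average_info(pc)
        try:
            cov_theta = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            cov_theta = np.linalg.pinv(ai)

        sg, se_comp = float(theta[0]), float(theta[1])
        vp = sg + se_comp
        h2 = sg / vp
        grad = np.array([se_comp, -sg]) / vp**2
        var_h2 = float(grad @ cov_theta @ grad)

        self.sigma2_g_ = sg
        self.sigma2_e_ = se_comp
        self.vp_ = vp
        self.h2_ = float(np.clip(h2, 0.0, 1.0))
        self.se_sigma2_g_ = float(np.sqrt(max(cov_theta[0, 0], 0.0)))
        self.se_sigma2_e_ = float(np.sqrt(max(cov_theta[1, 1], 0.0)))
        self.se_vp_ = float(np.sqrt(max(cov_theta.sum(), 0.0)))
        self.se_h2_ = float(np.sqrt(max(var_h2, 0.0)))
        self.logL_ = float(pc["logl"])
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.constrained_ = constrained
        self.n_used_ = n
        self.history_ = np.array(history)
        return self

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "sigma2_g": self.sigma2_g_,
            "sigma2_e": self.sigma2_e_,
            "vp": self.vp_,
            "h2": self.h2_,
            "se_sigma2_g": self.se_sigma2_g_,
            "se_vp": self.se_vp_,
            "se_h2": self.se_h2_,
            "logL": self.logL_,
            "n_iterations": self.n_iter_,
            "converged": self.converged_,
            "n": self.n_used_,
        }


def reml_fit(
    grm: GrmFile | np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    algorithm: str = "ai",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GREML:
    """Fit the GRM variance-component model; see :class:`GREML`."""
    return GREML(algorithm=algorithm, max_iter=max_iter, tol=tol).fit(
        grm, phenotype, covariates
    )


def restricted_loglik(
    grm: GrmFile | np.ndarray,
    y: np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
    covariates: np.ndarray | None = None,
) -> float:
    """Restricted log-likelihood at given variance components."""
    a = grm.to_square() if isinstance(grm, GrmFile) else np.asarray(grm)
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = (
        np.ones((n, 1))
        if covariates is None
        else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    )
    pc = _RotatedREML(a, y, x).pieces(sigma2_g, sigma2_e)
    if pc is None:
        raise np.linalg.LinAlgError("V not positive definite")
    return float(pc["logl"])


# ---------------------------------------------------------------------
# Haseman-Elston regression
# ---------------------------------------------------------------------

def _residualize_standardize(
    y: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = (
        np.ones((n, 1))
        if covariates is None
        else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    )
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    sd = resid.std()
    if sd == 0:
        raise ValueError("phenotype has zero variance after residualization")
    return resid / sd


def _he_slope(
    z: np.ndarray, a: np.ndarray, pair_threshold: float,
    form: str, min_pairs: int = 3,
    pair_mask: np.ndarray | None = None,
) -> tuple[float, float, int, int]:
    """Pairwise regression core; returns (slope, intercept, used, excluded)."""
    n = len(z)
    iu, ju = np.triu_indices(n, 1)
    rel = a[iu, ju]
    keep = rel <= pair_threshold
    if pair_mask is not None:
        keep &= pair_mask
        n_considered = int(pair_mask.sum())
    else:
        n_considered = len(rel)
    n_used = int(keep.sum())
    n_excluded = n_considered - n_used
    if n_used < min_pairs:
        raise ValueError(f"only {n_used} surviving pairs")
    x = rel[keep]
    if np.ptp(x) == 0:
        raise ValueError("relatedness is constant across surviving pairs")
    if form == "cross_product":
        dep = z[iu[keep]] * z[ju[keep]]
    elif form == "squared_difference":
        dep = (z[iu[keep]] - z[ju[keep]]) ** 2
    else:
        raise ValueError(f"unknown H-E form {form!r}")
    xc = x - x.mean()
    slope = float(xc @ dep / (xc @ xc))
    intercept = float(dep.mean() - slope * x.mean())
    return slope, intercept, n_used, n_excluded


def _slope_to_h2(slope: float, form: str) -> float:
    return slope if form == "cross_product" else -slope / 2.0


class HasemanElston:
    """Pair-filtered Haseman-Elston regression with subject bootstrap.

    The phenotype is residualized on the covariates and standardized to
    unit variance; for every pair (i < j) with GRM entry at or below
    ``pair_threshold`` the cross-product z_i * z_j (default) or squared
    difference (z_i - z_j)² is regressed on A_ij. The slope is the h²
    estimate for the cross-product form (-slope/2 for the squared
    difference). Excluding related *pairs* rather than whole subjects
    keeps the full sample in the analysis.

    With ``n_bootstrap`` > 0 inference resamples whole subjects with
    replacement, keeps only pairs whose members descend from distinct
    original subjects, and reruns the regression; the bootstrap
    distribution of slopes gives the SE, the 2.5/97.5 percentile CI and
    a two-sided sign-percentile p-value.
    """

    def __init__(
        self,
        pair_threshold: float = 0.025,
        form: str = "cross_product",
        n_bootstrap: int = 0,
        seed: int = 0,
    ):
        self.pair_threshold = pair_threshold
        self.form = form
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"pair_threshold": self.pair_threshold, "form": self.form,
                "n_bootstrap": self.n_bootstrap, "seed": self.seed}

    def set_params(self, **params) -> "HasemanElston":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self,
        grm: GrmFile | np.ndarray,
        y: np.ndarray,
        covariates: np.ndarray | pd.DataFrame | None = None,
    ) -> "HasemanElston":
        a = grm.to_square() if isinstance(grm, GrmFile) else np.asarray(grm)
        y = np.asarray(y, dtype=float)
        cov = (
            None if covariates is None else np.asarray(covariates, dtype=float)
        )
        if cov is not None and cov.ndim == 1:
            cov = cov[:, None]
        n = len(y)
        if a.shape != (n, n):
            raise ValueError("GRM and phenotype are not aligned")

        z = _residualize_standardize(y, cov)
        slope, intercept, used, excluded = _he_slope(
            z, a, self.pair_threshold, self.form
        )
        if used < 100:
            warnings.warn(f"only {used} surviving pairs; estimate unstable")
        self.slope_ = slope
        self.intercept_ = intercept
        self.h2_ = _slope_to_h2(slope, self.form)
        self.n_pairs_used_ = used
        self.n_pairs_excluded_ = excluded
        self.n_used_ = n
        self.bootstrap_ = None

        if self.n_bootstrap > 0:
            self.bootstrap_ = self._bootstrap(a, y, cov)
        return self

    def _bootstrap(
        self, a: np.ndarray, y: np.ndarray, cov: np.ndarray | None
    ) -> dict:
        rng = np.random.default_rng(self.seed)
        n = len(y)
        slopes = np.empty(self.n_bootstrap)
        n_degenerate = 0
        r = 0
        while r < self.n_bootstrap:
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size < 2:
                n_degenerate += 1
                continue
            yb = y[idx]
            covb = None if cov is None else cov[idx]
            try:
                zb = _residualize_standardize(yb, covb)
            except (ValueError, np.linalg.LinAlgError):
                n_degenerate += 1
                continue
            ab = a[np.ix_(idx, idx)]
            iu, ju = np.triu_indices(n, 1)
            distinct = idx[iu] != idx[ju]
            try:
                slope, *_ = _he_slope(
                    zb, ab, self.pair_threshold, self.form,
                    pair_mask=distinct,
                )
            except ValueError:
                n_degenerate += 1
                continue
            slopes[r] = slope
            r += 1

        ci_low, ci_high = np.percentile(slopes, [2.5, 97.5])
        frac_le = np.mean(slopes <= 0.0)
        frac_ge = np.mean(slopes >= 0.0)
        return {
            "n_reps": self.n_bootstrap,
            "n_degenerate_redrawn": n_degenerate,
            "se": float(slopes.std(ddof=1)),
            "ci_low": float(ci_low),
            "ci_high": float(ci_high),
            "p_value": float(min(1.0, 2.0 * min(frac_le, frac_ge))),
            "se_h2": float(
                np.std([_slope_to_h2(s, self.form) for s in slopes], ddof=1)
            ),
            "slopes": slopes,
            "seed": self.seed,
        }

    def summary(self) -> dict:
        out = {
            "form": self.form,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "h2": self.h2_,
            "n_pairs_used": self.n_pairs_used_,
            "n_pairs_excluded": self.n_pairs_excluded_,
            "n": self.n_used_,
        }
        if self.bootstrap_ is not None:
            out["bootstrap"] = {
                k: v for k, v in self.bootstrap_.items() if k != "slopes"
            }
        return out


def he_regression(
    grm: GrmFile | np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    pair_threshold: float = 0.025,
    form: str = "cross_product",
) -> HasemanElston:
    """Pair-filtered H-E regression; see :class:`HasemanElston`."""
    return HasemanElston(pair_threshold=pair_threshold, form=form).fit(
        grm, phenotype, covariates
    )


def he_bootstrap(
    grm: GrmFile | np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    pair_threshold: float = 0.025,
    n_reps: int = 1000,
    seed: int = 0,
    form: str = "cross_product",
) -> dict:
    """Subject-resampling bootstrap of the H-E slope; see
    :class:`HasemanElston`."""
    if n_reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    fit = HasemanElston(
        pair_threshold=pair_threshold, form=form, n_bootstrap=n_reps,
        seed=seed,
    ).fit(grm, phenotype, covariates)
    return fit.bootstrap_
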
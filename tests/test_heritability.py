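"""GRM and heritability estimation: oracles, recovery, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from polyfrs.heritability import (
    GREML,
    HasemanElston,
    compute_grm,
    grm_prune_subjects,
    he_regression,
    restricted_loglik,
)
from polyfrs.simulate import SimConfig, simulate_dataset, simulate_genotypes

from conftest import make_panel, random_panel


def grm_oracle(dosages):
    """Naive double-loop GRM with the same weighting conventions."""
    n, m = dosages.shape
    p = np.nanmean(dosages, axis=0) / 2
    a = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            if i == k:
                terms = []
                for j in range(m):
                    x = dosages[i, j]
                    if np.isnan(x):
                        continue
                    denom = 2 * p[j] * (1 - p[j])
                    terms.append(
                        1 + (x * x - (1 + 2 * p[j]) * x + 2 * p[j] ** 2) / denom
                    )
                a[i, i] = np.mean(terms)
            else:
                terms = []
                for j in range(m):
                    xi, xk = dosages[i, j], dosages[k, j]
                    if np.isnan(xi) or np.isnan(xk):
                        continue
                    denom = np.sqrt(2 * p[j] * (1 - p[j]))
                    terms.append(
                        (xi - 2 * p[j]) / denom * (xk - 2 * p[j]) / denom
                    )
                a[i, k] = np.mean(terms)
    return a


def polymorphic(panel):
    maf = panel.minor_allele_frequency()
    return panel.subset(snp_ids=panel.snp_ids[maf > 0])


class TestGrm:
    def test_matches_double_loop_oracle(self, rng):
        panel = polymorphic(
            random_panel(rng, 10, 20, maf_range=(0.2, 0.5), missing_rate=0.1)
        )
        grm = compute_grm(panel).to_square()
        np.testing.assert_allclose(grm, grm_oracle(panel.dosages), atol=1e-12)

    def test_three_by_two_hand_panel(self):
        dos = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 1.0]])
        grm = compute_grm(make_panel(dos)).to_square()
        np.testing.assert_allclose(grm, grm_oracle(dos), atol=1e-12)

    def test_unrelated_hwe_mean_offdiagonal_near_zero(self):
        cfg = SimConfig(n_samples=500, n_snps=2000, maf_range=(0.1, 0.5),
                        seed=60)
        panel, _ = simulate_genotypes(cfg)
        a = compute_grm(polymorphic(panel)).to_square()
        off = a[np.triu_indices_from(a, 1)]
        # centering on sample frequencies forces the expected off-diagonal
        # to -1/n rather than 0 (column sums of standardized dosages vanish)
        n = a.shape[0]
        assert abs(off.mean() + 1.0 / n) <= 5e-4
        assert abs(off.mean()) <= 3.0 / n
        assert 0.9 <= np.mean(np.diag(a)) <= 1.1

    def test_monomorphic_rejected(self):
        dos = np.array([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_panel(dos))

    def test_pair_snp_counts_recorded(self, rng):
        panel = polymorphic(
            random_panel(rng, 8, 30, maf_range=(0.3, 0.5), missing_rate=0.2)
        )
        grm = compute_grm(panel)
        counts = grm.counts_to_square()
        nonmiss = ~np.isnan(panel.dosages)
        expected = nonmiss.astype(float) @ nonmiss.T
        np.testing.assert_array_equal(counts, expected)


@pytest.fixture(scope="module")
def sim_h2_50():
    cfg = SimConfig(n_samples=500, n_snps=1500, h2_true=0.5, n_causal=150,
                    maf_range=(0.1, 0.5), seed=61)
    panel, y, truth = simulate_dataset(cfg)
    maf = panel.minor_allele_frequency()
    panel = panel.subset(snp_ids=panel.snp_ids[maf > 0])
    return compute_grm(panel), y, truth


class TestGreml:
    def test_recovers_simulated_heritability(self, sim_h2_50):
        grm, y, truth = sim_h2_50
        fit = GREML(algorithm="ai").fit(grm, y)
        # single replicate: allow ~2 sampling SDs around realized h2
        assert fit.converged_
        assert fit.h2_ == pytest.approx(truth.h2_realized, abs=0.25)
        assert fit.vp_ == pytest.approx(np.var(y, ddof=1), rel=0.2)

    def test_three_algorithms_reach_same_optimum(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        fits = {
            algo: GREML(algorithm=algo, tol=1e-10).fit(grm, y)
            for algo in ("ai", "fisher", "em")
        }
        vp = fits["ai"].vp_
        for a in ("fisher", "em"):
            assert abs(fits[a].sigma2_g_ - fits["ai"].sigma2_g_) <= 1e-4 * vp
            assert abs(fits[a].logL_ - fits["ai"].logL_) <= 1e-4

    def test_em_loglik_monotone(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        fit = GREML(algorithm="em", max_iter=50).fit(grm, y)
        assert np.all(np.diff(fit.history_) >= -1e-9)

    def test_gradient_vanishes_at_optimum(self, sim_h2_50):
        """Central-difference gradient of the restricted log-likelihood is
        ~0 at the converged components."""
        grm, y, _ = sim_h2_50
        fit = GREML(algorithm="ai", tol=1e-10).fit(grm, y)
        eps = 1e-5 * fit.vp_
        for i, (sg, se) in enumerate(
            [(fit.sigma2_g_, fit.sigma2_e_)] * 2
        ):
            args = np.array([sg, se])
            up, dn = args.copy(), args.copy()
            up[i] += eps
            dn[i] -= eps
            grad = (
                restricted_loglik(grm, y, *up) - restricted_loglik(grm, y, *dn)
            ) / (2 * eps)
            assert abs(grad) < 1e-2

    def test_identity_grm_matches_iid_reml_closed_form(self, rng):
        """With A = I only Vp is identified; the converged restricted
        likelihood must equal the closed-form iid value and Vp = RSS/(n-1)."""
        n = 120
        y = rng.normal(size=n)
        fit = GREML(algorithm="em", tol=1e-12, max_iter=500).fit(np.eye(n), y)
        s2 = np.sum((y - y.mean()) ** 2) / (n - 1)
        expected = -0.5 * ((n - 1) * np.log(s2) + np.log(n) + (n - 1))
        assert fit.vp_ == pytest.approx(s2, rel=1e-6)
        assert fit.logL_ == pytest.approx(expected, abs=1e-6)

    def test_covariates_absorb_fixed_effects(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        rng = np.random.default_rng(4)
        cov = rng.normal(size=(len(y), 2))
        y_shifted = y + cov @ np.array([3.0, -2.0])
        f0 = GREML(algorithm="ai").fit(grm, y)
        f1 = GREML(algorithm="ai").fit(grm, y_shifted, covariates=cov)
        assert f1.h2_ == pytest.approx(f0.h2_, abs=0.02)

    def test_unknown_algorithm_rejected(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        with pytest.raises(ValueError, match="algorithm"):
            GREML(algorithm="nr").fit(grm, y)


class TestHasemanElston:
    def test_slope_matches_naive_ols_oracle(self, rng):
        n = 60
        a = rng.normal(scale=0.05, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        y = rng.normal(size=n)
        fit = HasemanElston(pair_threshold=0.08).fit(a, y)
        z = (y - y.mean()) / (y - y.mean()).std()
        xs, ds = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if a[i, j] <= 0.08:
                    xs.append(a[i, j])
                    ds.append(z[i] * z[j])
        slope = np.polyfit(xs, ds, 1)[0]
        assert fit.slope_ == pytest.approx(slope, abs=1e-10)
        assert fit.n_pairs_used_ == len(xs)
        assert fit.n_pairs_used_ + fit.n_pairs_excluded_ == n * (n - 1) // 2

    def test_recovers_simulated_heritability(self, sim_h2_50):
        grm, y, truth = sim_h2_50
        fit = HasemanElston(pair_threshold=0.1).fit(grm, y)
        assert fit.h2_ == pytest.approx(truth.h2_realized, abs=0.3)

    def test_cross_product_and_squared_difference_agree(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        cp = HasemanElston(pair_threshold=0.1, form="cross_product",
                           n_bootstrap=150, seed=1).fit(grm, y)
        sq = HasemanElston(pair_threshold=0.1, form="squared_difference"
                           ).fit(grm, y)
        assert abs(cp.h2_ - sq.h2_) <= 2 * cp.bootstrap_["se_h2"]

    def test_permuted_phenotype_destroys_signal(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        rng = np.random.default_rng(9)
        fit = HasemanElston(pair_threshold=0.1, n_bootstrap=200, seed=2).fit(
            grm, rng.permutation(y)
        )
        assert fit.bootstrap_["ci_low"] <= 0.0 <= fit.bootstrap_["ci_high"]

    def test_constant_relatedness_rejected(self, rng):
        a = np.full((30, 30), 0.01)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="constant"):
            HasemanElston(pair_threshold=0.5).fit(a, rng.normal(size=30))

    def test_zero_variance_phenotype_rejected(self, rng):
        a = rng.normal(scale=0.02, size=(30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="variance"):
            HasemanElston().fit(a, np.ones(30))

    def test_bootstrap_deterministic_under_seed(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        b1 = HasemanElston(pair_threshold=0.1, n_bootstrap=120, seed=7).fit(
            grm, y
        ).bootstrap_
        b2 = HasemanElston(pair_threshold=0.1, n_bootstrap=120, seed=7).fit(
            grm, y
        ).bootstrap_
        assert b1["se"] == b2["se"]
        assert b1["ci_low"] == b2["ci_low"]
        np.testing.assert_array_equal(b1["slopes"], b2["slopes"])

    def test_subject_bootstrap_se_inflation_factor(self):
        """Among unrelateds the H-E slope is driven by pair-level GRM
        noise, so its kernel is first-order degenerate and the naive
        subject bootstrap overstates the SE by a factor approaching
        sqrt(3) (the variance of near-Poisson pair multiplicities).
        This pins the measured inflation so inference stays
        deliberately conservative rather than silently miscalibrated."""
        import warnings

        slopes, ses = [], []
        for d in range(20):
            cfg = SimConfig(n_samples=200, n_snps=500, h2_true=0.0,
                            maf_range=(0.1, 0.5), seed=8000 + d)
            panel, _ = simulate_genotypes(cfg)
            panel = polymorphic(panel)
            grm = compute_grm(panel)
            rng = np.random.default_rng(8100 + d)
            y = rng.normal(size=panel.n_samples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = HasemanElston(pair_threshold=0.12, n_bootstrap=100,
                                    seed=d).fit(grm, y)
            slopes.append(fit.slope_)
            ses.append(fit.bootstrap_["se"])
        ratio = np.mean(ses) / np.std(slopes, ddof=1)
        assert 1.2 <= ratio <= 2.4

    def test_percentile_ci_brackets_point_estimate(self, sim_h2_50):
        grm, y, _ = sim_h2_50
        fit = HasemanElston(pair_threshold=0.1, n_bootstrap=200, seed=3).fit(
            grm, y
        )
        assert fit.bootstrap_["ci_low"] <= fit.slope_ <= fit.bootstrap_["ci_high"]


class TestSubjectPruning:
    def test_one_related_pair_loses_one_subject(self, rng):
        panel = polymorphic(random_panel(rng, 20, 300, maf_range=(0.2, 0.5)))
        dos = panel.dosages.copy()
        dos[1] = dos[0]  # duplicate
        grm = compute_grm(make_panel(dos))
        pruned = grm_prune_subjects(grm, threshold=0.25)
        assert pruned.n_samples == 19

    def test_planted_sib_pairs_all_broken(self):
        cfg = SimConfig(n_samples=200, n_snps=800, n_sib_pairs=50,
                        maf_range=(0.2, 0.5), seed=62)
        panel, truth = simulate_genotypes(cfg)
        grm = compute_grm(polymorphic(panel))
        pruned = grm_prune_subjects(grm, threshold=0.25)
        removed = 200 - pruned.n_samples
        assert removed >= 50
        kept = set(pruned.ids["sample_id"])
        for a, b, _ in truth.relative_pairs:
            assert not ({a, b} <= kept)  # at most one of each pair survives

    def test_no_pair_above_threshold_is_identity(self, rng):
        panel = polymorphic(random_panel(rng, 15, 500, maf_range=(0.2, 0.5)))
        grm = compute_grm(panel)
        pruned = grm_prune_subjects(grm, threshold=0.5)
        assert pruned.n_samples == 15
        np.testing.assert_array_equal(pruned.to_square(), grm.to_square())

    def test_reml_and_he_agree_without_relatives(self, sim_h2_50):
        """On unrelated simulations the REML and pair-filtered H-E
        estimates agree within 2 combined SEs."""
        grm, y, _ = sim_h2_50
        reml = GREML(algorithm="ai").fit(grm, y)
        he = HasemanElston(pair_threshold=0.1, n_bootstrap=150, seed=5).fit(
            grm, y
        )
        gap = abs(reml.h2_ - he.h2_)
        assert gap <= 2 * np.hypot(reml.se_h2_, he.bootstrap_["se_h2"])
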
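"""Quality-control filters: exact-test oracle, fixtures, relatedness."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyfrs.qc import (
    PRESETS,
    GenotypeQC,
    QcConfig,
    estimate_pihat,
    hwe_exact_test,
    ibs_ancestry_outliers,
    marker_filters,
    pihat_matrix,
    prune_relatives_subjectwise,
    sample_filters,
)
from polyfrs.simulate import SimConfig, simulate_genotypes

from conftest import make_panel, random_panel


def hwe_exact_oracle(n_hom1, n_het, n_hom2):
    """Exact rational-arithmetic enumeration of the Levene-Haldane test."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    rare = min(n_a, n_b)

    def prob(h):
        hom1 = (n_a - h) // 2
        hom2 = (n_b - h) // 2
        num = (
            Fraction(comb(n, hom1) * comb(n - hom1, h))
            * Fraction(2) ** h
            * Fraction(comb(2 * n, n_a)) ** -1
        )
        # multinomial / hypergeometric identity:
        # P(h) = n! 2^h na! nb! / (hom1! h! hom2! (2n)!)
        return num

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= p_obs))


class TestHweExact:
    def test_hwe_proportions_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_homozygote_excess_tiny_p(self):
        p = hwe_exact_test(50, 0, 50)
        assert p == pytest.approx(hwe_exact_oracle(50, 0, 50), rel=1e-9)
        assert p < 1e-20

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hwe_exact_test(0, 0, 0)

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_rational_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_exact_oracle(a, h, b), abs=1e-12
        )


class TestMarkerFilters:
    def _clean_column(self, rng, n):
        # exact HWE-modal column: counts as close to (n/4, n/2, n/4)
        col = np.array([2.0] * (n // 4) + [0.0] * (n // 4)
                       + [1.0] * (n - 2 * (n // 4)))
        return rng.permuted(col)

    def test_planted_violations_attributed_in_order(self, rng):
        n = 40
        clean = np.column_stack([self._clean_column(rng, n) for _ in range(4)])
        low_call = self._clean_column(rng, n)
        low_call[: n // 2] = np.nan  # 50% call rate
        low_maf = np.zeros(n)  # monomorphic, maf 0
        bad_hwe = np.array([2.0] * (n // 2) + [0.0] * (n // 2))  # no hets
        panel = make_panel(
            np.column_stack([clean, low_call, low_maf, bad_hwe]),
            snp_ids=[f"ok{i}" for i in range(4)] + ["lowcall", "lowmaf", "hwe"],
        )
        recs = marker_filters(panel, QcConfig())
        by_name = {r.name: r.removed for r in recs}
        assert by_name["marker_call_rate"] == ["lowcall"]
        assert by_name["marker_maf"] == ["lowmaf"]
        assert by_name["marker_hwe"] == ["hwe"]

    def test_maf_boundary_retained(self):
        # 50 samples -> one A1 allele copy gives maf exactly 0.01
        col = np.zeros(50)
        col[0] = 1.0
        panel = make_panel(col[:, None], snp_ids=["edge"])
        recs = marker_filters(panel, QcConfig(hwe_p_min=0.0))
        assert all(r.n_removed == 0 for r in recs)

    def test_no_violations_no_removals(self, rng):
        panel = random_panel(rng, 100, 20, maf_range=(0.3, 0.5))
        recs = marker_filters(panel, QcConfig())
        assert all(r.n_removed == 0 for r in recs)


class TestSampleFilters:
    def test_low_call_rate_removed(self, rng):
        dos = random_panel(rng, 20, 40, maf_range=(0.3, 0.5)).dosages
        dos[0, :4] = np.nan  # 90% call rate
        panel = make_panel(dos)
        recs = sample_filters(panel, QcConfig())
        assert recs[0].removed == ["S000"]

    def test_all_homozygous_sample_flagged(self, rng):
        n, m = 30, 200
        p = rng.uniform(0.4, 0.5, size=m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        dos[0] = np.where(dos[0] == 1.0, 0.0, dos[0])  # zero heterozygosity
        panel = make_panel(dos)
        recs = sample_filters(panel, QcConfig())
        assert "S000" in recs[1].removed

    def test_identical_samples_no_het_outliers(self):
        dos = np.tile([1.0, 0.0, 2.0, 1.0], (5, 1))
        panel = make_panel(dos)
        recs = sample_filters(panel, QcConfig())
        assert recs[1].removed == []


class TestPihat:
    @pytest.fixture(scope="class")
    def related_panel(self):
        cfg = SimConfig(n_samples=40, n_snps=2000, n_duplicate_pairs=1,
                        n_sib_pairs=1, maf_range=(0.1, 0.5), seed=42)
        return simulate_genotypes(cfg)

    def test_duplicates_near_one(self, related_panel):
        panel, truth = related_panel
        a, b, _ = truth.relative_pairs[0]
        ia, ib = panel.sample_indexer([a, b])
        assert estimate_pihat(panel, (ia, ib)) == pytest.approx(1.0, abs=0.05)

    def test_sibs_near_half(self, related_panel):
        panel, truth = related_panel
        a, b, _ = truth.relative_pairs[1]
        ia, ib = panel.sample_indexer([a, b])
        assert estimate_pihat(panel, (ia, ib)) == pytest.approx(0.5, abs=0.07)

    def test_unrelateds_near_zero(self, related_panel):
        # simplex clamping makes individual estimates non-negative, so the
        # mean sits slightly above zero; check the mean and a loose cap
        panel, _ = related_panel
        vals = [estimate_pihat(panel, (10, j)) for j in range(20, 30)]
        assert abs(np.mean(vals)) <= 0.05
        assert np.max(np.abs(vals)) <= 0.12

    def test_too_few_joint_snps_gives_nan(self, rng):
        panel = random_panel(rng, 4, 30)
        with pytest.warns(UserWarning, match="joint"):
            assert np.isnan(estimate_pihat(panel, (0, 1), min_joint_snps=50))


class TestPruneRelatives:
    def test_one_pair_one_removed(self):
        rel = np.eye(3)
        rel[0, 1] = rel[1, 0] = 0.5
        removed = prune_relatives_subjectwise(rel, ["a", "b", "c"], 0.25)
        assert removed == {"a"}  # tie broken by smallest id

    def test_star_hub_removed_alone(self):
        ids = ["hub", "x1", "x2", "x3"]
        rel = np.eye(4)
        for j in range(1, 4):
            rel[0, j] = rel[j, 0] = 0.5
        assert prune_relatives_subjectwise(rel, ids, 0.25) == {"hub"}

    def test_no_over_threshold_pairs_nothing_removed(self):
        rel = np.eye(4) + 0.01
        assert prune_relatives_subjectwise(rel, list("abcd"), 0.25) == set()

    def test_result_leaves_no_edge_above_threshold(self, rng):
        n = 15
        rel = rng.uniform(0, 0.4, size=(n, n))
        rel = (rel + rel.T) / 2
        ids = [f"s{i}" for i in range(n)]
        removed = prune_relatives_subjectwise(rel, ids, 0.25)
        keep = [i for i, s in enumerate(ids) if s not in removed]
        sub = rel[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.25


class TestIbsAncestry:
    def test_planted_minority_subpopulation_flagged(self):
        cfg = SimConfig(n_samples=120, n_snps=800, fst=0.2, seed=13)
        panel, truth = simulate_genotypes(cfg)
        # keep 3 minority samples among 57 majority ones (~5%)
        subpop = np.array([truth.subpop[s] for s in panel.sample_ids])
        keep = list(panel.sample_ids[subpop == 1][:57]) + list(
            panel.sample_ids[subpop == 2][:3]
        )
        sub = panel.subset(sample_ids=keep)
        flagged = ibs_ancestry_outliers(sub, sd_limit=3.0)
        minority = set(panel.sample_ids[subpop == 2][:3])
        assert flagged == minority

    def test_homogeneous_panel_unflagged(self, rng):
        panel = random_panel(rng, 40, 500, maf_range=(0.2, 0.5))
        assert ibs_ancestry_outliers(panel, sd_limit=3.0) == set()

    def test_too_small_panel_rejected(self, rng):
        panel = random_panel(rng, 2, 50)
        with pytest.raises(ValueError, match="3 samples"):
            ibs_ancestry_outliers(panel)


class TestPipeline:
    def test_presets_match_published_thresholds(self):
        g = PRESETS["gwas"]
        assert (g.sample_call_rate_min, g.maf_min, g.hwe_p_min,
                g.relatedness_subject_max) == (0.95, 0.01, 1e-4, 0.25)
        h = PRESETS["heritability"]
        assert (h.sample_call_rate_min, h.maf_min, h.hwe_p_min,
                h.relatedness_pair_max) == (0.99, 0.01, 0.05, 0.025)

    def test_rerun_is_fixed_point(self, rng):
        panel = random_panel(rng, 50, 300, maf_range=(0.1, 0.5),
                             missing_rate=0.03)
        cfg = QcConfig(do_relatedness=False, do_ancestry=False)
        qc = GenotypeQC(config=cfg).fit(panel)
        filtered = qc.transform(panel)
        qc2 = GenotypeQC(config=cfg).fit(filtered)
        assert all(r.n_removed == 0 for r in qc2.report_.filters)

    def test_filter_order_logged(self, rng):
        panel = random_panel(rng, 30, 100, maf_range=(0.2, 0.5))
        qc = GenotypeQC(
            config=QcConfig(do_relatedness=False, do_ancestry=False)
        ).fit(panel)
        names = [f.name for f in qc.report_.filters]
        assert names == ["sample_call_rate", "marker_call_rate", "marker_maf",
                         "marker_hwe", "sample_heterozygosity"]
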
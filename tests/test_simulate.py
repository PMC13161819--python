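import numpy as np
import pytest
from scipy import stats

from mindnet.enrich import overlap_permutation
from mindnet.simulate import (
    CohortSpec,
    ExpressionTruth,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    generate_stage_region_sets,
    spatial_covariance,
)


def _regional_means(fs):
    """Per-region mean over vertices and features (the cohort oracle)."""
    out = np.empty(fs.n_regions)
    for r in range(fs.n_regions):
        out[r] = fs.region_vertices(r).mean()
    return out


class TestCohort:
    def test_null_model_group_means_balanced(self, small_geometry):
        spec = CohortSpec(
            n_patients=25, n_controls=25,
            site_offsets={"a": 0.0, "b": 0.0}, seed=3,
        )
        subjects, pheno = generate_cohort(small_geometry, spec)
        means = np.array([_regional_means(fs) for fs in subjects])
        grp = pheno["group"].to_numpy().astype(bool)
        t, p = stats.ttest_ind(means[grp], means[~grp], axis=0)
        assert (p < 0.05).mean() < 0.25  # 20 regions, expect ~1 hit

    def test_injected_effect_dominates_t(self, small_geometry):
        """Affected regions carry the largest two-sample t on regional
        feature means, averaged over replicate seeds."""
        delta = np.zeros(20)
        affected = [2, 7, 11, 15]
        delta[affected] = 0.8
        ranks = []
        for seed in range(10):
            spec = CohortSpec(
                n_patients=20, n_controls=20, effect_map=delta, seed=seed
            )
            subjects, pheno = generate_cohort(small_geometry, spec)
            means = np.array([_regional_means(fs) for fs in subjects])
            grp = pheno["group"].to_numpy().astype(bool)
            t = stats.ttest_ind(means[grp], means[~grp], axis=0).statistic
            top4 = set(np.argsort(np.abs(t))[-4:])
            ranks.append(len(top4 & set(affected)))
        assert np.mean(ranks) >= 3.5

    def test_seeded_determinism(self, small_geometry):
        spec = CohortSpec(n_patients=3, n_controls=3, seed=11)
        s1, p1 = generate_cohort(small_geometry, spec)
        s2, p2 = generate_cohort(small_geometry, spec)
        assert np.array_equal(s1[0].features, s2[0].features)
        assert p1.equals(p2)

    def test_effect_map_dimension_mismatch(self, small_geometry):
        spec = CohortSpec(effect_map=np.zeros(7))
        with pytest.raises(ValueError, match="7"):
            generate_cohort(small_geometry, spec)

    def test_phenotype_schema(self, small_geometry):
        _, pheno = generate_cohort(
            small_geometry, CohortSpec(n_patients=2, n_controls=2)
        )
        assert list(pheno.columns) == [
            "subject_id", "group", "age", "sex", "site", "tiv",
            "fsiq", "inattention", "hyperactivity",
        ]
        assert set(pheno["group"]) == {0, 1}


class TestExpression:
    def test_white_noise_limit(self, small_geometry):
        truth = ExpressionTruth(autocorr_length=1e-6)
        expr = generate_expression(
            small_geometry, 200, truth,
            np.zeros(10) + np.arange(10), seed=0,
        )
        corr = np.corrcoef(expr.values)
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_no_signal_is_null_for_target(self, small_geometry, rng):
        target = rng.standard_normal(10)
        truth = ExpressionTruth(signal_gene_ids=(), autocorr_length=0.3)
        expr = generate_expression(small_geometry, 300, truth, target, seed=1)
        rhos = [
            stats.spearmanr(expr.values[:, j], target).statistic
            for j in range(300)
        ]
        assert abs(np.mean(rhos)) < 0.05

    def test_kernel_oracle_neighbor_correlation(self):
        """Empirical inter-region correlations match the exponential kernel
        evaluated at centroid distances (brute-force oracle)."""
        from mindnet.geometry import generate_parcellation

        g = generate_parcellation(40, 10, seed=0)
        left = g.hemisphere_regions("L")
        lam = 0.3
        truth = ExpressionTruth(autocorr_length=lam)
        expr = generate_expression(
            g, 4000, truth, np.zeros(len(left)), seed=2
        )
        emp = np.corrcoef(expr.values)
        cen = g.centroids[left]
        d = np.arccos(np.clip(cen @ cen.T, -1, 1))
        expect = np.exp(-d / lam)
        off = ~np.eye(len(left), dtype=bool)
        assert np.abs(emp[off] - expect[off]).mean() < 0.05

    def test_invalid_autocorr_length(self):
        with pytest.raises(ValueError):
            ExpressionTruth(autocorr_length=0.0)

    def test_target_map_length_checked(self, small_geometry):
        with pytest.raises(ValueError, match="left"):
            generate_expression(
                small_geometry, 10, ExpressionTruth(), np.zeros(3), seed=0
            )

    def test_signal_gene_alignment(self, small_geometry, rng):
        target = rng.standard_normal(10)
        truth = ExpressionTruth(
            signal_gene_ids=("G00000", "G00001"), signal_strength=2.0,
        )
        expr = generate_expression(small_geometry, 50, truth, target, seed=3)
        r = stats.spearmanr(expr.values[:, 0], target).statistic
        assert r > 0.5


class TestGeneSets:
    def test_deterministic_and_sized(self):
        universe = [f"G{i:05d}" for i in range(200)]
        truth = ExpressionTruth(signal_gene_ids=tuple(universe[:20]))
        a = generate_gene_sets(universe, truth, 5, 30, seed=9,
                               enrichment_ratio=4.0)
        b = generate_gene_sets(universe, truth, 5, 30, seed=9,
                               enrichment_ratio=4.0)
        assert a.sets == b.sets
        assert all(len(s) == 30 for s in a.sets.values())

    def test_enriched_set_composition(self):
        universe = [f"G{i:05d}" for i in range(200)]
        signal = set(universe[:20])
        truth = ExpressionTruth(signal_gene_ids=tuple(signal))
        coll = generate_gene_sets(universe, truth, 5, 30, seed=1,
                                  enrichment_ratio=5.0)
        # base rate 0.1, ratio 5 -> 15 of 30 members are signal genes
        assert len(coll.sets["SET01"] & signal) == 15
        res = overlap_permutation(
            coll.sets["SET01"], signal, universe, n_perm=500, seed=0
        )
        assert res.p_exact < 1e-6

    def test_impossible_ratio_rejected(self):
        universe = [f"G{i}" for i in range(100)]
        truth = ExpressionTruth(signal_gene_ids=tuple(universe[:5]))
        with pytest.raises(ValueError):
            generate_gene_sets(universe, truth, 3, 50, seed=0,
                               enrichment_ratio=10.0)

    def test_stage_region_grid_names(self):
        universe = [f"G{i}" for i in range(300)]
        truth = ExpressionTruth(signal_gene_ids=tuple(universe[:30]))
        grid = generate_stage_region_sets(
            universe, truth, n_stages=3, n_brain_regions=2, set_size=20,
            seed=0, enrichment_ratio=3.0, enriched_cell=("stage02", "regionB"),
        )
        assert len(grid.sets) == 6
        assert all("|" in name for name in grid.sets)


def test_spatial_covariance_positive_definite(small_geometry):
    cov = spatial_covariance(small_geometry.centroids, 0.5)
    np.linalg.cholesky(cov)  # raises if not PD


def test_effect_monotonicity(small_geometry):
    """Expected downstream |t| in an affected region grows with delta."""
    region = 4
    mean_abs_t = []
    for d in (0.0, 0.4, 0.8):
        delta = np.zeros(20)
        delta[region] = d
        ts = []
        for seed in range(10):
            spec = CohortSpec(
                n_patients=15, n_controls=15, effect_map=delta, seed=seed
            )
            subjects, pheno = generate_cohort(small_geometry, spec)
            means = np.array(
                [fs.region_vertices(region).mean() for fs in subjects]
            )
            grp = pheno["group"].to_numpy().astype(bool)
            ts.append(abs(stats.ttest_ind(means[grp], means[~grp]).statistic))
        mean_abs_t.append(np.mean(ts))
    assert mean_abs_t[0] < mean_abs_t[1] < mean_abs_t[2]


def test_multiplicative_site_scale(small_geometry):
    """Site scale factors multiply the feature variability."""
    spec = CohortSpec(
        n_patients=4, n_controls=4,
        site_offsets={"a": 0.0, "b": 0.0},
        site_scales={"a": 1.0, "b": 3.0},
        seed=0,
    )
    subjects, pheno = generate_cohort(small_geometry, spec)
    sds = {
        site: np.mean(
            [s.features.std() for s, st in zip(subjects, pheno["site"])
             if st == site]
        )
        for site in ("a", "b")
    }
    assert sds["b"] / sds["a"] == pytest.approx(3.0, rel=0.1)
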
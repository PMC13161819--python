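import numpy as np
import pytest

from mindnet.mind import (
    DegenerateFeatureError,
    InsufficientSampleError,
    MINDMatrix,
    RegionTooSmallError,
    VertexFeatureSet,
    compute_mind_matrix,
    js_divergence,
    knn_kl_divergence,
    mind_similarity,
    regional_and_global_mind,
    threshold_by_density,
    zscore_vertex_features,
)


def _feature_set(features, region_idx, n_regions):
    return VertexFeatureSet(
        subject_id="s",
        features=np.asarray(features, dtype=float),
        region_ids=np.array([f"r{i}" for i in range(n_regions)]),
        vertex_region_idx=np.asarray(region_idx),
    )


class TestZscore:
    def test_population_sd_convention(self):
        fs = _feature_set(
            np.column_stack([[1.0, 2.0, 3.0]] * 5), [0, 0, 1], 2
        )
        z = zscore_vertex_features(fs)
        expect = np.array([-1.2247448714, 0.0, 1.2247448714])
        assert np.allclose(z.features[:, 0], expect, atol=1e-9)
        assert z.standardized

    def test_idempotent(self, rng):
        fs = _feature_set(rng.normal(2, 3, (40, 5)), [0] * 20 + [1] * 20, 2)
        once = zscore_vertex_features(fs)
        twice = zscore_vertex_features(once)
        assert np.allclose(once.features, twice.features, atol=1e-9)

    def test_constant_column_names_offender(self, rng):
        x = rng.normal(0, 1, (30, 5))
        x[:, 2] = 7.0  # MC column dead
        with pytest.raises(DegenerateFeatureError, match="MC"):
            zscore_vertex_features(_feature_set(x, [0] * 30, 1))

    def test_nonfinite_rejected(self, rng):
        x = rng.normal(0, 1, (20, 5))
        x[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            zscore_vertex_features(_feature_set(x, [0] * 20, 1))


class TestKnnKL:
    def test_identical_gaussians_near_zero(self, rng):
        a = rng.normal(0, 1, (2000, 5))
        b = rng.normal(0, 1, (2000, 5))
        assert knn_kl_divergence(a, b, k=1) < 0.05

    @pytest.mark.parametrize(
        "mu2,sigma2,expected",
        [
            # KL(N(0,1) || N(mu,s^2)) closed forms
            (1.0, 1.0, 0.5),
            (0.0, 2.0, np.log(2) + 1.0 / 8 - 0.5),
        ],
    )
    def test_gaussian_closed_form(self, rng, mu2, sigma2, expected):
        a = rng.normal(0, 1, (5000, 1))
        b = rng.normal(mu2, sigma2, (5000, 1))
        est = knn_kl_divergence(a, b, k=1)
        assert abs(est - expected) / expected < 0.15

    def test_insufficient_sample(self, rng):
        with pytest.raises(InsufficientSampleError):
            knn_kl_divergence(rng.normal(0, 1, (3, 2)),
                              rng.normal(0, 1, (10, 2)), k=3)

    def test_consistency_error_shrinks_with_n(self, rng):
        """Estimator MAE against the closed form decreases with n."""
        for d in (1, 5):
            true = 0.5 * d  # mean shift of 1 per dimension
            maes = []
            for n in (500, 2000, 8000):
                errs = [
                    abs(
                        knn_kl_divergence(
                            rng.normal(0, 1, (n, d)),
                            rng.normal(1, 1, (n, d)),
                            k=1,
                        )
                        - true
                    )
                    for _ in range(5)
                ]
                maes.append(np.mean(errs))
            assert maes[2] < maes[0]


class TestMindSimilarity:
    def test_exchange_symmetry_exact(self, rng):
        a = rng.normal(0, 1, (200, 5))
        b = rng.normal(0.5, 1, (200, 5))
        assert mind_similarity(a, b) == mind_similarity(b, a)

    def test_monotone_in_separation(self, rng):
        base = rng.normal(0, 1, (800, 5))
        sims = [
            mind_similarity(base, rng.normal(mu, 1, (800, 5)))
            for mu in (0.0, 0.7, 1.5)
        ]
        assert sims[0] > sims[1] > sims[2]

    def test_transform_arithmetic(self):
        # 1/(1+D): D=0 -> 1, D=1 -> 0.5
        assert 1.0 / (1.0 + 0.0) == 1.0
        d_sym = 1.0
        assert 1.0 / (1.0 + d_sym) == 0.5
        # realized through the estimator: a sample against itself has
        # rho == nu so every log-ratio is 0 except the bias term
        x = np.arange(100.0).reshape(-1, 1)
        assert mind_similarity(x, x) >= 1.0 / (1.0 + np.log(100 / 99))


class TestMindMatrix:
    def test_matches_pairwise_estimator(self, rng):
        feats = rng.normal(0, 1, (8 * 40, 5))
        fs = zscore_vertex_features(
            _feature_set(feats, np.repeat(np.arange(8), 40), 8)
        )
        m = compute_mind_matrix(fs, k=2)
        for a in range(8):
            for b in range(a + 1, 8):
                direct = mind_similarity(
                    fs.region_vertices(a), fs.region_vertices(b), k=2
                )
                assert m.values[a, b] == pytest.approx(direct, abs=1e-12)

    def test_shape_symmetry_range(self, test_geometry, rng):
        feats = rng.normal(0, 1, (test_geometry.n_vertices, 5))
        fs = zscore_vertex_features(
            VertexFeatureSet(
                "s", feats, test_geometry.region_ids,
                test_geometry.vertex_region_idx,
            )
        )
        m = compute_mind_matrix(fs)
        assert m.values.shape == (60, 60)
        off = m.offdiag()
        assert ((off > 0) & (off <= 1)).all()
        assert np.isnan(np.diag(m.values)).all()

    def test_region_permutation_consistency(self, rng):
        feats = rng.normal(0, 1, (6 * 30, 5))
        idx = np.repeat(np.arange(6), 30)
        fs = zscore_vertex_features(_feature_set(feats, idx, 6))
        m = compute_mind_matrix(fs, k=2)
        perm = np.array([3, 1, 5, 0, 2, 4])
        fs_p = zscore_vertex_features(
            VertexFeatureSet(
                "s", feats,
                np.array([f"r{i}" for i in range(6)])[perm],
                np.argsort(perm)[idx],
            )
        )
        m_p = compute_mind_matrix(fs_p, k=2)
        assert np.allclose(
            m_p.values[np.ix_(np.argsort(perm), np.argsort(perm))],
            m.values, equal_nan=True,
        )

    def test_affine_invariance_via_standardization(self, rng):
        feats = rng.normal(0, 1, (5 * 50, 5))
        idx = np.repeat(np.arange(5), 50)
        m1 = compute_mind_matrix(
            zscore_vertex_features(_feature_set(feats, idx, 5)), k=2
        )
        m2 = compute_mind_matrix(
            zscore_vertex_features(
                _feature_set(feats * 3.7 - 11.0, idx, 5)
            ),
            k=2,
        )
        assert np.allclose(m1.values, m2.values, atol=1e-6, equal_nan=True)

    def test_region_too_small_lists_offenders(self, rng):
        feats = rng.normal(0, 1, (45, 5))
        idx = np.array([0] * 30 + [1] * 10 + [2] * 5)
        fs = zscore_vertex_features(_feature_set(feats, idx, 3))
        with pytest.raises(RegionTooSmallError, match="r2"):
            compute_mind_matrix(fs, min_vertices=10)

    def test_requires_standardization(self, rng):
        fs = _feature_set(
            rng.normal(0, 1, (60, 5)), np.repeat([0, 1], 30), 2
        )
        with pytest.raises(ValueError, match="z-scored"):
            compute_mind_matrix(fs)

    def test_js_mode_bounded(self, rng):
        feats = rng.normal(0, 1, (4 * 150, 5))
        fs = zscore_vertex_features(
            _feature_set(feats, np.repeat(np.arange(4), 150), 4)
        )
        m = compute_mind_matrix(fs, mode="js")
        off = m.offdiag()
        assert ((off >= 0) & (off <= 1)).all()
        # identical distributions: JS similarity well above the midpoint
        assert off.min() > 0.55


class TestProfiles:
    def test_constant_matrix(self):
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, np.nan)
        prof = regional_and_global_mind(
            MINDMatrix(values=v, region_ids=np.array(["a", "b", "c"]))
        )
        assert np.allclose(prof.regional_mind, 0.5)
        assert prof.global_mind == pytest.approx(0.5)

    def test_hand_mean(self):
        v = np.array(
            [[np.nan, 0.2, 0.4], [0.2, np.nan, 0.6], [0.4, 0.6, np.nan]]
        )
        prof = regional_and_global_mind(
            MINDMatrix(values=v, region_ids=np.array(["a", "b", "c"]))
        )
        assert prof.regional_mind[0] == pytest.approx(0.3)
        assert prof.global_mind == pytest.approx(
            np.mean(prof.regional_mind)
        )


class TestDensityThreshold:
    def _random_matrix(self, rng, n=6):
        w = rng.uniform(0.1, 1.0, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, np.nan)
        return MINDMatrix(
            values=w, region_ids=np.array([f"r{i}" for i in range(n)])
        )

    def test_identity_at_full_density(self, rng):
        m = self._random_matrix(rng)
        out = threshold_by_density(m, 1.0)
        assert np.allclose(out.values, m.values, equal_nan=True)

    def test_half_density_keeps_top_edges(self, rng):
        m = self._random_matrix(rng, n=4)
        out = threshold_by_density(m, 0.5)
        kept = out.offdiag()
        assert (kept > 0).sum() == 3  # ceil(0.5 * 6)
        # brute force: the survivors are the 3 strongest of the 6 weights
        top3 = set(np.sort(m.offdiag())[-3:])
        assert set(kept[kept > 0]) == top3

    def test_monotone_in_density(self, rng):
        m = self._random_matrix(rng)
        counts = [
            (threshold_by_density(m, d).offdiag() > 0).sum()
            for d in (0.2, 0.5, 0.8, 1.0)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("d", [0.0, -0.1, 1.5])
    def test_invalid_density(self, rng, d):
        with pytest.raises(ValueError):
            threshold_by_density(self._random_matrix(rng), d)
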
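import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mindnet.contrast import (
    DesignSpec,
    bh_fdr,
    bonferroni,
    build_design,
    fit_region_glm,
    network_aggregate,
    partial_spearman,
)


def _cohort_frame(rng, n_sub=60, n_reg=12, delta=None):
    subjects = [f"s{i:03d}" for i in range(n_sub)]
    group = np.repeat([1, 0], n_sub // 2)
    pheno = pd.DataFrame(
        {
            "subject_id": subjects,
            "group": group,
            "age": rng.uniform(8, 16, n_sub),
            "sex": rng.integers(0, 2, n_sub),
            "tiv": rng.normal(1500, 150, n_sub),
        }
    )
    y = rng.normal(0, 1, (n_reg, n_sub))
    if delta is not None:
        y += np.outer(delta, group)
    profiles = pd.DataFrame(
        y, index=[f"r{i}" for i in range(n_reg)], columns=subjects
    )
    return profiles, pheno


class TestRegionGLM:
    def test_reduces_to_two_sample_t_without_covariates(self, rng):
        profiles, pheno = _cohort_frame(rng, n_reg=1)
        design = DesignSpec(covariates=(), interactions=False)
        cm = fit_region_glm(profiles, pheno, design)
        g = pheno["group"].astype(bool).to_numpy()
        y = profiles.iloc[0].to_numpy()
        t_ref = stats.ttest_ind(y[g], y[~g]).statistic
        assert cm.t[0] == pytest.approx(t_ref, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        profiles, pheno = _cohort_frame(rng, n_reg=3)
        design = DesignSpec()
        cm = fit_region_glm(profiles, pheno, design)
        x, names = build_design(pheno, design)
        res = sm.OLS(profiles.iloc[1].to_numpy(), x).fit()
        assert cm.t[1] == pytest.approx(
            res.tvalues[names.index("group")], abs=1e-8
        )
        assert cm.p[1] == pytest.approx(
            res.pvalues[names.index("group")], abs=1e-10
        )

    def test_null_calibration(self, rng):
        profiles, pheno = _cohort_frame(rng, n_sub=100, n_reg=60)
        cm = fit_region_glm(profiles, pheno)
        frac = (cm.p < 0.05).mean()
        # binomial tolerance around 0.05 at 60 regions
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_orthogonal_covariate_leaves_group_t(self, rng):
        profiles, pheno = _cohort_frame(rng, n_reg=5)
        design0 = DesignSpec(covariates=(), interactions=False)
        t0 = fit_region_glm(profiles, pheno, design0).t
        # covariate orthogonalized against group (and intercept)
        z = rng.normal(0, 1, len(pheno))
        g = pheno["group"].to_numpy().astype(float)
        span = np.column_stack([np.ones_like(g), g])
        z = z - span @ np.linalg.lstsq(span, z, rcond=None)[0]
        pheno2 = pheno.assign(noise=z)
        design1 = DesignSpec(covariates=("noise",), interactions=False)
        t1 = fit_region_glm(profiles, pheno2, design1).t
        # group coefficient is untouched exactly; t moves only through the
        # residual df / variance estimate
        y = profiles.to_numpy().T
        x0, n0 = build_design(pheno, design0)
        x1, n1 = build_design(pheno2, design1)
        b0 = np.linalg.lstsq(x0, y, rcond=None)[0][n0.index("group")]
        b1 = np.linalg.lstsq(x1, y, rcond=None)[0][n1.index("group")]
        assert np.allclose(b0, b1, atol=1e-10)
        assert np.allclose(t0, t1, rtol=0.1)

    def test_sign_convention_patient_positive(self, rng):
        delta = np.zeros(6)
        delta[2] = 2.0
        profiles, pheno = _cohort_frame(rng, n_reg=6, delta=delta)
        cm = fit_region_glm(profiles, pheno)
        assert cm.t[2] > 3  # patients higher => positive t

    def test_permutation_consistency_of_p(self, rng):
        """Permutation |t| exceedance matches the parametric p for a null
        region (internal consistency)."""
        profiles, pheno = _cohort_frame(rng, n_sub=80, n_reg=1)
        design = DesignSpec(covariates=(), interactions=False)
        cm = fit_region_glm(profiles, pheno, design)
        count = 0
        n_perm = 200
        for i in range(n_perm):
            perm = pheno.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            t_p = fit_region_glm(profiles, perm, design).t[0]
            count += abs(t_p) >= abs(cm.t[0])
        p_perm = count / n_perm
        assert abs(p_perm - cm.p[0]) < 0.15

    def test_rank_deficient_design_named(self, rng):
        profiles, pheno = _cohort_frame(rng)
        pheno["tiv"] = pheno["age"] * 2.0
        with pytest.raises(ValueError, match="rank deficient"):
            fit_region_glm(
                profiles, pheno,
                DesignSpec(covariates=("age", "tiv"), interactions=False),
            )


class TestCorrections:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(np.array([0.5]), 308)[0] == 1.0
        assert bonferroni(np.array([1e-4]), 308)[0] == pytest.approx(0.0308)
        p = np.array([0.01, 0.2, 0.7])
        assert np.allclose(bonferroni(p, 1), p)

    def test_bh_stepup_hand_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_bh_equal_p_unchanged(self):
        q = bh_fdr(np.full(7, 0.03))
        assert np.allclose(q, 0.03)

    def test_bh_monotone_in_sorted_order(self, rng):
        p = rng.random(50)
        q = q_sorted = bh_fdr(p)[np.argsort(p)]
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_bonferroni_never_beats_bh(self, rng):
        p = rng.random(100) ** 2
        alpha = 0.05
        n_bonf = (bonferroni(p) < alpha).sum()
        n_bh = (bh_fdr(p) < alpha).sum()
        assert n_bonf <= n_bh


class TestNetworkAggregate:
    def test_constant_regions_constant_networks(self, rng):
        profiles, pheno = _cohort_frame(rng, n_reg=6)
        profiles.iloc[:, :] = 0.7
        profiles += rng.normal(0, 1e-6, profiles.shape)  # avoid zero var
        mapping = {r: f"net{i % 2}" for i, r in enumerate(profiles.index)}
        labels = pd.Series(mapping)
        means = profiles.groupby(labels).mean()
        assert np.allclose(means.to_numpy(), 0.7, atol=1e-5)

    def test_hand_computed_network_means(self):
        profiles = pd.DataFrame(
            {"s1": [1.0, 3.0, 2.0, 4.0]},
            index=["r0", "r1", "r2", "r3"],
        )
        mapping = {"r0": "A", "r1": "A", "r2": "B", "r3": "B"}
        labels = pd.Series(mapping)
        means = profiles.groupby(labels).mean()["s1"]
        assert means["A"] == 2.0 and means["B"] == 3.0

    def test_bonferroni_family_is_network_count(self, rng):
        profiles, pheno = _cohort_frame(rng, n_reg=14)
        mapping = {r: f"net{i % 7}" for i, r in enumerate(profiles.index)}
        cm = network_aggregate(profiles, mapping, pheno)
        assert len(cm.region_ids) == 7
        assert np.allclose(cm.p_bonf, np.minimum(1.0, 7 * cm.p))

    def test_unmapped_region_listed(self, rng):
        profiles, pheno = _cohort_frame(rng, n_reg=3)
        with pytest.raises(ValueError, match="r2"):
            network_aggregate(
                profiles, {"r0": "a", "r1": "a"}, pheno
            )


class TestPartialSpearman:
    def test_reduces_to_plain_spearman(self, rng):
        v = rng.normal(0, 1, 30)
        s = v + rng.normal(0, 1, 30)
        rho, p = partial_spearman(v, s)
        ref = stats.spearmanr(v, s)
        assert rho == pytest.approx(ref.statistic, abs=1e-10)

    def test_matches_brute_force_residualized_ranks(self, rng):
        n = 10
        v = rng.normal(0, 1, n)
        s = rng.normal(0, 1, n)
        z = rng.normal(0, 1, (n, 2))
        rho, _ = partial_spearman(v, s, z)
        # brute force: rank, regress out [1, z], correlate residuals
        rv, rs = stats.rankdata(v), stats.rankdata(s)
        zi = np.column_stack([np.ones(n), z])
        proj = zi @ np.linalg.inv(zi.T @ zi) @ zi.T
        res_v, res_s = rv - proj @ rv, rs - proj @ rs
        expect = np.corrcoef(res_v, res_s)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-10)

    def test_null_p_calibrated(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            z = rng.normal(0, 1, (40, 1))
            v = z[:, 0] + rng.normal(0, 1, 40)
            s = z[:, 0] + rng.normal(0, 1, 40)  # related only through z
            _, p = partial_spearman(v, s, z)
            hits += p < 0.05
        assert 0.01 < hits / n_rep < 0.11

    def test_constant_score_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(rng.normal(0, 1, 12), np.ones(12))


def test_clinical_associations_batch_fdr(rng):
    """Per-region partial Spearman with a clinical score, BH across
    regions; a region coupled to the score is detected."""
    from mindnet.contrast import clinical_associations

    profiles, pheno = _cohort_frame(rng, n_sub=80, n_reg=10)
    pheno = pheno.assign(inattention=rng.normal(15, 4, 80))
    profiles.iloc[3] = (
        0.2 * pheno["inattention"].to_numpy() + rng.normal(0, 0.3, 80)
    )
    out = clinical_associations(
        profiles, pheno, "inattention", covariates=("age", "sex")
    )
    assert list(out.columns) == ["region_id", "rho", "p", "q"]
    assert out.loc[out["region_id"] == "r3", "q"].iloc[0] < 0.05
    assert (out["q"] >= out["p"] - 1e-12).all()
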
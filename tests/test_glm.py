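"""Voxelwise GLM, permutation maxT FWE, clusters, ROIs and power maps."""

import itertools
import math

import numpy as np
import pytest
from scipy import ndimage, stats

from iterlesion.glm import (Contrast, MassUnivariateGLM, build_design_matrix,
                            cluster_level_fwe, default_contrast,
                            fit_voxelwise_glm, permutation_maxT_fwe,
                            power_map, threshold_and_extract_rois,
                            DESIGN_COLUMNS)
from iterlesion.lesion_io import AnalysisMask, build_analysis_mask, overlap_map

from conftest import GRID, make_cohort


def brute_force_t(X, y, c):
    """Independent OLS oracle from the normal equations."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - np.linalg.matrix_rank(X)
    sigma2 = resid @ resid / df
    return (c @ beta) / math.sqrt(sigma2 * (c @ XtX_inv @ c)), df


class TestDesignMatrix:
    def test_shape_and_columns(self, rng):
        cohort = make_cohort(10, rng)
        d = build_design_matrix(cohort)
        assert d.X.shape == (10, 7)
        assert d.columns == DESIGN_COLUMNS
        np.testing.assert_array_equal(d.X[:, -1], 1.0)

    def test_identical_scores_for_two_patients_ok(self, rng):
        cohort = make_cohort(10, rng)
        cohort.patients[1].scores = cohort.patients[0].scores
        build_design_matrix(cohort)  # no error

    def test_constant_column_raises(self, rng):
        from conftest import make_scores
        cohort = make_cohort(10, rng)
        same = make_scores()
        for p in cohort.patients:
            p.scores = same  # composite constant -> collinear with intercept
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(cohort)

    def test_lesion_volume_column_matches_lesion_io(self, rng):
        cohort = make_cohort(8, rng)
        d = build_design_matrix(cohort, center=False)
        np.testing.assert_allclose(d.X[:, 5], cohort.lesion_volumes())

    def test_centering_does_not_change_t(self, rng):
        cohort = make_cohort(12, rng)
        mask = build_analysis_mask(overlap_map(cohort), min_overlap=1)
        ctr = default_contrast()
        t1 = fit_voxelwise_glm(cohort, build_design_matrix(cohort, True),
                               ctr, mask).t
        t2 = fit_voxelwise_glm(cohort, build_design_matrix(cohort, False),
                               ctr, mask).t
        np.testing.assert_allclose(t1[mask.include], t2[mask.include],
                                   atol=1e-9)


class TestVoxelwiseOLS:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [6, 8])
    def test_matches_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        X = np.column_stack([rng.normal(size=(n, 3)), np.ones(n)])
        Y = rng.normal(size=(n, 5))
        c = np.array([-1.0, 0.0, 0.0, 0.0])
        est = MassUnivariateGLM(contrast=list(c), n_perm=0).fit(X, Y)
        for v in range(Y.shape[1]):
            t_ref, df_ref = brute_force_t(X, Y[:, v], c)
            assert est.t_[v] == pytest.approx(t_ref, abs=1e-10)
            assert est.df_ == df_ref

    def test_constant_lesion_values_degenerate(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=(8, 2)), np.ones(8)])
        Y = np.full((8, 1), 0.7)  # zero residual variance, zero effect
        est = MassUnivariateGLM(contrast=[1, 0, 0], n_perm=0).fit(X, Y)
        assert est.t_[0] == 0.0 or np.isinf(est.t_[0])
        assert est.p_unc_[0] in (0.0, 1.0) or 0 <= est.p_unc_[0] <= 1

    def test_perfect_fit_gives_infinite_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        X = np.column_stack([x, np.ones(10)])
        Y = (2.0 * x)[:, None]  # exactly linear in the regressor
        est = MassUnivariateGLM(contrast=[1, 0], n_perm=0).fit(X, Y)
        assert np.isinf(est.t_[0]) and est.t_[0] > 0
        assert est.p_unc_[0] == 0.0

    def test_singular_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="singular"):
            MassUnivariateGLM(contrast=[1, 0], n_perm=0).fit(
                X, np.zeros((6, 1)))

    def test_null_p_values_roughly_uniform(self):
        # lesion values independent of all regressors
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.normal(size=(60, 3)), np.ones(60)])
        Y = rng.normal(size=(60, 400))
        est = MassUnivariateGLM(contrast=[1, 0, 0, 0],
                                alternative="two-sided", n_perm=0).fit(X, Y)
        ks = stats.kstest(est.p_unc_, "uniform")
        assert ks.pvalue > 0.01
        assert np.abs(est.t_).mean() < 2.0

    def test_orthogonal_noise_column_changes_t_by_df_only(self):
        rng = np.random.default_rng(3)
        n = 12
        X = np.column_stack([rng.normal(size=(n, 2)), np.ones(n)])
        y = rng.normal(size=(n, 1))
        # a column orthogonal to the design AND the data: only df changes
        extra = rng.normal(size=n)
        basis = np.linalg.qr(np.column_stack([X, y]))[0]
        extra -= basis @ (basis.T @ extra)
        c0 = [1.0, 0.0, 0.0]
        est0 = MassUnivariateGLM(contrast=c0, n_perm=0).fit(X, y)
        est1 = MassUnivariateGLM(contrast=c0 + [0.0], n_perm=0).fit(
            np.column_stack([X, extra]), y)
        ratio = math.sqrt(est1.df_ / est0.df_)
        assert est1.t_[0] == pytest.approx(est0.t_[0] * ratio, rel=1e-9)


class TestPermutationMaxT:
    def _tiny_problem(self, seed=0, n=5, v=4):
        rng = np.random.default_rng(seed)
        X = np.column_stack([rng.normal(size=n), np.ones(n)])
        Y = rng.normal(size=(n, v)) + 0.5 * X[:, [0]]
        return X, Y

    def exhaustive_oracle(self, X, Y, c):
        """Freedman-Lane maxT by explicit enumeration, independent code path."""
        n = len(X)
        c = np.asarray(c, float)
        Z = X[:, c == 0]
        Hz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        fitted, resid = Hz @ Y, Y - Hz @ Y
        t_obs = np.array([brute_force_t(X, Y[:, v], c)[0]
                          for v in range(Y.shape[1])])
        max_ts = []
        for perm in itertools.permutations(range(n)):
            Ystar = fitted + resid[list(perm)]
            ts = [brute_force_t(X, Ystar[:, v], c)[0]
                  for v in range(Y.shape[1])]
            max_ts.append(max(ts))
        max_ts = np.array(max_ts)
        p = np.array([(max_ts >= t).sum() / len(max_ts) for t in t_obs])
        return t_obs, p

    def test_exhaustive_enumeration_matches_oracle_exactly(self):
        X, Y = self._tiny_problem()
        c = [1.0, 0.0]
        t_ref, p_ref = self.exhaustive_oracle(X, Y, c)
        est = MassUnivariateGLM(contrast=c, n_perm=5000,
                                random_state=1).fit(X, Y)
        assert est.exhaustive_
        assert est.n_perm_used_ == math.factorial(5)
        np.testing.assert_allclose(est.t_, t_ref, atol=1e-10)
        np.testing.assert_array_equal(est.p_fwe_, p_ref)

    def test_montecarlo_request_above_n_factorial_falls_back(self):
        X, Y = self._tiny_problem(seed=4)
        a = MassUnivariateGLM(contrast=[1, 0], n_perm=120,
                              random_state=0).fit(X, Y)
        b = MassUnivariateGLM(contrast=[1, 0], n_perm=99999,
                              random_state=99).fit(X, Y)
        assert a.exhaustive_ and b.exhaustive_
        np.testing.assert_array_equal(a.p_fwe_, b.p_fwe_)  # seed-independent

    def test_p_fwe_floor_and_ordering(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=30), np.ones(30)])
        Y = rng.normal(size=(30, 50))
        est = MassUnivariateGLM(contrast=[1, 0], n_perm=200,
                                random_state=0).fit(X, Y)
        assert np.all(est.p_fwe_ >= 1.0 / 201.0)
        assert np.all(est.p_fwe_ >= est.p_unc_ - 1e-12)
        # monotone non-increasing in t
        order = np.argsort(est.t_)
        assert np.all(np.diff(est.p_fwe_[order]) <= 1e-12)

    def test_same_seed_reproduces_p_fwe(self, rng):
        cohort = make_cohort(20, rng)
        mask = build_analysis_mask(overlap_map(cohort), min_overlap=2)
        d = build_design_matrix(cohort)
        sm1 = permutation_maxT_fwe(cohort, d, default_contrast(), mask,
                                   n_perm=50, seed=9)
        sm2 = permutation_maxT_fwe(cohort, d, default_contrast(), mask,
                                   n_perm=50, seed=9)
        np.testing.assert_array_equal(sm1.p_fwe[mask.include],
                                      sm2.p_fwe[mask.include])


class TestClusters:
    def _statmap_with_blobs(self, rng):
        """Cohort engineered so two disjoint blobs carry a strong effect."""
        from conftest import make_patient, make_scores
        from iterlesion.cohort import Cohort
        patients = []
        for i in range(24):
            affected = i < 12
            # background blobs above the binarization threshold so lesion
            # volume varies independently of the effect
            vals = rng.random(GRID) * 0.45
            if affected:
                vals[1:3, 1:3, 1:3] = 0.95   # blob A
                vals[5:7, 5:7, 5:7] = 0.95   # blob B, disjoint from A
            comp = 50.0 if affected else 75.0
            sc = make_scores(spk=comp + rng.normal(0, 2),
                             wri=comp - 7 + rng.normal(0, 2),
                             rep=61 + rng.normal(0, 3),
                             sem=59 + rng.normal(0, 3),
                             csp=61 + rng.normal(0, 3),
                             cop=60 + rng.normal(0, 3))
            patients.append(make_patient(f"p{i:02d}", np.clip(vals, 0, 1), sc))
        cohort = Cohort(patients)
        mask = build_analysis_mask(overlap_map(cohort), min_overlap=1)
        sm = permutation_maxT_fwe(cohort, build_design_matrix(cohort),
                                  default_contrast(), mask, n_perm=200,
                                  seed=3)
        return sm

    def test_two_disjoint_blobs_found_with_oracle_sizes(self, rng):
        sm = self._statmap_with_blobs(rng)
        cs = cluster_level_fwe(sm)
        # independent connected-components oracle on the supra-threshold set
        d = np.nan_to_num(sm.t, nan=-np.inf)
        supra = sm.mask.include & (d > sm.perm.t_forming_)
        lab, nlab = ndimage.label(supra, structure=np.ones((3, 3, 3)))
        sizes = sorted(np.bincount(lab.ravel())[1:], reverse=True)
        assert len(cs) == nlab
        assert sorted((c.n_voxels for c in cs.clusters), reverse=True) == sizes
        assert len(cs) >= 2
        # sorted by peak statistic descending
        peaks = [c.peak_t for c in cs.clusters]
        assert peaks == sorted(peaks, reverse=True)

    def test_single_voxel_cluster(self):
        # hand-built: one supra-threshold voxel
        rng = np.random.default_rng(11)
        from conftest import make_patient, make_scores
        from iterlesion.cohort import Cohort
        patients = []
        for i in range(16):
            affected = i < 8
            vals = rng.random(GRID) * 0.45
            if affected:
                vals[4, 4, 4] = 1.0
            comp = 50.0 if affected else 75.0
            sc = make_scores(spk=comp + rng.normal(0, 2),
                             wri=comp - 7 + rng.normal(0, 2),
                             rep=61 + rng.normal(0, 3),
                             sem=59 + rng.normal(0, 3),
                             csp=61 + rng.normal(0, 3),
                             cop=60 + rng.normal(0, 3))
            patients.append(make_patient(f"p{i:02d}", np.clip(vals, 0, 1), sc))
        cohort = Cohort(patients)
        mask = AnalysisMask(include=np.zeros(GRID, dtype=bool))
        mask.include[4, 4, 4] = True
        mask.include[0, 0, 0] = True
        sm = permutation_maxT_fwe(cohort, build_design_matrix(cohort),
                                  default_contrast(), mask, n_perm=100,
                                  seed=0)
        cs = cluster_level_fwe(sm)
        assert len(cs) == 1
        assert cs.clusters[0].n_voxels == 1
        assert cs.clusters[0].peak_ijk == (4, 4, 4)

    def test_no_suprathreshold_voxels_empty_clusterset(self, rng):
        cohort = make_cohort(20, rng)  # scores independent of lesions
        mask = build_analysis_mask(overlap_map(cohort), min_overlap=2)
        sm = permutation_maxT_fwe(cohort, build_design_matrix(cohort),
                                  default_contrast(), mask, n_perm=60,
                                  seed=2)
        cs = cluster_level_fwe(sm)
        assert (len(cs) == 0) == (not (np.nan_to_num(sm.t, nan=-np.inf)
                                       [mask.include]
                                       > sm.perm.t_forming_).any())

    def test_roi_extraction_rules(self, rng):
        sm = self._statmap_with_blobs(rng)
        cs = cluster_level_fwe(sm)
        rois_v = threshold_and_extract_rois(sm, cs, alpha=0.05, rule="voxel")
        sig = sm.mask.include & (np.nan_to_num(sm.p_fwe, nan=1) <= 0.05)
        np.testing.assert_array_equal(rois_v.union_mask(), sig)
        rois_c = threshold_and_extract_rois(sm, cs, alpha=0.05, rule="cluster")
        expected = np.zeros(GRID, dtype=bool)
        for c in cs.clusters:
            if c.cluster_p_fwe <= 0.05:
                expected |= (cs.labels == c.label)
        np.testing.assert_array_equal(rois_c.union_mask(), expected)

    def test_all_nonsignificant_gives_empty_roiset(self, rng):
        cohort = make_cohort(20, rng)
        mask = build_analysis_mask(overlap_map(cohort), min_overlap=2)
        sm = permutation_maxT_fwe(cohort, build_design_matrix(cohort),
                                  default_contrast(), mask, n_perm=60, seed=4)
        sm.p_fwe = np.where(np.isnan(sm.p_fwe), np.nan, 1.0)  # force null
        rois = threshold_and_extract_rois(sm, cluster_level_fwe(sm),
                                          alpha=0.05, rule="voxel")
        assert rois.is_empty()


class TestPowerMap:
    def test_extreme_overlap_counts_not_powered(self, rng):
        from conftest import make_patient, make_scores
        from iterlesion.cohort import Cohort
        vals_all = np.ones(GRID)
        vals_none = np.zeros(GRID)

        def varied(pid, vals):
            sc = make_scores(spk=70 + rng.normal(0, 8),
                             wri=63 + rng.normal(0, 8))
            return make_patient(pid, vals, sc, kind="binary")

        mask = AnalysisMask(include=np.ones(GRID, dtype=bool))
        cohort = Cohort([varied(f"p{i}", vals_all if i < 6 else vals_none)
                         for i in range(12)])
        # every voxel lesioned in exactly 6/12 patients -> contrast exists
        pm = power_map(cohort, mask, critical_t=0.0)
        assert pm.powered.all()
        all_lesioned = Cohort([varied(f"q{i}", vals_all) for i in range(8)])
        assert not power_map(all_lesioned, mask,
                             critical_t=0.0).powered.any()   # k = n
        none_lesioned = Cohort([varied(f"r{i}", vals_none) for i in range(8)])
        assert not power_map(none_lesioned, mask,
                             critical_t=0.0).powered.any()   # k = 0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_best_assignment_matches_exhaustive_oracle(self, k, rng):
        """Assigning the k lowest scores to the lesioned group maximises t
        over all possible assignments (checked by enumeration at n=6)."""
        n = 6
        scores = rng.normal(70, 8, size=n)

        def two_sample_t(group):
            g = np.zeros(n, dtype=bool)
            g[list(group)] = True
            a, b = scores[g], scores[~g]
            sp2 = (((a - a.mean()) ** 2).sum()
                   + ((b - b.mean()) ** 2).sum()) / (n - 2)
            return (b.mean() - a.mean()) / math.sqrt(
                sp2 * (1 / len(a) + 1 / len(b)))

        best_brute = max(two_sample_t(gr)
                         for gr in itertools.combinations(range(n), k))
        sorted_assign = two_sample_t(np.argsort(scores)[:k])
        assert sorted_assign == pytest.approx(best_brute, abs=1e-12)


class TestContrast:
    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            Contrast(weights=(0.0,) * 7)

    def test_default_contrast_targets_composite(self):
        c = default_contrast()
        assert c.as_array()[0] == -1.0
        assert c.alternative == "greater"
        assert np.count_nonzero(c.as_array()) == 1
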
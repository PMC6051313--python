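"""Unit tests for masking, double centering, PCA and score projection."""

import numpy as np
import pytest

from ssmpca.core import (
    Mask,
    ScanImage,
    build_common_mask,
    compute_srp,
    project_score,
    run_pca,
    select_top_variance,
)

from conftest import toy_scan


class TestCommonMask:
    def test_two_identical_scans_give_single_scan_mask(self, rng):
        vol = rng.uniform(1, 10, (8, 8, 8))
        a, b = ScanImage("a", vol), ScanImage("b", vol.copy())
        mask = build_common_mask([a, b], 0.35)
        np.testing.assert_array_equal(mask.keep, vol >= 0.35 * vol.max())

    def test_threshold_is_per_scan_maximum(self):
        # voxel at 40 passes scan A's threshold (0.35*100) but fails scan
        # B's (0.35*200), so the intersection drops it
        base = np.full((8, 8, 8), 50.0)
        a = base.copy()
        a[0, 0, 0], a[1, 1, 1] = 100.0, 40.0
        b = base.copy()
        b[0, 0, 0], b[1, 1, 1] = 200.0, 40.0
        mask = build_common_mask([ScanImage("a", a), ScanImage("b", b)], 0.35)
        assert not mask.keep[1, 1, 1]
        assert mask.keep[0, 0, 0]

    def test_empty_intersection_names_fraction(self):
        a = np.ones((8, 8, 8))
        a[0, 0, 0] = 100.0
        b = np.ones((8, 8, 8))
        b[7, 7, 7] = 100.0
        with pytest.raises(ValueError, match="0.9"):
            build_common_mask([ScanImage("a", a), ScanImage("b", b)], 0.9)

    def test_dim_mismatch_names_subject(self, rng):
        a = ScanImage("a", rng.uniform(1, 2, (8, 8, 8)))
        b = ScanImage("oddball", rng.uniform(1, 2, (8, 8, 9)))
        with pytest.raises(ValueError, match="oddball"):
            build_common_mask([a, b], 0.35)


class TestSRP:
    def test_hand_worked_two_by_two(self):
        # intensities [[e, e^2], [e^2, e^4]] -> logs [[1,2],[2,4]];
        # row-center -> [[-.5,.5],[-1,1]]; GMP = [-.75,.75];
        # SRP = [[.25,-.25],[-.25,.25]]
        e = np.e
        scans = [toy_scan([[e, e**2]], "a"), toy_scan([[e**2, e**4]], "b")]
        mask = Mask(np.ones((1, 2, 1), dtype=bool))
        srp = compute_srp(scans, mask)
        np.testing.assert_allclose(srp.values, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)
        np.testing.assert_allclose(srp.group_mean_profile, [-0.75, 0.75], atol=1e-12)

    def test_double_centering_row_and_column_sums(self, small_srp):
        tol = 1e-8 * small_srp.mask.n_voxels
        assert np.abs(small_srp.values.sum(axis=1)).max() < tol
        assert np.abs(small_srp.values.sum(axis=0)).max() < tol

    def test_global_rescaling_leaves_srp_unchanged(self, small_cohort):
        _, scans, _, table = small_cohort
        mask = build_common_mask(scans, 0.35)
        srp0 = compute_srp(scans, mask)
        scaled = [
            ScanImage(s.subject_id, s.voxels * (5.0 if i == 3 else 1.0))
            for i, s in enumerate(scans)
        ]
        srp1 = compute_srp(scaled, build_common_mask(scaled, 0.35))
        np.testing.assert_allclose(srp1.values, srp0.values, atol=1e-10)

    def test_nonpositive_masked_intensity_identifies_subject(self):
        a = toy_scan(np.full((8, 8), 2.0), "a")
        bad = np.full((8, 8), 2.0)
        bad[2, 2] = 0.0
        b = toy_scan(bad, "badsub")
        mask = Mask(np.ones((8, 8, 1), dtype=bool))
        with pytest.raises(ValueError, match="badsub"):
            compute_srp([a, b], mask)


class TestPCA:
    def test_rank_one_input_has_full_vaf(self, rng):
        v = rng.normal(size=50)
        v -= v.mean()
        coeffs = np.array([1.0, -2.0, 0.5, 0.5])
        coeffs -= coeffs.mean()
        srp = np.outer(coeffs, v)
        pca = run_pca(srp)
        assert len(pca.vaf) == 1
        np.testing.assert_allclose(pca.vaf, [1.0], atol=1e-12)

    def test_components_orthonormal_and_reconstruct(self, small_srp):
        pca = run_pca(small_srp)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(len(pca.vaf)), atol=1e-8)
        recon = pca.subject_loadings @ pca.components
        np.testing.assert_allclose(recon, small_srp.values, atol=1e-8)
        assert np.all(np.diff(pca.vaf) <= 1e-12)
        assert pca.vaf.sum() <= 1 + 1e-9

    def test_matches_dense_svd_oracle_up_to_sign(self, rng):
        srp = rng.normal(size=(10, 120))
        srp -= srp.mean(axis=1, keepdims=True)
        srp -= srp.mean(axis=0)
        pca = run_pca(srp)
        u, s, vt = np.linalg.svd(srp, full_matrices=False)
        # the double centering leaves at most n-1 non-null components
        k = len(pca.vaf)
        assert k == 9
        for j in range(k):
            sign = np.sign(vt[j] @ pca.components[j])
            np.testing.assert_allclose(pca.components[j], sign * vt[j], atol=1e-6)
            np.testing.assert_allclose(pca.subject_loadings[:, j], sign * u[:, j] * s[j], atol=1e-6)
        np.testing.assert_allclose(pca.vaf, (s**2 / (s**2).sum())[:k], atol=1e-9)

    def test_subject_space_dual_path_agrees(self, small_srp):
        """Eigendecomposition of the small subjects x subjects covariance must
        reproduce the voxel-space loadings and vaf (the duality that licenses
        the efficient path)."""
        pca = run_pca(small_srp)
        x = small_srp.values
        evals, evecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(evals)[::-1][: len(pca.vaf)]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(evals / np.sum(x**2), pca.vaf, atol=1e-9)
        for k in range(len(pca.vaf)):
            dual_loading = evecs[:, k] * np.sqrt(evals[k])
            sign = np.sign(dual_loading @ pca.subject_loadings[:, k])
            np.testing.assert_allclose(
                pca.subject_loadings[:, k], sign * dual_loading, atol=1e-6
            )

    def test_subject_permutation_permutes_rows_only(self, small_srp):
        pca = run_pca(small_srp)
        perm = np.random.default_rng(0).permutation(small_srp.values.shape[0])
        pca_p = run_pca(small_srp.values[perm])
        np.testing.assert_allclose(pca_p.vaf, pca.vaf, atol=1e-9)
        for k in range(len(pca.vaf)):
            sign = np.sign(pca_p.components[k] @ pca.components[k])
            np.testing.assert_allclose(pca_p.components[k], sign * pca.components[k], atol=1e-6)
            np.testing.assert_allclose(
                pca_p.subject_loadings[:, k], sign * pca.subject_loadings[perm, k], atol=1e-6
            )

    def test_all_zero_srp_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.zeros((5, 30)))


class TestSelectTopVariance:
    @pytest.mark.parametrize(
        "vaf, threshold, expected",
        [
            ([0.30, 0.15, 0.10, 0.08, 0.37], 0.5, [0, 1, 2]),  # cumulative 0.55
            ([0.60, 0.40], 0.5, [0]),
            ([0.25, 0.25, 0.25], 0.5, [0, 1]),  # exact tie includes the reaching one
            ([0.2, 0.1], 0.5, [0, 1]),  # total short of threshold -> all
        ],
    )
    def test_prefix_selection(self, vaf, threshold, expected):
        from ssmpca.core import PCAResult

        vaf = np.asarray(vaf)
        pca = PCAResult(components=np.eye(len(vaf)), subject_loadings=np.eye(len(vaf)), vaf=vaf)
        assert select_top_variance(pca, threshold) == expected


class TestProjectScore:
    def test_new_scan_path_equals_srp_row_projection(self, small_cohort, small_srp):
        _, scans, _, _ = small_cohort
        pattern = small_srp.values[0] / np.linalg.norm(small_srp.values[0])
        for i in (0, 5, len(scans) - 1):
            via_scan = project_score(
                scans[i], pattern, small_srp.mask, small_srp.group_mean_profile
            )
            via_row = small_srp.values[i] @ pattern
            assert via_scan == pytest.approx(via_row, abs=1e-10)

    def test_scan_equal_to_gmp_scores_zero(self, small_srp):
        vol = np.ones(small_srp.mask.keep.shape)
        vol[small_srp.mask.keep] = np.exp(small_srp.group_mean_profile + 3.0)
        pattern = np.zeros(small_srp.mask.n_voxels)
        pattern[0] = 1.0
        score = project_score(ScanImage("g", vol), pattern, small_srp.mask,
                              small_srp.group_mean_profile)
        assert score == pytest.approx(0.0, abs=1e-10)

    def test_collinear_residual_gives_its_amplitude(self, small_srp, rng):
        pattern = rng.normal(size=small_srp.mask.n_voxels)
        pattern -= pattern.mean()  # zero-mean so the row-centering is inert
        pattern /= np.linalg.norm(pattern)
        vol = np.ones(small_srp.mask.keep.shape)
        vol[small_srp.mask.keep] = np.exp(small_srp.group_mean_profile + 2.0 * pattern)
        score = project_score(ScanImage("c", vol), pattern, small_srp.mask,
                              small_srp.group_mean_profile)
        assert score == pytest.approx(2.0, abs=1e-8)

    def test_dimension_mismatch_rejected(self, small_srp):
        with pytest.raises(ValueError):
            project_score(
                ScanImage("x", np.ones((9, 9, 9))),
                np.zeros(small_srp.mask.n_voxels),
                small_srp.mask,
                small_srp.group_mean_profile,
            )
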
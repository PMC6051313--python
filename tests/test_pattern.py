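"""Tests of stepwise-AIC component selection and pattern combination."""

import itertools

import numpy as np
import pytest

from ssmpca.core import PCAResult, build_common_mask, compute_srp
from ssmpca.pattern import (
    combine_pattern,
    control_reference,
    derive_pattern,
    fit_logistic,
    stepwise_logistic_aic,
    zscore_scores,
)
from ssmpca.synthetic import CohortParams, simulate_cohort


def _loadings_cohort(sep, seed, informative=2, n_cand=7):
    rng = np.random.default_rng(seed)
    labels = np.r_[np.zeros(16), np.ones(17)]
    load = rng.normal(0, 1, (33, n_cand))
    load[:, informative] = labels * sep + rng.normal(0, 1, 33)
    return load, labels


def _exhaustive_aic(load, labels):
    best = (np.inf, ())
    for r in range(load.shape[1] + 1):
        for sub in itertools.combinations(range(load.shape[1]), r):
            aic = fit_logistic(load[:, list(sub)], labels).aic
            if aic < best[0] - 1e-10:
                best = (aic, sub)
    return best


class TestStepwiseAIC:
    def test_strongly_informative_candidate_always_enters(self):
        for seed in range(2000, 2020):
            load, labels = _loadings_cohort(4.0, seed)
            sel, _, _ = stepwise_logistic_aic(load, labels)
            assert 2 in sel

    def test_null_candidates_keep_models_small(self):
        sizes = []
        for seed in range(3000, 3050):
            rng = np.random.default_rng(seed)
            load = rng.normal(0, 1, (33, 7))
            labels = np.r_[np.zeros(16), np.ones(17)]
            sel, _, _ = stepwise_logistic_aic(load, labels)
            sizes.append(len(sel))
        # AIC's 2-per-parameter penalty keeps null selections sparse
        assert np.mean(sizes) < 2.5
        assert 0 in sizes

    def test_perfect_separation_falls_back_to_single_component(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.zeros(10), np.ones(10)]
        load = rng.normal(0, 1, (20, 3))
        load[:, 1] = labels * 50 + rng.normal(0, 0.1, 20)  # separates alone
        sel, coefs, info = stepwise_logistic_aic(load, labels)
        assert sel == [1]
        assert info["separated"]
        assert info["fallback"] == "separating_single_component"
        assert np.all(np.isfinite(coefs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stepwise_logistic_aic(np.ones((5, 2)), np.ones(5))


class TestCombinePattern:
    def _pca(self, k=3, v=40, seed=0):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(v, k)))
        return PCAResult(components=q.T, subject_loadings=np.eye(k), vaf=np.full(k, 1 / k))

    def test_single_component_unit_scaling(self):
        pca = self._pca()
        w = combine_pattern(pca, [1], np.array([4.0]))
        np.testing.assert_allclose(w, pca.components[1], atol=1e-12)

    def test_norm_before_renormalization_is_pythagorean(self):
        pca = self._pca()
        raw = np.array([1.0, 2.5]) @ pca.components[[0, 1]]
        assert np.linalg.norm(raw) == pytest.approx(np.sqrt(1 + 6.25), abs=1e-12)
        w = combine_pattern(pca, [0, 1], np.array([1.0, 2.5]))
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)

    def test_zero_combination_rejected(self):
        pca = self._pca()
        with pytest.raises(ValueError):
            combine_pattern(pca, [0], np.array([0.0]))


class TestZScores:
    def test_definition_and_control_normalization(self):
        raw = np.array([1.0, 3.0, 5.0, 2.0, 9.0])
        labels = np.array([0, 0, 0, 0, 1])
        ref = control_reference(raw, labels)
        scores = zscore_scores(raw, ref)
        z = np.array([s.z for s in scores])
        ctrl = z[:4]
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-10)
        assert ctrl.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        # a value at mean + 2 SD maps to z = 2
        probe = zscore_scores([ref[0] + 2 * ref[1]], ref)[0]
        assert probe.z == pytest.approx(2.0, abs=1e-12)

    def test_constant_controls_rejected(self):
        with pytest.raises(ValueError):
            control_reference(np.array([1.0, 1.0, 5.0]), np.array([0, 0, 1]))


class TestDerivePattern:
    def test_recovers_embedded_pattern(self):
        for seed in (1, 2):
            scans, truth, table = simulate_cohort(CohortParams(seed=seed))
            labels = table["label"].to_numpy()
            mask = build_common_mask(scans, 0.35)
            srp = compute_srp(scans, mask, labels)
            model, raw = derive_pattern(srp)
            r = np.corrcoef(model.weights, truth.pattern[mask.keep])[0, 1]
            assert abs(r) >= 0.9

    def test_patients_score_higher_sign_convention(self, small_cohort):
        _, scans, _, table = small_cohort
        labels = table["label"].to_numpy()
        mask = build_common_mask(scans, 0.35)
        srp = compute_srp(scans, mask, labels)
        model, raw = derive_pattern(srp)
        assert raw[labels == 1].mean() > raw[labels == 0].mean()

    def test_pattern_invariant_to_global_rescaling(self, small_cohort):
        from ssmpca.core import ScanImage

        _, scans, _, table = small_cohort
        labels = table["label"].to_numpy()
        rng = np.random.default_rng(0)
        factors = rng.uniform(0.5, 2.0, len(scans))
        scaled = [ScanImage(s.subject_id, s.voxels * f) for s, f in zip(scans, factors)]

        def weights(scan_list):
            mask = build_common_mask(scan_list, 0.35)
            srp = compute_srp(scan_list, mask, labels)
            return derive_pattern(srp)[0].weights

        np.testing.assert_allclose(weights(scaled), weights(scans), atol=1e-6)

    def test_separation_monotone_in_effect_size(self):
        seps = []
        for effect in (0.0, 1.0, 2.0, 3.0):
            scans, truth, table = simulate_cohort(
                CohortParams(grid_dims=(12, 12, 12), effect_size=effect, seed=42)
            )
            labels = table["label"].to_numpy()
            mask = build_common_mask(scans, 0.35)
            srp = compute_srp(scans, mask, labels)
            model, raw = derive_pattern(srp)
            ref = model.control_ref
            z = (raw - ref[0]) / ref[1]
            seps.append(z[labels == 1].mean() - z[labels == 0].mean())
        assert all(b >= a - 1e-9 for a, b in zip(seps, seps[1:]))
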
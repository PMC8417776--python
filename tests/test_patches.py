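import numpy as np
import pytest

import lesionquant as lq
from lesionquant.patches import (
    NotFittedError,
    PatchClassifier,
    SingleClassError,
    build_grid,
    extract_features,
    features_for_grid,
    features_for_patches,
    predict_probs,
)
from lesionquant.synthetic import LabeledPatchSet


def _all_tissue(h, w):
    return np.ones((h, w), dtype=bool)


class TestBuildGrid:
    def test_exact_tiling(self):
        g = build_grid((100, 100), _all_tissue(100, 100), patch_size=50, stride=50,
                       min_tissue_frac=0.5)
        assert sorted(map(tuple, g.origins)) == [(0, 0), (0, 50), (50, 0), (50, 50)]

    def test_flush_position_appended(self):
        # positions {0, 30, 60} per axis; 60 + 40 = 100 is already flush
        g = build_grid((100, 100), _all_tissue(100, 100), patch_size=40, stride=30,
                       min_tissue_frac=0.5)
        assert len(g) == 9
        assert set(g.origins[:, 0]) == {0, 30, 60}

    def test_flush_position_added_when_missing(self):
        g = build_grid((70, 70), _all_tissue(70, 70), patch_size=40, stride=25,
                       min_tissue_frac=0.0)
        assert set(g.origins[:, 0]) == {0, 25, 30}  # 70 - 40 = 30 appended

    def test_empty_tissue_mask_gives_no_origins(self):
        g = build_grid((100, 100), np.zeros((100, 100), bool), patch_size=50,
                       stride=50, min_tissue_frac=0.5)
        assert len(g) == 0

    def test_origins_inside_image_and_sorted(self):
        rng = np.random.default_rng(0)
        mask = rng.random((97, 83)) < 0.6
        g = build_grid((97, 83), mask, patch_size=16, stride=7, min_tissue_frac=0.3)
        assert np.all(g.origins[:, 0] + 16 <= 97)
        assert np.all(g.origins[:, 1] + 16 <= 83)
        order = np.lexsort((g.origins[:, 1], g.origins[:, 0]))
        assert np.array_equal(order, np.arange(len(g)))

    def test_full_coverage_when_tau_zero_and_overlap(self):
        h, w, p, s = 90, 110, 16, 8
        g = build_grid((h, w), _all_tissue(h, w), patch_size=p, stride=s,
                       min_tissue_frac=0.0)
        cov = np.zeros((h, w), dtype=int)
        for r, c in g.origins:
            cov[r : r + p, c : c + p] += 1
        assert cov.min() >= 1

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            build_grid((30, 30), _all_tissue(30, 30), patch_size=40, stride=10,
                       min_tissue_frac=0.0)


class TestFeatures:
    def test_constant_patch_has_zero_spread_and_gradients(self):
        f = extract_features(np.full((8, 8, 3), 37, dtype=np.uint8))
        assert np.allclose(f[1::4], 0)  # SDs
        assert np.allclose(f[2::4], 0)  # horizontal gradient energy
        assert np.allclose(f[3::4], 0)  # vertical gradient energy

    def test_checkerboard_gradients(self):
        patch = np.zeros((8, 8, 3), dtype=np.uint8)
        rr, cc = np.mgrid[0:8, 0:8]
        patch[(rr + cc) % 2 == 0, 0] = 255  # 1-px checkerboard in R only
        f = extract_features(patch)
        assert f[0] == pytest.approx(127.5)  # R mean
        assert f[2] == pytest.approx(255.0)  # every horizontal pair differs by 255
        assert f[3] == pytest.approx(255.0)

    def test_feature_vector_length(self):
        assert extract_features(np.zeros((8, 8, 3))).shape == (12,)

    def test_vectorized_matches_single_patch(self, rng):
        patches = rng.integers(0, 256, size=(20, 8, 8, 3)).astype(np.uint8)
        batch = features_for_patches(patches)
        for i in range(20):
            assert np.allclose(batch[i], extract_features(patches[i]))

    def test_grid_features_match_patch_slicing(self, rng):
        img = rng.integers(0, 256, size=(64, 80, 3)).astype(np.uint8)
        g = build_grid((64, 80), _all_tissue(64, 80), patch_size=8, stride=8,
                       min_tissue_frac=0.0)
        feats = features_for_grid(img, g)
        for i in [0, 7, len(g) // 2, len(g) - 1]:
            r, c = g.origins[i]
            assert np.allclose(feats[i], extract_features(img[r : r + 8, c : c + 8]),
                               atol=1e-8)


class TestClassifier:
    def test_training_accuracy_on_separable_textures(self, classifier):
        assert classifier.train_accuracy >= 0.99

    def test_fit_is_deterministic(self, patch_set):
        c1 = lq.fit_classifier(patch_set)
        c2 = lq.fit_classifier(patch_set)
        assert np.array_equal(c1.weights, c2.weights)
        assert c1.intercept == c2.intercept

    def test_duplicating_training_rows_leaves_fit_unchanged(self, patch_set):
        doubled = LabeledPatchSet(
            np.concatenate([patch_set.patches, patch_set.patches]),
            np.concatenate([patch_set.labels, patch_set.labels]),
            patch_set.purity,
        )
        c1 = lq.fit_classifier(patch_set)
        c2 = lq.fit_classifier(doubled)
        assert np.allclose(c1.weights, c2.weights, atol=1e-6)
        assert c1.intercept == pytest.approx(c2.intercept, abs=1e-6)

    def test_single_class_rejected(self, patch_set):
        ones = LabeledPatchSet(
            patch_set.patches, np.zeros_like(patch_set.labels), patch_set.purity
        )
        with pytest.raises(SingleClassError):
            lq.fit_classifier(ones)

    def test_pure_lesion_prototype_scores_high(self, patch_set, classifier):
        lesion_patches = patch_set.patches[patch_set.labels == 1]
        probs = classifier.predict_prob(lesion_patches[:10])
        assert np.all(probs > 0.9)

    def test_probabilities_in_unit_interval(self, classifier, rng):
        patches = rng.integers(0, 256, size=(50, 8, 8, 3)).astype(np.uint8)
        probs = classifier.predict_prob(patches)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_prediction_invariant_to_patch_order(self, classifier, rng):
        patches = rng.integers(0, 256, size=(30, 8, 8, 3)).astype(np.uint8)
        perm = rng.permutation(30)
        assert np.allclose(
            classifier.predict_prob(patches)[perm], classifier.predict_prob(patches[perm])
        )

    def test_affine_channel_map_absorbed_by_standardization(self, patch_set):
        """Mapping every patch x -> a*x + b (a > 0) before fit+predict leaves
        predictions unchanged: standardization cancels the map."""
        raw = patch_set.patches.astype(np.float64)
        mapped = LabeledPatchSet(0.5 * raw + 20.0, patch_set.labels, patch_set.purity)
        c_raw = lq.fit_classifier(patch_set)
        c_map = lq.fit_classifier(mapped)
        p_raw = c_raw.predict_prob(raw[:40])
        p_map = c_map.predict_prob(0.5 * raw[:40] + 20.0)
        assert np.allclose(p_raw, p_map, atol=1e-6)

    def test_matches_sklearn_logistic_cross_check(self, patch_set):
        """Same objective fitted by sklearn (C = 1/(n*reg)) agrees."""
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        feats = features_for_patches(patch_set.patches)
        mu, sd = feats.mean(axis=0), feats.std(axis=0)
        x = (feats - mu) / np.where(sd > 0, sd, 1.0)
        reg = 1e-3
        skl = sklearn_lm.LogisticRegression(
            C=1.0 / (len(x) * reg), solver="lbfgs", tol=1e-10, max_iter=5000
        ).fit(x, patch_set.labels)
        ours = lq.fit_classifier(patch_set, reg_strength=reg)
        p_skl = skl.predict_proba(x)[:, 1]
        p_ours = ours.predict_prob(patch_set.patches)
        assert np.max(np.abs(p_skl - p_ours)) < 0.01

    def test_unfitted_classifier_refuses_to_predict(self):
        clf = PatchClassifier()
        with pytest.raises(NotFittedError):
            clf.predict_prob(np.zeros((1, 8, 8, 3)))

    def test_json_round_trip(self, classifier, rng, tmp_path):
        path = tmp_path / "clf.json"
        classifier.save(path)
        loaded = PatchClassifier.load(path)
        patches = rng.integers(0, 256, size=(10, 8, 8, 3)).astype(np.uint8)
        assert np.allclose(classifier.predict_prob(patches), loaded.predict_prob(patches))


class TestPredictProbs:
    def test_one_probability_per_origin(self, classifier, training_slide):
        image, gt = training_slide
        g = build_grid(image.shape[:2], gt.tissue_mask, patch_size=8, stride=16,
                       min_tissue_frac=0.5)
        probs = predict_probs(g, image, classifier)
        assert probs.shape == (len(g),)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_empty_grid_gives_empty_list(self, classifier):
        g = build_grid((64, 64), np.zeros((64, 64), bool), patch_size=8, stride=8,
                       min_tissue_frac=0.5)
        assert predict_probs(g, np.zeros((64, 64, 3), np.uint8), classifier).size == 0

    def test_patch_size_mismatch_rejected(self, classifier):
        g = build_grid((64, 64), _all_tissue(64, 64), patch_size=16, stride=16,
                       min_tissue_frac=0.0)
        with pytest.raises(ValueError):
            predict_probs(g, np.zeros((64, 64, 3), np.uint8), classifier)
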
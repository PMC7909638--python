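"""Feature bank, pixel-classifier and mean-threshold contracts."""

import numpy as np
import pytest

import shellproxy as sp
from shellproxy.segmentation import DEFAULT_SCALES


def _two_phase_image(rng, shape=(96, 96), lo=0.2, hi=0.8):
    """Noiseless image of bright blobs on a dark background + truth mask."""
    img = np.full(shape, lo)
    truth = np.zeros(shape, dtype=bool)
    from skimage.draw import disk

    for _ in range(15):
        rr, cc = disk(
            (rng.integers(10, shape[0] - 10), rng.integers(10, shape[1] - 10)),
            rng.integers(3, 7),
            shape=shape,
        )
        img[rr, cc] = hi
        truth[rr, cc] = True
    return img, truth


def _labels_from(truth, rng, n=12):
    """Sparse single-pixel labels: n per class."""
    lab = np.zeros(truth.shape, dtype=np.uint8)
    fg = np.argwhere(truth)
    bg = np.argwhere(~truth)
    for cls, coords in ((1, fg), (2, bg)):
        picks = coords[rng.choice(len(coords), size=n, replace=False)]
        # keep picks isolated so each is its own labeled region
        for r, c in picks:
            lab[r, c] = cls
    return lab


class TestFeatureStack:
    def test_constant_image_has_zero_derivative_features(self):
        stack = sp.compute_feature_stack(np.full((32, 32), 0.5))
        by_name = dict(zip(stack.names, np.moveaxis(stack.features, -1, 0)))
        for name, plane in by_name.items():
            if "gradient" in name or "laplacian" in name:
                assert np.allclose(plane, 0.0, atol=1e-10), name

    def test_feature_count_is_raw_plus_families_times_scales(self):
        stack = sp.compute_feature_stack(np.zeros((16, 16)))
        assert stack.n_features == 1 + 5 * len(DEFAULT_SCALES) == 26

    def test_step_edge_gradient_peaks_on_edge(self):
        # vertical step edge: gradient magnitude maximal at the step column,
        # cross-checked against brute-force finite differences
        img = np.zeros((40, 40))
        img[:, 20:] = 1.0
        stack = sp.compute_feature_stack(img, scales=(1.0,))
        grad = stack.features[..., stack.names.index("gradient_magnitude_s1.0")]
        brute = np.abs(np.diff(img, axis=1))  # finite differences peak at 19/20
        assert abs(int(np.argmax(grad[20])) - int(np.argmax(brute[20]))) <= 1

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sp.compute_feature_stack(np.zeros((8, 8)), scales=(0.0,))


class TestPixelClassifier:
    def test_separable_phases_classified_almost_perfectly(self, rng):
        img, truth = _two_phase_image(rng)
        clf = sp.train_pixel_classifier([img], [_labels_from(truth, rng)], seed=0)
        mask = sp.predict_mask(clf, img)
        acc = (mask.mask == truth).mean()
        assert acc >= 0.99

    def test_matches_optimal_intensity_threshold(self, rng):
        # equivalence oracle: on intensity-separable images the classifier
        # agrees with the optimal threshold on at least 99% of pixels
        img, truth = _two_phase_image(rng)
        clf = sp.train_pixel_classifier([img], [_labels_from(truth, rng)], seed=0)
        mask = sp.predict_mask(clf, img)
        by_threshold = img > 0.5  # midpoint of the two phases
        assert (mask.mask == by_threshold).mean() >= 0.99

    def test_too_few_label_regions_rejected(self, rng):
        img, truth = _two_phase_image(rng)
        with pytest.raises(ValueError, match="entity"):
            sp.train_pixel_classifier([img], [_labels_from(truth, rng, n=9)], seed=0)

    def test_missing_class_rejected(self, rng):
        img, truth = _two_phase_image(rng)
        lab = _labels_from(truth, rng)
        lab[lab == 2] = 0
        with pytest.raises(ValueError, match="background"):
            sp.train_pixel_classifier([img], [lab], seed=0)

    def test_same_seed_identical_predictions(self, rng):
        img, truth = _two_phase_image(rng)
        lab = _labels_from(truth, rng)
        m1 = sp.predict_mask(sp.train_pixel_classifier([img], [lab], seed=5), img)
        m2 = sp.predict_mask(sp.train_pixel_classifier([img], [lab], seed=5), img)
        assert np.array_equal(m1.mask, m2.mask)

    def test_resubstitution_accuracy_on_labels(self, rng):
        img, truth = _two_phase_image(rng)
        lab = _labels_from(truth, rng)
        clf = sp.train_pixel_classifier([img], [lab], seed=0)
        mask = sp.predict_mask(clf, img)
        labeled = lab > 0
        pred_cls = np.where(mask.mask, 1, 2)
        assert (pred_cls[labeled] == lab[labeled]).mean() >= 0.95

    def test_blank_image_predicts_all_background(self, rng):
        img, truth = _two_phase_image(rng)
        clf = sp.train_pixel_classifier([img], [_labels_from(truth, rng)], seed=0)
        mask = sp.predict_mask(clf, np.full(img.shape, 0.2))
        assert not mask.mask.any()

    def test_untrained_classifier_refused(self):
        from sklearn.ensemble import RandomForestClassifier

        clf = sp.PixelClassifier(model=RandomForestClassifier(), scales=DEFAULT_SCALES)
        with pytest.raises(ValueError, match="trained"):
            sp.predict_mask(clf, np.zeros((8, 8)))

    def test_classifier_serialization_roundtrip(self, rng, tmp_path):
        img, truth = _two_phase_image(rng)
        clf = sp.train_pixel_classifier([img], [_labels_from(truth, rng)], seed=0)
        sp.save_classifier(clf, tmp_path / "c.pkl")
        back = sp.load_classifier(tmp_path / "c.pkl")
        assert np.array_equal(sp.predict_mask(back, img).mask, sp.predict_mask(clf, img).mask)


def _img(arr):
    return sp.SEMImage(pixels=np.asarray(arr, dtype=float), pixel_area=0.0003)


class TestMeanThreshold:
    def test_half_and_half_gives_50_percent(self):
        arr = np.zeros((10, 10))
        arr[:5] = 1.0
        masks, thr = sp.binarize_mean_threshold(_img(arr))
        assert thr == pytest.approx(0.5)
        assert sp.coverage(masks[0]) == pytest.approx(50.0)

    def test_constant_image_all_black(self):
        # strictly-greater-than comparison: ties go to black
        masks, _ = sp.binarize_mean_threshold(_img(np.full((8, 8), 0.3)))
        assert masks[0].mask.sum() == 0

    def test_4x4_matrix_threshold_and_count(self):
        arr = np.array(
            [[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8], [0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]]
        )
        masks, thr = sp.binarize_mean_threshold(_img(arr))
        assert thr == pytest.approx(arr.mean()) == pytest.approx(0.45)
        assert int(masks[0].mask.sum()) == 8

    def test_batch_threshold_is_pooled_mean(self):
        a, b = _img(np.full((4, 4), 0.2)), _img(np.full((4, 4), 0.8))
        masks, thr = sp.binarize_mean_threshold([a, b])
        assert thr == pytest.approx(0.5)
        assert masks[0].mask.sum() == 0 and masks[1].mask.all()

    def test_per_image_mode(self):
        a, b = _img(np.full((4, 4), 0.2)), _img(np.full((4, 4), 0.8))
        masks, thr = sp.binarize_mean_threshold([a, b], per_image=True)
        assert thr == [pytest.approx(0.2), pytest.approx(0.8)]
        assert masks[0].mask.sum() == 0 and masks[1].mask.sum() == 0

    def test_affine_rescaling_invariance(self, rng):
        # jointly rescaling all images leaves the batch masks unchanged
        imgs = [_img(rng.random((16, 16))) for _ in range(3)]
        rescaled = [_img(0.5 * im.pixels + 0.2) for im in imgs]
        m1, _ = sp.binarize_mean_threshold(imgs)
        m2, _ = sp.binarize_mean_threshold(rescaled)
        for a, b in zip(m1, m2):
            assert np.array_equal(a.mask, b.mask)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            sp.binarize_mean_threshold([])


class TestCoverage:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            (np.ones((5, 5), dtype=bool), 100.0),
            (np.zeros((5, 5), dtype=bool), 0.0),
        ],
    )
    def test_extremes(self, mask, expected):
        assert sp.coverage(mask) == expected

    def test_fraction(self):
        m = np.zeros((3, 4), dtype=bool)
        m.ravel()[:3] = True
        assert sp.coverage(m) == pytest.approx(25.0)

    def test_monotone_in_white_pixels(self, rng):
        m = rng.random((20, 20)) > 0.5
        grown = m.copy()
        grown[0, 0] = True
        assert sp.coverage(grown) >= sp.coverage(m)

    def test_exclusion_mask(self):
        m = np.ones((4, 4), dtype=bool)
        excl = np.zeros((4, 4), dtype=bool)
        excl[:2] = True
        assert sp.coverage(m, exclusion=excl) == 100.0
        with pytest.raises(ValueError, match="excluded"):
            sp.coverage(m, exclusion=np.ones((4, 4), dtype=bool))
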
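"""Method 1: flattening, undersampling, boosted-tree training and tuning."""

import numpy as np
import pytest

from hsinucdb import seg_spectral as s1
from hsinucdb.containers import BACKGROUND, BORDER, NUCLEI, HyperCube


def _cube(data, **meta):
    data = np.asarray(data, dtype=float)
    return HyperCube(data=data, wavelengths_nm=np.arange(data.shape[2], dtype=float), meta=meta)


def _gaussian_table(n_per_class, n_bands=8, sep=5.0, seed=0):
    """Two spherical Gaussians sep standard deviations apart."""
    rng = np.random.default_rng(seed)
    bg = rng.standard_normal((n_per_class, n_bands))
    nuc = rng.standard_normal((n_per_class, n_bands)) + sep / np.sqrt(n_bands)
    spectra = np.vstack([bg, nuc])
    labels = np.array([BACKGROUND] * n_per_class + [NUCLEI] * n_per_class)
    origin = np.zeros((2 * n_per_class, 3), dtype=int)
    return s1.PixelTable(spectra=spectra, labels=labels, origin=origin)


class TestFlatten:
    def test_raster_order(self):
        data = np.arange(2 * 2 * 3).reshape(2, 2, 3)
        table = s1.flatten_cube(_cube(data))
        assert table.spectra.shape == (4, 3)
        np.testing.assert_array_equal(table.spectra[1], data[0, 1])
        np.testing.assert_array_equal(table.origin[:, 1:], [[0, 0], [0, 1], [1, 0], [1, 1]])

    def test_border_pixels_become_background(self):
        mask = np.array([[BACKGROUND, BORDER], [NUCLEI, NUCLEI]])
        table = s1.flatten_cube(_cube(np.zeros((2, 2, 3))), mask)
        np.testing.assert_array_equal(table.labels, [BACKGROUND, BACKGROUND, NUCLEI, NUCLEI])

    def test_nuclei_fraction_matches_mask(self, tumor_truth):
        cube = _cube(tumor_truth.ideal_cube)
        table = s1.flatten_cube(cube, tumor_truth.class_mask)
        frac_table = (table.labels == NUCLEI).mean()
        frac_mask = (tumor_truth.class_mask == NUCLEI).mean()
        assert frac_table == pytest.approx(frac_mask)

    def test_shape_mismatch_raises(self):
        with pytest.raises(Exception):
            s1.flatten_cube(_cube(np.zeros((2, 2, 3))), np.zeros((3, 3), dtype=int))


class TestBalance:
    def test_majority_subsampled_to_minority(self):
        rng = np.random.default_rng(0)
        table = s1.PixelTable(
            spectra=rng.random((110, 4)),
            labels=np.array([BACKGROUND] * 100 + [NUCLEI] * 10),
            origin=np.zeros((110, 3), dtype=int),
        )
        out = s1.undersample_balance(table, seed=1)
        assert out.class_counts() == {BACKGROUND: 10, NUCLEI: 10}

    def test_balanced_counts_rule_on_study_numbers(self):
        # full-scale training-table bookkeeping: 35,643,517 background and
        # 6,234,563 nuclei signatures balance to 6,234,563 each
        out = s1.balanced_class_counts({"background": 35_643_517, "nuclei": 6_234_563})
        assert out["background"] == 6_234_563
        assert out["nuclei"] == 6_234_563
        assert out["total"] == 12_469_126

    def test_already_balanced_unchanged(self):
        table = _gaussian_table(50)
        out = s1.undersample_balance(table, seed=0)
        assert out.class_counts() == table.class_counts()

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        table = s1.PixelTable(
            spectra=rng.random((60, 4)),
            labels=np.array([BACKGROUND] * 50 + [NUCLEI] * 10),
            origin=np.zeros((60, 3), dtype=int),
        )
        a = s1.undersample_balance(table, seed=5)
        b = s1.undersample_balance(table, seed=5)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_absent_class_raises(self):
        table = s1.PixelTable(
            spectra=np.zeros((5, 4)),
            labels=np.full(5, BACKGROUND),
            origin=np.zeros((5, 3), dtype=int),
        )
        with pytest.raises(s1.ClassAbsentError):
            s1.undersample_balance(table)


class TestClassifier:
    def test_separable_spectra_trained_to_high_accuracy(self):
        table = _gaussian_table(200, sep=5.0)
        model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=50), seed=0)
        acc = (model.predict(table.spectra) == (table.labels == NUCLEI)).mean()
        assert acc >= 0.99

    def test_empty_or_single_class_raises(self):
        empty = s1.PixelTable(
            spectra=np.zeros((0, 4)), labels=np.zeros(0, dtype=int),
            origin=np.zeros((0, 3), dtype=int),
        )
        with pytest.raises(Exception):
            s1.train_pixel_classifier(empty)
        single = s1.PixelTable(
            spectra=np.zeros((5, 4)), labels=np.full(5, NUCLEI),
            origin=np.zeros((5, 3), dtype=int),
        )
        with pytest.raises(s1.ClassAbsentError):
            s1.train_pixel_classifier(single)

    def test_same_data_and_seed_identical_predictions(self):
        table = _gaussian_table(100, sep=2.0)
        cube = _cube(np.random.default_rng(1).random((6, 6, 8)))
        maps = []
        for _ in range(2):
            model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=30), seed=4)
            maps.append(s1.predict_pixel_map(model, cube))
        np.testing.assert_array_equal(maps[0], maps[1])

    def test_prediction_map_shape_and_classes(self):
        table = _gaussian_table(100)
        model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=30), seed=0)
        cube = _cube(np.random.default_rng(2).random((5, 7, 8)))
        seg = s1.predict_pixel_map(model, cube)
        assert seg.shape == (5, 7)
        assert set(np.unique(seg)) <= {BACKGROUND, NUCLEI}

    def test_band_mismatch_raises(self):
        table = _gaussian_table(50, n_bands=8)
        model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=10), seed=0)
        with pytest.raises(Exception):
            s1.predict_pixel_map(model, _cube(np.zeros((4, 4, 5))))


class TestQualitativeBehaviour:
    def test_null_phantom_low_false_positive_rate(self):
        """A nucleus-free cube yields at most a noise-level nuclei fraction."""
        from hsinucdb import phantom as ph

        spec = ph.PhantomSpec(height=96, width=96, n_bands=8, tissue_class="tumor", seed=1)
        truth = ph.make_phantom_scene(spec)
        table = s1.undersample_balance(
            s1.flatten_cube(_cube(truth.ideal_cube), truth.class_mask), seed=0
        )
        model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=100), seed=0)
        empty = ph.make_phantom_scene(
            ph.PhantomSpec(height=96, width=96, n_bands=8, nucleus_density=0.0, seed=2)
        )
        rng = np.random.default_rng(3)
        noisy = empty.ideal_cube + 0.01 * rng.standard_normal(empty.ideal_cube.shape)
        seg = s1.predict_pixel_map(model, _cube(noisy))
        assert (seg == NUCLEI).mean() <= 0.05

    def test_overlapping_spectra_produce_isolated_speckles(self):
        """With heavy noise relative to class separation, pixel-wise
        prediction fragments into small false components that the smooth
        elliptical ground truth never contains."""
        from scipy import ndimage

        from hsinucdb import phantom as ph

        spec = ph.PhantomSpec(
            height=128, width=128, n_bands=8, tissue_class="tumor",
            seed=5, noise_sd=0.12,
        )
        truth = ph.make_phantom_scene(spec)
        rng = np.random.default_rng(6)
        noisy = np.clip(
            truth.ideal_cube + spec.noise_sd * rng.standard_normal(truth.ideal_cube.shape),
            0.0, 1.0,
        )
        table = s1.undersample_balance(
            s1.flatten_cube(_cube(noisy), truth.class_mask), seed=0
        )
        model = s1.train_pixel_classifier(table, s1.BoostParams(n_estimators=100), seed=0)
        noisy2 = np.clip(
            truth.ideal_cube + spec.noise_sd * rng.standard_normal(truth.ideal_cube.shape),
            0.0, 1.0,
        )
        seg = s1.predict_pixel_map(model, _cube(noisy2))

        def small_components(mask):
            labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
            if n == 0:
                return 0
            areas = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
            return int((areas <= 3).sum())

        assert small_components(truth.class_mask == NUCLEI) == 0
        assert small_components(seg == NUCLEI) > 0


class TestTuning:
    def _val_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        bg = rng.standard_normal((8, 8, 8))
        nuc = bg + 5.0 / np.sqrt(8)
        mask = np.zeros((8, 8), dtype=int)
        mask[2:6, 2:6] = NUCLEI
        data = np.where(mask[..., None] == NUCLEI, nuc, bg)
        return _cube(data), mask

    def test_single_point_space_returned(self):
        table = _gaussian_table(100)
        space = s1.BoostSearchSpace(
            n_estimators=(30, 30), max_depth=(5, 5), learning_rate=(0.1, 0.1), n_trials=1
        )
        best, history = s1.tune_pixel_classifier(space, table, [self._val_pair()])
        assert best.n_estimators == 30
        assert best.max_depth == 5
        assert len(history) == 1

    def test_best_at_least_first_trial(self):
        table = _gaussian_table(100)
        space = s1.BoostSearchSpace(n_estimators=(10, 60), max_depth=(5, 8),
                                    learning_rate=(0.05, 0.3), n_trials=4, seed=1)
        best, history = s1.tune_pixel_classifier(space, table, [self._val_pair()])
        best_dsc = max(h["nuclei_dsc"] for h in history)
        assert best_dsc >= history[0]["nuclei_dsc"]

    def test_patient_overlap_rejected(self):
        table = _gaussian_table(50)
        space = s1.BoostSearchSpace(n_trials=1)
        with pytest.raises(Exception):
            s1.tune_pixel_classifier(
                space, table, [self._val_pair()],
                train_patients={"P1"}, val_patients={"P1", "P2"},
            )

    def test_study_final_values_inside_search_ranges(self):
        assert s1.FULLSCALE_TUNED_PARAMS.validate_in_search_space(s1.BoostSearchSpace())
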
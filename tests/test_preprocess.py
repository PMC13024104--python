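"""Six-step preprocessing chain: calibration, stitching, correction,
registration, normalization, RGB synthesis, and the full round trip."""

import numpy as np
import pytest

from hsinucdb import phantom as ph
from hsinucdb import preprocess as pp
from hsinucdb.containers import HyperCube


def _cube(data, wavelengths=None):
    data = np.asarray(data, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(data.shape[2], dtype=float)
    return HyperCube(data=data, wavelengths_nm=wavelengths)


class TestCalibration:
    def _raw(self, frame_value, sensor):
        frames = np.full((3, sensor.n_rows, 80), frame_value, dtype=np.uint8)
        return ph.RawScanSequence(frames=frames, sensor=sensor)

    def test_frame_equal_white_gives_one(self, sensor):
        white = np.full((sensor.n_rows, 80), 250, dtype=np.uint8)
        dark = np.full((sensor.n_rows, 80), 50, dtype=np.uint8)
        refs = ph.ReferencePair(white=white, dark=dark)
        out = pp.calibrate_frames(self._raw(250, sensor), refs)
        np.testing.assert_allclose(out, 1.0)

    def test_frame_equal_dark_gives_zero(self, sensor):
        refs = ph.ReferencePair(
            white=np.full((sensor.n_rows, 80), 250, dtype=np.uint8),
            dark=np.full((sensor.n_rows, 80), 50, dtype=np.uint8),
        )
        out = pp.calibrate_frames(self._raw(50, sensor), refs)
        np.testing.assert_allclose(out, 0.0)

    def test_midpoint_arithmetic(self, sensor):
        refs = ph.ReferencePair(
            white=np.full((sensor.n_rows, 80), 250, dtype=np.uint8),
            dark=np.full((sensor.n_rows, 80), 50, dtype=np.uint8),
        )
        out = pp.calibrate_frames(self._raw(150, sensor), refs)
        np.testing.assert_allclose(out, 0.5)

    def test_dead_pixels_set_to_zero(self, sensor):
        white = np.full((sensor.n_rows, 80), 250, dtype=np.uint8)
        dark = np.full((sensor.n_rows, 80), 50, dtype=np.uint8)
        white[0, 0] = dark[0, 0] = 77
        refs = ph.ReferencePair(white=white, dark=dark)
        out = pp.calibrate_frames(self._raw(150, sensor), refs)
        assert out[0, 0, 0] == 0.0
        assert out[0, 1, 1] == 0.5

    def test_shape_mismatch_raises(self, sensor):
        refs = ph.ReferencePair(
            white=np.full((sensor.n_rows, 40), 250, dtype=np.uint8),
            dark=np.full((sensor.n_rows, 40), 50, dtype=np.uint8),
        )
        with pytest.raises(pp.CalibrationError):
            pp.calibrate_frames(self._raw(150, sensor), refs)

    def test_calibration_invariant_to_affine_lighting(self, sensor, references, tumor_truth):
        """Eq.-1 identity: doubling illumination leaves transmittance fixed."""
        raw = ph.render_linescan_frames(tumor_truth, sensor, references, noise_sd=0.0)
        out1 = pp.calibrate_frames(raw, references)
        assert out1.min() >= 0.0


class TestStitch:
    def test_identity_sensor_stacks_frames(self):
        sensor = ph.SensorModel(
            n_virtual_bands=3, n_spectral_bands=3,
            row_to_band=[0, 1, 2], row_offset=[0, 0, 0],
            wavelength_grid=[470.0, 600.0, 890.0],
        )
        frames = np.arange(4 * 3 * 5, dtype=float).reshape(4, 3, 5)
        cube = pp.stitch(frames, sensor)
        assert cube.data.shape == (4, 5, 3)
        for v in range(3):
            np.testing.assert_array_equal(cube.data[:, :, v], frames[:, v, :])

    def test_too_few_frames_raises(self, sensor):
        frames = np.zeros((sensor.max_offset, sensor.n_rows, 8))
        with pytest.raises(pp.StitchError):
            pp.stitch(frames, sensor)

    def test_roundtrip_recovers_virtual_cube(self, sensor, references, tumor_truth):
        raw = ph.render_linescan_frames(tumor_truth, sensor, references, noise_sd=0.0)
        virtual = pp.stitch(pp.calibrate_frames(raw, references), sensor)
        expected = ph.expand_to_virtual(tumor_truth.ideal_cube, sensor)
        assert virtual.data.shape == expected.shape
        # 8-bit quantization against references bounds the error
        assert np.abs(virtual.data - expected).max() <= 1.0 / 255.0


class TestSpectralCorrection:
    def test_selection_matrix_subsets_bands(self):
        cube = _cube(np.random.default_rng(0).random((3, 4, 5)))
        M = np.zeros((5, 2))
        M[1, 0] = 1.0
        M[4, 1] = 1.0
        out = pp.apply_spectral_correction(cube, M)
        np.testing.assert_array_equal(out.data[:, :, 0], cube.data[:, :, 1])
        np.testing.assert_array_equal(out.data[:, :, 1], cube.data[:, :, 4])

    def test_normalized_matrix_preserves_ones(self):
        cube = _cube(np.ones((2, 2, 6)))
        M = np.abs(np.random.default_rng(1).random((6, 3)))
        M /= M.sum(axis=0, keepdims=True)
        out = pp.apply_spectral_correction(cube, M)
        np.testing.assert_allclose(out.data, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        cube = _cube(rng.random((4, 4, 6)))
        M = rng.random((6, 3))
        out = pp.apply_spectral_correction(cube, M)
        expected = np.zeros((4, 4, 3))
        for y in range(4):
            for x in range(4):
                for s in range(3):
                    for v in range(6):
                        expected[y, x, s] += cube.data[y, x, v] * M[v, s]
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_shape_mismatch_raises(self):
        cube = _cube(np.ones((2, 2, 4)))
        with pytest.raises(Exception):
            pp.apply_spectral_correction(cube, np.ones((5, 3)))


@pytest.fixture(scope="module")
def textured():
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(np.random.default_rng(0).random((256, 256)), 3)


@pytest.fixture(scope="module")
def base_band():
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(np.random.default_rng(3).random((64, 60)), 2)


class TestShiftEstimation:
    def test_identical_images_give_zero(self, textured):
        assert pp.estimate_band_shift(textured, textured) == (0, 0)

    def test_known_translation_recovered(self, textured):
        rolled = np.roll(textured, (3, -2), axis=(0, 1))
        assert pp.estimate_band_shift(rolled, textured) == (3, -2)

    def test_large_translation_recovered(self, textured):
        rolled = np.roll(textured, (120, 0), axis=(0, 1))
        assert pp.estimate_band_shift(rolled, textured) == (120, 0)

    def test_constant_image_raises(self, textured):
        with pytest.raises(pp.UndefinedShiftError):
            pp.estimate_band_shift(np.ones((32, 32)), textured[:32, :32])


class TestShiftCorrection:
    def test_zero_shift_cube_unchanged(self, base_band):
        data = np.stack([base_band] * 4, axis=-1)
        out = pp.correct_shifts(_cube(data))
        assert out.status == "ok"
        np.testing.assert_array_equal(out.data, data)

    def test_shifted_bands_aligned_and_cropped(self, base_band):
        shifted = np.roll(base_band, (4, 2), axis=(0, 1))
        data = np.stack([base_band, shifted], axis=-1)
        out = pp.correct_shifts(_cube(data))
        # output reduced by exactly the max shift per axis
        assert out.data.shape[:2] == (64 - 4, 60 - 2)
        np.testing.assert_allclose(out.data[:, :, 0], out.data[:, :, 1], atol=1e-12)

    def test_threshold_discards_cube(self):
        from scipy.ndimage import gaussian_filter

        wide = gaussian_filter(np.random.default_rng(11).random((64, 256)), 2)
        big = np.roll(wide, 101, axis=1)
        out = pp.correct_shifts(_cube(np.stack([wide, big], axis=-1)))
        assert out.status == "discarded"
        assert out.data is None

    def test_idempotent_on_aligned_cube(self, base_band):
        shifted = np.roll(base_band, (3, -1), axis=(0, 1))
        once = pp.correct_shifts(_cube(np.stack([base_band, shifted], axis=-1)))
        twice = pp.correct_shifts(once)
        assert np.all(twice.meta["band_shifts"] == 0)
        np.testing.assert_array_equal(twice.data, once.data)


class TestNormalization:
    def test_arithmetic(self):
        data = np.full((2, 2, 2), 0.45)
        data[0, 0, 0] = 0.2
        data[1, 1, 1] = 0.7
        out = pp.minmax_normalize(_cube(data))
        assert out.data[0, 1, 0] == pytest.approx(0.5)

    def test_unit_range_input_unchanged(self):
        rng = np.random.default_rng(4)
        data = rng.random((3, 3, 3))
        data.flat[0], data.flat[-1] = 0.0, 1.0
        out = pp.minmax_normalize(_cube(data))
        np.testing.assert_allclose(out.data, data)

    def test_output_spans_unit_interval(self):
        data = np.random.default_rng(5).random((4, 4, 4)) * 3 + 1
        out = pp.minmax_normalize(_cube(data))
        assert out.data.min() == 0.0
        assert out.data.max() == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.random((4, 4, 4))
        a = pp.minmax_normalize(_cube(data))
        b = pp.minmax_normalize(_cube(2.5 * data + 0.3))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_constant_cube_raises(self):
        with pytest.raises(pp.NormalizationError):
            pp.minmax_normalize(_cube(np.ones((2, 2, 2))))


class TestRgbSynthesis:
    def test_reference_band_indices_on_full_grid(self):
        grid = np.linspace(470.0, 890.0, 145)
        r, g, b = pp.rgb_band_indices(grid)
        assert b == 0  # 462.14 nm sits below the grid start -> clamped
        assert g == 25
        assert r == 46

    def test_single_band_cube_replicates_channel(self):
        data = np.random.default_rng(7).random((3, 3, 1))
        cube = HyperCube(data=data, wavelengths_nm=[600.0])
        rgb = pp.synthesize_rgb(cube)
        for c in range(3):
            np.testing.assert_array_equal(rgb[:, :, c], data[:, :, 0])

    def test_output_shape_and_uint8_export(self):
        data = np.random.default_rng(8).random((5, 4, 16))
        cube = HyperCube(data=data, wavelengths_nm=np.linspace(470, 890, 16))
        rgb = pp.synthesize_rgb(cube)
        assert rgb.shape == (5, 4, 3)
        rgb8 = pp.synthesize_rgb(cube, as_uint8=True)
        assert rgb8.dtype == np.uint8


class TestPipeline:
    def test_noiseless_roundtrip_within_quantization(self, sensor, references, tumor_truth):
        raw = ph.render_linescan_frames(tumor_truth, sensor, references, noise_sd=0.0)
        M = ph.make_correction_matrix(sensor)
        res = pp.preprocess_pipeline(raw, references, M, sensor)
        assert not res.discarded
        ideal = tumor_truth.ideal_cube
        ideal_norm = (ideal - ideal.min()) / (ideal.max() - ideal.min())
        assert res.cube.data.shape == ideal.shape
        assert np.abs(res.cube.data - ideal_norm).max() <= 2.0 / 255.0

    def test_injected_shifts_recovered_exactly(self, sensor, references):
        shifts = np.zeros((16, 2), dtype=int)
        shifts[5] = (4, -3)
        shifts[11] = (-2, 6)
        spec = ph.PhantomSpec(
            height=96, width=80, n_bands=16, tissue_class="tumor",
            seed=4, noise_sd=0.0, texture_sd=0.0, band_shifts=shifts,
        )
        truth = ph.make_phantom_scene(spec)
        raw = ph.render_linescan_frames(truth, sensor, references, noise_sd=0.0)
        res = pp.preprocess_pipeline(raw, references, ph.make_correction_matrix(sensor), sensor)
        est = res.cube.meta["band_shifts"]
        np.testing.assert_array_equal(est, shifts)
        # crop by extreme shifts per axis
        assert res.cube.data.shape[:2] == (96 - 4 - 2, 80 - 3 - 6)

    def test_overthreshold_shift_discards(self, sensor):
        shifts = np.zeros((16, 2), dtype=int)
        shifts[7] = (101, 0)
        # the scene must exceed twice the shift for the estimate to be
        # unambiguous (a 101-px roll on a short axis aliases to a small one)
        spec = ph.PhantomSpec(
            height=256, width=128, n_bands=16, tissue_class="tumor",
            seed=9, noise_sd=0.0, texture_sd=0.0, band_shifts=shifts,
        )
        truth = ph.make_phantom_scene(spec)
        refs = ph.make_references(sensor, 128)
        raw = ph.render_linescan_frames(truth, sensor, refs, noise_sd=0.0)
        res = pp.preprocess_pipeline(raw, refs, ph.make_correction_matrix(sensor), sensor)
        assert res.discarded
        assert res.rgb is None

    def test_log_lists_one_shift_per_nonanchor_band(self, sensor, references, tumor_truth):
        raw = ph.render_linescan_frames(tumor_truth, sensor, references, noise_sd=0.0)
        res = pp.preprocess_pipeline(raw, references, ph.make_correction_matrix(sensor), sensor)
        shift_lines = [l for l in res.log if "estimated shift" in l]
        assert len(shift_lines) == sensor.n_spectral_bands - 1
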
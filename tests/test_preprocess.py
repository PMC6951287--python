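import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramclass as rc
from ramclass.io import SpectralDataset, Spectrum
from ramclass.preprocess import PreprocessConfig, _baseline_arrays

from conftest import make_meta


def spectrum(wavenumbers, intensities, **kw):
    return Spectrum(np.asarray(wavenumbers, float), np.asarray(intensities, float), **kw)


class TestTruncate:
    def test_closed_interval(self):
        s = spectrum([300, 400, 1000, 1800, 1900], [1, 2, 3, 4, 5])
        out = rc.truncate(s, 400, 1800)
        np.testing.assert_array_equal(out.wavenumbers, [400, 1000, 1800])
        np.testing.assert_array_equal(out.intensities, [2, 3, 4])

    def test_fewer_than_two_points_errors(self):
        s = spectrum([300, 400, 1000], [1, 2, 3])
        with pytest.raises(ValueError, match="grid points"):
            rc.truncate(s, 399, 401)

    def test_full_range_is_identity_and_idempotent(self):
        s = spectrum([400, 500, 600], [1, 2, 3])
        once = rc.truncate(s, 400, 600)
        twice = rc.truncate(once, 400, 600)
        np.testing.assert_array_equal(once.intensities, s.intensities)
        np.testing.assert_array_equal(twice.wavenumbers, once.wavenumbers)
        np.testing.assert_array_equal(twice.intensities, once.intensities)

    def test_metadata_preserved(self):
        s = spectrum([400, 500, 600], [1, 2, 3], scan_id="x", class_label="a")
        out = rc.truncate(s, 450, 600)
        assert out.scan_id == "x" and out.class_label == "a"


class TestSmooth:
    def test_window_one_is_identity(self):
        s = spectrum([1, 2, 3, 4], [4, 1, 3, 2])
        np.testing.assert_array_equal(rc.smooth(s, 1).intensities, s.intensities)

    def test_constant_spectrum_unchanged(self):
        s = spectrum(np.arange(9.0), np.full(9, 2.5))
        np.testing.assert_allclose(rc.smooth(s, 5).intensities, 2.5)

    def test_shrunken_edge_windows(self):
        s = spectrum([1, 2, 3], [0, 3, 0])
        np.testing.assert_allclose(rc.smooth(s, 3).intensities, [1.5, 1.0, 1.5])

    def test_even_window_rejected(self):
        s = spectrum([1, 2, 3], [0, 3, 0])
        with pytest.raises(ValueError, match="odd"):
            rc.smooth(s, 2)


class TestBaseline:
    grid = np.arange(400.0, 1801.0, 2.0)

    def cubic(self, coeffs):
        t = (self.grid - 400.0) / 1400.0
        return np.polynomial.polynomial.polyval(t, coeffs)

    def test_peak_free_polynomial_matches_least_squares_oracle(self):
        # oracle: the ordinary least-squares cubic fit, exact when no peaks exist
        y = self.cubic([50.0, -5.0, 3.0, 2.0])
        s = spectrum(self.grid, y)
        baseline, corrected = rc.goldindec_baseline(s, PreprocessConfig())
        t = 2.0 * (self.grid - self.grid[0]) / (self.grid[-1] - self.grid[0]) - 1.0
        ols = np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyfit(t, y, 3)
        )
        scale = np.abs(y).max()
        assert np.abs(baseline - ols).max() <= 1e-6 * scale
        assert np.abs(corrected.intensities).max() <= 1e-6 * scale

    def test_recovers_baseline_under_sparse_peaks(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            coeffs = rng.uniform([-20, -10, -8, -4], [60, 10, 8, 4])
            truth = self.cubic(coeffs)
            c1, c2 = rng.uniform(500, 1700, 2)
            height = 10.0
            y = (
                truth
                + height * np.exp(-0.5 * ((self.grid - c1) / 12.0) ** 2)
                + height * np.exp(-0.5 * ((self.grid - c2) / 9.0) ** 2)
            )
            baseline, _ = rc.goldindec_baseline(spectrum(self.grid, y), PreprocessConfig())
            off_peak = (np.abs(self.grid - c1) > 36.0) & (np.abs(self.grid - c2) > 27.0)
            assert np.abs(baseline - truth)[off_peak].max() <= 0.02 * height

    def test_zero_spectrum_gives_zero_baseline(self):
        s = spectrum(self.grid, np.zeros_like(self.grid))
        baseline, corrected = rc.goldindec_baseline(s, PreprocessConfig())
        np.testing.assert_array_equal(baseline, 0.0)
        np.testing.assert_array_equal(corrected.intensities, 0.0)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        y = self.cubic([40, 5, -3, 1]) + rng.normal(0, 0.5, len(self.grid))
        b1 = _baseline_arrays(self.grid, y, PreprocessConfig())
        b2 = _baseline_arrays(self.grid, y, PreprocessConfig())
        np.testing.assert_array_equal(b1, b2)


class TestVectorNormalize:
    def test_three_four_five(self):
        s = spectrum([1, 2], [3, 4])
        np.testing.assert_allclose(rc.vector_normalize(s).intensities, [0.6, 0.8])

    def test_idempotent(self):
        s = spectrum([1, 2, 3], [1.0, 2.0, 2.0])
        once = rc.vector_normalize(s)
        twice = rc.vector_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)
        assert abs(np.linalg.norm(once.intensities) - 1.0) < 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            rc.vector_normalize(spectrum([1, 2, 3], [0, 0, 0]))

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariant(self, scale):
        s = spectrum([1, 2, 3], [1.0, -2.0, 2.0])
        a = rc.vector_normalize(s).intensities
        b = rc.vector_normalize(spectrum([1, 2, 3], scale * s.intensities)).intensities
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestAverageReplicates:
    def dataset(self, rows, specimens, labels):
        grid = np.array([400.0, 500.0])
        ids = [f"r{i}" for i in range(len(rows))]
        meta = make_meta(ids, specimens=specimens, labels=labels,
                         reps=list(range(1, len(rows) + 1)))
        return SpectralDataset(grid, np.asarray(rows, float), meta)

    def test_mean_of_identical_rows(self):
        d = self.dataset([[1, 2]] * 10, ["p1"] * 10, ["a"] * 10)
        out = rc.average_replicates(d)
        assert out.n_scans == 1
        np.testing.assert_array_equal(out.matrix, [[1, 2]])
        assert int(out.meta.replicate_index.iloc[0]) == 10

    def test_pointwise_mean(self):
        d = self.dataset([[0, 2], [2, 0]], ["p1", "p1"], ["a", "a"])
        np.testing.assert_array_equal(rc.average_replicates(d).matrix, [[1, 1]])

    def test_conflicting_labels_name_the_group(self):
        d = self.dataset([[0, 2], [2, 0]], ["p1", "p1"], ["healthy", "unhealthy"])
        with pytest.raises(ValueError, match="p1"):
            rc.average_replicates(d)

    def test_sum_conservation(self, rng):
        rows = rng.normal(size=(12, 2))
        d = self.dataset(rows.tolist(), ["p1"] * 5 + ["p2"] * 7, ["a"] * 5 + ["b"] * 7)
        out = rc.average_replicates(d)
        np.testing.assert_allclose(5 * out.matrix[0], rows[:5].sum(axis=0), rtol=1e-10)
        np.testing.assert_allclose(7 * out.matrix[1], rows[5:].sum(axis=0), rtol=1e-10)


class TestResample:
    def test_identity_on_same_grid(self):
        s = spectrum([1, 2, 3], [5.0, 7.0, 6.0])
        np.testing.assert_array_equal(
            rc.resample_to_grid(s, s.wavenumbers).intensities, s.intensities
        )

    def test_linear_ramp_exact(self):
        s = spectrum([0, 10], [0.0, 20.0])
        out = rc.resample_to_grid(s, np.array([2.5, 5.0, 7.5]))
        np.testing.assert_allclose(out.intensities, [5.0, 10.0, 15.0])

    def test_no_extrapolation(self):
        s = spectrum([0, 10], [0.0, 20.0])
        with pytest.raises(ValueError, match="outside source span"):
            rc.resample_to_grid(s, np.array([5.0, 11.0]))


@pytest.fixture(scope="module")
def synth_data():
    cfg = rc.SynthConfig(n_specimens_per_class=4, n_replicates=3, grid_step=10, seed=5)
    d, _ = rc.generate_dataset(cfg)
    return d


class TestRunPreprocess:
    def test_output_rows_unit_norm_before_averaging(self, synth_data):
        out, log = rc.run_preprocess(synth_data, PreprocessConfig(average_by="none"))
        np.testing.assert_allclose(np.linalg.norm(out.matrix, axis=1), 1.0, atol=1e-12)
        assert out.n_scans == synth_data.n_scans

    def test_averaged_rows_norm_at_most_one(self, synth_data):
        out, log = rc.run_preprocess(synth_data)
        norms = np.linalg.norm(out.matrix, axis=1)
        assert np.all(norms <= 1.0 + 1e-12)
        assert out.n_scans == 8  # one row per specimen
        assert dict(log)["average"] == 8

    def test_external_averaging_matches_integrated(self, synth_data):
        separate, _ = rc.run_preprocess(synth_data, PreprocessConfig(average_by="none"))
        combined, _ = rc.run_preprocess(synth_data, PreprocessConfig(average_by="specimen"))
        manual = rc.average_replicates(separate, by="specimen")
        np.testing.assert_allclose(manual.matrix, combined.matrix, atol=1e-12)

    def test_empty_truncation_window_errors(self, synth_data):
        with pytest.raises(ValueError, match="grid points"):
            rc.run_preprocess(synth_data, PreprocessConfig(trunc_low=100.0, trunc_high=150.0))

    def test_config_from_yaml_file(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("trunc_low: 500\ntrunc_high: 1700\naverage_by: none\n")
        cfg = PreprocessConfig.from_file(p)
        assert cfg.trunc_low == 500 and cfg.average_by == "none"
        p.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            PreprocessConfig.from_file(p)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(trunc_low=1800, trunc_high=400)
        with pytest.raises(ValueError):
            PreprocessConfig(smooth_window=4)
        with pytest.raises(ValueError):
            PreprocessConfig(peak_ratio=1.5)
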
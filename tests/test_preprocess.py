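import numpy as np
import pytest
from scipy import stats

from seedgc import preprocess
from seedgc.types import BoldSeries, NuisanceSet, PreprocessParams


def _series(rng, shape=(8, 8, 8), T=64, tr=2.5):
    data = rng.standard_normal((*shape, T))
    return BoldSeries(data, (3.0, 3.0, 3.0), tr, np.ones(shape, bool))


class TestSmoothGaussian:
    def test_fwhm_zero_is_identity(self, rng):
        vol = rng.standard_normal((6, 6, 6, 3))
        out = preprocess.smooth_gaussian(vol, 0.0, (3, 3, 3))
        np.testing.assert_array_equal(out, vol)

    def test_constant_volume_unchanged_in_interior(self):
        vol = np.full((15, 15, 15), 7.0)
        out = preprocess.smooth_gaussian(vol, 6.0, (3, 3, 3))
        # zero-padding attenuates only near the faces
        np.testing.assert_allclose(out[5:-5, 5:-5, 5:-5], 7.0, rtol=1e-7)

    def test_impulse_matches_dense_convolution_oracle(self):
        """Face-neighbor / center ratio of a smoothed unit impulse equals the
        analytic kernel ratio exp(-4 ln2 d^2 / FWHM^2) = 0.5 for d=3, FWHM=6."""
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        out = preprocess.smooth_gaussian(vol, 6.0, (3, 3, 3))
        ratio = out[5, 4, 4] / out[4, 4, 4]
        assert ratio == pytest.approx(0.5, abs=5e-3)
        # independent oracle: direct dense convolution with the analytic kernel
        sigma_mm = 6.0 / (2 * np.sqrt(2 * np.log(2)))
        offs = np.arange(-20, 21) * 3.0
        k = np.exp(-(offs**2) / (2 * sigma_mm**2))
        k /= k.sum()
        center = k[20] ** 3
        neighbor = k[21] * k[20] * k[20]
        assert ratio == pytest.approx(neighbor / center, rel=1e-3)

    def test_sum_conserved_for_interior_support(self, rng):
        vol = np.zeros((12, 12, 12))
        vol[4:8, 4:8, 4:8] = rng.standard_normal((4, 4, 4))
        out = preprocess.smooth_gaussian(vol, 4.0, (3, 3, 3))
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            preprocess.smooth_gaussian(np.zeros((4, 4, 4, 2)), -1.0, (3, 3, 3))


class TestBandpass:
    def test_inband_sinusoid_preserved(self):
        t = np.arange(230) * 2.5
        x = np.sin(2 * np.pi * 0.04 * t)[:, None]
        out = preprocess.bandpass_filter(x, 2.5, 0.01, 0.08)
        assert out.var() >= 0.90 * x.var()

    def test_outband_sinusoid_suppressed(self):
        t = np.arange(230) * 2.5
        x = np.sin(2 * np.pi * 0.15 * t)[:, None]
        out = preprocess.bandpass_filter(x, 2.5, 0.01, 0.08)
        assert out.var() <= 0.05 * x.var()

    def test_matches_spectral_mask_oracle(self, rng):
        """Output variance equals the energy of the retained DFT bins."""
        x = rng.standard_normal((230, 3))
        out = preprocess.bandpass_filter(x, 2.5, 0.01, 0.08)
        # oracle: project onto the complex exponential basis explicitly
        T = 230
        freqs = np.fft.rfftfreq(T, 2.5)
        kept = freqs[(freqs >= 0.01) & (freqs <= 0.08)]
        tsec = np.arange(T) * 2.5
        for c in range(3):
            coeffs = np.array(
                [np.sum(x[:, c] * np.exp(-2j * np.pi * f * tsec)) for f in kept]
            )
            # Parseval: kept bins are neither DC nor Nyquist, so each counts twice
            energy = 2.0 * np.sum(np.abs(coeffs) ** 2) / T**2
            assert np.mean(out[:, c] ** 2) == pytest.approx(energy, rel=1e-8)

    def test_zero_in_zero_out(self):
        out = preprocess.bandpass_filter(np.zeros((64, 2)), 2.5, 0.01, 0.08)
        np.testing.assert_array_equal(out, 0.0)

    def test_idempotent(self, rng):
        x = rng.standard_normal((120, 4))
        once = preprocess.bandpass_filter(x, 2.5, 0.01, 0.08)
        twice = preprocess.bandpass_filter(once, 2.5, 0.01, 0.08)
        assert np.max(np.abs(once - twice)) < 1e-8

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            preprocess.bandpass_filter(np.zeros((64, 1)), 2.5, 0.08, 0.01)
        with pytest.raises(ValueError):
            preprocess.bandpass_filter(np.zeros((64, 1)), 2.5, 0.01, 0.3)


class TestRegressNuisance:
    def test_residuals_orthogonal_to_design(self, rng):
        ts = rng.standard_normal((80, 10))
        Z = rng.standard_normal((80, 9))
        resid = preprocess.regress_nuisance(ts, Z)
        cross = np.abs(Z.T @ resid)
        norms = 80 * np.linalg.norm(Z, axis=0)[:, None]
        assert np.max(cross / norms) < 1e-8

    def test_column_equal_to_regressor_zeroed(self, rng):
        Z = rng.standard_normal((60, 3))
        ts = np.column_stack([Z[:, 1], rng.standard_normal(60)])
        resid = preprocess.regress_nuisance(ts, Z)
        assert np.max(np.abs(resid[:, 0])) < 1e-10

    def test_known_orthogonal_component_recovered(self, rng):
        """ts = z1 + e with e pre-orthogonalized against [1, Z]: residual == e."""
        Z = rng.standard_normal((100, 4))
        design = np.column_stack([np.ones(100), Z])
        e_raw = rng.standard_normal(100)
        # oracle: explicit projection via normal-equation solve
        beta = np.linalg.solve(design.T @ design, design.T @ e_raw)
        e = e_raw - design @ beta
        resid = preprocess.regress_nuisance((Z[:, 0] + e)[:, None], Z)
        assert np.max(np.abs(resid[:, 0] - e)) < 1e-8

    def test_collinear_design_names_columns(self, rng):
        Z = rng.standard_normal((50, 2))
        Zdup = np.column_stack([Z, Z[:, 0]])
        nuis = NuisanceSet(Zdup, ["csf", "wm", "csf_copy"])
        with pytest.raises(ValueError, match="csf_copy"):
            preprocess.regress_nuisance(rng.standard_normal((50, 2)), nuis)


class TestMotionExclusion:
    @pytest.mark.parametrize(
        "peak_mm,peak_rad,expected",
        [
            (1.5, 0.0, True),  # translation exactly at the limit is excluded
            (1.49, 0.0, False),
            (0.0, np.radians(1.5), True),
            (0.0, np.radians(1.49), False),
        ],
    )
    def test_limits_inclusive_with_degree_conversion(self, peak_mm, peak_rad, expected):
        motion = np.zeros((20, 6))
        motion[10, 0] = peak_mm
        motion[12, 4] = peak_rad
        assert preprocess.motion_exceeds_limit(motion) is expected


class TestPipeline:
    @pytest.fixture
    def masks(self):
        shape = (10, 10, 10)
        csf = np.zeros(shape, bool)
        csf[0:2, 0:2, 0:2] = True
        wm = np.zeros(shape, bool)
        wm[8:10, 8:10, 8:10] = True
        return shape, csf, wm

    def test_output_length_and_nuisance_shape(self, rng, masks):
        shape, csf, wm = masks
        series = BoldSeries(
            rng.standard_normal((*shape, 50)), (3, 3, 3), 2.5, np.ones(shape, bool)
        )
        motion = rng.normal(0, 0.01, (50, 6))
        out, nuis, flag = preprocess.preprocess_pipeline(series, csf, wm, motion)
        assert out.n_timepoints == 40
        assert nuis.matrix.shape == (40, 9)
        assert nuis.labels[:3] == ["csf", "wm", "global"]
        assert flag is False

    def test_constant_series_gives_zero_residuals(self, masks):
        shape, csf, wm = masks
        series = BoldSeries(
            np.full((*shape, 40), 5.0), (3, 3, 3), 2.5, np.ones(shape, bool)
        )
        motion = np.random.default_rng(0).normal(0, 0.01, (40, 6))
        out, _, _ = preprocess.preprocess_pipeline(series, csf, wm, motion)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_global_signal_series_fully_regressed(self, rng, masks):
        """Every voxel carrying the same series is removed by the global regressor."""
        shape, csf, wm = masks
        g = rng.standard_normal(40)
        data = np.broadcast_to(g, (*shape, 40)).copy()
        series = BoldSeries(data, (3, 3, 3), 2.5, np.ones(shape, bool))
        motion = rng.normal(0, 0.01, (40, 6))
        out, _, _ = preprocess.preprocess_pipeline(
            series, csf, wm, motion, PreprocessParams(n_discard=0, smooth_fwhm_mm=0)
        )
        assert np.max(np.abs(out.data)) < 1e-8

    def test_motion_row_mismatch_rejected(self, rng, masks):
        shape, csf, wm = masks
        series = BoldSeries(
            rng.standard_normal((*shape, 40)), (3, 3, 3), 2.5, np.ones(shape, bool)
        )
        with pytest.raises(ValueError, match="motion"):
            preprocess.preprocess_pipeline(series, csf, wm, np.zeros((39, 6)))

    def test_excluded_subject_flagged(self, rng, masks):
        shape, csf, wm = masks
        series = BoldSeries(
            rng.standard_normal((*shape, 40)), (3, 3, 3), 2.5, np.ones(shape, bool)
        )
        motion = rng.normal(0, 0.01, (40, 6))
        motion[20, 1] = 1.5
        *_, flag = preprocess.preprocess_pipeline(series, csf, wm, motion)
        assert flag is True
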
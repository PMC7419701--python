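"""Denoising chain: detrending, band behavior, smoothing, regression, censoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import langmap
from langmap.errors import (InsufficientDataError, MaskError, ParameterError,
                            SingularityError)
from langmap.phantom import AcquisitionProtocol, BoldRun
from langmap.preprocess import (FWHM_TO_SIGMA, NuisanceSet, PreprocessConfig,
                                censor_frames, detrend_run, lowpass_filter,
                                preprocess_run, regress_nuisance,
                                select_contiguous_frames, spatial_smooth)


def _run_from_series(series, tr=2.2, shape=(8, 8, 8)):
    """Embed one time series at every in-mask voxel of a small run."""
    n = len(series)
    proto = AcquisitionProtocol(tr=tr, n_frames_per_run=n, n_runs=1,
                                grid_shape=shape)
    data = np.zeros(shape + (n,))
    mask = np.zeros(shape, bool)
    mask[2:6, 2:6, 2:6] = True
    data[mask] = series
    return BoldRun(data=data, protocol=proto, brain_mask=mask)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(50)
        run = _run_from_series(3.0 + 0.25 * t)
        out = detrend_run(run)
        assert np.allclose(out.data[run.brain_mask], 0.0, atol=1e-10)

    def test_sinusoid_residual_slope_tiny(self):
        t = np.arange(200)
        x = np.sin(2 * np.pi * t / 40)
        out = detrend_run(_run_from_series(x))
        y = out.data[out.brain_mask][0]
        slope = np.polyfit(t, y, 1)[0]
        assert abs(slope) < 1e-10

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            detrend_run(_run_from_series(np.array([1.0, 2.0])))


class TestLowpass:
    @staticmethod
    def _amplitude_ratio(freq_hz, tr=2.2, n=320, cutoff=0.1):
        """FFT amplitude at the probe frequency, output over input."""
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq_hz * t)
        run = _run_from_series(x, tr=tr)
        y = lowpass_filter(run, cutoff).data[run.brain_mask][0]
        freqs = np.fft.rfftfreq(n, tr)
        k = np.argmin(np.abs(freqs - freq_hz))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x))[k]

    def test_passband(self):
        assert self._amplitude_ratio(0.05) >= 0.9

    def test_stopband(self):
        assert self._amplitude_ratio(0.2) <= 0.1

    def test_constant_series_unchanged(self):
        run = _run_from_series(np.full(64, 7.0))
        out = lowpass_filter(run, 0.1)
        assert np.allclose(out.data[run.brain_mask], 7.0, atol=1e-8)

    def test_cutoff_above_nyquist_rejected(self):
        run = _run_from_series(np.zeros(64))
        with pytest.raises(ParameterError):
            lowpass_filter(run, 0.3)  # Nyquist at TR 2.2 is ~0.227

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 100))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 100))
        rx = _run_from_series(x)
        lp = lambda s: lowpass_filter(_run_from_series(s), 0.1).data[rx.brain_mask][0]
        assert np.allclose(lp(a * x + b * y), a * lp(x) + b * lp(y), atol=1e-10)


class TestSpatialSmooth:
    def test_fwhm_zero_identity(self):
        v = np.random.default_rng(0).standard_normal((10, 10, 10))
        assert np.array_equal(spatial_smooth(v, 0.0), v)

    def test_impulse_matches_gaussian_kernel(self):
        """6 mm FWHM at 3 mm voxels -> sigma ~0.849 voxels, checked against a
        directly evaluated separable Gaussian kernel."""
        v = np.zeros((15, 15, 15))
        v[7, 7, 7] = 1.0
        out = spatial_smooth(v, 6.0, 3.0)
        sigma = 6.0 * FWHM_TO_SIGMA / 3.0
        assert sigma == pytest.approx(0.8493, abs=1e-3)
        x = np.arange(-4, 5)
        g = np.exp(-x ** 2 / (2 * sigma ** 2))
        g /= g.sum()  # scipy's discretization of the kernel
        expected = np.einsum("i,j,k->ijk", g, g, g)
        got = out[3:12, 3:12, 3:12]
        assert np.allclose(got, expected, atol=1e-4)

    def test_total_intensity_conserved(self):
        v = np.random.default_rng(1).random((12, 12, 12))
        out = spatial_smooth(v, 6.0, 3.0)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-6)

    def test_uniform_volume_unchanged(self):
        v = np.full((10, 10, 10), 3.5)
        assert np.allclose(spatial_smooth(v, 6.0, 3.0), 3.5, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ParameterError):
            spatial_smooth(np.zeros((8, 8, 8)), -1.0)


class TestNuisanceRegression:
    def test_voxel_equal_to_regressor_zeroed(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(60)
        run = _run_from_series(g)
        out = regress_nuisance(run, NuisanceSet(g[:, None], ["global_mean"]))
        assert np.allclose(out.data[run.brain_mask], 0.0, atol=1e-10)

    def test_orthogonal_voxel_unchanged(self):
        n = 60
        t = np.arange(n)
        x = np.sin(2 * np.pi * t / 10)      # orthogonal to cos over full periods
        g = np.cos(2 * np.pi * t / 10)
        run = _run_from_series(x)
        out = regress_nuisance(run, NuisanceSet(g[:, None], ["g"]))
        assert np.allclose(out.data[run.brain_mask][0], x, atol=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        n = 50
        G = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        run = _run_from_series(y)
        out = regress_nuisance(run, NuisanceSet(G, list("abc")))
        X = np.column_stack([np.ones(n), G])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y   # explicit normal equations
        assert np.allclose(out.data[run.brain_mask][0], y - X @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(3)
        G = rng.standard_normal((40, 2))
        run = _run_from_series(rng.standard_normal(40))
        out = regress_nuisance(run, NuisanceSet(G, ["a", "b"]))
        resid = out.data[run.brain_mask][0]
        assert np.abs(G.T @ resid).max() < 1e-8 * np.linalg.norm(resid)

    def test_collinear_columns_named(self):
        g = np.arange(30.0)
        with pytest.raises(SingularityError, match="collinear"):
            regress_nuisance(_run_from_series(g),
                             NuisanceSet(np.column_stack([g, 2 * g]), ["a", "b"]))


class TestCensoring:
    def test_constant_run_keeps_everything(self):
        run = _run_from_series(np.full(30, 100.0))
        assert censor_frames(run).n_kept == 30

    def test_uniform_offset_flags_spike_and_successor(self):
        x = np.full(20, 1000.0)
        x[7] *= 1.05  # +5 % at frame 7: transitions 6->7 and 7->8 exceed 0.5 %
        mask = censor_frames(_run_from_series(x), 0.5)
        assert mask.excluded_frames == {7, 8}

    def test_zero_threshold_excludes_all_but_first(self):
        rng = np.random.default_rng(0)
        run = _run_from_series(1000 + rng.standard_normal(25))
        mask = censor_frames(run, 0.0)
        assert mask.keep[0] and not mask.keep[1:].any()

    def test_idempotence(self, noisy_subject):
        m1 = censor_frames(noisy_subject)
        kept = noisy_subject.data[..., m1.keep]
        proto = AcquisitionProtocol(tr=2.2, n_frames_per_run=kept.shape[-1],
                                    n_runs=1, grid_shape=kept.shape[:3])
        m2 = censor_frames(BoldRun(kept, proto, noisy_subject.brain_mask))
        assert m2.keep.all() or m2.n_kept >= m1.n_kept - 1

    def test_empty_mask_rejected(self):
        run = _run_from_series(np.zeros(10) + 1.0)
        run.brain_mask[:] = False
        with pytest.raises(MaskError):
            censor_frames(run)


class TestChain:
    def test_noiseless_phantom_correlation_survives(self, small_atlas,
                                                    small_protocol):
        run = langmap.simulate_rest_run(small_atlas, small_protocol,
                                        snr=np.inf, drift_amplitude=0.0, seed=0)
        out, censor = preprocess_run(run, wm_mask=small_atlas.wm_mask,
                                     csf_mask=small_atlas.csf_mask)
        m1, m2 = small_atlas.roi_mask(1), (small_atlas.labels
                                           == small_atlas.network_rois(1)[1])
        a = out.data[m1][:, censor.keep].mean(axis=0)
        b = out.data[m2][:, censor.keep].mean(axis=0)
        assert np.corrcoef(a, b)[0, 1] >= 0.99

    def test_stage_toggling(self, noisy_subject, small_atlas):
        cfg_off = PreprocessConfig(smooth_fwhm_mm=None)
        out_off, _ = preprocess_run(noisy_subject, cfg_off,
                                    wm_mask=small_atlas.wm_mask,
                                    csf_mask=small_atlas.csf_mask)
        # manual chain without smoothing
        manual = detrend_run(noisy_subject)
        manual = lowpass_filter(manual, 0.1)
        from langmap.preprocess import build_nuisance_set
        nuis = build_nuisance_set(manual, small_atlas.wm_mask,
                                  small_atlas.csf_mask)
        manual = regress_nuisance(manual, nuis)
        assert np.allclose(out_off.data, manual.data, atol=1e-10)

    def test_chain_determinism(self, noisy_subject, small_atlas):
        a, _ = preprocess_run(noisy_subject, wm_mask=small_atlas.wm_mask)
        b, _ = preprocess_run(noisy_subject, wm_mask=small_atlas.wm_mask)
        assert np.array_equal(a.data, b.data)

    def test_contiguous_subset_selection(self):
        keep = np.ones(320, bool)
        keep[[5, 50]] = False
        sub = select_contiguous_frames(keep, 100)
        assert sub.sum() == 100
        # first 100 kept frames: indices 0..101 minus the censored two
        assert sub[:102].sum() == 100 and not sub[102:].any()
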
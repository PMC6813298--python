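"""Temporal pipeline: discard, motion QC, filters, nuisance regression."""
import numpy as np
import pytest

from rsgica.config import StudyConfig
from rsgica.core_io import MotionTrace, SubjectRun, Volume4D
from rsgica.errors import BandError, InvalidVolumeError
from rsgica.preprocess import (
    bandpass,
    bandpass_gain,
    detrend_linear,
    discard_initial,
    gaussian_smooth,
    motion_summary,
    nuisance_regress,
    percent_flagged,
    preprocess_run,
    run_duration_s,
    scan_to_scan_displacement,
)


def _run(n_volumes, shape=(6, 6, 4), tr=2.64, seed=0):
    rng = np.random.default_rng(seed)
    return SubjectRun(
        subject_id="s01", run_index=1,
        volume=Volume4D(data=rng.normal(size=(*shape, n_volumes)),
                        affine=np.diag([2.0, 2.0, 2.5, 1.0]), tr_s=tr),
        motion=MotionTrace(params=rng.normal(0, 0.01, size=(n_volumes, 6))),
    )


class TestVolumeBookkeeping:
    def test_discard_initial(self):
        run = _run(139)
        out = discard_initial(run, 5)
        assert out.volume.n_volumes == 134
        assert out.motion.n_volumes == 134
        np.testing.assert_array_equal(out.volume.data,
                                      run.volume.data[..., 5:])
        assert discard_initial(run, 0) is run
        with pytest.raises(InvalidVolumeError):
            discard_initial(_run(5), 5)

    @pytest.mark.parametrize("n,tr,expected", [
        (139, 2.64, 367),   # the acquisition's per-run scan time
        (1, 2.64, 3),
        (0, 2.64, 0),
    ])
    def test_run_duration(self, n, tr, expected):
        assert run_duration_s(n, tr) == expected

    def test_run_duration_negative(self):
        with pytest.raises(ValueError):
            run_duration_s(-1, 2.64)


class TestMotionQC:
    cfg = StudyConfig()

    def test_motionless_trace(self):
        s = motion_summary(MotionTrace(params=np.zeros((10, 6))), self.cfg)
        assert s.mean_motion_mm == 0.0
        assert s.n_flagged == 0
        assert s.percent_flagged == 0.0
        assert s.run_ok and s.censor_after_index is None

    def test_translation_step_displacement(self):
        params = np.zeros((3, 6))
        params[1, 0] = 0.3  # 0.3 mm jump in x between volumes 1 and 2
        disp = scan_to_scan_displacement(MotionTrace(params=params))
        np.testing.assert_allclose(disp, [0.3, 0.3])
        s = motion_summary(MotionTrace(params=params), self.cfg)
        assert s.n_flagged == 2  # both transitions exceed 0.2 mm

    def test_rotation_contributes_arc_displacement(self):
        params = np.zeros((2, 6))
        params[1, 3] = 1.0  # 1 degree about x
        disp = scan_to_scan_displacement(MotionTrace(params=params),
                                         rotation_radius_mm=30.0)
        np.testing.assert_allclose(disp, [np.radians(1.0) * 30.0])

    def test_censor_after_violation_at_volume_128(self):
        # first limit violation at (1-based) volume 128 of 134 -> 127
        # retained volumes, matching the study's one censored run
        params = np.zeros((134, 6))
        params[127:, 0] = 2.5
        s = motion_summary(MotionTrace(params=params), self.cfg)
        assert not s.run_ok
        assert s.censor_after_index == 127

    @pytest.mark.parametrize("n_flagged,n_total,expected", [
        (3, 5975, 0.05),    # the study's motion-flag tally
        (0, 100, 0.0),
        (1, 3, 33.33),
    ])
    def test_percent_flagged(self, n_flagged, n_total, expected):
        assert percent_flagged(n_flagged, n_total) == expected

    def test_percent_flagged_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent_flagged(0, 0)


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(100, dtype=float)
        np.testing.assert_allclose(detrend_linear(2 * t + 1), 0.0, atol=1e-9)
        np.testing.assert_allclose(detrend_linear(np.full(100, 7.0)), 0.0,
                                   atol=1e-9)

    def test_sine_survives_line_removal(self):
        t = np.arange(134, dtype=float)
        sine = np.sin(2 * np.pi * t / 20.0)
        out = detrend_linear(sine + 0.5 * t + 3.0)
        # closed-form oracle: subtract the least-squares line of the input
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, sine + 0.5 * t + 3.0, rcond=None)[0]
        oracle = sine + 0.5 * t + 3.0 - X @ beta
        np.testing.assert_allclose(out, oracle, atol=1e-9)
        amp_err = np.abs(out - (sine - (X @ np.linalg.lstsq(X, sine, rcond=None)[0])))
        assert amp_err.max() < 0.01 * np.abs(sine).max()

    def test_output_orthogonal_to_time(self):
        rng = np.random.default_rng(1)
        out = detrend_linear(rng.normal(size=200))
        t = np.arange(200) - 99.5
        assert abs(out.mean()) < 1e-10
        assert abs(out @ t) / (np.linalg.norm(out) * np.linalg.norm(t)) < 1e-10

    def test_too_short(self):
        with pytest.raises(InvalidVolumeError):
            detrend_linear(np.array([1.0, 2.0]))


class TestBandpass:
    tr = 2.64

    def _ratio(self, freq_bin, n=512):
        # exact DFT-bin frequencies: a non-periodic sine would leak
        # boundary transients across the whole spectrum
        freq = freq_bin / (n * self.tr)
        t = np.arange(n) * self.tr
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, self.tr, 0.01, 0.1)
        return np.abs(y).max() / np.abs(x).max()

    def test_passband_center(self):
        assert 0.9 <= self._ratio(68) <= 1.1  # ~0.050 Hz

    def test_dc_removed(self):
        y = bandpass(np.full(512, 10.0), self.tr, 0.01, 0.1)
        assert np.abs(y).max() < 1.0

    def test_stopband(self):
        assert self._ratio(243) < 0.1  # ~0.180 Hz

    def test_transfer_function_matches_spec(self):
        freqs = np.fft.rfftfreq(512, d=self.tr)
        g = bandpass_gain(freqs, 0.01, 0.1)
        mid = (freqs > 0.03) & (freqs < 0.08)
        assert np.all(g[mid] >= 0.9)
        assert g[freqs == 0.0] == 0.0
        assert np.all(g[freqs >= 0.2] <= 0.1)

    def test_infeasible_band(self):
        with pytest.raises(BandError):
            bandpass(np.zeros(64), self.tr, 0.3, 0.4)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 256))
        lhs = bandpass(a + b, self.tr, 0.01, 0.1)
        rhs = bandpass(a, self.tr, 0.01, 0.1) + bandpass(b, self.tr, 0.01, 0.1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestSmoothing:
    def _vol(self, data):
        return Volume4D(data=data, affine=np.diag([2.0, 2.0, 2.0, 1.0]),
                        tr_s=1.0)

    def test_fwhm_zero_is_identity(self):
        vol = self._vol(np.random.default_rng(0).normal(size=(8, 8, 8, 2)))
        assert gaussian_smooth(vol, 0.0) is vol

    def test_impulse_response_matches_gaussian(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        out = gaussian_smooth(self._vol(data), 4.0).data[..., 0]
        sigma_mm = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(-(2.0**2) / (2 * sigma_mm**2))  # 2 mm voxel away
        ratio = out[8, 7, 7] / out[7, 7, 7]
        np.testing.assert_allclose(ratio, expected, rtol=1e-3)

    def test_constant_volume_preserved(self):
        vol = self._vol(np.full((10, 10, 10, 2), 3.0))
        out = gaussian_smooth(vol, 4.0)
        interior = out.data[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(interior, 3.0, rtol=1e-5)

    def test_negative_fwhm(self):
        with pytest.raises(ValueError):
            gaussian_smooth(self._vol(np.zeros((4, 4, 4, 1))), -1.0)


class TestNuisanceRegression:
    def test_perfect_fit_gives_zeros(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=30)
        Y = np.outer([2.0, -1.0], c)
        res = nuisance_regress(Y, c[:, None])
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_orthogonal_confound_leaves_demeaned_data(self):
        t = 40
        y = np.sin(2 * np.pi * np.arange(t) / 10)
        c = np.cos(2 * np.pi * np.arange(t) / 10)  # orthogonal over full cycles
        res = nuisance_regress(y[None, :], c[:, None])
        np.testing.assert_allclose(res[0], y - y.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 134))
        C = rng.normal(size=(134, 8))
        res = nuisance_regress(Y, C)
        X = np.column_stack([np.ones(134), C])
        beta = np.linalg.solve(X.T @ X, X.T @ Y.T)
        oracle = Y - (X @ beta).T
        np.testing.assert_allclose(res, oracle, atol=1e-8)
        # residuals orthogonal to every confound column
        assert np.abs(res @ X).max() / np.abs(Y).max() < 1e-8

    def test_rank_deficient_confounds_ok(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(3, 50))
        c = rng.normal(size=50)
        res = nuisance_regress(Y, np.column_stack([c, c]))  # duplicated column
        assert np.isfinite(res).all()

    def test_too_few_timepoints(self):
        with pytest.raises(InvalidVolumeError):
            nuisance_regress(np.zeros((2, 5)), np.zeros((5, 6)))


def test_pipeline_order_is_fixed(tiny_study):
    """Golden check: preprocess_run equals the documented stage order and
    differs if detrend/band-pass are swapped."""
    from rsgica.preprocess import _eroded_or_full

    run = tiny_study.runs[0]
    cfg = tiny_study.config
    masks = tiny_study.masks
    out = preprocess_run(run, masks, cfg)

    r = discard_initial(run, cfg.discard_initial)
    vol = gaussian_smooth(r.volume, cfg.smooth_fwhm_mm)
    brain = masks["brain"].data
    Y = vol.data[brain].astype(float)
    Y = detrend_linear(Y, axis=-1)
    Y = bandpass(Y, cfg.tr_s, *cfg.band_hz, axis=-1)
    wm = _eroded_or_full(masks["white"].data)[brain]
    csf = _eroded_or_full(masks["csf"].data)[brain]
    mp = bandpass(detrend_linear(r.motion.params, axis=0), cfg.tr_s,
                  *cfg.band_hz, axis=0)
    conf = np.column_stack([Y[wm].mean(axis=0), Y[csf].mean(axis=0), mp])
    manual = nuisance_regress(Y, conf).T
    np.testing.assert_allclose(out.data, manual, atol=1e-10)

    # swapping detrend and band-pass changes the result
    Y2 = vol.data[brain].astype(float)
    Y2 = bandpass(Y2, cfg.tr_s, *cfg.band_hz, axis=-1)
    Y2 = detrend_linear(Y2, axis=-1)
    assert not np.allclose(Y2, Y, atol=1e-6)
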
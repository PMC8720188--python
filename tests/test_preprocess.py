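"""Censoring, DVARS, GM masking, nuisance cleaning and band-pass filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoconn.preprocess import (
    MotionTrace,
    RegionalRun,
    bandpass,
    censor_volumes,
    clean_regional_series,
    compute_dvars,
    framewise_displacement,
    mask_atlas_by_gm,
)


def _trace(n, fd_bad=(), dvars_bad=()):
    fd = np.full(n, 0.1)
    dvars = np.full(n, 1.0)
    fd[0] = dvars[0] = 0.0
    for t in fd_bad:
        fd[t] = 0.9
    for t in dvars_bad:
        dvars[t] = 5.0
    return MotionTrace(fd=fd, dvars=dvars)


def oracle_keep_mask(fd, dvars, fd_thresh=0.5, dvars_thresh=3.0, before=1, after=2):
    """Independent set-union oracle for the scrubbing window rule."""
    n = len(fd)
    removed = set()
    for t in range(n):
        if fd[t] > fd_thresh or dvars[t] > dvars_thresh:
            removed |= set(range(max(0, t - before), min(n, t + after + 1)))
    return np.array([t not in removed for t in range(n)])


class TestCensoring:
    def test_single_exceedance_window(self):
        res = censor_volumes(_trace(10, fd_bad=[5]))
        assert sorted(np.flatnonzero(~res.keep_mask)) == [4, 5, 6, 7]
        assert res.keep_mask.sum() == 6

    def test_boundary_clipping_and_retention_edge(self):
        res = censor_volumes(_trace(10, fd_bad=[0], dvars_bad=[9]))
        assert sorted(np.flatnonzero(~res.keep_mask)) == [0, 1, 2, 8, 9]
        assert res.retained_fraction == pytest.approx(0.5)
        # 50% retained counts as inclusion (>= rule)
        assert res.include_subject

    def test_exclusion_below_half(self):
        res = censor_volumes(_trace(10, fd_bad=[0, 4, 8]))
        assert res.retained_fraction < 0.5
        assert not res.include_subject

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            MotionTrace(fd=np.array([]), dvars=np.array([]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_set_union_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        fd = r.exponential(0.25, n)
        dvars = r.exponential(1.5, n)
        fd[0] = dvars[0] = 0.0
        res = censor_volumes(MotionTrace(fd=fd, dvars=dvars))
        np.testing.assert_array_equal(res.keep_mask, oracle_keep_mask(fd, dvars))
        assert res.include_subject == (res.keep_mask.mean() >= 0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed)
        n = 40
        fd = r.exponential(0.3, n)
        dvars = r.exponential(1.5, n)
        fd[0] = dvars[0] = 0.0
        first = censor_volumes(MotionTrace(fd=fd, dvars=dvars))
        kept = first.keep_mask
        second = censor_volumes(MotionTrace(fd=fd[kept], dvars=dvars[kept]))
        assert second.keep_mask.all()


class TestDvars:
    def test_constant_series_is_zero(self):
        vols = np.full((4, 4, 3, 10), 7.0)
        np.testing.assert_allclose(compute_dvars(vols), 0.0)

    def test_two_volume_hand_computation(self):
        # voxels: vol0 = [10, 20, 30, 40], vol1 = [12, 18, 33, 37]
        v = np.array([[10.0, 12.0], [20.0, 18.0], [30.0, 33.0], [40.0, 37.0]])
        diff = v[:, 1] - v[:, 0]  # [2, -2, 3, -3]
        expected = 100.0 * diff.std() / v.mean()
        got = compute_dvars(v)
        assert got[0] == 0.0
        assert got[1] == pytest.approx(expected, rel=1e-12)

    def test_percent_convention_scale_invariant(self, rng):
        v = rng.normal(100, 5, size=(50, 20))
        np.testing.assert_allclose(compute_dvars(v), compute_dvars(10 * v), rtol=1e-12)

    def test_empty_mask_rejected(self, rng):
        v = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="mask"):
            compute_dvars(v, brain_mask=np.zeros(10, dtype=bool))


class TestFramewiseDisplacement:
    def test_rotation_scaled_to_sphere(self):
        params = np.zeros((3, 6))
        params[1, 0] = 0.2  # 0.2 mm translation
        params[2, 3] = 0.01  # 0.01 rad pitch -> 0.5 mm at 50 mm radius
        fd = framewise_displacement(params)
        np.testing.assert_allclose(fd, [0.0, 0.2, 0.2 + 0.5])


class TestGmMasking:
    @pytest.mark.parametrize(
        "probs,kept",
        [((0.6, 0.3, 0.1), True), ((0.4, 0.4, 0.2), True), ((0.3, 0.5, 0.2), False)],
    )
    def test_rule_with_tie_retention(self, probs, kept):
        gm, wm, csf = (np.array([p]) for p in probs)
        out = mask_atlas_by_gm(gm, wm, csf, labels=np.array([7]))
        assert out[0] == (7 if kept else 0)

    def test_masking_never_adds_labels(self, rng):
        shape = (6, 6, 4)
        gm, wm, csf = rng.dirichlet(np.ones(3), size=shape).transpose(3, 0, 1, 2)
        labels = rng.integers(0, 91, size=shape)
        out = mask_atlas_by_gm(gm, wm, csf, labels)
        assert set(np.unique(out)) - {0} <= set(np.unique(labels))
        assert np.all((out == labels) | (out == 0))


class TestCleaning:
    def test_regressing_signal_on_itself_zeroes_it(self, rng):
        sig = rng.normal(size=(3, 80))
        run = RegionalRun(signals=sig, tr=1.6)
        out = clean_regional_series(run, nuisance=sig[0][:, None])
        np.testing.assert_allclose(out.signals[0], 0.0, atol=1e-10)

    def test_linear_ramp_detrended_to_zero(self):
        ramp = np.vstack([np.linspace(2, 9, 60), 5 - 3 * np.linspace(0, 1, 60)])
        out = clean_regional_series(RegionalRun(signals=ramp, tr=1.6))
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        sig = rng.normal(size=(5, 100))
        nuis = rng.normal(size=(100, 3))
        out = clean_regional_series(RegionalRun(signals=sig, tr=1.6), nuisance=nuis)
        # normal equations: residuals orthogonal to every design column
        np.testing.assert_allclose(out.signals @ nuis, 0.0, atol=1e-8)
        np.testing.assert_allclose(out.signals.sum(axis=1), 0.0, atol=1e-8)

    def test_censoring_applied_before_regression(self, rng):
        sig = rng.normal(size=(2, 30))
        keep = np.ones(30, dtype=bool)
        keep[5:10] = False
        from neoconn.preprocess import CensorResult

        censor = CensorResult(keep_mask=keep, retained_fraction=keep.mean(), include_subject=True)
        out = clean_regional_series(RegionalRun(signals=sig, tr=1.6), censor=censor)
        assert out.signals.shape == (2, 25)

    def test_voxel_to_region_averaging(self, rng):
        sig = rng.normal(size=(6, 50))
        labels = np.array([1, 1, 2, 2, 2, 0])  # 0 = background, dropped
        out = clean_regional_series(
            RegionalRun(signals=sig, tr=1.6), labels=labels
        )
        assert out.signals.shape == (2, 50)
        assert list(out.region_ids) == [1, 2]


class TestBandpass:
    def _sine(self, freq, tr=1.6, n=300):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq * t)[None, :]

    def test_passband_amplitude_preserved(self):
        run = RegionalRun(signals=self._sine(0.05), tr=1.6)
        out = bandpass(run)
        # FFT amplitude at the driving frequency, before vs after
        f_in = np.abs(np.fft.rfft(run.signals[0]))
        f_out = np.abs(np.fft.rfft(out.signals[0]))
        k = f_in.argmax()
        assert f_out[k] == pytest.approx(f_in[k], rel=0.05)

    def test_stopband_attenuated(self):
        run = RegionalRun(signals=self._sine(0.2), tr=1.6)
        out = bandpass(run)
        # FFT amplitude at the driving frequency (edge transients excluded)
        f_in = np.abs(np.fft.rfft(run.signals[0]))
        f_out = np.abs(np.fft.rfft(out.signals[0]))
        k = f_in.argmax()
        assert f_out[k] < 0.1 * f_in[k]

    def test_dc_removed(self):
        run = RegionalRun(signals=np.full((2, 200), 3.0), tr=1.6)
        out = bandpass(run)
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-6)

    def test_double_filtering_nearly_idempotent(self, rng):
        run = RegionalRun(signals=rng.normal(size=(3, 300)), tr=1.6)
        once = bandpass(run)
        twice = bandpass(once)
        # a second pass only re-attenuates the soft Butterworth shoulders, so
        # the outputs agree in RMS within the filter's tolerance
        resid = twice.signals - once.signals
        assert np.sqrt((resid**2).mean()) < 0.2 * once.signals.std()

    def test_band_outside_nyquist_rejected(self):
        run = RegionalRun(signals=np.random.default_rng(0).normal(size=(1, 100)), tr=1.6)
        with pytest.raises(ValueError, match="band"):
            bandpass(run, 0.01, 0.4)  # Nyquist at TR 1.6 is 0.3125 Hz
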
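"""Filter chains, R peaks, epoching, corrections, downsampling, normalization."""

import numpy as np
import pandas as pd
import pytest

import physofr as pf
from physofr.preprocess import TrialEpochSet

FS = 500.0


def _epochset(data, trials=None, stage="epoched", rate=FS, t0=-1.0,
              channels=("respiration", "heart_rate", "emg_cor", "emg_zyg")):
    n = data.shape[0]
    trials = trials if trials is not None else pd.DataFrame({
        "participant_id": ["P001"] * n, "trial": np.arange(n),
        "odor": ["Maltol"] * n, "test_half": [1] * n,
    })
    return TrialEpochSet(data=data, trials=trials, channels=list(channels),
                         rate_hz=rate, t0=t0, stage=stage)


class TestFilters:
    def test_respiration_lowpass_attenuates_10hz_by_40db(self):
        # closed form: 5th-order Butterworth at 5x cutoff attenuates by
        # ~50 dB one-pass; the zero-phase double pass only increases that
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = pf.filter_channel(x, "respiration", FS)
        core = slice(int(2 * FS), int(18 * FS))  # avoid edge transients
        atten_db = 20 * np.log10(np.abs(y[core]).max() / 1.0)
        assert atten_db < -40

    def test_respiration_passband_nearly_untouched(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 0.3 * t)
        y = pf.filter_channel(x, "respiration", FS)
        core = slice(int(5 * FS), int(25 * FS))
        rms_ratio = np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))
        assert abs(rms_ratio - 1) < 0.01

    def test_ecg_highpass_rejects_dc(self):
        x = np.full(int(10 * FS), 3.7)
        y = pf.filter_channel(x, "ecg", FS)
        assert np.abs(y).max() < 1e-6

    def test_emg_envelope_nonnegative(self):
        rng = np.random.default_rng(0)
        y = pf.filter_channel(rng.standard_normal(int(8 * FS)), "emg_cor", FS)
        assert (y >= 0).all()

    def test_unknown_channel_and_nan_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            pf.filter_channel(np.zeros(100), "eda", FS)
        x = np.zeros(1000)
        x[37] = np.nan
        with pytest.raises(ValueError, match="37"):
            pf.filter_channel(x, "respiration", FS)


class TestHeartRate:
    def test_regular_impulse_train_recovers_60_bpm(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 30, 1 / FS)
        ecg = rng.normal(0, 0.02, t.size)
        peak_times = np.arange(1, 29, 1.0)
        for pt in peak_times:
            i = int(pt * FS)
            ecg[i - 5:i + 6] += np.exp(-0.5 * ((np.arange(-5, 6)) / 1.5) ** 2)
        peaks = pf.detect_r_peaks(ecg, FS)
        assert len(peaks) == len(peak_times)
        hr = pf.instantaneous_heart_rate(peaks, np.arange(2, 28, 0.2))
        assert np.abs(hr - 60).max() < 1.0

    def test_refractory_suppresses_close_peak(self):
        x = np.zeros(int(2 * FS))
        x[int(0.5 * FS)] = 1.0
        x[int(0.6 * FS)] = 0.9  # 0.1 s later: inside refractory window
        x[int(1.5 * FS)] = 1.0
        peaks = pf.detect_r_peaks(x, FS)
        assert len(peaks) == 2
        assert np.all(np.diff(peaks) >= 0.25)

    def test_flat_and_empty_signals(self):
        with pytest.warns(UserWarning, match="flat"):
            assert pf.detect_r_peaks(np.zeros(1000), FS).size == 0
        assert pf.detect_r_peaks(np.array([]), FS).size == 0

    def test_ihr_stepwise_interpolation(self):
        # IBIs 1.0 s then 0.5 s anchored at the closing peaks
        grid = np.array([0.0, 0.5, 1.0, 1.25, 1.5, 2.0])
        hr = pf.instantaneous_heart_rate(np.array([0.0, 1.0, 1.5]), grid)
        assert np.allclose(hr, [60, 60, 60, 90, 120, 120])

    def test_ihr_constant_rate_and_extrapolation(self):
        peaks = np.arange(0, 8, 0.8)
        hr = pf.instantaneous_heart_rate(peaks, np.linspace(-1, 9, 50))
        assert np.allclose(hr, 75.0)
        with pytest.raises(ValueError):
            pf.instantaneous_heart_rate(np.array([1.0]), np.arange(3))


class TestEpoching:
    def test_epoch_counts_and_windowing_identity(self):
        t = np.arange(0, 120, 1 / FS)
        ramp = t.copy()
        with pytest.warns(UserWarning):
            eps, kept = pf.epoch(ramp, np.array([0.5, 20.0, 110.0]), FS)
        # first onset lacks baseline, last lacks 14 s of future
        assert kept.tolist() == [False, True, False]
        assert eps.shape == (1, 7500)
        assert np.allclose(eps[0], np.arange(int(19 * FS), int(34 * FS)) / FS)

    def test_baseline_correction_zeroes_baseline_and_skips_emg(self):
        rng = np.random.default_rng(2)
        data = rng.normal(3.0, 1.0, (4, 4, 7500))
        es = _epochset(data)
        out = pf.baseline_correct(es)
        nb = int(FS)
        for ci, c in enumerate(out.channels):
            base = out.data[:, ci, :nb].mean(axis=1)
            if c in ("respiration", "heart_rate"):
                assert np.allclose(base, 0.0, atol=1e-10)
                assert np.allclose(out.data[:, ci], data[:, ci] - data[:, ci, :nb].mean(axis=1, keepdims=True))
            else:
                assert np.array_equal(out.data[:, ci], data[:, ci])

    def test_stage_enforcement(self):
        es = _epochset(np.zeros((2, 4, 7500)), stage="raw")
        with pytest.raises(ValueError, match="stage"):
            pf.baseline_correct(es)
        with pytest.raises(ValueError, match="stage"):
            pf.normalize_participant(es)


class TestRespirationCorrection:
    def _set(self, hr, resp):
        n = hr.shape[0]
        data = np.zeros((n, 4, hr.shape[1]))
        data[:, 0] = resp
        data[:, 1] = hr
        return _epochset(data, stage="corrected")

    def test_perfect_dependence_gives_zero_residuals(self):
        rng = np.random.default_rng(3)
        resp = rng.standard_normal((5, 400))
        out = pf.respiration_correct_hr(self._set(2.0 * resp, resp))
        assert np.abs(out.data[:, 1]).max() < 1e-8

    def test_lagged_dependence_captured(self):
        rng = np.random.default_rng(4)
        resp = rng.standard_normal((5, 400))
        hr = np.concatenate([resp[:, :1], resp[:, :-1]], axis=1)  # hr_t = resp_{t-1}
        out = pf.respiration_correct_hr(self._set(hr, resp), lag=1)
        assert np.abs(out.data[:, 1]).max() < 1e-8

    def test_independent_hr_residuals_match_direct_ols(self):
        rng = np.random.default_rng(5)
        resp = rng.standard_normal((6, 300))
        hr = rng.standard_normal((6, 300)) + 5.0
        out = pf.respiration_correct_hr(self._set(hr, resp), lag=1)
        # oracle: explicit OLS on the pooled samples
        lagged = np.concatenate([resp[:, :1], resp[:, :-1]], axis=1)
        X = np.column_stack([np.ones(hr.size), resp.ravel(), lagged.ravel()])
        coef, *_ = np.linalg.lstsq(X, hr.ravel(), rcond=None)
        expect = (hr.ravel() - X @ coef).reshape(hr.shape)
        assert np.allclose(out.data[:, 1], expect, atol=1e-10)
        # residuals orthogonal to both regressors
        r = out.data[:, 1].ravel()
        assert abs(r @ resp.ravel()) / r.size < 1e-8
        assert abs(r @ lagged.ravel()) / r.size < 1e-8


class TestDownsampleNormalize:
    def test_block_means_of_constant_and_alternating(self):
        data = np.zeros((2, 4, 7500))
        data[0] = 3.3
        data[1] = np.where(np.arange(7500) % 2 == 0, 1.0, -1.0)
        out = pf.downsample(_epochset(data, stage="corrected"), 5.0)
        assert out.data.shape[-1] == 75
        assert np.allclose(out.data[0], 3.3)
        assert np.allclose(out.data[1], 0.0)

    def test_ramp_passes_through_block_midpoints(self):
        t = -1 + np.arange(7500) / FS
        data = np.tile(2.0 * t + 1.0, (1, 4, 1))
        out = pf.downsample(_epochset(data, stage="corrected"), 5.0)
        # oracle: hand block-average of a ramp = ramp at the block's mean time
        mean_t = t.reshape(75, 100).mean(axis=1)
        assert np.allclose(out.data[0, 0], 2.0 * mean_t + 1.0)
        assert np.allclose(out.grid, -0.9 + 0.2 * np.arange(75))

    def test_non_divisible_rate_rejected(self):
        with pytest.raises(ValueError):
            pf.downsample(_epochset(np.zeros((1, 4, 7500)), stage="corrected"), 7.0)

    def test_normalization_unit_pooled_sd_per_participant(self):
        rng = np.random.default_rng(6)
        trials = pd.DataFrame({
            "participant_id": ["A"] * 3 + ["B"] * 3, "trial": np.arange(6),
            "odor": ["Maltol"] * 6, "test_half": [1] * 6})
        data = rng.normal(0, 4.0, (6, 4, 75))
        data[3:] *= 0.1
        es = _epochset(data, trials=trials, stage="downsampled", rate=5.0, t0=-0.9)
        out = pf.normalize_participant(es)
        for rows in (slice(0, 3), slice(3, 6)):
            for ci in range(4):
                assert out.data[rows, ci, :].std() == pytest.approx(1.0)
        # scaling only: shape preserved within participant/channel
        assert np.allclose(out.data[0, 0] / data[0, 0],
                           out.data[0, 0][0] / data[0, 0][0])

    def test_zero_sd_named_in_error(self):
        data = np.zeros((2, 4, 75))
        es = _epochset(data, stage="downsampled", rate=5.0, t0=-0.9)
        with pytest.raises(ValueError, match="P001"):
            pf.normalize_participant(es)


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_template_at_block_midpoints(self, quiet_config):
        cfg = quiet_config
        d = pf.generate_design(cfg.n_participants, seed=2).groupby(
            "participant_id").head(4).reset_index(drop=True)
        t = pf.simulate_truth(cfg, seed=2)
        epochs, _ = pf.simulate_trials(d, t, seed=2)
        down = pf.downsample(pf.baseline_correct(
            epochs.replace(stage="epoched")), 5.0)
        grid = down.grid
        for i, row in down.trials.iterrows():
            for ci, c in enumerate(["respiration"]):
                amp = t.template_amps[c][row["odor"]]
                expect = amp * pf.simulate.channel_shape(c, grid)
                expect = expect - expect[grid < 0].mean()
                got = down.data[i, down.channels.index(c)]
                # block means of a smooth template match its midpoint values
                # up to the O(dt^2) curvature term of the 0.2 s bins
                assert np.abs(got - expect).max() < 1e-2
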
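"""ECG/EMG preprocessing: filters, R-peaks, IBI correction, bursts, epochs."""

import numpy as np
import pytest
from scipy.signal import periodogram

from elab import physio
from elab.physio import (
    Burst,
    EpochMatrix,
    IBISeries,
    bandpass_zero_phase,
    correct_ibis,
    detect_bursts,
    detect_r_peaks,
    emg_envelope,
    epoch_ihr,
    ibi_to_ihr,
    reject_outlier_peaks,
    remove_line_noise,
    zscore_within_participant,
)


class TestBandpass:
    def test_drift_attenuated(self):
        fs = 1000
        t = np.arange(0, 60, 1 / fs)
        drift = np.sin(2 * np.pi * 0.001 * t)
        out = bandpass_zero_phase(drift, fs, 1.0, 100.0)
        assert np.abs(out[fs : -fs]).max() < 0.1 * np.abs(drift).max()

    def test_passband_preserved_zero_phase(self):
        fs = 1000
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass_zero_phase(x, fs, 1.0, 100.0)
        mid = slice(fs, -fs)
        amp = np.sqrt(2.0) * out[mid].std()
        assert amp == pytest.approx(1.0, abs=0.05)
        # zero phase lag: peak positions unchanged
        assert np.corrcoef(x[mid], out[mid])[0, 1] > 0.999

    def test_forward_backward_impulse_symmetric(self):
        # the 1 Hz high-pass has a ~1 s impulse response, so keep the
        # impulse far from the edges; forward-backward filtering makes the
        # response symmetric in time
        fs = 1000
        x = np.zeros(20001)
        x[10000] = 1.0
        out = bandpass_zero_phase(x, fs, 1.0, 100.0)
        core = out[5000:15001]
        assert np.allclose(core, core[::-1], atol=1e-8 * np.abs(out).max())

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(1000), 1000, 1.0, 600.0)


def _synthetic_ecg(beat_times, fs=1000, duration=None, noise_sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    duration = beat_times[-1] + 1.0 if duration is None else duration
    n = int(duration * fs)
    x = noise_sd * rng.standard_normal(n)
    tt = np.arange(-60, 61) / fs
    template = np.exp(-0.5 * (tt / 0.012) ** 2)
    for b in beat_times:
        c = int(b * fs)
        x[c - 60 : c + 61] += template
    return x


class TestRPeaks:
    def test_known_beats_recovered_exactly(self):
        beats = np.arange(1.0, 59.0, 0.8)
        x = _synthetic_ecg(beats)
        filt = bandpass_zero_phase(x, 1000, 1.0, 100.0)
        det = detect_r_peaks(filt, 1000)
        assert len(det) == len(beats)
        assert np.max(np.abs(det - beats)) <= 0.002

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(60000), 1000)

    def test_scale_invariance(self):
        beats = np.arange(1.0, 30.0, 0.75)
        x = _synthetic_ecg(beats, duration=31.0)
        filt = bandpass_zero_phase(x, 1000, 1.0, 100.0)
        d1 = detect_r_peaks(filt, 1000)
        d2 = detect_r_peaks(2.0 * filt, 1000)
        assert np.array_equal(d1, d2)


class TestIBICorrection:
    def test_fixture_50pct_jump_replaced(self):
        series = IBISeries(
            beat_times=np.cumsum([0, 0.8, 0.8, 1.2, 0.8, 0.8]),
            ibis=np.array([800.0, 800.0, 1200.0, 800.0, 800.0]),
        )
        out = correct_ibis(series)
        assert list(out.artifact_flags) == [False, False, True, False, False]
        assert out.ibis[2] == pytest.approx(800.0, abs=20.0)

    def test_25pct_change_kept(self):
        series = IBISeries(
            beat_times=np.zeros(6),
            ibis=np.array([800.0, 1000.0, 1000.0, 1000.0, 1000.0]),
        )
        out = correct_ibis(series)
        assert not out.artifact_flags.any()
        assert np.array_equal(out.ibis, series.ibis)

    def test_constant_series_unchanged(self):
        series = IBISeries(beat_times=np.zeros(9), ibis=np.full(8, 750.0))
        out = correct_ibis(series)
        assert np.array_equal(out.ibis, series.ibis)

    def test_flagging_uses_last_accepted_value(self):
        # after the 1200 artifact, 810 is compared against 800 (accepted),
        # not against the artifact, so it survives
        series = IBISeries(
            beat_times=np.zeros(6),
            ibis=np.array([800.0, 1200.0, 810.0, 800.0, 805.0]),
        )
        out = correct_ibis(series)
        assert list(out.artifact_flags) == [False, True, False, False, False]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correct_ibis(IBISeries(beat_times=np.zeros(3), ibis=np.array([800.0, 810.0])))


@pytest.mark.parametrize("ibi,bpm", [(800.0, 75.0), (1000.0, 60.0), (600.0, 100.0)])
def test_ibi_to_ihr_values(ibi, bpm):
    assert ibi_to_ihr(np.array([ibi]))[0] == pytest.approx(bpm)


def test_ibi_to_ihr_nonpositive_rejected():
    with pytest.raises(ValueError):
        ibi_to_ihr(np.array([800.0, 0.0]))


class TestEpochIHR:
    def _beats_constant(self, ibi_s=0.8, duration=200.0):
        return np.arange(0.0, duration, ibi_s)

    def test_constant_rate_epochs_are_flat_zero(self):
        beats = self._beats_constant()
        series = IBISeries.from_beats(beats)
        events = [(1, 50.0, 0.5), (2, 80.0, 0.6)]
        ep = epoch_ihr(series, events)
        assert ep.values.shape == (2, 141)
        assert np.abs(ep.values).max() < 0.2  # flat up to filter ripple

    def test_planted_deceleration_recovered(self):
        # stretch IBIs by ~7% (75 -> ~70 bpm) between 0 and 3 s post-onset
        onset = 100.0
        beats = [0.0]
        while beats[-1] < 200.0:
            ibi = 0.8
            if 0.0 <= beats[-1] - onset <= 3.0:
                ibi *= 75.0 / 70.0
            beats.append(beats[-1] + ibi)
        series = IBISeries.from_beats(np.asarray(beats))
        ep = epoch_ihr(series, [(1, onset, 0.5)])
        dip = ep.values[0].min()
        t_at_min = ep.time_axis[np.argmin(ep.values[0])]
        assert dip == pytest.approx(-5.0, abs=1.5)
        assert 0.0 <= t_at_min <= 3.5

    def test_baseline_window_mean_is_zero(self):
        beats = self._beats_constant(0.75)
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 0.01, beats.size).cumsum()
        series = IBISeries.from_beats(beats + jitter - jitter[0])
        ep = epoch_ihr(series, [(1, 60.0, 0.5), (2, 100.0, 0.4)])
        bl = (ep.time_axis >= -2.0) & (ep.time_axis <= -1.0)
        assert np.allclose(ep.values[:, bl].mean(axis=1), 0.0, atol=1e-9)

    def test_out_of_bounds_events_dropped(self):
        series = IBISeries.from_beats(self._beats_constant(duration=60.0))
        ep = epoch_ihr(series, [(1, 2.0, 0.5), (2, 30.0, 0.5)])
        assert list(ep.trial_index) == [2]


class TestLineNoise:
    def test_line_component_removed(self):
        fs = 2000
        rng = np.random.default_rng(1)
        t = np.arange(0, 20, 1 / fs)
        x = rng.standard_normal(t.size) + 2.0 * np.sin(2 * np.pi * 50 * t)
        out = remove_line_noise(x, fs, line_hz=50.0)
        f, pxx_in = periodogram(x, fs)
        _, pxx_out = periodogram(out, fs)
        band = (f > 49.5) & (f < 50.5)
        near = ((f > 45) & (f < 48)) | ((f > 52) & (f < 55))
        assert 10 * np.log10(pxx_in[band].sum() / pxx_out[band].sum()) >= 20
        assert abs(10 * np.log10(pxx_in[near].sum() / pxx_out[near].sum())) < 1.0

    def test_clean_signal_unchanged(self):
        fs = 2000
        rng = np.random.default_rng(2)
        x = rng.standard_normal(fs * 5)
        out = remove_line_noise(x, fs)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 0.01

    def test_60hz_configuration(self):
        fs = 2000
        t = np.arange(0, 10, 1 / fs)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(t.size) + 2.0 * np.sin(2 * np.pi * 60 * t)
        out = remove_line_noise(x, fs, line_hz=60.0)
        f, pxx_in = periodogram(x, fs)
        _, pxx_out = periodogram(out, fs)
        band = (f > 59.5) & (f < 60.5)
        assert 10 * np.log10(pxx_in[band].sum() / pxx_out[band].sum()) >= 20


class TestEnvelope:
    def test_zero_signal_gives_zero_envelope(self):
        assert np.allclose(emg_envelope(np.zeros(10000), 2000), 0.0)

    def test_envelope_nonnegative_up_to_ringing(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20000)
        env = emg_envelope(x, 2000)
        assert env.min() > -0.01 * env.max()

    def test_burst_plateau_tracks_rectified_mean(self):
        fs = 2000
        rng = np.random.default_rng(5)
        x = rng.standard_normal(fs * 4)
        x[fs : 3 * fs] *= 5.0
        env = emg_envelope(x, fs)
        plateau = env[int(1.5 * fs) : int(2.5 * fs)].mean()
        # mean of |N(0, 5)| = 5 * sqrt(2/pi)
        assert plateau == pytest.approx(5.0 * np.sqrt(2 / np.pi), rel=0.1)


class TestBursts:
    def _envelope_with_burst(self, fs=2000, stim=2.0, rt=0.5, amp=10.0, width=0.15, seed=0):
        rng = np.random.default_rng(seed)
        n = int(fs * 4)
        env = 1.0 + 0.05 * rng.standard_normal(n)  # already-smoothed floor
        c = int((stim + rt) * fs)
        w = int(width * fs)
        env[c - w // 2 : c + w // 2] += amp
        return env

    def test_planted_burst_found_and_contains_rt(self):
        fs = 2000
        env = self._envelope_with_burst(fs=fs)
        bursts, rtb = detect_bursts(env, fs, stim_onset=2.0, rt=0.5)
        assert rtb is not None and rtb.contains_rt
        true_onset = 2.5 - 0.075 / 2 * 2  # burst starts half a width early
        assert rtb.onset == pytest.approx(2.5 - 0.075, abs=0.010)

    def test_ten_ms_gap_merged(self):
        fs = 2000
        rng = np.random.default_rng(1)
        env = 1.0 + 0.05 * rng.standard_normal(4 * fs)
        # two supra-threshold runs separated by 10 ms inside the window
        env[int(2.45 * fs) : int(2.50 * fs)] += 10.0
        env[int(2.51 * fs) : int(2.56 * fs)] += 10.0
        bursts, _ = detect_bursts(env, fs, 2.0, 0.5)
        assert len(bursts) == 1
        assert bursts[0].offset - bursts[0].onset > 0.10

    def test_short_isolated_run_dropped(self):
        fs = 2000
        rng = np.random.default_rng(2)
        env = 1.0 + 0.05 * rng.standard_normal(4 * fs)
        env[int(2.48 * fs) : int(2.48 * fs) + int(0.020 * fs)] += 10.0
        bursts, rtb = detect_bursts(env, fs, 2.0, 0.5)
        assert all(b.peak_amplitude < 5.0 for b in bursts)  # the 20 ms run is gone
        assert rtb is None or rtb.peak_amplitude < 5.0

    def test_missing_rt_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.ones(8000), 2000, 2.0, float("nan"))

    def test_no_baseline_span_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.ones(1000), 2000, 0.2, 0.5)


class TestOutlierPeaks:
    def test_identical_amplitudes_all_kept(self):
        mask = reject_outlier_peaks(np.full(10, 3.3))
        assert mask.all()

    def test_extreme_amplitude_rejected(self):
        x = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.2, 0.8, 1.0, 10.0])
        mask = reject_outlier_peaks(x)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 0.4, 20)
        m1 = reject_outlier_peaks(x)
        m2 = reject_outlier_peaks(3.0 * x + 7.0)
        assert np.array_equal(m1, m2)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reject_outlier_peaks(np.ones(5))


def test_participant_quality_exclusion_rule():
    from elab.physio import participant_quality_ok

    assert participant_quality_ok(10, 96)
    assert not participant_quality_ok(30, 96)
    assert not participant_quality_ok(0, 0)


class TestZScore:
    def _epochs(self, values):
        return EpochMatrix(
            values=values,
            time_axis=np.arange(values.shape[1], dtype=float),
            fs_epoch=1.0,
            lock="stimulus_onset",
        )

    def test_concatenated_mean_zero_sd_one(self):
        rng = np.random.default_rng(7)
        z = zscore_within_participant(self._epochs(rng.normal(3, 2, (10, 50))))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        z1 = zscore_within_participant(self._epochs(rng.normal(0, 5, (6, 30))))
        z2 = zscore_within_participant(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_within_participant(self._epochs(np.ones((4, 10))))
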
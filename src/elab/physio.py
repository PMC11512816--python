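"""ECG and EMG preprocessing.

ECG chain: 1-100 Hz zero-phase band-pass, quantile-calibrated R-peak
detection with a 250 ms refractory period, inter-beat-interval (IBI)
computation, 30%-change artifact correction by cubic-spline interpolation,
conversion to instantaneous heart rate (iHR = 60000/IBI, bpm), 10 Hz
linearly-interpolated stimulus-locked series band-passed 0.01-2 Hz, epoched
-4..10 s around stimulus onset and baseline-corrected over -2..-1 s.

EMG chain: 20-500 Hz zero-phase band-pass, spectral interpolation of line
noise, full-wave rectification, 10 Hz low-pass envelope, single-threshold
burst detection (baseline = lowest-amplitude 500 ms moving-average window
between 1 s pre-stimulus and the response; threshold = baseline mean + 3
baseline SDs; bursts closer than 20 ms merged, isolated bursts shorter than
25 ms dropped), Tukey 1.5-IQR peak-amplitude rejection, and +/-500 ms
peak-centered epochs.  Epochs are z-scored within participants over the
concatenated trial data before model fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "IBISeries",
    "EpochMatrix",
    "Burst",
    "bandpass_zero_phase",
    "detect_r_peaks",
    "compute_ibis",
    "correct_ibis",
    "ibi_to_ihr",
    "epoch_ihr",
    "remove_line_noise",
    "emg_envelope",
    "detect_bursts",
    "reject_outlier_peaks",
    "participant_quality_ok",
    "zscore_within_participant",
]


def bandpass_zero_phase(
    signal: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Butterworth band-pass applied forward and backward (zero phase)."""
    nyq = fs / 2.0
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    if low_hz <= 0:
        sos = butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    else:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, float))


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    threshold_fraction: float = 0.6,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """R-peak times from a filtered ECG trace.

    The per-recording threshold is ``threshold_fraction`` of the 99th
    percentile of the positive amplitudes (quantile-based, hence invariant
    to rescaling); local maxima above it, separated by the refractory
    period, are beats.  Fewer than 10 beats per minute of signal raises a
    quality error.
    """
    x = np.asarray(ecg, float)
    pos = x[x > 0]
    duration_min = len(x) / fs / 60.0
    if pos.size == 0:
        raise ValueError("no positive amplitudes; ECG quality insufficient")
    thresh = threshold_fraction * np.percentile(pos, 99)
    peaks, _ = find_peaks(x, height=thresh, distance=max(int(refractory_s * fs), 1))
    if peaks.size < 10 * duration_min:
        raise ValueError(
            f"detected {peaks.size} beats in {duration_min:.1f} min; quality insufficient"
        )
    return peaks / fs


@dataclass
class IBISeries:
    """Beat times (s) with the IBIs (ms) between consecutive beats."""

    beat_times: np.ndarray
    ibis: np.ndarray  # ms, ibis[i] = 1000*(beat_times[i+1]-beat_times[i])
    artifact_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @classmethod
    def from_beats(cls, beat_times: np.ndarray) -> "IBISeries":
        bt = np.asarray(beat_times, float)
        ibis = 1000.0 * np.diff(bt)
        return cls(beat_times=bt, ibis=ibis, artifact_flags=np.zeros(ibis.size, bool))


def compute_ibis(beat_times: np.ndarray) -> IBISeries:
    return IBISeries.from_beats(beat_times)


def correct_ibis(series: IBISeries, max_change: float = 0.30) -> IBISeries:
    """Replace IBIs deviating more than 30% from the preceding accepted value
    with cubic-spline interpolations over the unflagged neighbors.

    Flagging runs left to right against the last accepted (unflagged) IBI, so
    a single ectopic interval does not cascade into flagging its successors.
    More than 20% flagged raises a quality warning.
    """
    ibis = np.asarray(series.ibis, float)
    if ibis.size < 4:
        raise ValueError("need at least 4 IBIs for artifact correction")
    flags = np.zeros(ibis.size, bool)
    last_ok = ibis[0]
    for i in range(1, ibis.size):
        if abs(ibis[i] - last_ok) > max_change * last_ok:
            flags[i] = True
        else:
            last_ok = ibis[i]
    if flags.mean() > 0.20:
        warnings.warn(
            f"{100 * flags.mean():.1f}% of IBIs flagged as artifacts", stacklevel=2
        )
    corrected = ibis.copy()
    if flags.any() and (~flags).sum() >= 2:
        good = np.flatnonzero(~flags)
        spline = CubicSpline(good, ibis[good])
        corrected[flags] = spline(np.flatnonzero(flags))
    return IBISeries(beat_times=series.beat_times, ibis=corrected, artifact_flags=flags)


def ibi_to_ihr(ibis: np.ndarray | IBISeries) -> np.ndarray:
    """Instantaneous heart rate in bpm: iHR = 60000 / IBI(ms)."""
    x = ibis.ibis if isinstance(ibis, IBISeries) else np.asarray(ibis, float)
    if np.any(x <= 0):
        raise ValueError("non-positive IBI encountered")
    return 60000.0 / x


@dataclass
class EpochMatrix:
    """Trials x time-points signal matrix with its epoch time axis."""

    values: np.ndarray  # (n_trials, n_timepoints)
    time_axis: np.ndarray  # s relative to the lock event
    fs_epoch: float
    lock: str  # "stimulus_onset" or "emg_peak"
    baseline_window: tuple[float, float] | None = None
    trial_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def epoch_ihr(
    series: IBISeries,
    events: list[tuple[int, float, float]],
    fs_epoch: float = 10.0,
    window: tuple[float, float] = (-4.0, 10.0),
    baseline: tuple[float, float] = (-2.0, -1.0),
    filter_band: tuple[float, float] = (0.01, 2.0),
) -> EpochMatrix:
    """Stimulus-locked iHR epochs in bpm change from baseline.

    Beat-wise iHR is assigned at the second R-peak of each interval, linearly
    interpolated to ``fs_epoch``, band-pass filtered (0.01-2 Hz, 2nd-order
    zero-phase Butterworth), epoched over ``window`` around each event onset
    and baseline-corrected by the mean over ``baseline``.  Events whose
    epoch exceeds the recording are dropped (logged via the returned trial
    index).
    """
    ihr = ibi_to_ihr(series)
    t_beats = series.beat_times[1:]  # assignment at the second R-peak
    t0, t1 = t_beats[0], t_beats[-1]
    grid = np.arange(t0, t1, 1.0 / fs_epoch)
    ihr_grid = np.interp(grid, t_beats, ihr)
    ihr_filt = bandpass_zero_phase(ihr_grid, fs_epoch, filter_band[0], filter_band[1], order=2)

    n_pts = int(round((window[1] - window[0]) * fs_epoch)) + 1
    time_axis = window[0] + np.arange(n_pts) / fs_epoch
    kept, rows = [], []
    for trial_idx, onset, _rt in events:
        rel_t = onset + time_axis
        if rel_t[0] < t0 or rel_t[-1] > t1:
            continue
        epoch = np.interp(rel_t, grid, ihr_filt)
        bl = (time_axis >= baseline[0]) & (time_axis <= baseline[1])
        rows.append(epoch - epoch[bl].mean())
        kept.append(trial_idx)
    if not rows:
        raise ValueError("no events fell inside the recording margins")
    return EpochMatrix(
        values=np.asarray(rows),
        time_axis=time_axis,
        fs_epoch=fs_epoch,
        lock="stimulus_onset",
        baseline_window=baseline,
        trial_index=np.asarray(kept),
    )


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def remove_line_noise(
    signal: np.ndarray,
    fs: float,
    line_hz: float = 50.0,
    bandwidth: float = 0.5,
    max_harmonic_hz: float = 250.0,
) -> np.ndarray:
    """Spectral interpolation of power-line noise and its harmonics.

    The magnitude of rFFT bins within ``bandwidth`` of each harmonic is
    replaced by linear interpolation between the adjacent clean bins; bin
    phases are preserved.  A harmonic band is only touched when its median
    magnitude exceeds that of the flanking bins (a real line component), so
    clean recordings pass through essentially unchanged.
    """
    x = np.asarray(signal, float)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mag = np.abs(spec)
    phase = np.angle(spec)
    for h in np.arange(line_hz, max_harmonic_hz + 1e-9, line_hz):
        band = np.flatnonzero(np.abs(freqs - h) <= bandwidth)
        if band.size == 0:
            continue
        lo, hi = band[0] - 1, band[-1] + 1
        if lo < 0 or hi >= mag.size:
            continue
        flank = np.flatnonzero(
            (np.abs(freqs - h) > bandwidth) & (np.abs(freqs - h) <= 4 * bandwidth)
        )
        # a line concentrates in very few bins, so compare mean magnitudes
        if flank.size and np.mean(mag[band]) <= 1.5 * np.mean(mag[flank]):
            continue  # no line component here
        mag[band] = np.interp(band, [lo, hi], [mag[lo], mag[hi]])
    return np.fft.irfft(mag * np.exp(1j * phase), n=x.size)


def emg_envelope(signal: np.ndarray, fs: float, lowpass_hz: float = 10.0) -> np.ndarray:
    """Full-wave rectification then 4th-order zero-phase 10 Hz low-pass."""
    sos = butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.abs(np.asarray(signal, float)))


@dataclass
class Burst:
    onset: float
    offset: float
    peak_time: float
    peak_amplitude: float
    contains_rt: bool


def detect_bursts(
    envelope: np.ndarray,
    fs: float,
    stim_onset: float,
    rt: float,
    baseline_window_s: float = 0.5,
    n_sd: float = 3.0,
    merge_gap_s: float = 0.020,
    min_duration_s: float = 0.025,
    search_pad_s: float = 0.5,
) -> tuple[list[Burst], Burst | None]:
    """Single-threshold burst detection on an envelope trace.

    The baseline is the 500 ms window with the lowest moving-average
    amplitude between 1 s before stimulus onset and the response time; the
    threshold is its mean + 3 SD.  Contiguous supra-threshold runs become
    bursts, runs separated by less than 20 ms merge, isolated bursts shorter
    than 25 ms are dropped.  The burst whose [onset, offset] contains
    ``stim_onset + rt`` is the RT-generating burst (None if no burst
    contains it).
    """
    if not np.isfinite(rt):
        raise ValueError("rt is missing; cannot search for a response burst")
    env = np.asarray(envelope, float)
    i_lo = int(round((stim_onset - 1.0) * fs))
    i_rt = int(round((stim_onset + rt) * fs))
    win = int(round(baseline_window_s * fs))
    if i_lo < 0 or i_rt - win <= i_lo or i_rt > env.size:
        raise ValueError("baseline search span unavailable in this envelope")
    seg = env[i_lo:i_rt]
    csum = np.concatenate([[0.0], np.cumsum(seg)])
    means = (csum[win:] - csum[:-win]) / win
    start = int(np.argmin(means))
    bl = seg[start : start + win]
    thresh = bl.mean() + n_sd * bl.std()

    i_hi = min(int(round((stim_onset + rt + search_pad_s) * fs)), env.size)
    above = env[i_lo:i_hi] > thresh
    if not above.any():
        return [], None
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    gap = int(round(merge_gap_s * fs))
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = int(round(min_duration_s * fs))
    bursts = []
    rt_abs = stim_onset + rt
    for s, e in merged:
        if e - s < min_len:
            continue
        seg_b = env[i_lo + s : i_lo + e]
        pk = int(np.argmax(seg_b))
        onset_t = (i_lo + s) / fs
        offset_t = (i_lo + e - 1) / fs
        bursts.append(
            Burst(
                onset=onset_t,
                offset=offset_t,
                peak_time=(i_lo + s + pk) / fs,
                peak_amplitude=float(seg_b[pk]),
                contains_rt=bool(onset_t <= rt_abs <= offset_t),
            )
        )
    rt_burst = next((b for b in bursts if b.contains_rt), None)
    return bursts, rt_burst


def reject_outlier_peaks(peak_amplitudes: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Tukey-fence keep-mask over one participant's peak amplitudes."""
    x = np.asarray(peak_amplitudes, float)
    if x.size < 8:
        raise ValueError("need at least 8 trials for outlier fences")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def epoch_around_peaks(
    envelope: np.ndarray,
    fs: float,
    peak_times: np.ndarray,
    half_window_s: float = 0.5,
    trial_index: np.ndarray | None = None,
) -> EpochMatrix:
    """Peak-centered +/-500 ms EMG epochs at the native envelope resolution."""
    half = int(round(half_window_s * fs))
    time_axis = np.arange(-half, half + 1) / fs
    rows, kept = [], []
    idx = np.arange(len(peak_times)) if trial_index is None else np.asarray(trial_index)
    for ti, pt in zip(idx, peak_times):
        c = int(round(pt * fs))
        if c - half < 0 or c + half + 1 > envelope.size:
            continue
        rows.append(envelope[c - half : c + half + 1])
        kept.append(ti)
    if not rows:
        raise ValueError("no peaks with a full window inside the recording")
    return EpochMatrix(
        values=np.asarray(rows),
        time_axis=time_axis,
        fs_epoch=fs,
        lock="emg_peak",
        trial_index=np.asarray(kept),
    )


def participant_quality_ok(n_dropped: int, n_total: int, max_dropped_frac: float = 0.20) -> bool:
    """Automated participant-level exclusion rule: a recording loses its
    participant when more than 20% of trials were dropped by the artifact
    rules (the automated stand-in for exclusion by visual inspection)."""
    if n_total <= 0:
        return False
    return n_dropped / n_total <= max_dropped_frac


def zscore_within_participant(epochs: EpochMatrix) -> EpochMatrix:
    """Z-score every sample with one mean/SD over the concatenated trials."""
    if epochs.values.shape[0] < 2:
        raise ValueError("need at least 2 trials to z-score")
    mu = epochs.values.mean()
    sd = epochs.values.std()
    if sd == 0:
        raise ValueError("zero variance; cannot z-score")
    return EpochMatrix(
        values=(epochs.values - mu) / sd,
        time_axis=epochs.time_axis,
        fs_epoch=epochs.fs_epoch,
        lock=epochs.lock,
        baseline_window=epochs.baseline_window,
        trial_index=epochs.trial_index,
    )
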
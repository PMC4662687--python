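"""Per-trial feature bank from respiration, skin conductance, BVP and HRV.

Exactly 40 named features per trial, computed over the 12 s stimulus block
of each trial from the preprocessed (smoothed, 256 Hz) peripheral channels:

* respiration (10): mean, variance, SD, kurtosis, skewness, max-min, and
  band powers in [0, 0.5), [0.5, 1), [1, 1.5), [1.5, 2) Hz;
* skin conductance (9): mean, variance, SD, kurtosis, skewness, maximum,
  mean derivative (per second), signal energy (mean squared value) and the
  proportion of negative first-difference samples;
* BVP (15): the five raw-waveform moments plus mean and variance of five
  per-beat "variability" series — trough values, peak values, beat
  amplitudes (peak minus preceding trough), per-beat mean values, and a
  baseline series (2 s moving mean sampled at beat times);
* HRV (6): mean, variance and SD of the heart-rate series, LF power
  (0.05-0.15 Hz) of the 4 Hz-resampled HR series, LF relative to total
  power over 0.05-1 Hz, and the Petrosian fractal dimension of HR.

Kurtosis is the non-excess convention (a normal distribution gives 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .core import Recording, StimulusSchedule, trial_key
from .eeg_features import petrosian_fd
from .preprocessing import downsample, moving_average

RESP_FEATURES = ("mean", "var", "sd", "kurtosis", "skewness", "range",
                 "bp_0.0_0.5", "bp_0.5_1.0", "bp_1.0_1.5", "bp_1.5_2.0")
SC_FEATURES = ("mean", "var", "sd", "kurtosis", "skewness", "max",
               "deriv_mean", "energy", "deriv_neg_prop")
BVP_FEATURES = ("mean", "var", "sd", "kurtosis", "skewness",
                "trough_mean", "trough_var", "peak_mean", "peak_var",
                "amp_mean", "amp_var", "beatmean_mean", "beatmean_var",
                "baseline_mean", "baseline_var")
HRV_FEATURES = ("hr_mean", "hr_var", "hr_sd", "lf_power", "lf_ratio",
                "hr_pfd")

#: All 40 feature names in fixed order.
PERIPHERAL_FEATURE_NAMES = tuple(
    [f"resp_{f}" for f in RESP_FEATURES]
    + [f"sc_{f}" for f in SC_FEATURES]
    + [f"bvp_{f}" for f in BVP_FEATURES]
    + [f"hrv_{f}" for f in HRV_FEATURES])


@dataclass
class BeatSeries:
    """Beat landmarks extracted from a BVP waveform."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_values: np.ndarray = field(default_factory=lambda: np.array([]))
    trough_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def ibi(self) -> np.ndarray:
        """Successive peak-to-peak intervals in seconds."""
        return np.diff(self.peak_times)

    @property
    def hr(self) -> np.ndarray:
        """Instantaneous heart rate, beats/min, one value per interval."""
        return 60.0 / self.ibi

    @property
    def n_beats(self) -> int:
        return len(self.peak_times)


def _enforce_alternation(times_a, vals_a, times_b, vals_b, keep_max: bool):
    """Drop the lesser (or greater) of two same-type consecutive extrema so
    that peaks and troughs alternate in time."""
    events = [(t, v, 0) for t, v in zip(times_a, vals_a)] + \
             [(t, v, 1) for t, v in zip(times_b, vals_b)]
    events.sort()
    cleaned = []
    for t, v, kind in events:
        if cleaned and cleaned[-1][2] == kind:
            prev = cleaned[-1]
            better = (v > prev[1]) if (kind == 0) == keep_max else (v < prev[1])
            if better:
                cleaned[-1] = (t, v, kind)
        else:
            cleaned.append((t, v, kind))
    a = [(t, v) for t, v, k in cleaned if k == 0]
    b = [(t, v) for t, v, k in cleaned if k == 1]
    return (np.array([t for t, _ in a]), np.array([v for _, v in a]),
            np.array([t for t, _ in b]), np.array([v for _, v in b]))


def detect_beats(bvp: np.ndarray, fs: float,
                 refractory_s: float = 0.33) -> BeatSeries:
    """Detect systolic peaks and diastolic troughs in a BVP waveform.

    Local extrema with a refractory period (default 0.33 s, i.e. a maximum
    plausible rate of ~180 bpm); alternation is enforced by discarding the
    lesser of two consecutive same-type extrema.
    """
    x = np.asarray(bvp, dtype=float)
    dist = max(int(round(refractory_s * fs)), 1)
    prom = 0.1 * (np.max(x) - np.min(x)) if np.ptp(x) > 0 else None
    if prom is None or prom == 0:
        warnings.warn("no detectable beats (flat signal)", stacklevel=2)
        empty = np.array([])
        return BeatSeries(empty, empty.copy(), empty.copy(), empty.copy())
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-x, distance=dist, prominence=prom)
    if len(peaks) == 0:
        warnings.warn("no detectable beats", stacklevel=2)
        empty = np.array([])
        return BeatSeries(empty, empty.copy(), empty.copy(), empty.copy())
    pt, pv, tt, tv = _enforce_alternation(
        peaks / fs, x[peaks], troughs / fs, x[troughs], keep_max=True)
    return BeatSeries(peak_times=pt, trough_times=tt,
                      peak_values=pv, trough_values=tv)


def _moments(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, variance, SD, non-excess kurtosis, skewness)."""
    return (float(np.mean(x)), float(np.var(x)), float(np.std(x)),
            float(stats.kurtosis(x, fisher=False)) if np.std(x) > 0 else 0.0,
            float(stats.skew(x)) if np.std(x) > 0 else 0.0)


def _band_powers(x: np.ndarray, fs: float,
                 edges: list[tuple[float, float]]) -> list[float]:
    f, pxx = signal.periodogram(x, fs=fs, window="hann", detrend="constant")
    return [float(np.sum(pxx[(f >= lo) & (f < hi)])) for lo, hi in edges]


def respiration_features(resp: np.ndarray, fs: float) -> np.ndarray:
    """Ten respiration features (moments, range and 0-2 Hz band powers)."""
    x = np.asarray(resp, dtype=float)
    if len(x) < 12 * fs:
        raise ValueError("respiration segment shorter than one 12 s block")
    m, v, sd, k, sk = _moments(x)
    bands = _band_powers(x, fs, [(0.0, 0.5), (0.5, 1.0), (1.0, 1.5),
                                 (1.5, 2.0)])
    return np.array([m, v, sd, k, sk, float(np.ptp(x))] + bands)


def sc_features(sc: np.ndarray, fs: float) -> np.ndarray:
    """Nine skin-conductance features (moments, max, derivative, energy)."""
    x = np.asarray(sc, dtype=float)
    if len(x) < 2:
        raise ValueError("SC segment too short")
    m, v, sd, k, sk = _moments(x)
    d = np.diff(x)
    return np.array([m, v, sd, k, sk, float(np.max(x)),
                     float(np.mean(d) * fs), float(np.mean(x ** 2)),
                     float(np.mean(d < 0))])


def bvp_features(bvp: np.ndarray, fs: float, beats: BeatSeries) -> np.ndarray:
    """Fifteen BVP features: raw moments + five per-beat variability pairs."""
    x = np.asarray(bvp, dtype=float)
    if beats.n_beats < 3:
        raise ValueError("need at least 3 detected beats")
    m, v, sd, k, sk = _moments(x)

    def mv(series: np.ndarray) -> tuple[float, float]:
        if len(series) == 0:
            return 0.0, 0.0
        return float(np.mean(series)), float(np.var(series))

    # amplitude: peak minus the immediately preceding trough
    amps = []
    for t_pk, v_pk in zip(beats.peak_times, beats.peak_values):
        prior = np.flatnonzero(beats.trough_times < t_pk)
        if prior.size:
            amps.append(v_pk - beats.trough_values[prior[-1]])
    # per-beat mean value: mean of samples between consecutive peaks
    beat_means = []
    idx = (beats.peak_times * fs).astype(int)
    for i0, i1 in zip(idx[:-1], idx[1:]):
        if i1 > i0:
            beat_means.append(float(np.mean(x[i0:i1])))
    # baseline: 2 s moving mean sampled at beat (peak) times
    base = moving_average(x, min(int(round(2.0 * fs)), len(x)))
    baseline = base[np.clip(idx, 0, len(x) - 1)]

    pairs = [mv(beats.trough_values), mv(beats.peak_values),
             mv(np.asarray(amps)), mv(np.asarray(beat_means)), mv(baseline)]
    return np.array([m, v, sd, k, sk] + [u for p in pairs for u in p])


def hrv_features(beats: BeatSeries, resample_fs: float = 4.0) -> np.ndarray:
    """Six HRV features from the beat series.

    The HR series is cubic-interpolated onto an even ``resample_fs`` grid
    before the periodogram; LF is 0.05-0.15 Hz and total power is 0.05-1 Hz.
    """
    if beats.n_beats < 8:
        raise ValueError("need at least 8 beats for HRV features")
    hr = beats.hr
    hr_t = beats.peak_times[1:]  # HR value assigned to the closing beat
    m, v, sd = float(np.mean(hr)), float(np.var(hr)), float(np.std(hr))
    t_grid = np.arange(hr_t[0], hr_t[-1], 1.0 / resample_fs)
    if len(t_grid) >= 4:
        cs = interpolate.CubicSpline(hr_t, hr)
        hr_even = cs(t_grid)
        lf, total = _band_powers(hr_even, resample_fs,
                                 [(0.05, 0.15), (0.05, 1.0)])
    else:
        lf, total = 0.0, 0.0
    ratio = lf / total if total > 0 else 0.0
    pfd = petrosian_fd(hr) if len(hr) >= 3 else 1.0
    return np.array([m, v, sd, lf, ratio, pfd])


def preprocess_peripherals(recording: Recording, smooth_s: float = 0.25
                           ) -> dict[str, tuple[np.ndarray, float]]:
    """Smooth and downsample the peripheral channels to 256 Hz.

    BVP and SC (2048 Hz) are decimated by 8; all three channels are then
    moving-average smoothed (except BVP, which is smoothed only lightly so
    that systolic peaks survive).
    """
    out = {}
    for name in ("BVP", "SC", "RESP"):
        ch = recording.channel(name)
        x, fs = ch.samples, ch.fs
        if fs != 256.0:
            x = downsample(x, fs, 256.0)
            fs = 256.0
        win = int(round((0.05 if name == "BVP" else smooth_s) * fs))
        x = moving_average(x, max(win, 1))
        out[name] = (x, fs)
    return out


def extract_peripheral_features(recording: Recording,
                                schedule: StimulusSchedule | None = None,
                                smooth_s: float = 0.25) -> pd.DataFrame:
    """One 40-column row per trial, computed over its 12 s stimulus block."""
    schedule = schedule or recording.schedule
    prep = preprocess_peripherals(recording, smooth_s=smooth_s)
    rows, meta = [], []
    for trial in schedule.trials:
        vec = []
        resp, fs_r = prep["RESP"]
        sc, fs_s = prep["SC"]
        bvp, fs_b = prep["BVP"]
        i0r, i1r = int(trial.block_start_s * fs_r), int(trial.end_s * fs_r)
        i0b, i1b = int(trial.block_start_s * fs_b), int(trial.end_s * fs_b)
        seg_bvp = bvp[i0b:i1b]
        beats = detect_beats(seg_bvp, fs_b)
        vec.extend(respiration_features(resp[i0r:i1r], fs_r))
        vec.extend(sc_features(sc[i0b:i1b], fs_s))
        vec.extend(bvp_features(seg_bvp, fs_b, beats))
        vec.extend(hrv_features(beats))
        rows.append(vec)
        meta.append(trial)
    df = pd.DataFrame(rows, columns=list(PERIPHERAL_FEATURE_NAMES))
    df.insert(0, "intended_class", [t.intended_class for t in meta])
    df.insert(0, "trial_key", [trial_key(recording.subject_id, t.trial_id)
                               for t in meta])
    df.insert(0, "trial_id", [t.trial_id for t in meta])
    df.insert(0, "subject", recording.subject_id)
    return df
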
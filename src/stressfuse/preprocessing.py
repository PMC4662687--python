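"""Filtering, smoothing, downsampling, artifact rejection and segmentation.

EEG is band-pass filtered to 0.5-40 Hz with a zero-phase (forward-backward)
4th-order Butterworth filter, peripheral channels are smoothed with a moving
average and decimated from 2048 Hz to the common 256 Hz rate, and epochs are
cut with a rectangular window (2 s / 512 samples, no overlap, by default).
Epochs exceeding an absolute-amplitude threshold are rejected, standing in
for manual removal of blinks, drifts and environmental noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)


@dataclass
class Epoch:
    samples: np.ndarray
    channel: str
    trial_id: int
    t_start_s: float


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping signal epochs with their provenance."""

    epochs: list[Epoch]
    fs: float
    epoch_len: int

    def __post_init__(self) -> None:
        for e in self.epochs:
            if len(e.samples) != self.epoch_len:
                raise ValueError("all epochs must have exactly epoch_len "
                                 "samples")

    def __len__(self) -> int:
        return len(self.epochs)


def bandpass_eeg(samples: np.ndarray, fs: float, lo: float = 0.5,
                 hi: float = 40.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi < "
                         f"Nyquist ({fs / 2})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def moving_average(samples: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window == 1`` is the identity; output length equals input length.
    """
    x = np.asarray(samples, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError("window longer than the signal")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def downsample(samples: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased decimation by the integer factor ``fs_in / fs_out``."""
    x = np.asarray(samples, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs_in/fs_out = {factor} is not an integer factor")
    q = int(round(factor))
    if q == 1:
        return x.copy()
    y = signal.decimate(x, q, ftype="fir", zero_phase=True)
    n_out = int(len(x) * fs_out // fs_in)
    return y[:n_out]


def segment(samples: np.ndarray, fs: float, epoch_s: float,
            overlap: float, trial_windows: list[tuple[float, float, int]],
            channel: str = "") -> EpochSet:
    """Tile each trial window with fixed-length epochs, left to right.

    ``trial_windows`` is a list of ``(start_s, end_s, trial_id)``. A trailing
    partial window is dropped. ``overlap`` is the fractional overlap between
    consecutive epochs (0 for the rectangular non-overlapping configuration).
    """
    x = np.asarray(samples, dtype=float)
    epoch_len_f = epoch_s * fs
    if abs(epoch_len_f - round(epoch_len_f)) > 1e-9:
        raise ValueError("epoch_s * fs must be an integer number of samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    epoch_len = int(round(epoch_len_f))
    step = max(int(round(epoch_len * (1 - overlap))), 1)
    epochs = []
    for start_s, end_s, trial_id in trial_windows:
        i0 = int(round(start_s * fs))
        i1 = min(int(round(end_s * fs)), len(x))
        if i1 - i0 < epoch_len:
            warnings.warn(f"trial {trial_id}: window shorter than one epoch; "
                          "no epochs produced", stacklevel=2)
            continue
        for s in range(i0, i1 - epoch_len + 1, step):
            epochs.append(Epoch(samples=x[s:s + epoch_len], channel=channel,
                                trial_id=int(trial_id), t_start_s=s / fs))
    return EpochSet(epochs=epochs, fs=fs, epoch_len=epoch_len)


def remove_artifact_epochs(epochs: EpochSet, amp_threshold: float
                           ) -> tuple[EpochSet, list[int]]:
    """Reject epochs whose peak absolute amplitude exceeds the threshold.

    Returns the retained :class:`EpochSet` and the indices (into the input
    epoch list) of the rejected epochs.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be > 0")
    if not epochs.epochs:
        warnings.warn("empty epoch set passed to artifact removal",
                      stacklevel=2)
        return EpochSet([], epochs.fs, epochs.epoch_len), []
    kept, rejected = [], []
    for i, e in enumerate(epochs.epochs):
        if np.max(np.abs(e.samples)) <= amp_threshold:
            kept.append(e)
        else:
            rejected.append(i)
    if rejected:
        log.info("rejected %d/%d epochs above %.3g",
                 len(rejected), len(epochs.epochs), amp_threshold)
    return EpochSet(kept, epochs.fs, epochs.epoch_len), rejected
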
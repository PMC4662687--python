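"""Per-epoch EEG features: fractal dimension, Lempel-Ziv complexity and
db4 wavelet sub-band statistics.

For each 512-sample (2 s) epoch and channel the feature vector is:

* **Petrosian fractal dimension (PFD)** — from the number of sign changes
  ``N_delta`` of the first-difference sequence of the ``N``-sample epoch::

      PFD = log10(N) / (log10(N) + log10(N / (N + 0.4 * N_delta)))

  A zero first difference inherits the previous sign so the sequence stays
  binary; a constant or monotone epoch has ``N_delta = 0`` and ``PFD = 1``.

* **Normalized Lempel-Ziv complexity** — the epoch is binarized at its
  median, parsed into the LZ76 exhaustive history (the final, possibly
  non-innovative word is counted), and the word count ``c(n)`` is normalized
  by the random-sequence asymptote ``b(n) = n / log2(n)``:
  ``C(n) = c(n) * log2(n) / n``.

* **12 wavelet statistics** — a 5-level db4 DWT (periodization boundary, so
  the transform is orthonormal) yields sub-bands A5 (delta, 0-4 Hz),
  D5 (theta, 4-8), D4 (alpha, 8-16) and D3 (beta, 16-32) at 256 Hz; D1 and
  D2 (> 32 Hz) are discarded as noise. Per retained band: mean absolute
  coefficient, average power (mean squared coefficient) and standard
  deviation — 3 x 4 = 12 features per channel.

With PFD and LZC this is 14 features per channel, 70 per epoch for the
five-channel montage. Features are min-max normalized to [-1, 1] with the
affine map fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .core import EEG_CHANNELS, feature_columns
from .preprocessing import EpochSet

SUBBANDS = ("A5", "D5", "D4", "D3")
SUBBAND_STATS = ("meanabs", "power", "std")

#: Per-channel feature suffixes, fixed order.
CHANNEL_FEATURES = ("pfd", "lzc") + tuple(
    f"{b}_{s}" for b in SUBBANDS for s in SUBBAND_STATS)


@dataclass
class BinarySequence:
    """A 0/1 symbolization of an epoch with the threshold that produced it."""

    bits: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size and not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("alphabet must be exactly {0, 1}")

    def __len__(self) -> int:
        return len(self.bits)


def sign_changes(samples: np.ndarray) -> int:
    """Number of sign changes in the first-difference sequence.

    Zero differences inherit the previous sign (leading zeros take the first
    nonzero sign), so constant and monotone inputs give 0.
    """
    d = np.diff(np.asarray(samples, dtype=float))
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return 0
    # propagate the last nonzero sign forward, then backfill the head
    idx = np.maximum.accumulate(np.where(s != 0, np.arange(len(s)), -1))
    first = nz[0]
    idx[idx < 0] = first
    filled = s[idx]
    return int(np.count_nonzero(np.diff(filled)))


def petrosian_fd(samples: np.ndarray) -> float:
    """Petrosian fractal dimension of an epoch (>= 1; 1 for monotone input)."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    n_delta = sign_changes(x)
    if n_delta == 0:
        return 1.0
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def binarize(samples: np.ndarray, mode: str = "median") -> BinarySequence:
    """Threshold an epoch into bits: 0 where value <= threshold, else 1."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot binarize an empty sequence")
    if mode == "median":
        thr = float(np.median(x))
    elif mode == "mean":
        thr = float(np.mean(x))
    else:
        raise ValueError(f"unknown binarization mode {mode!r}")
    return BinarySequence(bits=(x > thr).astype(np.uint8), threshold_used=thr)


def lz_complexity(bits: BinarySequence | np.ndarray) -> int:
    """LZ76 word count c(n) of a binary sequence.

    Exhaustive-history parsing: scanning left to right, the current word is
    extended until it is no longer a substring of the prefix ending one
    symbol before the current position; the final word is counted even if it
    is not innovative.
    """
    b = bits.bits if isinstance(bits, BinarySequence) else np.asarray(bits)
    n = len(b)
    if n == 0:
        raise ValueError("empty sequence")
    s = "".join("1" if v else "0" for v in b)
    c = 0
    i = 0
    while i < n:
        j = i + 1
        # grow the word while s[i:j] occurs in s[:j-1]
        while j <= n and s.find(s[i:j], 0, j - 1) != -1:
            j += 1
        c += 1
        i = j if j <= n else n
    return c


def normalized_lz(samples: np.ndarray, mode: str = "median") -> float:
    """Median-binarized, b(n)-normalized Lempel-Ziv complexity C(n)."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    c = lz_complexity(binarize(x, mode=mode))
    return float(c * np.log2(n) / n)


def dwt_subband_stats(samples: np.ndarray, fs: float = 256.0,
                      wavelet: str = "db4", level: int = 5) -> np.ndarray:
    """Mean-abs / average-power / SD over the A5, D5, D4, D3 sub-bands.

    Returns the 12 statistics in :data:`CHANNEL_FEATURES` order (band-major:
    A5 then D5, D4, D3; meanabs, power, std within each band).
    """
    x = np.asarray(samples, dtype=float)
    min_len = 2 ** level
    if len(x) < min_len:
        raise ValueError(f"epoch of {len(x)} samples too short for "
                         f"{level}-level DWT")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    # coeffs = [A5, D5, D4, D3, D2, D1]; keep the first four
    out = []
    for c in coeffs[:4]:
        out.extend([np.mean(np.abs(c)), np.mean(c ** 2), np.std(c)])
    return np.asarray(out)


def extract_eeg_features(epochs: EpochSet,
                         channels: tuple[str, ...] = EEG_CHANNELS,
                         binarize_mode: str = "median") -> pd.DataFrame:
    """One row per epoch slot with all channels' features concatenated.

    Epoch slots are identified by ``(trial_id, t_start_s)``; a slot is kept
    only if every configured channel survived artifact rejection, so rows are
    complete. Columns are ``<channel>_<feature>`` in fixed order, preceded by
    ``trial_id``, ``epoch_id`` and ``t_start_s``.
    """
    present = {e.channel for e in epochs.epochs}
    for ch in channels:
        if epochs.epochs and ch not in present:
            raise ValueError(f"missing channel {ch!r} in epoch set")
    by_slot: dict[tuple[int, float], dict[str, np.ndarray]] = {}
    for e in epochs.epochs:
        if e.channel in channels:
            by_slot.setdefault((e.trial_id, e.t_start_s), {})[e.channel] = \
                e.samples
    colnames = [f"{ch}_{f}" for ch in channels for f in CHANNEL_FEATURES]
    rows, meta = [], []
    for slot in sorted(by_slot):
        chans = by_slot[slot]
        if any(ch not in chans for ch in channels):
            continue  # partially rejected slot
        vec = []
        for ch in channels:
            x = chans[ch]
            vec.append(petrosian_fd(x))
            vec.append(normalized_lz(x, mode=binarize_mode))
            vec.extend(dwt_subband_stats(x, fs=epochs.fs))
        rows.append(vec)
        meta.append(slot)
    df = pd.DataFrame(rows, columns=colnames)
    df.insert(0, "t_start_s", [m[1] for m in meta] if meta else
              pd.Series(dtype=float))
    df.insert(0, "epoch_id", range(len(df)))
    df.insert(0, "trial_id", [m[0] for m in meta] if meta else
              pd.Series(dtype=int))
    return df


def normalize_features(matrix: pd.DataFrame,
                       fit_rows: np.ndarray | pd.Index | None = None,
                       params: dict[str, tuple[float, float]] | None = None
                       ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max normalize feature columns to [-1, 1].

    The affine map per feature sends ``[min, max]`` over ``fit_rows`` (all
    rows when omitted) to ``[-1, 1]``; it is then applied to *all* rows, so
    held-out values may fall outside [-1, 1]. Constant features map to 0.
    Pass ``params`` to reuse a previously fitted map.
    """
    out = matrix.copy()
    cols = feature_columns(matrix)
    if params is None:
        fit = matrix if fit_rows is None else matrix.loc[fit_rows]
        if len(fit) == 0:
            raise ValueError("fit_rows must select at least one row")
        params = {c: (float(fit[c].min()), float(fit[c].max())) for c in cols}
    for c in cols:
        lo, hi = params[c]
        if hi - lo < 1e-12:
            out[c] = 0.0
        else:
            out[c] = 2.0 * (matrix[c] - lo) / (hi - lo) - 1.0
    return out, params
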
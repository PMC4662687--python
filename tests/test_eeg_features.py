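"""Fractal dimension, Lempel-Ziv and wavelet feature contracts."""

import itertools

import numpy as np
import pytest
import pywt

from stressfuse.eeg_features import (CHANNEL_FEATURES, BinarySequence,
                                     binarize, dwt_subband_stats,
                                     extract_eeg_features, lz_complexity,
                                     normalize_features, normalized_lz,
                                     petrosian_fd, sign_changes)
from stressfuse.preprocessing import Epoch, EpochSet

import pandas as pd


# --- independent oracles -------------------------------------------------

def pfd_oracle(x):
    """Two-pass reference: explicit sign sequence, then the formula."""
    x = np.asarray(x, float)
    signs = []
    last = 0
    for a, b in zip(x[:-1], x[1:]):
        d = b - a
        s = 1 if d > 0 else (-1 if d < 0 else last)
        signs.append(s)
        last = s if s != 0 else last
    # leading zeros inherit the first nonzero sign
    first_nz = next((s for s in signs if s != 0), 0)
    signs = [s if s != 0 else first_nz for s in signs]
    n_delta = sum(1 for a, b in zip(signs[:-1], signs[1:]) if a != b)
    n = len(x)
    if n_delta == 0:
        return 1.0
    return np.log10(n) / (np.log10(n)
                          + np.log10(n / (n + 0.4 * n_delta)))


def lz76_bruteforce(s: str) -> int:
    """Quadratic reference parser: substring membership by enumeration."""
    n = len(s)
    c, i = 0, 0
    while i < n:
        j = i + 1
        while j <= n:
            word = s[i:j]
            prefix = s[:j - 1]
            occurs = any(prefix[k:k + len(word)] == word
                         for k in range(len(prefix) - len(word) + 1))
            if not occurs:
                break
            j += 1
        c += 1
        i = j if j <= n else n
    return c


# --- Petrosian fractal dimension -----------------------------------------

class TestPetrosianFD:
    def test_monotone_ramp_gives_one(self):
        assert petrosian_fd(np.arange(512, dtype=float)) == 1.0

    def test_constant_gives_one(self):
        assert petrosian_fd(np.zeros(512)) == 1.0

    def test_alternating_sequence_maximal_sign_changes(self):
        x = np.tile([1.0, -1.0], 256)  # N = 512
        assert sign_changes(x) == 510  # every interior difference flips
        n, nd = 512, 510
        expected = np.log10(n) / (np.log10(n)
                                  + np.log10(n / (n + 0.4 * nd)))
        assert petrosian_fd(x) == pytest.approx(expected)

    def test_matches_independent_oracle_on_noise(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 512)
            assert petrosian_fd(x) == pytest.approx(pfd_oracle(x), abs=1e-12)

    def test_zero_differences_inherit_previous_sign(self):
        # up, flat, up: the flat step must not count as a change
        assert sign_changes(np.array([0.0, 1.0, 1.0, 2.0])) == 0
        # up, flat, down: exactly one change
        assert sign_changes(np.array([0.0, 1.0, 1.0, 0.0])) == 1

    def test_monotonic_in_sign_changes_exhaustive_n16(self):
        """PFD is nondecreasing in N_delta over its full range at N = 16."""
        n = 16
        values = []
        for n_delta in range(n - 1):  # 0 .. 14
            # exactly n_delta changes: a run of +1 diffs, then alternation
            diffs = [1.0] * (n - 1 - n_delta)
            for i in range(n_delta):
                diffs.append(-diffs[-1])
            x = np.concatenate([[0.0], np.cumsum(diffs)])
            assert sign_changes(x) == n_delta
            values.append(petrosian_fd(x))
        assert all(b >= a for a, b in zip(values[:-1], values[1:]))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            petrosian_fd(np.array([1.0, 2.0]))


# --- binarization and LZ76 ------------------------------------------------

class TestBinarize:
    def test_median_threshold(self):
        b = binarize(np.array([1.0, 2.0, 3.0, 4.0]), "median")
        np.testing.assert_array_equal(b.bits, [0, 0, 1, 1])
        assert b.threshold_used == 2.5

    def test_constant_all_zero(self):
        b = binarize(np.full(8, 3.3))
        np.testing.assert_array_equal(b.bits, np.zeros(8))

    def test_mean_threshold(self):
        b = binarize(np.array([0.0, 0.0, 10.0]), "mean")
        np.testing.assert_array_equal(b.bits, [0, 0, 1])

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            BinarySequence(bits=np.array([0, 1, 2]), threshold_used=0.0)


class TestLZComplexity:
    def test_all_zero_sequence(self):
        assert lz_complexity(np.zeros(16, dtype=int)) == 2

    def test_alternating_sequence(self):
        assert lz_complexity(np.array([0, 1, 0, 1, 0, 1, 0, 1])) == 3

    def test_single_bit(self):
        assert lz_complexity(np.array([1])) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lz_complexity(np.array([], dtype=int))

    def test_equals_bruteforce_for_all_length10_strings(self):
        for bits in itertools.product([0, 1], repeat=10):
            s = "".join(map(str, bits))
            assert lz_complexity(np.array(bits)) == lz76_bruteforce(s), s


class TestNormalizedLZ:
    def test_constant_epoch_512(self):
        # c = 2 for a constant binarized epoch; b(512) = 512/9
        assert normalized_lz(np.full(512, 1.3)) == pytest.approx(2 * 9 / 512)

    def test_fair_coin_near_unity(self):
        rng = np.random.default_rng(7)
        x = rng.choice([-1.0, 1.0], size=4096)
        assert 0.8 <= normalized_lz(x) <= 1.2

    def test_positive_for_nonconstant(self, rng):
        assert normalized_lz(rng.normal(0, 1, 512)) > 0


# --- wavelet sub-band statistics -----------------------------------------

class TestDWTSubbands:
    def test_zero_epoch_gives_zero_features(self):
        np.testing.assert_array_equal(dwt_subband_stats(np.zeros(512)),
                                      np.zeros(12))

    @pytest.mark.parametrize("freq,winner", [(10.0, "D4"), (6.0, "D5"),
                                             (2.0, "A5"), (20.0, "D3")])
    def test_tone_lands_in_expected_subband(self, freq, winner):
        t = np.arange(512) / 256.0
        feats = dwt_subband_stats(np.sin(2 * np.pi * freq * t), 256)
        powers = {b: feats[3 * i + 1] for i, b in
                  enumerate(["A5", "D5", "D4", "D3"])}
        assert max(powers, key=powers.get) == winner

    def test_energy_conservation_orthonormal(self, rng):
        x = rng.normal(0, 1, 512)
        coeffs = pywt.wavedec(x, "db4", mode="periodization", level=5)
        energy = sum(float(np.sum(c ** 2)) for c in coeffs)
        assert abs(energy - np.sum(x ** 2)) / np.sum(x ** 2) < 1e-6

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            dwt_subband_stats(np.zeros(16))


# --- normalization and extraction ----------------------------------------

class TestNormalizeFeatures:
    def test_minmax_to_unit_interval(self):
        df = pd.DataFrame({"a": [0.0, 5.0, 10.0]})
        out, _ = normalize_features(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        out, _ = normalize_features(df)
        np.testing.assert_array_equal(out["a"], np.zeros(3))

    def test_heldout_values_may_exceed_bounds(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, params = normalize_features(df, fit_rows=[0, 1])
        np.testing.assert_allclose(out["a"], [-1.0, 1.0, 3.0])
        out2, _ = normalize_features(df, params=params)
        np.testing.assert_allclose(out2["a"], out["a"])


def _epochset(rng, n_epochs, channels, fs=256.0, n=512):
    epochs = [Epoch(rng.normal(0, 1, n), ch, 0, 2.0 * i)
              for i in range(n_epochs) for ch in channels]
    return EpochSet(epochs, fs, n)


class TestExtractEEGFeatures:
    CHANNELS = ("FP1", "FP2", "T3", "T4", "Pz")

    def test_five_channel_shape(self, rng):
        feats = extract_eeg_features(_epochset(rng, 6, self.CHANNELS))
        assert feats.shape[0] == 6
        assert len([c for c in feats.columns
                    if c not in ("trial_id", "epoch_id", "t_start_s")]) == 70

    def test_single_channel_gives_14_columns(self, rng):
        feats = extract_eeg_features(_epochset(rng, 3, ("Pz",)),
                                     channels=("Pz",))
        assert len(feats.columns) == 3 + 14
        assert list(feats.columns[3:]) == [f"Pz_{f}"
                                           for f in CHANNEL_FEATURES]

    def test_empty_epochset_gives_headers_only(self):
        feats = extract_eeg_features(EpochSet([], 256.0, 512))
        assert len(feats) == 0
        assert "FP1_pfd" in feats.columns

    def test_missing_channel_raises(self, rng):
        with pytest.raises(ValueError, match="T4"):
            extract_eeg_features(_epochset(rng, 2, ("FP1", "FP2", "T3",
                                                    "Pz")))

    def test_partially_rejected_slot_dropped(self, rng):
        es = _epochset(rng, 3, self.CHANNELS)
        es.epochs.pop(7)  # remove one channel of the second slot
        feats = extract_eeg_features(es)
        assert len(feats) == 2
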
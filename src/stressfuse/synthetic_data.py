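"""Synthetic stimulus schedules, multimodal recordings and feature fixtures.

The generator emulates a picture-presentation protocol: each trial is a 10 s
fixation cross followed by a 12 s block of four affective pictures (3 s each),
with the two target states *calm_neutral* and *negative* (negatively excited).
Class-conditional structure mirrors what the downstream analysis assumes:

* EEG during negative blocks is a more strongly low-pass-weighted noise
  process, which lowers its sign-change rate and binary pattern diversity —
  i.e. its Petrosian fractal dimension and Lempel-Ziv complexity — without
  changing its variance;
* skin conductance shows a gradual event-related level rise during negative
  blocks (sympathetic sweat-gland activation);
* blood volume pulse is a pulsatile waveform whose instantaneous heart rate
  carries a 0.1 Hz low-frequency modulation and rises during negative blocks;
* respiration is a slow oscillation whose rate increases and becomes
  irregular during negative blocks.

Optionally a fraction of trials are *non-responders*: the physiology (and the
participant's self-assessment) follows the opposite class while the intended
stimulus label is kept. This is the label noise that peripheral-signal
screening exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .core import (CALM, CLASSES, EEG_CHANNELS, EEG_FS, NEGATIVE,
                   PERIPHERAL_FS, RESP_FS, Channel, Recording,
                   StimulusSchedule, Trial)

#: Class-conditional IAPS-style rating ranges (valence, arousal), stand-in
#: selection rule for the two target classes.
RATING_RANGES = {
    NEGATIVE: {"valence": (1.5, 3.5), "arousal": (6.0, 8.0)},
    CALM: {"valence": (4.0, 6.0), "arousal": (1.5, 3.5)},
}


@dataclass
class SubjectParams:
    """Subject-level effect sizes and noise levels for signal synthesis.

    Parameters
    ----------
    eeg_complexity_shift
        Increase of the low-pass mixing weight of the EEG noise process in
        the negative state (unitless, >= 0). Larger values reduce fractal
        dimension and Lempel-Ziv complexity of negative-block epochs.
    sc_level_shift
        Event-related skin-conductance rise during negative blocks, in uS.
    hr_shift
        Heart-rate elevation during negative blocks, in beats/min.
    noise_sd
        Per-modality additive noise scales (EEG scale in uV; SC in uS; BVP
        and RESP relative to unit waveform amplitude).
    nonresponse_p
        Probability that a trial's realized physiological state follows the
        class opposite to the intended one.
    artifact_rate_per_min
        Expected rate of blink-like amplitude bursts injected into the
        frontal EEG channels (FP1, FP2).
    """

    eeg_complexity_shift: float = 0.35
    sc_level_shift: float = 2.0
    hr_shift: float = 8.0
    noise_sd: dict = field(default_factory=lambda: {
        "EEG": 20.0, "SC": 0.05, "BVP": 0.03, "RESP": 0.05})
    seed: int = 0
    nonresponse_p: float = 0.0
    artifact_rate_per_min: float = 1.0
    baseline_hr_bpm: float = 70.0
    baseline_sc_us: float = 2.0
    #: Spontaneous (nonspecific) skin-conductance responses occur at rest
    #: regardless of stimulation; rate per minute and mean amplitude in uS.
    scr_rate_per_min: float = 2.0
    scr_amp_us: float = 0.15

    def __post_init__(self) -> None:
        if self.eeg_complexity_shift < 0:
            raise ValueError("eeg_complexity_shift must be >= 0")


def generate_protocol(n_trials: int = 8, picture_s: float = 3.0,
                      n_pictures: int = 4, fixation_s: float = 10.0,
                      class_balance: float = 0.5,
                      seed: int = 0,
                      self_rating_noise: float = 0.7) -> StimulusSchedule:
    """Generate a randomized picture-presentation schedule.

    ``class_balance`` is the fraction of trials whose intended class is
    *negative*; the class order is shuffled. Per-trial valence/arousal are
    drawn from class-conditional ranges and self-assessment ratings are the
    true ratings plus bounded uniform noise, clipped to the 1-9 scales.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if picture_s <= 0 or fixation_s < 0 or n_pictures < 1:
        raise ValueError("durations and picture count must be positive")
    if not 0.0 <= class_balance <= 1.0:
        raise ValueError("class_balance must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_neg = int(round(n_trials * class_balance))
    classes = np.array([NEGATIVE] * n_neg + [CALM] * (n_trials - n_neg))
    rng.shuffle(classes)

    block_s = n_pictures * picture_s
    trials = []
    t = 0.0
    for i, cls in enumerate(classes):
        rr = RATING_RANGES[cls]
        val = rng.uniform(*rr["valence"])
        aro = rng.uniform(*rr["arousal"])
        sv = float(np.clip(val + rng.uniform(-self_rating_noise,
                                             self_rating_noise), 1, 9))
        sa = float(np.clip(aro + rng.uniform(-self_rating_noise,
                                             self_rating_noise), 1, 9))
        trials.append(Trial(onset_s=t, fixation_s=fixation_s, block_s=block_s,
                            intended_class=str(cls), valence=float(val),
                            arousal=float(aro), self_valence=sv,
                            self_arousal=sa, trial_id=i))
        t += fixation_s + block_s
    return StimulusSchedule(trials)


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    kernel = np.ones(k)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same")


def _block_mask(schedule: StimulusSchedule, fs: float, n: int,
                states: list[str], target: str) -> np.ndarray:
    """Boolean mask of samples falling in blocks whose realized state is
    ``target``."""
    mask = np.zeros(n, dtype=bool)
    for trial, st in zip(schedule.trials, states):
        if st != target:
            continue
        i0 = int(round(trial.block_start_s * fs))
        i1 = int(round(trial.end_s * fs))
        mask[i0:min(i1, n)] = True
    return mask


def _smooth_transitions(x: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Single-pole low-pass, used to turn step-like state profiles into
    gradual physiological transitions (rise time ``tau_s``)."""
    alpha = 1.0 / (tau_s * fs)
    return signal.lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def synthesize_recording(schedule: StimulusSchedule,
                         params: SubjectParams,
                         subject_id: str = "S01") -> Recording:
    """Synthesize a full multimodal recording for one subject.

    Returns a :class:`Recording` with five EEG channels and RESP at 256 Hz
    and BVP/SC at 2048 Hz, spanning the whole schedule. Identical
    ``(schedule, params)`` give bit-identical samples.
    """
    if not schedule.trials:
        raise ValueError("schedule has no trials")
    dur = schedule.duration_s
    n_eeg = int(round(dur * EEG_FS))
    n_per = int(round(dur * PERIPHERAL_FS))
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(10)

    # Realized per-trial state: intended, flipped with prob nonresponse_p.
    rng_state = np.random.default_rng(streams[0])
    states = []
    for t in schedule.trials:
        if rng_state.uniform() < params.nonresponse_p:
            states.append(CALM if t.intended_class == NEGATIVE else NEGATIVE)
        else:
            states.append(t.intended_class)

    # Self ratings of non-responders are re-drawn near the realized class.
    new_trials = []
    for trial, st in zip(schedule.trials, states):
        if st != trial.intended_class:
            rr = RATING_RANGES[st]
            sv = float(np.clip(rng_state.uniform(*rr["valence"])
                               + rng_state.uniform(-0.7, 0.7), 1, 9))
            sa = float(np.clip(rng_state.uniform(*rr["arousal"])
                               + rng_state.uniform(-0.7, 0.7), 1, 9))
            new_trials.append(replace(trial, self_valence=sv, self_arousal=sa))
        else:
            new_trials.append(replace(trial))
    schedule = StimulusSchedule(new_trials)

    neg_eeg = _block_mask(schedule, EEG_FS, n_eeg, states, NEGATIVE)
    neg_per = _block_mask(schedule, PERIPHERAL_FS, n_per, states, NEGATIVE)

    channels: dict[str, Channel] = {}

    # --- EEG: variance-matched mixture of white noise and its moving
    # average; the mixing weight rises during negative blocks, lowering the
    # sign-change rate and pattern diversity without changing amplitude.
    k = 9
    base_mix = 0.25
    a = np.full(n_eeg, base_mix)
    a[neg_eeg] = min(base_mix + params.eeg_complexity_shift, 0.95)
    var_mix = (1 - a) ** 2 + a ** 2 / k + 2 * a * (1 - a) / k
    eeg_scale = params.noise_sd.get("EEG", 20.0)
    rng_art = np.random.default_rng(streams[1])
    channel_streams = streams[2].spawn(len(EEG_CHANNELS))
    for ci, name in enumerate(EEG_CHANNELS):
        w = np.random.default_rng(channel_streams[ci]).normal(0, 1, n_eeg)
        x = (1 - a) * w + a * _moving_average(w, k)
        x = x / np.sqrt(var_mix) * eeg_scale
        if name in ("FP1", "FP2") and params.artifact_rate_per_min > 0:
            n_bursts = rng_art.poisson(params.artifact_rate_per_min
                                       * dur / 60.0)
            for _ in range(n_bursts):
                i0 = int(rng_art.integers(0, max(n_eeg - 80, 1)))
                burst = 150.0 * np.hanning(80)
                x[i0:i0 + 80] += burst[:len(x[i0:i0 + 80])]
        channels[name] = Channel(x, EEG_FS, "EEG")

    # --- Skin conductance: tonic level + slow drift + event-related rises.
    rng_sc = np.random.default_rng(streams[3])
    t_per = np.arange(n_per) / PERIPHERAL_FS
    target = np.where(neg_per, params.sc_level_shift, 0.0)
    phasic = _smooth_transitions(target, PERIPHERAL_FS, tau_s=2.5)
    drift = 0.15 * np.sin(2 * np.pi * 0.005 * t_per + rng_sc.uniform(0, 2 * np.pi))
    sc_noise = _moving_average(rng_sc.normal(0, 1, n_per), 257) \
        * params.noise_sd.get("SC", 0.05) * 16.0
    # spontaneous (nonspecific) SCRs: sharp rise, slow exponential recovery
    spont = np.zeros(n_per)
    if params.scr_rate_per_min > 0:
        n_scr = rng_sc.poisson(params.scr_rate_per_min * dur / 60.0)
        onsets = np.sort(rng_sc.uniform(0, dur, n_scr))
        amps = rng_sc.exponential(params.scr_amp_us, n_scr)
        for t0_scr, amp in zip(onsets, amps):
            i0 = int(t0_scr * PERIPHERAL_FS)
            tail = t_per[i0:] - t0_scr
            spont[i0:] += amp * (1 - np.exp(-tail / 1.5)) * np.exp(-tail / 6.0)
    channels["SC"] = Channel(params.baseline_sc_us + drift + phasic
                             + spont + sc_noise, PERIPHERAL_FS, "SC")

    # --- Blood volume pulse: two-harmonic pulsatile waveform driven by an
    # instantaneous heart rate with LF (0.1 Hz) modulation, beat-to-beat
    # jitter, and a smoothed elevation during negative blocks.
    rng_bvp = np.random.default_rng(streams[4])
    hr_target = np.where(neg_per, params.hr_shift, 0.0)
    hr_rise = _smooth_transitions(hr_target, PERIPHERAL_FS, tau_s=2.0)
    lf_mod = 2.5 * np.sin(2 * np.pi * 0.1 * t_per + rng_bvp.uniform(0, 2 * np.pi))
    jitter = _moving_average(rng_bvp.normal(0, 1, n_per), 2048) * 12.0
    hr = params.baseline_hr_bpm + hr_rise + lf_mod + jitter
    phase = 2 * np.pi * np.cumsum(hr / 60.0) / PERIPHERAL_FS
    bvp = -np.cos(phase) + 0.3 * np.cos(2 * phase) \
        + rng_bvp.normal(0, params.noise_sd.get("BVP", 0.03), n_per)
    channels["BVP"] = Channel(bvp, PERIPHERAL_FS, "BVP")

    # --- Respiration: slow oscillation; faster and irregular when negative.
    rng_resp = np.random.default_rng(streams[5])
    n_resp = int(round(dur * RESP_FS))
    neg_resp = _block_mask(schedule, RESP_FS, n_resp, states, NEGATIVE)
    f_resp = np.full(n_resp, 0.25)
    f_resp[neg_resp] = 0.32
    irreg = _moving_average(rng_resp.normal(0, 1, n_resp), 129)
    f_resp = f_resp + 0.01 * irreg * 16.0 + np.where(neg_resp, 1.0, 0.0) \
        * 0.04 * _moving_average(rng_resp.normal(0, 1, n_resp), 129) * 16.0
    phase_r = 2 * np.pi * np.cumsum(np.clip(f_resp, 0.05, 1.0)) / RESP_FS
    resp = np.sin(phase_r) + rng_resp.normal(
        0, params.noise_sd.get("RESP", 0.05), n_resp)
    channels["RESP"] = Channel(resp, RESP_FS, "RESP")

    return Recording(channels=channels, schedule=schedule,
                     subject_id=subject_id, realized_classes=states)


def generate_feature_dataset(n_epochs: int, n_features: int,
                             n_informative: int, effect_size: float,
                             seed: int = 0) -> pd.DataFrame:
    """Fast two-class Gaussian feature fixture for selection/classifier tests.

    Exactly ``n_informative`` columns (named ``f<i>_inf``) have their class
    means separated by ``effect_size`` (in SD units); the remaining columns
    (``f<i>_noise``) are pure standard normal noise. Rows alternate classes;
    each row is its own trial group.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    if n_epochs < 2 or n_features < 1:
        raise ValueError("need at least 2 epochs and 1 feature")
    rng = np.random.default_rng(seed)
    labels = np.array([CLASSES[i % 2] for i in range(n_epochs)])
    X = rng.normal(0, 1, (n_epochs, n_features))
    y = (labels == NEGATIVE).astype(float)
    X[:, :n_informative] += np.outer(y - 0.5, np.full(n_informative,
                                                      effect_size))
    names = [f"f{i}_inf" if i < n_informative else f"f{i}_noise"
             for i in range(n_features)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", labels)
    df.insert(0, "trial_key", [f"fixture:{i}" for i in range(n_epochs)])
    return df
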
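"""Three-stage fusion-link labeling: peripheral signals as a label tutor.

A trial's EEG epochs receive the intended stimulus class as their label only
if the trial survives three screens:

1. **Self-assessment** — the participant's self-reported valence and arousal
   must both lie within ``max_discrepancy`` rating points of the stimulus
   ratings (inclusive).
2. **Qualitative peripheral check** — baseline-relative rules codifying the
   physiological narrative: a negative trial must show a skin-conductance
   rise or a heart-rate rise over its pre-stimulus fixation baseline; a calm
   trial must show neither a large SC rise nor respiratory irregularity.
3. **Quantitative peripheral classification** — a leave-one-trial-out
   one-vs-all SVM (RBF, C = 1) over the 40 peripheral features; the trial is
   accepted only if the held-out prediction matches the intended class.

Trials failing any applicable stage are rejected and their epochs excluded
from the labeled EEG dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CALM, NEGATIVE, Recording, StimulusSchedule, trial_key
from .peripheral_features import detect_beats, preprocess_peripherals
from .selection_classification import (ConfusionMatrix, REJECT, evaluate,
                                       train_ovr_svm)

log = logging.getLogger(__name__)


@dataclass
class TrialDecision:
    """Accept/reject outcome of the labeling stages for one trial."""

    trial_id: int
    trial_key: str = ""
    intended_class: str = ""
    stage1_pass: bool = True
    stage2_pass: bool = True
    stage3_predicted: str | None = None
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)


@dataclass
class LabeledDataset:
    """EEG feature rows restricted to accepted trials, with final labels."""

    features: pd.DataFrame
    rejected_fraction: float

    @property
    def labels(self) -> np.ndarray:
        return self.features["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class Stage2Config:
    """Thresholds of the qualitative peripheral screen (baseline-relative)."""

    neg_sc_rise_min_us: float = 0.1     # negative: SC must rise this much...
    neg_hr_rise_min_bpm: float = 1.0    # ...OR HR must rise this much
    calm_sc_rise_max_us: float = 1.0    # calm: no large SC rise...
    calm_resp_irregularity_max: float = 2.5  # ...and no resp irregularity


def stage1_self_assessment(schedule: StimulusSchedule,
                           max_discrepancy: float = 2.0) -> list[bool]:
    """Per-trial pass flags of the self-assessment screen (inclusive bound)."""
    flags = []
    for t in schedule.trials:
        if t.self_valence is None or t.self_arousal is None or \
                np.isnan(t.self_valence) or np.isnan(t.self_arousal):
            flags.append(False)
            continue
        flags.append(abs(t.self_valence - t.valence) <= max_discrepancy
                     and abs(t.self_arousal - t.arousal) <= max_discrepancy)
    return flags


def _window_mean(x: np.ndarray, fs: float, t0: float, t1: float) -> float:
    seg = x[int(t0 * fs):int(t1 * fs)]
    return float(np.mean(seg)) if len(seg) else 0.0


def _hr_mean(bvp: np.ndarray, fs: float, t0: float, t1: float) -> float:
    seg = bvp[int(t0 * fs):int(t1 * fs)]
    beats = detect_beats(seg, fs)
    return float(np.mean(beats.hr)) if beats.n_beats >= 2 else np.nan


def _irregularity(resp: np.ndarray, fs: float, t0: float, t1: float) -> float:
    seg = resp[int(t0 * fs):int(t1 * fs)]
    return float(np.std(np.diff(seg))) if len(seg) > 1 else 0.0


def stage2_qualitative(recording: Recording, trial,
                       config: Stage2Config | None = None,
                       prep: dict | None = None) -> tuple[bool, list[str]]:
    """Rule-based peripheral screen for one trial.

    The pre-stimulus fixation window serves as the trial's baseline; block
    statistics are compared against it. All thresholds are configurable and
    setting them to ``inf`` (and ``-inf`` for the minima) makes the screen
    vacuous.
    """
    config = config or Stage2Config()
    prep = prep or preprocess_peripherals(recording)
    sc, fs_sc = prep["SC"]
    bvp, fs_b = prep["BVP"]
    resp, fs_r = prep["RESP"]
    b0, b1 = trial.onset_s, trial.block_start_s          # fixation baseline
    s0, s1 = trial.block_start_s, trial.end_s            # stimulus block
    sc_rise = _window_mean(sc, fs_sc, s0, s1) - _window_mean(sc, fs_sc, b0, b1)
    hr_block = _hr_mean(bvp, fs_b, s0, s1)
    hr_base = _hr_mean(bvp, fs_b, b0, b1)
    hr_rise = (hr_block - hr_base
               if np.isfinite(hr_block) and np.isfinite(hr_base) else 0.0)
    irr_base = _irregularity(resp, fs_r, b0, b1)
    irr_block = _irregularity(resp, fs_r, s0, s1)
    irr_ratio = irr_block / irr_base if irr_base > 0 else 1.0

    reasons: list[str] = []
    if trial.intended_class == NEGATIVE:
        ok = (sc_rise >= config.neg_sc_rise_min_us
              or hr_rise >= config.neg_hr_rise_min_bpm)
        if not ok:
            reasons.append(
                f"no sympathetic response in negative trial "
                f"(SC rise {sc_rise:.2f} uS, HR rise {hr_rise:.1f} bpm)")
    else:
        ok = True
        if sc_rise > config.calm_sc_rise_max_us:
            ok = False
            reasons.append(f"SC rise in calm trial ({sc_rise:.2f} uS)")
        if irr_ratio > config.calm_resp_irregularity_max:
            ok = False
            reasons.append(
                f"respiration irregularity in calm trial (x{irr_ratio:.1f})")
    return ok, reasons


def stage3_quantitative(features: pd.DataFrame,
                        intended: np.ndarray | None = None,
                        kernel: str = "rbf", C: float = 1.0
                        ) -> tuple[list[TrialDecision], ConfusionMatrix]:
    """Leave-one-trial-out peripheral classification.

    For each trial, the one-vs-all SVM pair is trained on all remaining
    trials with their intended labels and predicts the held-out trial; the
    trial passes iff the prediction matches its intended class. The
    confusion matrix accumulates the held-out predictions.
    """
    y = np.asarray(features["intended_class"] if intended is None
                   else intended)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("stage 3 needs trials of both classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("stage 3 needs at least 2 trials per class")
    preds, decisions = [], []
    for i in range(len(features)):
        train = features.drop(index=features.index[i])
        held = features.iloc[[i]]
        model = train_ovr_svm(train.assign(label=np.delete(y, i)),
                              kernel=kernel, C=C)
        pred = model.predict(held)[0]
        preds.append(pred)
        tid = int(features.iloc[i]["trial_id"]) \
            if "trial_id" in features.columns else i
        tkey = str(features.iloc[i]["trial_key"]) \
            if "trial_key" in features.columns else str(i)
        dec = TrialDecision(trial_id=tid, trial_key=tkey,
                            intended_class=str(y[i]),
                            stage3_predicted=None if pred == REJECT else pred,
                            accepted=(pred == y[i]))
        if not dec.accepted:
            dec.reasons.append(
                f"peripheral classifier predicted {pred!r}, "
                f"intended {y[i]!r}")
        decisions.append(dec)
    cm = evaluate(preds, list(y))
    return decisions, cm


def build_labeled_dataset(eeg_features: pd.DataFrame,
                          decisions: list[TrialDecision]) -> LabeledDataset:
    """Keep epochs of accepted trials; label them with the intended class."""
    by_key = {d.trial_key: d for d in decisions}
    key_col = ("trial_key" if "trial_key" in eeg_features.columns
               else "trial_id")
    keys = eeg_features[key_col].astype(str)
    unknown = set(keys) - set(by_key)
    if unknown:
        raise ValueError(f"no decision for trials: {sorted(unknown)[:5]}")
    accepted_mask = keys.map(lambda k: by_key[k].accepted).to_numpy()
    labels = keys.map(lambda k: by_key[k].intended_class)
    out = eeg_features.copy()
    out["label"] = labels
    out = out[accepted_mask].reset_index(drop=True)
    n_rej = sum(1 for d in decisions if not d.accepted)
    frac = n_rej / len(decisions) if decisions else 0.0
    if len(out) == 0:
        warnings.warn("all trials rejected; labeled dataset is empty",
                      stacklevel=2)
    return LabeledDataset(features=out, rejected_fraction=frac)


def label_trials(recordings: list[Recording],
                 peripheral_features: pd.DataFrame,
                 max_discrepancy: float = 2.0,
                 stage2: Stage2Config | None = None,
                 kernel: str = "rbf", C: float = 1.0
                 ) -> tuple[list[TrialDecision], ConfusionMatrix]:
    """Run all three stages over the pooled trials of several recordings.

    Stage 3 is run on the full trial pool (it needs both classes); trials
    that already failed stage 1 or 2 are marked rejected regardless of the
    stage-3 prediction.
    """
    stage12: dict[str, tuple[bool, bool, list[str]]] = {}
    for rec in recordings:
        s1 = stage1_self_assessment(rec.schedule, max_discrepancy)
        prep = preprocess_peripherals(rec)
        for trial, ok1 in zip(rec.schedule.trials, s1):
            ok2, why2 = stage2_qualitative(rec, trial, stage2, prep=prep)
            why = ([] if ok1 else ["self-assessment discrepancy"]) + why2
            stage12[trial_key(rec.subject_id, trial.trial_id)] = (ok1, ok2,
                                                                  why)
    decisions, cm = stage3_quantitative(peripheral_features,
                                        kernel=kernel, C=C)
    for dec in decisions:
        ok1, ok2, why = stage12.get(dec.trial_key, (True, True, []))
        dec.stage1_pass, dec.stage2_pass = ok1, ok2
        dec.reasons = why + dec.reasons
        dec.accepted = bool(dec.accepted and ok1 and ok2)
    n_rej = sum(1 for d in decisions if not d.accepted)
    log.info("labeling: %d/%d trials rejected (%.1f%%)", n_rej,
             len(decisions), 100.0 * n_rej / max(len(decisions), 1))
    return decisions, cm


def decisions_frame(decisions: list[TrialDecision]) -> pd.DataFrame:
    """Decisions as a table for CSV export."""
    return pd.DataFrame({
        "trial_key": [d.trial_key for d in decisions],
        "trial_id": [d.trial_id for d in decisions],
        "intended_class": [d.intended_class for d in decisions],
        "stage1": [d.stage1_pass for d in decisions],
        "stage2": [d.stage2_pass for d in decisions],
        "stage3_pred": [d.stage3_predicted or "" for d in decisions],
        "accepted": [d.accepted for d in decisions],
        "reasons": ["; ".join(d.reasons) for d in decisions],
    })
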
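"""Shared domain types and constants.

Two emotional-stress classes are recognised throughout the package:
``calm_neutral`` and ``negative`` (negatively excited). Feature tables are
plain :class:`pandas.DataFrame` objects in which a fixed set of metadata
columns (:data:`META_COLUMNS`) coexists with named feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALM = "calm_neutral"
NEGATIVE = "negative"
CLASSES = (CALM, NEGATIVE)

#: Non-feature columns a FeatureMatrix may carry.
META_COLUMNS = ("subject", "trial_id", "trial_key", "epoch_id", "label",
                "intended_class", "t_start_s")

#: Fixed EEG montage (international 10-20 positions).
EEG_CHANNELS = ("FP1", "FP2", "T3", "T4", "Pz")

EEG_FS = 256.0
PERIPHERAL_FS = 2048.0
RESP_FS = 256.0


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature matrix (order preserved)."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


def trial_key(subject: str, trial_id: int) -> str:
    """Globally unique trial identifier across subjects."""
    return f"{subject}:{int(trial_id)}"


@dataclass
class Trial:
    """One stimulus trial: a fixation period followed by a picture block."""

    onset_s: float
    fixation_s: float
    block_s: float
    intended_class: str
    valence: float
    arousal: float
    self_valence: float
    self_arousal: float
    trial_id: int = 0

    @property
    def block_start_s(self) -> float:
        return self.onset_s + self.fixation_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.fixation_s + self.block_s


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping trials of one recording run."""

    trials: list[Trial]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for t in self.trials:
            if not (1.0 <= t.valence <= 9.0 and 1.0 <= t.arousal <= 9.0):
                raise ValueError("valence/arousal must lie in [1, 9]")
            if t.intended_class not in CLASSES:
                raise ValueError(f"unknown class {t.intended_class!r}")
            if t.onset_s < prev_end - 1e-9:
                raise ValueError("trials overlap or are out of order")
            prev_end = t.end_s

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        return self.trials[-1].end_s if self.trials else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.trial_id for t in self.trials],
                "onset_s": [t.onset_s for t in self.trials],
                "fixation_s": [t.fixation_s for t in self.trials],
                "block_s": [t.block_s for t in self.trials],
                "class": [t.intended_class for t in self.trials],
                "valence": [t.valence for t in self.trials],
                "arousal": [t.arousal for t in self.trials],
                "self_valence": [t.self_valence for t in self.trials],
                "self_arousal": [t.self_arousal for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StimulusSchedule":
        trials = [
            Trial(
                onset_s=float(r.onset_s), fixation_s=float(r.fixation_s),
                block_s=float(r.block_s), intended_class=str(r["class"]),
                valence=float(r.valence), arousal=float(r.arousal),
                self_valence=float(r.self_valence),
                self_arousal=float(r.self_arousal), trial_id=int(r.trial),
            )
            for _, r in frame.iterrows()
        ]
        return cls(trials)


@dataclass
class Channel:
    """One recorded channel: samples at a fixed rate with a modality tag."""

    samples: np.ndarray
    fs: float
    modality: str  # EEG | BVP | SC | RESP


@dataclass
class Recording:
    """Multichannel physiological recording spanning a stimulus schedule."""

    channels: dict[str, Channel]
    schedule: StimulusSchedule
    subject_id: str = "S01"
    #: Physiological state actually realised per trial (ground truth used only
    #: for diagnostics; the labeling stages never see it).
    realized_classes: list[str] | None = None

    def channel(self, name: str) -> Channel:
        if name not in self.channels:
            raise ValueError(f"missing channel {name!r}")
        return self.channels[name]
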
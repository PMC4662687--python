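"""End-to-end experiment orchestration.

One seeded configuration drives: simulate -> preprocess -> peripheral
features -> fusion-link labeling -> EEG features -> GA selection -> one-vs-
all SVM -> confusion-matrix evaluation. Every stochastic stage derives its
seed deterministically from the global seed, so the config fully determines
every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (CALM, EEG_CHANNELS, NEGATIVE, Recording, feature_columns,
                   trial_key)
from .eeg_features import extract_eeg_features
from .io import write_recording
from .labeling import (LabeledDataset, Stage2Config, TrialDecision,
                       build_labeled_dataset, decisions_frame, label_trials)
from .peripheral_features import extract_peripheral_features
from .preprocessing import (EpochSet, bandpass_eeg, remove_artifact_epochs,
                            segment)
from .selection_classification import (GAConfig, evaluate, ga_select,
                                       split_dataset, train_ovr_svm)
from .synthetic_data import SubjectParams, generate_protocol, \
    synthesize_recording

log = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    n_subjects: int = 15
    n_trials: int = 8
    picture_s: float = 3.0
    n_pictures: int = 4
    fixation_s: float = 10.0
    class_balance: float = 0.5
    eeg_complexity_shift: float = 0.35
    sc_level_shift: float = 2.0
    hr_shift: float = 8.0
    nonresponse_p: float = 0.1
    artifact_rate_per_min: float = 1.0


@dataclass
class PreprocessConfig:
    band_lo: float = 0.5
    band_hi: float = 40.0
    epoch_s: float = 2.0
    overlap: float = 0.0
    amp_threshold_uv: float = 100.0
    smooth_s: float = 0.25


@dataclass
class LabelingConfig:
    enabled: bool = True
    max_discrepancy: float = 2.0
    kernel: str = "rbf"
    C: float = 1.0
    stage2: Stage2Config = field(default_factory=Stage2Config)


@dataclass
class ClassifyConfig:
    kernel: str = "rbf"
    C: float = 1.0
    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    split: str = "trial"  # "trial" (grouped) | "epoch" (literal)


@dataclass
class ExperimentConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    selection: GAConfig = field(default_factory=GAConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    global_seed: int = 7
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def build(klass, block):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - fields
            if unknown:
                raise ValueError(f"unknown config keys for "
                                 f"{klass.__name__}: {sorted(unknown)}")
            return klass(**block)

        cfg = cls()
        if "simulate" in d:
            cfg.simulate = build(SimulateConfig, d["simulate"])
        if "preprocess" in d:
            cfg.preprocess = build(PreprocessConfig, d["preprocess"])
        if "labeling" in d:
            block = dict(d["labeling"])
            if "stage2" in block:
                block["stage2"] = build(Stage2Config, block["stage2"])
            cfg.labeling = build(LabelingConfig, block)
        if "selection" in d:
            cfg.selection = build(GAConfig, d["selection"])
        if "classify" in d:
            block = dict(d["classify"])
            if "fractions" in block:
                block["fractions"] = tuple(block["fractions"])
            cfg.classify = build(ClassifyConfig, block)
        cfg.global_seed = int(d.get("global_seed", cfg.global_seed))
        cfg.output_dir = str(d.get("output_dir", cfg.output_dir))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage_seeds(global_seed: int, n_subjects: int) -> dict:
    rng = np.random.default_rng(global_seed)
    draw = lambda: int(rng.integers(0, 2 ** 31 - 1))
    return {
        "protocol": [draw() for _ in range(n_subjects)],
        "recording": [draw() for _ in range(n_subjects)],
        "split": draw(),
        "ga": draw(),
    }


def simulate_study(config: ExperimentConfig) -> list[Recording]:
    """Generate the seeded cohort of recordings."""
    sim = config.simulate
    seeds = _stage_seeds(config.global_seed, sim.n_subjects)
    recordings = []
    for i in range(sim.n_subjects):
        sched = generate_protocol(
            n_trials=sim.n_trials, picture_s=sim.picture_s,
            n_pictures=sim.n_pictures, fixation_s=sim.fixation_s,
            class_balance=sim.class_balance, seed=seeds["protocol"][i])
        params = SubjectParams(
            eeg_complexity_shift=sim.eeg_complexity_shift,
            sc_level_shift=sim.sc_level_shift, hr_shift=sim.hr_shift,
            nonresponse_p=sim.nonresponse_p,
            artifact_rate_per_min=sim.artifact_rate_per_min,
            seed=seeds["recording"][i])
        recordings.append(synthesize_recording(sched, params,
                                               subject_id=f"S{i + 1:02d}"))
    return recordings


def compute_eeg_features(recordings: list[Recording],
                         pre: PreprocessConfig) -> pd.DataFrame:
    """Band-pass, segment the stimulus blocks, reject artifacts, extract."""
    frames = []
    for rec in recordings:
        windows = [(t.block_start_s, t.end_s, t.trial_id)
                   for t in rec.schedule.trials]
        epochs_all = []
        fs = None
        for ch_name in EEG_CHANNELS:
            ch = rec.channel(ch_name)
            filtered = bandpass_eeg(ch.samples, ch.fs, pre.band_lo,
                                    pre.band_hi)
            es = segment(filtered, ch.fs, pre.epoch_s, pre.overlap, windows,
                         channel=ch_name)
            epochs_all.extend(es.epochs)
            fs = ch.fs
            epoch_len = es.epoch_len
        eset = EpochSet(epochs_all, fs, epoch_len)
        eset, _ = remove_artifact_epochs(eset, pre.amp_threshold_uv)
        feats = extract_eeg_features(eset)
        feats.insert(0, "trial_key",
                     [trial_key(rec.subject_id, t) for t in
                      feats["trial_id"]] if len(feats) else
                     pd.Series(dtype=str))
        feats.insert(0, "subject", rec.subject_id)
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


def _label_all_accepted(peripheral: pd.DataFrame) -> list[TrialDecision]:
    """Ablation path: accept every trial at its intended class."""
    return [TrialDecision(trial_id=int(r.trial_id), trial_key=str(r.trial_key),
                          intended_class=str(r.intended_class), accepted=True)
            for r in peripheral.itertuples()]


def classify_eeg(dataset: LabeledDataset, config: ExperimentConfig) -> dict:
    """Split, GA-select, train and evaluate on the labeled EEG dataset."""
    seeds = _stage_seeds(config.global_seed, config.simulate.n_subjects)
    train, test, val = split_dataset(
        dataset.features, config.classify.fractions, seed=seeds["split"],
        group_by_trial=(config.classify.split == "trial"))
    ga_cfg = dataclasses.replace(config.selection, seed=seeds["ga"])
    genome = ga_select(train, ga_cfg)
    feats = genome.selected(feature_columns(train))
    model = train_ovr_svm(train, kernel=config.classify.kernel,
                          C=config.classify.C, features=feats)

    def score(part: pd.DataFrame) -> dict:
        if len(part) == 0:
            return {"n": 0}
        preds = model.predict(part)
        cm = evaluate(preds, part["label"].to_numpy())
        return {"n": int(len(part)), "confusion": cm.to_dict(),
                "accuracy_percent": round(cm.accuracy, 2)}

    return {
        "n_train": int(len(train)), "n_test": int(len(test)),
        "n_validation": int(len(val)),
        "selected_features": feats,
        "n_selected": genome.n_selected,
        "ga_best_fitness": round(genome.fitness, 4),
        "ga_history": [round(f, 4) for f in genome.history],
        "test": score(test), "validation": score(val),
        "model": model,
    }


def run_experiment(config: ExperimentConfig,
                   output_dir: str | Path | None = None,
                   write_recordings: bool = False) -> dict:
    """Execute the full pipeline; write artifacts and return the report."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    recordings = simulate_study(config)
    if write_recordings:
        for rec in recordings:
            write_recording(rec, out / "recordings")

    peripheral = pd.concat(
        [extract_peripheral_features(rec,
                                     smooth_s=config.preprocess.smooth_s)
         for rec in recordings], ignore_index=True)
    peripheral.to_csv(out / "peripheral_features.csv", index=False)

    if config.labeling.enabled:
        decisions, peripheral_cm = label_trials(
            recordings, peripheral,
            max_discrepancy=config.labeling.max_discrepancy,
            stage2=config.labeling.stage2,
            kernel=config.labeling.kernel, C=config.labeling.C)
        peripheral_report = peripheral_cm.to_dict()
    else:
        decisions = _label_all_accepted(peripheral)
        peripheral_report = None
    decisions_frame(decisions).to_csv(out / "trial_decisions.csv",
                                      index=False)

    eeg = compute_eeg_features(recordings, config.preprocess)
    eeg.to_csv(out / "eeg_features.csv", index=False,
               float_format="%.6g")
    dataset = build_labeled_dataset(eeg, decisions)
    dataset.features.to_csv(out / "labeled_eeg_features.csv", index=False,
                            float_format="%.6g")

    cls_report = classify_eeg(dataset, config)
    model = cls_report.pop("model")
    (out / "model.json").write_text(model.to_json())

    report = {
        "config_hash": config.hash(),
        "global_seed": config.global_seed,
        "n_trials_total": len(decisions),
        "rejected_fraction": round(
            sum(1 for d in decisions if not d.accepted) / len(decisions), 4),
        "peripheral_confusion": peripheral_report,
        "eeg_classification": cls_report,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(
        {"config": config.to_dict(), "config_hash": config.hash()},
        indent=1, sort_keys=True, default=str))
    return report


def ablate(config: ExperimentConfig,
           arms: tuple[str, ...] = ("eeg_only", "peripheral_only", "fused"),
           output_dir: str | Path | None = None) -> dict:
    """Run ablation arms on identically seeded data.

    ``fused`` is the full pipeline (peripheral-gated labeling + EEG
    classification), ``eeg_only`` disables the labeling gate, and
    ``peripheral_only`` reports the trial-level peripheral classifier alone.
    """
    out = Path(output_dir or config.output_dir)
    results = {}
    for arm in arms:
        if arm not in ("eeg_only", "peripheral_only", "fused"):
            raise ValueError(f"unknown ablation arm {arm!r}")
        arm_cfg = ExperimentConfig.from_dict(json.loads(json.dumps(
            config.to_dict(), default=str)))
        arm_cfg.labeling.enabled = (arm != "eeg_only")
        report = run_experiment(arm_cfg, output_dir=out / arm)
        if arm == "peripheral_only":
            acc = (report["peripheral_confusion"] or
                   {}).get("accuracy_percent")
        else:
            acc = report["eeg_classification"]["test"].get(
                "accuracy_percent")
        results[arm] = {"accuracy_percent": acc, "report": report}
    (out / "ablation.json").write_text(
        json.dumps({a: {"accuracy_percent": r["accuracy_percent"]}
                    for a, r in results.items()}, indent=1, sort_keys=True))
    return results
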
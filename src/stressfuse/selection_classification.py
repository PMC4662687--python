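"""GA feature selection, one-vs-all SVM classification and evaluation.

The feature selector is a generational genetic algorithm over bitmask
genomes (one bit per feature): population 100, per-bit mutation probability
0.01, one-point crossover probability 0.4, roulette-wheel selection on
min-max-scaled fitness, elitism of one. Fitness is the cross-validated
(default 3-fold, trial-grouped) accuracy of the classifier on the masked
training features; a resubstitution mode is available for the literal
whole-dataset variant.

The classifier is one-vs-all: one binary SVM per class (RBF kernel, C = 1
by default), each trained with its class against the rest. At prediction
the feature vector is fed to both SVMs and a decision-logic rule picks the
class with the largest decision value; if no SVM claims the sample (all
decision values negative) the sample is rejected. Ties break toward
``calm_neutral``.

Accuracy is read off the confusion matrix by summing the diagonal
row-percentages weighted by the class priors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.svm import SVC

from .core import CLASSES, feature_columns
from .eeg_features import normalize_features

log = logging.getLogger(__name__)

REJECT = "reject"


# ---------------------------------------------------------------------------
# one-vs-all SVM


@dataclass
class OvRSVM:
    """One-vs-all SVM pair with its normalization affine and feature list.

    After fitting, the per-class decision functions are stored as explicit
    support-vector expansions so the model round-trips through JSON without
    pickling.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None  # default 1 / n_selected_features
    degree: int = 3
    coef0: float = 0.0
    classes: tuple[str, ...] = CLASSES
    features: list[str] = field(default_factory=list)
    norm_params: dict = field(default_factory=dict)
    _machines: list[dict] = field(default_factory=list)

    def fit(self, matrix: pd.DataFrame, labels: np.ndarray | None = None
            ) -> "OvRSVM":
        y = np.asarray(matrix["label"] if labels is None else labels)
        if len(set(y)) < 2:
            raise ValueError("training data must contain both classes")
        if not self.features:
            self.features = feature_columns(matrix)
        X = matrix[self.features]
        Xn, self.norm_params = normalize_features(X)
        Xn = Xn[self.features].to_numpy()
        if self.gamma is None:
            self.gamma = 1.0 / len(self.features)
        self._machines = []
        for cls in self.classes:
            svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                      degree=self.degree, coef0=self.coef0)
            svc.fit(Xn, (y == cls).astype(int))
            self._machines.append({
                "sv": svc.support_vectors_.tolist(),
                "dual_coef": svc.dual_coef_.ravel().tolist(),
                "intercept": float(svc.intercept_[0]),
            })
        return self

    def _kernel_matrix(self, X: np.ndarray, sv: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return X @ sv.T
        if self.kernel == "poly":
            return (self.gamma * (X @ sv.T) + self.coef0) ** self.degree
        if self.kernel == "rbf":
            d2 = (np.sum(X ** 2, axis=1)[:, None]
                  + np.sum(sv ** 2, axis=1)[None, :] - 2.0 * X @ sv.T)
            return np.exp(-self.gamma * np.maximum(d2, 0.0))
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def decision_values(self, matrix: pd.DataFrame) -> np.ndarray:
        """Per-class decision values, one column per class."""
        if not self._machines:
            raise ValueError("model is not fitted")
        Xn, _ = normalize_features(matrix[self.features],
                                   params=self.norm_params)
        X = Xn[self.features].to_numpy()
        cols = []
        for m in self._machines:
            sv = np.asarray(m["sv"])
            k = self._kernel_matrix(X, sv)
            cols.append(k @ np.asarray(m["dual_coef"]) + m["intercept"])
        return np.column_stack(cols)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Decision-logic prediction per row (may contain ``reject``)."""
        dv = self.decision_values(matrix)
        return np.array([decide(row, classes=self.classes) for row in dv])

    def to_json(self) -> str:
        return json.dumps({
            "kernel": self.kernel, "C": self.C, "gamma": self.gamma,
            "degree": self.degree, "coef0": self.coef0,
            "classes": list(self.classes), "features": self.features,
            "norm_params": self.norm_params, "machines": self._machines,
        })

    @classmethod
    def from_json(cls, text: str) -> "OvRSVM":
        d = json.loads(text)
        model = cls(kernel=d["kernel"], C=d["C"], gamma=d["gamma"],
                    degree=d["degree"], coef0=d["coef0"],
                    classes=tuple(d["classes"]), features=d["features"])
        model.norm_params = {k: tuple(v) for k, v in d["norm_params"].items()}
        model._machines = d["machines"]
        return model


def train_ovr_svm(train: pd.DataFrame, kernel: str = "rbf", C: float = 1.0,
                  gamma: float | None = None,
                  features: list[str] | None = None) -> OvRSVM:
    """Fit the one-vs-all SVM pair on a labeled feature matrix."""
    model = OvRSVM(kernel=kernel, C=C, gamma=gamma,
                   features=list(features) if features else [])
    return model.fit(train)


def decide(decision_values: np.ndarray,
           classes: tuple[str, ...] = CLASSES) -> str:
    """Decision logic: class of the largest decision value; ``reject`` when
    no machine claims the sample (all values negative); ties break toward
    the first class (calm_neutral)."""
    dv = np.asarray(decision_values, dtype=float)
    if dv.shape[-1] != len(classes):
        raise ValueError("one decision value per class required")
    if np.all(dv < 0):
        return REJECT
    return classes[int(np.argmax(dv == np.max(dv)))]


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ConfusionMatrix:
    """Two-class confusion counts with row percentages and prior-weighted
    accuracy (in percent). Rejected samples are tallied separately and
    excluded from the row percentages."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES
    priors: np.ndarray | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.priors is None:
            totals = self.counts.sum(axis=1)
            grand = totals.sum()
            self.priors = (totals / grand if grand > 0
                           else np.full(len(self.classes),
                                        1.0 / len(self.classes)))
        self.priors = np.asarray(self.priors, dtype=float)

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rp = 100.0 * self.counts / totals
        return np.where(totals > 0, rp, 0.0)

    @property
    def accuracy(self) -> float:
        """Sum of diagonal row-percentages weighted by the class priors."""
        return accuracy_from_row_percent(self.row_percent, self.priors)

    def to_dict(self) -> dict:
        return {"classes": list(self.classes),
                "counts": self.counts.tolist(),
                "row_percent": np.round(self.row_percent, 2).tolist(),
                "priors": np.round(self.priors, 4).tolist(),
                "n_rejected": int(self.n_rejected),
                "accuracy_percent": round(self.accuracy, 2)}


def accuracy_from_row_percent(row_percent: np.ndarray,
                              priors: np.ndarray) -> float:
    """Prior-weighted accuracy (%) from a row-normalized confusion matrix."""
    rp = np.asarray(row_percent, dtype=float)
    pr = np.asarray(priors, dtype=float)
    return float(np.sum(pr * np.diag(rp)))


def evaluate(predictions, truth, priors=None,
             classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Confusion matrix over predictions; rejects are tallied separately.

    ``priors`` default to the empirical class frequencies of ``truth``, in
    which case (and with no rejects) the accuracy equals the plain fraction
    of correct predictions.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    n_rej = 0
    for p, t in zip(predictions, truth):
        if p == REJECT:
            n_rej += 1
            continue
        counts[idx[t], idx[p]] += 1
    if priors is None:
        all_totals = np.array([truth.count(c) for c in classes], dtype=float)
        priors = (all_totals / all_totals.sum() if all_totals.sum() > 0
                  else None)
    return ConfusionMatrix(counts=counts, classes=classes, priors=priors,
                           n_rejected=n_rej)


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(dataset: pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.75, 0.15, 0.10),
                  seed: int = 0,
                  group_by_trial: bool = True) -> tuple[pd.DataFrame, ...]:
    """Stratified train/test/validation split, grouped by trial.

    All epochs of one trial land in the same partition (unless
    ``group_by_trial`` is off, which reproduces a literal epoch-level
    split). Allocation per class uses largest-remainder rounding, so e.g.
    40 trials at (0.75, 0.15, 0.10) give 30/6/4.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    group_col = "trial_key" if group_by_trial else None
    if group_col is None:
        dataset = dataset.copy()
        dataset["_row_group"] = np.arange(len(dataset))
        group_col = "_row_group"
    groups = dataset.groupby(group_col, sort=True)["label"].first()
    assignment: dict = {}
    for cls in sorted(set(groups)):
        keys = np.array(sorted(groups[groups == cls].index))
        rng.shuffle(keys)
        n = len(keys)
        ideal = np.array(fractions) * n
        base = np.floor(ideal).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(ideal - base))
        for i in range(rem):
            base[order[i]] += 1
        edges = np.cumsum(base)
        parts = np.split(keys, edges[:-1])
        for part_i, part_keys in enumerate(parts):
            for k in part_keys:
                assignment[k] = part_i
        for part_i, frac in enumerate(fractions):
            if frac > 0 and base[part_i] == 0:
                raise ValueError(
                    f"partition {part_i} received no {cls!r} trials; "
                    "more data (or larger fractions) are needed")
    out = []
    part_of = dataset[group_col].map(assignment)
    for part_i in range(3):
        part = dataset[part_of == part_i].drop(columns=["_row_group"],
                                               errors="ignore")
        out.append(part.reset_index(drop=True))
    return tuple(out)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GAConfig:
    pop_size: int = 100
    p_mutation: float = 0.01
    p_crossover: float = 0.4
    n_generations: int = 50
    seed: int = 0
    fitness_folds: int = 3
    early_stop_generations: int = 15
    kernel: str = "rbf"
    C: float = 1.0
    fitness_mode: str = "cv"  # "cv" | "resubstitution"


@dataclass
class Genome:
    """Feature-selection bitmask (1 = feature used)."""

    mask: np.ndarray
    fitness: float = np.nan
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected(self, features: list[str]) -> list[str]:
        return [f for f, b in zip(features, self.mask) if b]


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.any():
        return mask
    mask = mask.copy()
    mask[rng.integers(len(mask))] = True
    log.info("repaired empty genome by activating one random feature")
    return mask


class _FitnessEvaluator:
    """Precomputed cross-validation machinery for repeated mask scoring.

    For two classes the one-vs-all SVM pair is exactly complementary
    (training the second machine on flipped labels negates the decision
    function), so the pair's decision logic reduces to a single binary SVM
    per fold; that equivalence is exploited here to halve the work in the
    GA's inner loop. Feature data, fold indices and labels are extracted
    to numpy once, and the per-fold min-max normalization (constant columns
    to 0) matches :func:`normalize_features`.
    """

    def __init__(self, train: pd.DataFrame, config: GAConfig):
        self.config = config
        cols = feature_columns(train)
        self.n_features = len(cols)
        self.X = train[cols].to_numpy(dtype=float)
        y = train["label"].to_numpy()
        if len(set(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.y = (y == sorted(set(y))[1]).astype(int)
        if config.fitness_mode == "resubstitution":
            idx = np.arange(len(y))
            self.folds = [(idx, idx)]
        else:
            groups = (train["trial_key"].to_numpy()
                      if "trial_key" in train.columns
                      else np.arange(len(train)))
            per_class_groups = min(
                len({g for g, c in zip(groups, y) if c == cls})
                for cls in set(y))
            n_splits = max(2, min(config.fitness_folds, per_class_groups))
            skf = StratifiedGroupKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(config.seed) % (2 ** 31))
            self.folds = [(tr, ev) for tr, ev in skf.split(self.X, y,
                                                           groups=groups)
                          if len(set(self.y[tr])) == 2 and len(ev)]

    @staticmethod
    def _scale(fit_block: np.ndarray, block: np.ndarray) -> np.ndarray:
        lo = fit_block.min(axis=0)
        hi = fit_block.max(axis=0)
        span = hi - lo
        const = span < 1e-12
        span[const] = 1.0
        out = 2.0 * (block - lo) / span - 1.0
        out[:, const] = 0.0
        return out

    def __call__(self, mask: np.ndarray) -> float:
        Xm = self.X[:, mask]
        cfg = self.config
        gamma = 1.0 / int(mask.sum())
        accs = []
        for tr, ev in self.folds:
            Xtr, Xev = Xm[tr], Xm[ev]
            svc = SVC(kernel=cfg.kernel, C=cfg.C, gamma=gamma)
            svc.fit(self._scale(Xtr, Xtr), self.y[tr])
            pred = svc.predict(self._scale(Xtr, Xev))
            accs.append(float(np.mean(pred == self.y[ev])))
        return float(np.mean(accs)) if accs else 0.0


def fitness(mask: Genome | np.ndarray, train: pd.DataFrame,
            config: GAConfig | None = None) -> float:
    """Cross-validated accuracy of the one-vs-all SVM on the masked features.

    Folds are stratified and grouped by trial so that epochs of one trial
    never straddle a fold boundary. ``fitness_mode="resubstitution"`` trains
    and scores on the whole training partition instead.
    """
    config = config or GAConfig()
    m = mask.mask if isinstance(mask, Genome) else np.asarray(mask,
                                                              dtype=bool)
    rng = np.random.default_rng(config.seed)
    m = _repair(m, rng)
    evaluator = _FitnessEvaluator(train, config)
    if len(m) != evaluator.n_features:
        raise ValueError("mask length must equal the number of features")
    return evaluator(m)


def ga_select(train: pd.DataFrame, config: GAConfig | None = None) -> Genome:
    """Run the GA and return the best genome ever seen.

    The returned genome carries the per-generation best-fitness trajectory
    in ``history``; best-so-far fitness is nondecreasing by elitism.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    n_feat = len(feature_columns(train))
    pop = [rng.uniform(size=n_feat) < 0.5 for _ in range(config.pop_size)]
    pop = [_repair(m, rng) for m in pop]

    evaluator = _FitnessEvaluator(train, config)
    cache: dict[bytes, float] = {}

    def fit_of(m: np.ndarray) -> float:
        key = np.packbits(m).tobytes()
        if key not in cache:
            cache[key] = evaluator(m)
        return cache[key]

    fits = np.array([fit_of(m) for m in pop])
    best_i = int(np.argmax(fits))
    best = Genome(pop[best_i].copy(), float(fits[best_i]))
    best.history.append(best.fitness)
    stagnant = 0
    for gen in range(config.n_generations):
        # roulette selection on min-max-scaled fitness
        w = fits - fits.min()
        p = w / w.sum() if w.sum() > 0 else np.full(len(fits),
                                                    1.0 / len(fits))
        idx = rng.choice(len(pop), size=config.pop_size, p=p)
        parents = [pop[i].copy() for i in idx]
        children = []
        for a, b in zip(parents[0::2], parents[1::2]):
            if rng.uniform() < config.p_crossover and n_feat > 1:
                cut = int(rng.integers(1, n_feat))
                a2 = np.concatenate([a[:cut], b[cut:]])
                b2 = np.concatenate([b[:cut], a[cut:]])
                a, b = a2, b2
            children.extend([a, b])
        if len(children) < config.pop_size:
            children.append(parents[-1])
        for m in children:
            flips = rng.uniform(size=n_feat) < config.p_mutation
            m ^= flips
        children = [_repair(m, rng) for m in children]
        children[0] = best.mask.copy()  # elitism
        pop = children[:config.pop_size]
        fits = np.array([fit_of(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = Genome(pop[gen_best].copy(), float(fits[gen_best]),
                          history=best.history)
            stagnant = 0
        else:
            stagnant += 1
        best.history.append(best.fitness)
        log.debug("GA generation %d: best fitness %.4f (%d features)",
                  gen, best.fitness, best.n_selected)
        if stagnant >= config.early_stop_generations:
            log.info("GA early stop after %d stagnant generations", stagnant)
            break
    return best
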
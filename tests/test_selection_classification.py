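"""Splitting, GA selection, one-vs-all SVM and confusion-matrix evaluation."""

import numpy as np
import pandas as pd
import pytest

from stressfuse import CALM, NEGATIVE
from stressfuse.selection_classification import (ConfusionMatrix, GAConfig,
                                                 Genome, OvRSVM, REJECT,
                                                 accuracy_from_row_percent,
                                                 decide, evaluate, fitness,
                                                 ga_select, split_dataset,
                                                 train_ovr_svm)
from stressfuse.synthetic_data import generate_feature_dataset


def grouped_dataset(n_trials=40, epochs_per_trial=3, n_features=8,
                    n_informative=4, effect=3.0, seed=0):
    """Trial-grouped epoch dataset with known informative columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trials):
        label = CALM if t % 2 == 0 else NEGATIVE
        center = rng.normal(0, 0.5, n_features)
        center[:n_informative] += (effect / 2 if label == NEGATIVE
                                   else -effect / 2)
        for e in range(epochs_per_trial):
            x = center + rng.normal(0, 1.0, n_features)
            rows.append({"trial_key": f"S:{t}", "label": label,
                         **{f"f{i}": x[i] for i in range(n_features)}})
    return pd.DataFrame(rows)


class TestSplitDataset:
    def test_paper_fractions_on_40_trials(self):
        df = grouped_dataset(40)
        tr, te, va = split_dataset(df, (0.75, 0.15, 0.10), seed=1)
        count = lambda d: d["trial_key"].nunique()
        assert (count(tr), count(te), count(va)) == (30, 6, 4)

    def test_everything_in_train(self):
        df = grouped_dataset(8)
        tr, te, va = split_dataset(df, (1.0, 0.0, 0.0), seed=1)
        assert len(tr) == len(df) and len(te) == 0 and len(va) == 0

    def test_deterministic_for_seed(self):
        df = grouped_dataset(20)
        a = split_dataset(df, seed=5)
        b = split_dataset(df, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_epochs_of_a_trial_stay_together(self):
        df = grouped_dataset(20, epochs_per_trial=4)
        parts = split_dataset(df, seed=2)
        seen = {}
        for i, p in enumerate(parts):
            for k in p["trial_key"].unique():
                assert k not in seen
                seen[k] = i

    def test_stratified_by_class(self):
        df = grouped_dataset(40)
        tr, te, va = split_dataset(df, seed=3)
        for part in (tr, te, va):
            counts = part.groupby("label")["trial_key"].nunique()
            assert counts[CALM] == counts[NEGATIVE]

    def test_starved_partition_raises(self):
        df = grouped_dataset(4)
        with pytest.raises(ValueError, match="more data"):
            split_dataset(df, (0.34, 0.33, 0.33), seed=1)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(grouped_dataset(8), (0.5, 0.2, 0.2), seed=0)


class TestFitness:
    def test_informative_mask_beats_noise_mask(self):
        df = grouped_dataset(seed=4)
        cfg = GAConfig(seed=0)
        inf = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        noise = ~inf
        assert fitness(inf, df, cfg) > fitness(noise, df, cfg)

    def test_deterministic_given_seed(self):
        df = grouped_dataset(seed=4)
        cfg = GAConfig(seed=9)
        m = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
        assert fitness(m, df, cfg) == fitness(m, df, cfg)

    def test_random_labels_near_chance(self):
        accs = []
        for seed in range(6):
            df = grouped_dataset(n_trials=30, effect=0.0, seed=seed)
            accs.append(fitness(np.ones(8, dtype=bool), df,
                                GAConfig(seed=seed)))
        assert 0.3 < np.mean(accs) < 0.7

    def test_empty_mask_repaired(self):
        df = grouped_dataset(seed=4)
        val = fitness(np.zeros(8, dtype=bool), df, GAConfig(seed=0))
        assert 0.0 <= val <= 1.0

    def test_resubstitution_mode(self):
        df = grouped_dataset(seed=4, effect=5.0)
        cfg = GAConfig(seed=0, fitness_mode="resubstitution")
        assert fitness(np.ones(8, dtype=bool), df, cfg) > 0.9


class TestGASelect:
    def test_defaults_match_configuration(self):
        cfg = GAConfig()
        assert cfg.pop_size == 100
        assert cfg.p_mutation == 0.01
        assert cfg.p_crossover == 0.4

    def test_recovers_informative_features(self):
        """The GA finds most informative columns on a 5-of-20 fixture."""
        df = generate_feature_dataset(150, 20, 5, 2.0, seed=0)
        hits = 0
        cfg_base = GAConfig(pop_size=24, n_generations=8,
                            early_stop_generations=8)
        for seed in range(20):
            cfg = GAConfig(**{**cfg_base.__dict__, "seed": seed})
            genome = ga_select(df, cfg)
            cols = [c for c in df.columns if c.startswith("f")]
            chosen = genome.selected(cols)
            if sum(c.endswith("_inf") for c in chosen) >= 3:
                hits += 1
        assert hits >= 16  # >= 80% of runs

    def test_zero_generations_returns_best_initial(self):
        df = grouped_dataset(seed=1)
        cfg = GAConfig(pop_size=10, n_generations=0, seed=3)
        genome = ga_select(df, cfg)
        assert len(genome.history) == 1
        assert genome.fitness == genome.history[0]

    def test_no_variation_operators_preserve_population(self):
        df = grouped_dataset(seed=1)
        cfg = GAConfig(pop_size=6, n_generations=3, p_mutation=0.0,
                       p_crossover=0.0, seed=5, early_stop_generations=10)
        genome = ga_select(df, cfg)
        # without variation the best genome can only be one of the initial
        # population; its fitness never degrades
        assert genome.history == sorted(genome.history)

    def test_elitism_makes_best_fitness_nondecreasing(self):
        df = grouped_dataset(seed=2)
        cfg = GAConfig(pop_size=12, n_generations=6, seed=1,
                       early_stop_generations=10)
        genome = ga_select(df, cfg)
        assert all(b >= a for a, b in zip(genome.history[:-1],
                                          genome.history[1:]))


class TestDecide:
    def test_unique_positive_wins(self):
        assert decide([+1.2, -0.3]) == CALM

    def test_all_negative_rejects(self):
        assert decide([-0.5, -0.7]) == REJECT

    def test_tie_breaks_toward_calm(self):
        assert decide([+0.4, +0.4]) == CALM

    def test_largest_value_wins(self):
        assert decide([+0.2, +0.9]) == NEGATIVE


class TestEvaluate:
    def test_published_peripheral_matrix_accuracy(self):
        rp = np.array([[65.4, 34.6], [11.5, 88.5]])
        assert accuracy_from_row_percent(rp, [0.5, 0.5]) == pytest.approx(
            76.95)

    def test_perfect_predictions(self):
        truth = [CALM] * 5 + [NEGATIVE] * 5
        cm = evaluate(truth, truth)
        assert cm.accuracy == pytest.approx(100.0)

    def test_flipped_predictions(self):
        truth = [CALM] * 5 + [NEGATIVE] * 5
        flipped = [NEGATIVE] * 5 + [CALM] * 5
        assert evaluate(flipped, truth).accuracy == pytest.approx(0.0)

    def test_accuracy_equals_fraction_correct_with_empirical_priors(self,
                                                                    rng):
        truth = list(rng.choice([CALM, NEGATIVE], 40, p=[0.7, 0.3]))
        preds = list(rng.choice([CALM, NEGATIVE], 40))
        cm = evaluate(preds, truth)
        direct = 100.0 * np.mean([p == t for p, t in zip(preds, truth)])
        assert cm.accuracy == pytest.approx(direct)

    def test_rejects_tallied_separately(self):
        truth = [CALM, CALM, NEGATIVE, NEGATIVE]
        preds = [CALM, REJECT, NEGATIVE, REJECT]
        cm = evaluate(preds, truth)
        assert cm.n_rejected == 2
        assert cm.counts.sum() == 2

    def test_row_percent_sums_to_100(self, rng):
        truth = list(rng.choice([CALM, NEGATIVE], 30))
        preds = list(rng.choice([CALM, NEGATIVE], 30))
        cm = evaluate(preds, truth)
        np.testing.assert_allclose(cm.row_percent.sum(axis=1), [100, 100],
                                   atol=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([CALM], [CALM, NEGATIVE])


def xy_frame(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", y)
    return df


class TestOvRSVM:
    def test_separable_linear_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)),
                       rng.normal(+3, 0.3, (20, 2))])
        y = np.array([CALM] * 20 + [NEGATIVE] * 20)
        df = xy_frame(X, y)
        model = train_ovr_svm(df, kernel="linear", C=1.0)
        assert np.mean(model.predict(df) == y) == 1.0

    def test_default_configuration_is_rbf_c1(self):
        model = OvRSVM()
        assert model.kernel == "rbf" and model.C == 1.0

    def test_xor_pattern_needs_rbf(self, rng):
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]],
                           dtype=float)
        X = np.vstack([c + rng.normal(0, 0.15, (15, 2)) for c in centers])
        y = np.array([CALM] * 30 + [NEGATIVE] * 30)
        df = xy_frame(X, y)
        acc = lambda k: np.mean(
            train_ovr_svm(df, kernel=k).predict(df) == y)
        assert acc("rbf") > acc("linear")

    def test_single_class_rejected(self, rng):
        df = xy_frame(rng.normal(0, 1, (10, 2)), np.array([CALM] * 10))
        with pytest.raises(ValueError):
            train_ovr_svm(df)

    def test_json_round_trip_preserves_decisions(self, rng):
        X = np.vstack([rng.normal(-1, 1, (15, 3)),
                       rng.normal(+1, 1, (15, 3))])
        y = np.array([CALM] * 15 + [NEGATIVE] * 15)
        df = xy_frame(X, y)
        model = train_ovr_svm(df, kernel="rbf", C=1.0)
        clone = OvRSVM.from_json(model.to_json())
        np.testing.assert_allclose(clone.decision_values(df),
                                   model.decision_values(df), atol=1e-12)
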
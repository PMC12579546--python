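import dataclasses
import math

import numpy as np
import pytest

from phoszsl.bilinear import (
    CompatibilityModel,
    TrainConfig,
    TrainingError,
    _augment,
    class_probs,
    compatibility,
    loss_and_grad,
    random_search,
    run_restarts,
    sample_config,
    softmax,
    train,
)
from phoszsl.dataset import AssociationTable
from phoszsl.encoders import EmbeddingStore
from phoszsl.evaluation import macro_ap


def _one_hot_problem(n_classes=4, n_per_class=6, dim=4, noise=0.0, seed=0):
    """Sites one-hot aligned with their kinase's one-hot embedding."""
    rng = np.random.default_rng(seed)
    kin_vecs = {f"K{i}": np.eye(dim)[i] for i in range(n_classes)}
    site_vecs = {}
    pairs = []
    for i in range(n_classes):
        for j in range(n_per_class):
            sid = f"s{i}_{j}"
            site_vecs[sid] = np.eye(dim)[i] + noise * rng.normal(size=dim)
            pairs.append((sid, f"K{i}"))
    return (
        AssociationTable(pairs),
        EmbeddingStore.from_vectors(site_vecs),
        EmbeddingStore.from_vectors(kin_vecs),
    )


class TestCompatibility:
    def test_zero_matrix_scores_everything_zero(self):
        assert compatibility([1.0, 2.0], [3.0], np.zeros((3, 2))) == 0.0

    def test_corner_entry_is_a_global_scalar_offset(self):
        W = np.zeros((3, 2))
        W[-1, -1] = 4.25
        assert compatibility([5.0, -1.0], [9.0], W) == 4.25
        assert compatibility([0.0, 0.0], [0.0], W) == 4.25

    def test_scalar_case_matches_direct_product(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert compatibility([2.0], [3.0], W) == 6.0

    def test_four_term_expansion_identity(self):
        # F = theta^T W11 phi + theta^T w12 + w21^T phi + w22
        rng = np.random.default_rng(0)
        for _ in range(10):
            d, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            theta, phi = rng.normal(size=d), rng.normal(size=m)
            W = rng.normal(size=(d + 1, m + 1))
            expansion = (
                theta @ W[:d, :m] @ phi
                + theta @ W[:d, m]
                + W[d, :m] @ phi
                + W[d, m]
            )
            assert compatibility(theta, phi, W) == pytest.approx(
                expansion, abs=1e-12
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(TrainingError):
            compatibility([1.0, 2.0], [3.0], np.zeros((2, 2)))


class TestClassProbs:
    def test_equal_logits_give_uniform(self):
        store = EmbeddingStore.from_vectors({"a": np.zeros(2), "b": np.zeros(2)})
        probs = class_probs(np.ones(3), ["a", "b"], store, np.zeros((4, 3)))
        assert np.allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        store = EmbeddingStore.from_vectors(
            {f"k{i}": rng.normal(size=3) for i in range(5)}
        )
        probs = class_probs(rng.normal(size=2), [f"k{i}" for i in range(5)],
                            store, rng.normal(size=(3, 4)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_two_class_softmax(self):
        assert np.allclose(
            softmax(np.array([math.log(2.0), 0.0])), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_invariant_to_constant_logit_shift(self):
        logits = np.array([0.3, -1.2, 4.0])
        assert np.allclose(softmax(logits), softmax(logits + 123.4), atol=1e-12)


class TestGradient:
    def test_matches_finite_differences_on_toy_problem(self):
        rng = np.random.default_rng(2)
        Theta = _augment(rng.normal(size=(5, 3)))
        Phi = _augment(rng.normal(size=(4, 2)))
        labels = rng.integers(0, 4, size=5)
        W = rng.normal(size=(4, 3))
        _, grad = loss_and_grad(W, Theta, Phi, labels)
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (3, 1), (2, 2)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            lp, _ = loss_and_grad(Wp, Theta, Phi, labels)
            lm, _ = loss_and_grad(Wm, Theta, Phi, labels)
            fd = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_same_seed_is_bitwise_deterministic(self):
        pairs, sites, kinases = _one_hot_problem()
        config = TrainConfig(epochs=5, seed=3)
        a, _ = train(pairs, sites, kinases, config)
        b, _ = train(pairs, sites, kinases, config)
        assert np.array_equal(a.W, b.W)

    def test_heavier_weight_decay_shrinks_the_model(self):
        pairs, sites, kinases = _one_hot_problem()
        light = TrainConfig(epochs=30, weight_decay=1e-5, seed=0,
                            learning_rate=0.05)
        heavy = TrainConfig(epochs=30, weight_decay=1e-2, seed=0,
                            learning_rate=0.05)
        wl, _ = train(pairs, sites, kinases, light)
        wh, _ = train(pairs, sites, kinases, heavy)
        assert np.linalg.norm(wh.W) < np.linalg.norm(wl.W)

    def test_separable_one_hot_problem_reaches_perfect_training_accuracy(self):
        pairs, sites, kinases = _one_hot_problem()
        config = TrainConfig(epochs=60, learning_rate=0.05, seed=1)
        model, log = train(pairs, sites, kinases, config)
        train_kin = sorted({k for _, k in pairs})
        logits = model.scores(
            sites.matrix([s for s, _ in pairs]), kinases.matrix(train_kin)
        )
        predicted = [train_kin[j] for j in logits.argmax(axis=1)]
        truth = [k for _, k in pairs]
        assert predicted == truth
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]

    def test_validation_kinases_must_be_disjoint(self):
        pairs, sites, kinases = _one_hot_problem()
        with pytest.raises(TrainingError):
            train(pairs, sites, kinases, TrainConfig(epochs=1), val_pairs=pairs)

    def test_empty_training_set_rejected(self):
        _, sites, kinases = _one_hot_problem()
        with pytest.raises(TrainingError):
            train(AssociationTable([]), sites, kinases, TrainConfig(epochs=1))

    def test_checkpoint_save_load_round_trip(self, tmp_path):
        pairs, sites, kinases = _one_hot_problem()
        config = TrainConfig(epochs=3, seed=0)
        model, _ = train(pairs, sites, kinases, config)
        model.save(tmp_path / "model.json", config)
        again = CompatibilityModel.load(tmp_path / "model.json")
        assert np.allclose(again.W, model.W)
        assert (again.d, again.m) == (model.d, model.m)


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": 1.0},
            {"weight_decay": 0.5},
            {"momentum": 0.5},
            {"optimizer": "lbfgs"},
            {"schedule": "linear"},
        ],
    )
    def test_out_of_range_settings_rejected(self, kwargs):
        with pytest.raises(TrainingError):
            TrainConfig(**kwargs)


class TestRandomSearch:
    def _zero_shot_problem(self):
        # light kinases K0..K3 for training, K4..K5 for validation
        rng = np.random.default_rng(5)
        dim = 6
        kin_vecs = {f"K{i}": np.eye(dim)[i] for i in range(6)}
        site_vecs, train_rows, val_rows = {}, [], []
        for i in range(6):
            for j in range(5):
                sid = f"s{i}_{j}"
                site_vecs[sid] = np.eye(dim)[i] + 0.05 * rng.normal(size=dim)
                (train_rows if i < 4 else val_rows).append((sid, f"K{i}"))
        return (
            AssociationTable(train_rows),
            AssociationTable(val_rows),
            EmbeddingStore.from_vectors(site_vecs),
            EmbeddingStore.from_vectors(kin_vecs),
        )

    def test_same_seed_samples_identical_trials(self):
        rng_a = np.random.default_rng(7)
        rng_b = np.random.default_rng(7)
        for _ in range(5):
            assert sample_config(rng_a) == sample_config(rng_b)

    def test_best_config_is_argmax_of_trial_table(self):
        train_rows, val_rows, sites, kinases = self._zero_shot_problem()
        base = TrainConfig(epochs=5)
        best, trials = random_search(train_rows, sites, kinases, val_rows,
                                     n_trials=3, seed=0, base=base)
        assert len(trials) == 3
        top = trials.loc[trials["val_macro_ap"].idxmax()]
        assert best.learning_rate == pytest.approx(top["learning_rate"])
        assert best.optimizer == top["optimizer"]

    def test_single_trial_returns_that_config(self):
        train_rows, val_rows, sites, kinases = self._zero_shot_problem()
        best, trials = random_search(train_rows, sites, kinases, val_rows,
                                     n_trials=1, seed=1,
                                     base=TrainConfig(epochs=3))
        assert len(trials) == 1
        assert best.seed == trials["seed"].iloc[0]


class TestRestarts:
    def test_mean_and_std_over_restarts(self):
        train_rows, val_rows, sites, kinases = (
            TestRandomSearch()._zero_shot_problem()
        )
        config = TrainConfig(epochs=10, learning_rate=0.05, seed=0)
        result = run_restarts(train_rows, sites, kinases, val_rows,
                              config, n=3)
        assert len(result.per_run) == 3
        assert result.mean_macro_ap == pytest.approx(np.mean(result.per_run))
        assert result.std_macro_ap == pytest.approx(
            np.std(result.per_run, ddof=1))
        # mean ± std report formatting
        assert "±" in result.formatted()

    def test_single_restart_rejected(self):
        train_rows, val_rows, sites, kinases = (
            TestRandomSearch()._zero_shot_problem()
        )
        with pytest.raises(TrainingError):
            run_restarts(train_rows, sites, kinases, val_rows,
                         TrainConfig(epochs=1), n=1)
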
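"""Bilinear zero-shot compatibility model.

The model scores a (phosphosite, kinase) pair with a bilinear form over
bias-augmented representations,

    F(x, y) = [theta(x), 1] W [phi(y), 1]^T,

whose expansion separates a pairwise-compatibility term, a linear prior in
the site representation, a linear prior in the kinase representation, and a
trainable scalar.  W is the only learned parameter; the embeddings stay
fixed.  Training minimises the softmax cross-entropy of each training pair
against the training (light) kinase set, with an L2 penalty applied as
decoupled weight decay.  At test time the softmax runs over the held-out
(dark) kinase set, which is what makes the classifier zero-shot: any kinase
with an embedding can be scored, seen or not.

Implemented in NumPy with explicit gradients; the mini-batch optimisers
(Adam, SGD with momentum, RMSprop) and learning-rate schedules
(exponential, step, cosine annealing) are written out here, which keeps
single-threaded runs bit-reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import AssociationTable, PhoszslError
from .encoders import EmbeddingStore
from .evaluation import ScoreMatrix, macro_ap


class TrainingError(PhoszslError):
    """Invalid training configuration or diverged optimisation."""


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def _augment(matrix: np.ndarray) -> np.ndarray:
    """Append a constant-1 bias column."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    return np.hstack([matrix, np.ones((matrix.shape[0], 1))])


def compatibility(theta: np.ndarray, phi: np.ndarray, W: np.ndarray) -> float:
    """F(x, y) = [theta, 1] W [phi, 1]^T for a single pair."""
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    if W.shape != (theta.size + 1, phi.size + 1):
        raise TrainingError(
            f"W has shape {W.shape}, expected ({theta.size + 1}, {phi.size + 1})"
        )
    return float(_augment(theta)[0] @ W @ _augment(phi)[0])


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtracted)."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=axis, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=axis, keepdims=True)


@dataclass
class CompatibilityModel:
    """A trained bilinear compatibility matrix with its dimensions."""

    W: np.ndarray
    d: int
    m: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (self.d + 1, self.m + 1):
            raise TrainingError(
                f"W shape {self.W.shape} inconsistent with d={self.d}, m={self.m}"
            )

    def scores(self, Theta: np.ndarray, Phi: np.ndarray) -> np.ndarray:
        """Logit matrix F for all (site, kinase) combinations."""
        return _augment(Theta) @ self.W @ _augment(Phi).T

    def predict(
        self,
        site_ids: Sequence[str],
        site_store: EmbeddingStore,
        kinase_ids: Sequence[str],
        kinase_store: EmbeddingStore,
    ) -> ScoreMatrix:
        """Softmax probabilities over ``kinase_ids`` for every site."""
        logits = self.scores(
            site_store.matrix(list(site_ids)), kinase_store.matrix(list(kinase_ids))
        )
        return ScoreMatrix(softmax(logits, axis=1), list(site_ids), list(kinase_ids))

    def save(self, path: str | Path, config: "TrainConfig | None" = None) -> None:
        payload = {
            "d": self.d,
            "m": self.m,
            "W": self.W.tolist(),
            "config": dataclasses.asdict(config) if config else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CompatibilityModel":
        payload = json.loads(Path(path).read_text())
        return cls(W=np.array(payload["W"]), d=payload["d"], m=payload["m"])


def class_probs(
    theta: np.ndarray,
    kinase_ids: Sequence[str],
    kinase_store: EmbeddingStore,
    W: np.ndarray,
) -> np.ndarray:
    """Softmax of F over a kinase set for one site representation."""
    if not kinase_ids:
        raise TrainingError("kinase set must be non-empty")
    Phi = kinase_store.matrix(list(kinase_ids))
    logits = _augment(np.atleast_2d(theta)) @ W @ _augment(Phi).T
    return softmax(logits, axis=1)[0]


def loss_and_grad(
    W: np.ndarray,
    Theta_aug: np.ndarray,
    Phi_aug: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient in W.

    The L2 penalty is *not* included: it is applied as decoupled weight
    decay in the update step.
    """
    logits = Theta_aug @ W @ Phi_aug.T
    probs = softmax(logits, axis=1)
    n = Theta_aug.shape[0]
    nll = -np.log(probs[np.arange(n), labels] + 1e-300)
    delta = probs.copy()
    delta[np.arange(n), labels] -= 1.0
    grad = Theta_aug.T @ delta @ Phi_aug / n
    return float(nll.mean()), grad


# ---------------------------------------------------------------------------
# Optimisers and schedules
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, shape: tuple[int, int], momentum: float):
        self.momentum = momentum

    def step(self, W: np.ndarray, grad: np.ndarray, lr: float) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def __init__(self, shape, momentum):
        super().__init__(shape, momentum)
        self.buf = np.zeros(shape)

    def step(self, W, grad, lr):
        self.buf = self.momentum * self.buf + grad
        W -= lr * self.buf


class _Adam(_Optimizer):
    """Adam with beta1 = 0.9 and beta2 tied to the momentum hyperparameter."""

    def __init__(self, shape, momentum, beta1=0.9, eps=1e-8):
        super().__init__(shape, momentum)
        self.beta1, self.beta2, self.eps = beta1, momentum, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, W, grad, lr):
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        W -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _RMSprop(_Optimizer):
    def __init__(self, shape, momentum, alpha=0.99, eps=1e-8):
        super().__init__(shape, momentum)
        self.alpha, self.eps = alpha, eps
        self.sq = np.zeros(shape)
        self.buf = np.zeros(shape)

    def step(self, W, grad, lr):
        self.sq = self.alpha * self.sq + (1 - self.alpha) * grad**2
        update = grad / (np.sqrt(self.sq) + self.eps)
        self.buf = self.momentum * self.buf + update
        W -= lr * self.buf


_OPTIMIZERS = {"sgd": _SGD, "adam": _Adam, "rmsprop": _RMSprop}


def _lr_at(config: "TrainConfig", epoch: int) -> float:
    base = config.learning_rate
    if config.schedule == "exponential":
        return base * config.gamma**epoch
    if config.schedule == "step":
        return base * config.step_gamma ** (epoch // config.step_size)
    if config.schedule == "cosine-annealing":
        return config.eta_min + (base - config.eta_min) * 0.5 * (
            1 + math.cos(math.pi * epoch / max(config.epochs, 1))
        )
    raise TrainingError(f"unknown schedule {config.schedule!r}")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters for the bilinear model."""

    learning_rate: float = 1e-3
    optimizer: str = "adam"
    schedule: str = "exponential"
    momentum: float = 0.99
    weight_decay: float = 1e-4
    epochs: int = 200
    batch_size: int = 64
    restarts: int = 3
    seed: int = 0
    gamma: float = 0.99
    step_size: int = 50
    step_gamma: float = 0.5
    eta_min: float = 0.0

    def __post_init__(self) -> None:
        if not 1e-6 <= self.learning_rate <= 0.1:
            raise TrainingError("learning_rate must lie in [1e-6, 0.1]")
        if not 1e-5 <= self.weight_decay <= 0.01:
            raise TrainingError("weight_decay must lie in [1e-5, 0.01]")
        if self.optimizer not in _OPTIMIZERS:
            raise TrainingError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("exponential", "step", "cosine-annealing"):
            raise TrainingError(f"unknown schedule {self.schedule!r}")
        if not 0.95 <= self.momentum <= 0.9999:
            raise TrainingError("momentum must lie in [0.95, 0.9999]")
        if self.epochs < 1 or self.batch_size < 1:
            raise TrainingError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    train_pairs: AssociationTable | Sequence[tuple[str, str]],
    site_store: EmbeddingStore,
    kinase_store: EmbeddingStore,
    config: TrainConfig | None = None,
    val_pairs: AssociationTable | None = None,
) -> tuple[CompatibilityModel, pd.DataFrame]:
    """Fit W by mini-batch regularized cross-entropy over the light kinases.

    Each (site, kinase) training pair is one example with a single positive
    class among the training kinases.  When a validation split is given
    (its kinases must be disjoint from training), the checkpoint with the
    best validation macro AP is returned; the log records loss, learning
    rate and validation AP per epoch.
    """
    config = config or TrainConfig()
    pairs = list(train_pairs)
    if not pairs:
        raise TrainingError("empty training set")
    train_kinases = sorted({k for _, k in pairs})
    if val_pairs is not None:
        val_kinases = sorted({k for _, k in val_pairs})
        overlap = set(val_kinases) & set(train_kinases)
        if overlap:
            raise TrainingError(
                f"validation kinases overlap training kinases: {sorted(overlap)[:5]}"
            )
    kin_index = {k: j for j, k in enumerate(train_kinases)}
    labels = np.array([kin_index[k] for _, k in pairs])
    Theta_aug = _augment(site_store.matrix([s for s, _ in pairs]))
    Phi_aug = _augment(kinase_store.matrix(train_kinases))
    d = site_store.dim
    m = kinase_store.dim
    rng = np.random.default_rng(config.seed)
    W = rng.normal(0.0, 1.0 / math.sqrt(d + 1), size=(d + 1, m + 1))
    optimizer = _OPTIMIZERS[config.optimizer](W.shape, config.momentum)

    if val_pairs is not None:
        val_sites = val_pairs.site_ids
        val_Theta_aug = _augment(site_store.matrix(val_sites))
        val_Phi_aug = _augment(kinase_store.matrix(val_kinases))
        val_labels = val_pairs.site_labels

    n = len(pairs)
    best_ap = -np.inf
    best_W = W.copy()
    log_rows = []
    for epoch in range(config.epochs):
        lr = _lr_at(config, epoch)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = perm[start : start + config.batch_size]
            loss, grad = loss_and_grad(W, Theta_aug[batch], Phi_aug, labels[batch])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: loss={loss}, "
                    f"|W|={np.abs(W).max():.3g}, lr={lr:.3g}"
                )
            optimizer.step(W, grad, lr)
            W -= lr * config.weight_decay * W  # decoupled weight decay
            losses.append(loss)
        row = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))}
        if val_pairs is not None:
            probs = softmax(val_Theta_aug @ W @ val_Phi_aug.T, axis=1)
            ap, _ = macro_ap(ScoreMatrix(probs, val_sites, val_kinases), val_labels)
            row["val_macro_ap"] = ap
            if ap > best_ap:
                best_ap = ap
                best_W = W.copy()
        log_rows.append(row)
    final_W = best_W if val_pairs is not None else W
    return CompatibilityModel(W=final_W, d=d, m=m), pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Hyperparameter search and restarts
# ---------------------------------------------------------------------------

SEARCH_SPACE = {
    "learning_rate": (1e-6, 0.1),
    "weight_decay": (1e-5, 0.01),
    "optimizer": ("adam", "sgd", "rmsprop"),
    "schedule": ("exponential", "step", "cosine-annealing"),
    "momentum": (0.95, 0.9999),
}


def sample_config(
    rng: np.random.Generator, base: TrainConfig | None = None
) -> TrainConfig:
    """Draw one random hyperparameter combination from the search space.

    Learning rate and weight decay are sampled log-uniformly; optimizer and
    schedule uniformly; momentum uniformly on its interval.
    """
    base = base or TrainConfig()
    lo, hi = SEARCH_SPACE["learning_rate"]
    lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = SEARCH_SPACE["weight_decay"]
    wd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return dataclasses.replace(
        base,
        learning_rate=lr,
        weight_decay=wd,
        optimizer=str(rng.choice(SEARCH_SPACE["optimizer"])),
        schedule=str(rng.choice(SEARCH_SPACE["schedule"])),
        momentum=float(rng.uniform(*SEARCH_SPACE["momentum"])),
    )


def random_search(
    train_pairs: AssociationTable,
    site_store: EmbeddingStore,
    kinase_store: EmbeddingStore,
    val_pairs: AssociationTable,
    n_trials: int = 10,
    seed: int = 0,
    base: TrainConfig | None = None,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Random hyperparameter search scored by validation macro AP.

    Returns the best configuration and the full trial table (one row per
    trial with the sampled hyperparameters and the achieved AP).
    """
    if n_trials < 1:
        raise TrainingError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    configs = []
    for trial in range(n_trials):
        config = sample_config(rng, base)
        config = dataclasses.replace(config, seed=int(rng.integers(2**31 - 1)))
        _, log = train(train_pairs, site_store, kinase_store, config, val_pairs)
        ap = float(log["val_macro_ap"].max())
        configs.append(config)
        rows.append(
            {
                "trial": trial,
                "learning_rate": config.learning_rate,
                "weight_decay": config.weight_decay,
                "optimizer": config.optimizer,
                "schedule": config.schedule,
                "momentum": config.momentum,
                "seed": config.seed,
                "val_macro_ap": ap,
            }
        )
    trials = pd.DataFrame(rows)
    best = int(trials["val_macro_ap"].idxmax())
    return configs[best], trials


@dataclass
class RestartResult:
    """Mean and sample standard deviation of macro AP over restarts."""

    mean_macro_ap: float
    std_macro_ap: float
    per_run: list[float]

    def formatted(self, digits: int = 4) -> str:
        return (
            f"{self.mean_macro_ap:.{digits}f} "
            f"±{self.std_macro_ap:.{digits}f}"
        )


def run_restarts(
    train_pairs: AssociationTable,
    site_store: EmbeddingStore,
    kinase_store: EmbeddingStore,
    test_pairs: AssociationTable,
    config: TrainConfig | None = None,
    val_pairs: AssociationTable | None = None,
    n: int = 3,
) -> RestartResult:
    """Train ``n`` models differing only in initialisation seed.

    Each run's test macro AP is computed with the softmax over the test
    kinases; the mean and sample standard deviation are reported, matching
    the usual mean +/- std convention.
    """
    if n < 2:
        raise TrainingError("need n >= 2 restarts for a standard deviation")
    config = config or TrainConfig()
    seed_rng = np.random.default_rng(config.seed)
    test_sites = test_pairs.site_ids
    test_kinases = sorted({k for _, k in test_pairs})
    aps = []
    for _ in range(n):
        run_config = dataclasses.replace(
            config, seed=int(seed_rng.integers(2**31 - 1))
        )
        model, _ = train(train_pairs, site_store, kinase_store, run_config, val_pairs)
        scores = model.predict(test_sites, site_store, test_kinases, kinase_store)
        ap, _ = macro_ap(scores, test_pairs.site_labels)
        aps.append(ap)
    arr = np.array(aps)
    return RestartResult(
        mean_macro_ap=float(arr.mean()),
        std_macro_ap=float(arr.std(ddof=1)),
        per_run=aps,
    )
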
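"""Training loop, evaluation protocol, and paired statistical comparison.

The optimiser is a Riemannian Adam: Euclidean parameters follow standard
Adam, while Stiefel-housed BiMap weights take their step in the tangent
space of the current point and are retracted back to the manifold by a QR
factorisation after every update, so ``W^T W = I`` holds throughout
training to machine precision.

Evaluation follows a per-participant protocol: each participant's model is
trained and tested separately, repeated with several random seeds, and
accuracies (percent, on the unseen test split) are averaged across
participants and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import EEGSPDNet, NetworkConfig, Parameter, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "RiemannianAdam",
    "train",
    "train_test_split_trials",
    "evaluate_protocol",
    "wilcoxon_compare",
    "stiefel_residual",
]


@dataclass
class TrainConfig:
    """Hyperparameters of a single training run."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seeds: tuple[int, ...] = (0, 1, 2)
    test_fraction: float = 0.25
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning rate and weight decay must be nonnegative")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


def _qf_retract(W: np.ndarray) -> np.ndarray:
    """QR retraction onto the Stiefel manifold (sign-fixed Q factor)."""
    Q, R = np.linalg.qr(W)
    return Q * np.sign(np.diag(R))


def _proj_tangent(W: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Orthogonal projection of an ambient gradient onto the Stiefel tangent space."""
    WtG = W.T @ G
    return G - W @ (0.5 * (WtG + WtG.T))


def stiefel_residual(params: Sequence[Parameter]) -> float:
    """Largest ``||W^T W - I||_F`` over all Stiefel parameters (constraint audit)."""
    res = 0.0
    for p in params:
        if p.manifold == "stiefel":
            W = p.value
            res = max(res, float(np.linalg.norm(W.T @ W - np.eye(W.shape[1]))))
    return res


class RiemannianAdam:
    """Adam with manifold-aware steps for Stiefel parameters.

    For Euclidean parameters this is textbook Adam with L2 weight decay
    added to the gradient.  For Stiefel parameters the gradient is first
    projected to the tangent space; moments are kept in ambient
    coordinates, the Adam direction is re-projected before stepping, the
    new point is obtained by QR retraction, and the first moment is
    parallel-transported by projection onto the new tangent space.  Weight
    decay is not applied on the manifold (there is no meaningful origin to
    decay toward).
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if p.manifold == "stiefel":
                r = _proj_tangent(p.value, g)
                m[...] = self.b1 * m + (1.0 - self.b1) * r
                v[...] = self.b2 * v + (1.0 - self.b2) * r * r
                d = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                d = _proj_tangent(p.value, d)
                p.value[...] = _qf_retract(p.value - self.lr * d)
                m[...] = _proj_tangent(p.value, m)
            else:
                if self.weight_decay:
                    g = g + self.weight_decay * p.value
                m[...] = self.b1 * m + (1.0 - self.b1) * g
                v[...] = self.b2 * v + (1.0 - self.b2) * g * g
                p.value[...] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class NonFiniteLossError(RuntimeError):
    """Raised when a training batch produces a non-finite loss."""

    def __init__(self, epoch: int, batch_index: int, loss: float):
        super().__init__(
            f"non-finite loss {loss} at epoch {epoch}, batch {batch_index}"
        )
        self.epoch = epoch
        self.batch_index = batch_index


def train(
    model: EEGSPDNet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
) -> dict:
    """Train a network with Riemannian Adam; fully seeded and deterministic.

    Returns a history dict with per-epoch mean loss and the post-training
    Stiefel constraint residual.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    opt = RiemannianAdam(
        model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(config.shuffle_seed)
    n = len(X)
    losses = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start : start + config.batch_size]
            loss = model.loss_and_grad(X[idx], y[idx])
            if not np.isfinite(loss):
                raise NonFiniteLossError(epoch, bi, loss)
            opt.step()
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return {
        "loss": losses,
        "stiefel_residual": stiefel_residual(model.parameters()),
        "n_steps": opt.t,
    }


def train_test_split_trials(
    X: np.ndarray, y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified shuffle split of a trial set into train and test parts."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        k = max(1, int(round(len(idx) * test_fraction)))
        test_idx.extend(idx[:k])
        train_idx.extend(idx[k:])
    tr = np.sort(np.asarray(train_idx))
    te = np.sort(np.asarray(test_idx))
    return X[tr], y[tr], X[te], y[te]


def evaluate_protocol(
    cohort: Mapping[str, tuple[np.ndarray, np.ndarray]],
    model_builder: Callable[[int], EEGSPDNet],
    config: TrainConfig,
    condition: str = "default",
) -> pd.DataFrame:
    """Per-participant x seed training/testing protocol.

    ``cohort`` maps participant ids to ``(X, y)`` trial sets.  For every
    participant and every seed, a fresh model is built via
    ``model_builder(seed)``, trained on that participant's training split
    and scored on the held-out test split.  Returns a tidy score table with
    one row per participant x seed (accuracy in percent); the
    participant-and-seed mean is the protocol's summary statistic.
    """
    rows = []
    for pid, (X, y) in cohort.items():
        Xtr, ytr, Xte, yte = train_test_split_trials(
            X, y, config.test_fraction, seed=config.shuffle_seed
        )
        for seed in config.seeds:
            model = model_builder(seed)
            run_cfg = TrainConfig(
                learning_rate=config.learning_rate,
                weight_decay=config.weight_decay,
                epochs=config.epochs,
                batch_size=config.batch_size,
                seeds=(seed,),
                test_fraction=config.test_fraction,
                shuffle_seed=seed,
            )
            train(model, Xtr, ytr, run_cfg)
            acc = 100.0 * float(np.mean(model.predict(Xte) == yte))
            rows.append(
                {"participant": pid, "seed": seed, "condition": condition, "accuracy": acc}
            )
    return pd.DataFrame(rows)


def wilcoxon_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired scores.

    Uses the exact null distribution (no normal approximation), which at
    small sample sizes yields the characteristic discrete p-values: n
    all-same-sign pairs give ``p = 2 * 2^-n`` (0.0078125 at n=8, 0.015625
    at n=7).  Zero differences are dropped before ranking; if every pair is
    tied the comparison is vacuous and ``p = 1`` is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("paired score vectors must be 1-D, nonempty and equal length")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="exact", alternative="two-sided")
    return float(res.pvalue)
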
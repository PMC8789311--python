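"""Stacked-LSTM models for sweep inference, with MC-dropout intervals.

Four tasks share one architecture — a stack of LSTM layers read by a
dense head:

* ``classify``   — sweep vs. neutral; 2-unit softmax head on the final
  hidden state, cross-entropy loss;
* ``regress_s``  — selection coefficient; linear head, MSE;
* ``regress_onset`` — selection onset time; linear head, MSE;
* ``trajectory`` — allele frequency at every grid time (many-to-many);
  linear head applied to every timestep, MSE.

Features are fed present-to-past: timestep 0 is the present.  Prediction
intervals come from Monte-Carlo dropout: the dropout masks drawn during
training-time regularization are re-sampled at inference, each thinned
network yields one draw, and the interval is formed from empirical
percentiles of the draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from argsel.features import FeatureVector
from argsel.nn.lstm import Adam, Dense, LSTMStack, softmax

__all__ = ["NetConfig", "Prediction", "SiaModel", "train", "predict",
           "predict_with_dropout", "shape_input"]

_TASKS = ("classify", "regress_s", "regress_onset", "trajectory")


@dataclass(frozen=True)
class NetConfig:
    task: str = "regress_s"
    n_stacks: int = 2
    units_per_stack: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 40
    patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.n_stacks < 1 or self.units_per_stack < 1:
            raise ValueError("n_stacks and units_per_stack must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class Prediction:
    """Point estimate(s) with an optional dropout-sampled distribution."""

    task: str
    class_prob: Optional[float] = None
    s_hat: Optional[float] = None
    onset_hat: Optional[float] = None
    traj_hat: Optional[np.ndarray] = None
    ci: Optional[Tuple] = None
    samples: Optional[np.ndarray] = None

    @property
    def point(self):
        return {
            "classify": self.class_prob,
            "regress_s": self.s_hat,
            "regress_onset": self.onset_hat,
            "trajectory": self.traj_hat,
        }[self.task]


def shape_input(fv, K: Optional[int] = None) -> np.ndarray:
    """Reshape a flat feature vector to (K, channels), time-major.

    Accepts a :class:`FeatureVector` (its own K is used) or a flat array
    with ``K`` given; a 600-vector with K = 100 becomes 100 x 6.
    """
    if isinstance(fv, FeatureVector):
        return fv.matrix
    arr = np.asarray(fv, dtype=float)
    if arr.ndim == 2:
        return arr
    if K is None:
        raise ValueError("K is required to reshape a flat vector")
    if arr.size % K != 0:
        raise ValueError(f"length {arr.size} not divisible by K={K}")
    return arr.reshape(K, arr.size // K)


class SiaModel:
    """A trained (or trainable) stacked-LSTM sweep-inference model."""

    def __init__(self, config: NetConfig, n_channels: int, K: int,
                 rng: Optional[np.random.Generator] = None):
        self.config = config
        self.n_channels = n_channels
        self.K = K
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.stacks: List[LSTMStack] = []
        d = n_channels
        for _ in range(config.n_stacks):
            self.stacks.append(LSTMStack(d, config.units_per_stack, rng))
            d = config.units_per_stack
        n_out = 2 if config.task == "classify" else 1
        self.head = Dense(d, n_out, rng)
        self.training_log: List[dict] = []

    # -- plumbing ----------------------------------------------------------

    @property
    def _layers(self):
        return [*self.stacks, self.head]

    def parameters(self):
        return [p for layer in self._layers for p in layer.params]

    def gradients(self):
        return [g for layer in self._layers for g in layer.grads]

    def _forward(self, X, dropout_rng: Optional[np.random.Generator] = None):
        """Forward pass; with ``dropout_rng`` the network is 'thinned'."""
        rate = self.config.dropout_rate
        a = X
        self._masks = []
        for stack in self.stacks:
            a = stack.forward(a)
            if dropout_rng is not None and rate > 0.0:
                keep = 1.0 - rate
                mask = (
                    dropout_rng.uniform(size=(a.shape[0], 1, a.shape[2])) < keep
                ) / keep
            else:
                mask = None
            self._masks.append(mask)
            if mask is not None:
                a = a * mask
        self._h_all = a
        if self.config.task == "trajectory":
            return self.head.forward(a)[..., 0]  # (B, T)
        out = self.head.forward(a[:, -1])  # (B, n_out)
        if self.config.task == "classify":
            return softmax(out)
        return out[:, 0]

    def _loss_and_grad(self, X, y, dropout_rng):
        B = X.shape[0]
        task = self.config.task
        yhat = self._forward(X, dropout_rng=dropout_rng)
        if task == "classify":
            probs = np.clip(yhat, 1e-12, 1.0)
            onehot = np.zeros_like(probs)
            onehot[np.arange(B), y.astype(int)] = 1.0
            loss = -np.mean(np.sum(onehot * np.log(probs), axis=1))
            dlogits = (yhat - onehot) / B
            dh_last = self.head.backward(dlogits)
        elif task == "trajectory":
            err = yhat - y
            loss = float(np.mean(err**2))
            dy = (2.0 * err / err.size)[..., None]
            dH = self.head.backward(dy)
        else:
            err = yhat - y
            loss = float(np.mean(err**2))
            dyhat = (2.0 * err / err.size)[:, None]
            dh_last = self.head.backward(dyhat)
        if task != "trajectory":
            dH = np.zeros_like(self._h_all)
            dH[:, -1] = dh_last
        for stack, mask in zip(reversed(self.stacks), reversed(self._masks)):
            if mask is not None:
                dH = dH * mask
            dH = stack.backward(dH)
        return loss

    def _eval_loss(self, X, y, batch: int = 256) -> float:
        task = self.config.task
        tot, cnt = 0.0, 0
        for i in range(0, len(X), batch):
            yhat = self._forward(X[i : i + batch])
            yb = y[i : i + batch]
            if task == "classify":
                probs = np.clip(yhat, 1e-12, 1.0)
                ll = -np.log(probs[np.arange(len(yb)), yb.astype(int)])
                tot += float(ll.sum())
                cnt += len(yb)
            else:
                tot += float(np.sum((yhat - yb) ** 2))
                cnt += (yhat - yb).size
        return tot / cnt

    # -- persistence -------------------------------------------------------

    def save(self, path, extra_meta: Optional[dict] = None):
        """Single-file .npz checkpoint with a JSON self-description.

        ``extra_meta`` (e.g. grid parameters, channel order and the
        normalization flag of the training features) is stored verbatim
        so a checkpoint describes its own input contract.
        """
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        meta = {
            "config": asdict(self.config),
            "n_channels": self.n_channels,
            "K": self.K,
            "extra": extra_meta or {},
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SiaModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(NetConfig(**meta["config"]), meta["n_channels"], meta["K"])
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


def train(dataset: dict, config: NetConfig) -> SiaModel:
    """Train a model on ``{"X": (N, K, C), "y": labels}``.

    Labels must match the task: integer class labels for ``classify``,
    scalars for the regressions, (N, K) frequency curves for
    ``trajectory``.  A held-out validation fraction drives early
    stopping (best-epoch weights are restored); per-epoch losses are
    recorded in ``model.training_log``.
    """
    X = np.asarray(dataset["X"], dtype=float)
    y = np.asarray(dataset["y"], dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be (N, K, channels)")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if config.task == "trajectory" and (y.ndim != 2 or y.shape[1] != X.shape[1]):
        raise ValueError("trajectory labels must be (N, K)")
    if config.task == "classify" and not np.all(np.isin(y, (0, 1))):
        raise ValueError("classification labels must be 0/1")

    rng = np.random.default_rng(config.seed)
    model = SiaModel(config, n_channels=X.shape[2], K=X.shape[1], rng=rng)
    n_val = max(int(len(X) * config.validation_fraction), 1)
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=config.learning_rate)
    best = (np.inf, None)
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        tr_loss, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            loss = model._loss_and_grad(Xtr[idx], ytr[idx], dropout_rng=rng)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(model.gradients())
            tr_loss += loss
            nb += 1
        val_loss = model._eval_loss(Xval, yval)
        model.training_log.append(
            {"epoch": epoch, "train_loss": tr_loss / max(nb, 1),
             "val_loss": val_loss}
        )
        if val_loss < best[0] - 1e-9:
            best = (val_loss, [p.copy() for p in model.parameters()])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best[1] is not None:
        for p, bp in zip(model.parameters(), best[1]):
            p[...] = bp
    return model


def _single(model: SiaModel, fv, dropout_rng=None):
    X = shape_input(fv, K=model.K)[None, ...]
    if X.shape[1] != model.K or X.shape[2] != model.n_channels:
        raise ValueError(
            f"input shaped {X.shape[1:]} but model expects "
            f"({model.K}, {model.n_channels})"
        )
    out = model._forward(X, dropout_rng=dropout_rng)
    task = model.config.task
    if task == "classify":
        return float(out[0, 1])
    if task == "trajectory":
        return np.clip(out[0], 0.0, 1.0)
    val = float(out[0])
    return max(val, 0.0) if task == "regress_s" else val


def predict(model: SiaModel, fv) -> Prediction:
    """Deterministic point prediction (dropout disabled)."""
    val = _single(model, fv)
    task = model.config.task
    return Prediction(
        task=task,
        class_prob=val if task == "classify" else None,
        s_hat=val if task == "regress_s" else None,
        onset_hat=val if task == "regress_onset" else None,
        traj_hat=val if task == "trajectory" else None,
    )


def predict_with_dropout(
    model: SiaModel,
    fv,
    n_samples: int = 100,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> Prediction:
    """Monte-Carlo-dropout prediction with an empirical interval.

    Runs ``n_samples`` stochastic forward passes with dropout active and
    reports the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the
    sampled predictions alongside the deterministic point estimate.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    pred = predict(model, fv)
    samples = np.array([_single(model, fv, dropout_rng=rng) for _ in range(n_samples)])
    lo = 100 * (1 - level) / 2
    if model.config.task == "trajectory":
        ci = (np.minimum(np.percentile(samples, lo, axis=0), pred.traj_hat),
              np.maximum(np.percentile(samples, 100 - lo, axis=0), pred.traj_hat))
    else:
        # widen to contain the deterministic point estimate
        ci = (min(float(np.percentile(samples, lo)), pred.point),
              max(float(np.percentile(samples, 100 - lo)), pred.point))
    pred.ci = ci
    pred.samples = samples
    return pred
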
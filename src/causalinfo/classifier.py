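"""Feed-forward binary classifier encoding a density ratio.

The estimator trains a classifier to separate joint-batch rows
(class 1, distributed like ``p(x, y, z)``) from product-batch rows
(class 0, distributed like ``p(x|z) p(y, z)``) under binary
cross-entropy.  At the optimum, with balanced class priors, the
classifier's output ``w`` satisfies

    w / (1 - w) = p(x, y, z) / (p(x|z) p(y, z)) = Gamma(x, y, z),

so the trained odds are a plug-in estimate of the density ratio whose
logarithm is exactly the function at which the Donsker–Varadhan bound is
tight.  To keep the ratio finite, the sigmoid output is clipped to
``[tau, 1 - tau]`` whenever the ratio or the reported loss is evaluated;
gradients during training use unclipped logits.

The network is a plain multilayer perceptron (He-initialised ReLU
hidden layers, sigmoid head) trained with Adam on minibatches; it is
implemented directly on numpy arrays so that the whole training loop is
deterministic given a seed and serialisable to plain JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .batching import JointBatch, ProductBatch

__all__ = [
    "ClassifierConfig",
    "RatioModel",
    "init_model",
    "empirical_loss",
    "train_model",
    "density_ratio",
    "save_model",
    "load_model",
]


@dataclass
class ClassifierConfig:
    """Hyper-parameters of the ratio classifier.

    Defaults follow the reference experimental setup: two ReLU hidden
    layers of 64 units, Adam with learning rate 1e-3, 200 training
    epochs and clipping constant ``tau = 1e-3``.  ``minibatch`` may be an
    integer or ``"full"``; 1024 keeps the number of gradient steps
    proportional to the batch size, which full-batch training does not.
    """

    hidden_sizes: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    tau: float = 1e-3
    epochs: int = 200
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    minibatch: int | str = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not (0.0 < self.tau < 0.5):
            raise ValueError("tau must lie in (0, 0.5)")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation.lower() != "relu":
            raise ValueError("only the ReLU activation is supported")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.minibatch != "full" and int(self.minibatch) < 1:
            raise ValueError('minibatch must be a positive integer or "full"')


@dataclass
class RatioModel:
    """A (possibly trained) classifier and the density ratio it encodes."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_dims: tuple[int, int, int]
    config: ClassifierConfig
    trained: bool = False
    # recorded at training time; corrects the ratio if classes were unbalanced
    n_joint_train: int = 0
    n_prod_train: int = 0
    # per-feature affine input standardization, fitted on the training batches
    input_loc: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    @property
    def input_width(self) -> int:
        return sum(self.input_dims)

    @property
    def balance_coefficient(self) -> float:
        """|B_prod| / |B_joint| of the training batches (1 when untrained)."""
        if self.n_joint_train and self.n_prod_train:
            return self.n_prod_train / self.n_joint_train
        return 1.0

    def logits(self, inputs: np.ndarray) -> np.ndarray:
        """Pre-sigmoid network output for stacked ``(x, y, z)`` rows."""
        a = np.atleast_2d(np.asarray(inputs, dtype=float))
        if a.shape[1] != self.input_width:
            raise ValueError(
                f"input width {a.shape[1]} != expected {self.input_width}"
            )
        if self.input_loc is not None:
            a = (a - self.input_loc) / self.input_scale
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def omega(self, inputs: np.ndarray) -> np.ndarray:
        """Sigmoid output in (0, 1), unclipped."""
        return _sigmoid(self.logits(inputs))

    def omega_clipped(self, inputs: np.ndarray) -> np.ndarray:
        tau = self.config.tau
        return np.clip(self.omega(inputs), tau, 1.0 - tau)

    def log_ratio(self, inputs: np.ndarray) -> np.ndarray:
        """``log Gamma_hat`` on stacked rows, clipped and balance-corrected."""
        w = self.omega_clipped(inputs)
        return np.log(w) - np.log1p(-w) + np.log(self.balance_coefficient)

    def copy(self) -> "RatioModel":
        return RatioModel(
            weights=[W.copy() for W in self.weights],
            biases=[b.copy() for b in self.biases],
            input_dims=self.input_dims,
            config=self.config,
            trained=self.trained,
            n_joint_train=self.n_joint_train,
            n_prod_train=self.n_prod_train,
            input_loc=None if self.input_loc is None else self.input_loc.copy(),
            input_scale=None if self.input_scale is None else self.input_scale.copy(),
        )


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def init_model(
    config: ClassifierConfig, input_dims: Sequence[int]
) -> RatioModel:
    """Seeded He (fan-in scaled) initialisation of an untrained model."""
    dims = tuple(int(d) for d in input_dims)
    if len(dims) != 3 or any(d < 0 for d in dims) or sum(dims) == 0:
        raise ValueError("input_dims must be three non-negative widths, not all zero")
    rng = np.random.default_rng(config.seed)
    sizes = [sum(dims), *config.hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return RatioModel(weights, biases, dims, config)


def _stack(batch) -> np.ndarray:
    return np.hstack([batch.x, batch.y, batch.z])


def empirical_loss(
    model: RatioModel, joint: JointBatch, prod: ProductBatch
) -> float:
    """Class-balanced binary cross-entropy over the two batches.

    Returns ``-(1/(2|B_joint|)) sum log w  -  (1/(2|B_prod|)) sum log(1-w)``
    with the sigmoid output clipped to ``[tau, 1-tau]`` inside the logs.
    A classifier stuck at ``w = 0.5`` scores ``log 2``.
    """
    if len(joint) == 0 or len(prod) == 0:
        raise ValueError("both batches must be non-empty")
    wj = model.omega_clipped(_stack(joint))
    wp = model.omega_clipped(_stack(prod))
    return float(-0.5 * np.mean(np.log(wj)) - 0.5 * np.mean(np.log1p(-wp)))


def train_model(
    model: RatioModel,
    joint_train: JointBatch,
    prod_train: ProductBatch,
    config: ClassifierConfig | None = None,
) -> RatioModel:
    """Minimise the class-balanced cross-entropy with minibatch Adam.

    The two classes are weighted by the reciprocal of their batch size,
    matching the empirical loss exactly regardless of balance.  The
    returned model carries the parameters with the lowest end-of-epoch
    training loss seen during the run, so its loss never exceeds the
    initial model's; with ``epochs = 0`` the parameters are unchanged.
    """
    if config is None:
        config = model.config
    if len(joint_train) == 0 or len(prod_train) == 0:
        raise ValueError("both training batches must be non-empty")
    if config.epochs == 0:
        out = model.copy()
        out.trained = True
        out.n_joint_train = len(joint_train)
        out.n_prod_train = len(prod_train)
        return out
    Xj, Xp = _stack(joint_train), _stack(prod_train)
    if Xj.shape[1] != model.input_width or Xp.shape[1] != model.input_width:
        raise ValueError("batch width does not match model input width")

    nj, np_ = Xj.shape[0], Xp.shape[0]
    X = np.vstack([Xj, Xp])
    t = np.concatenate([np.ones(nj), np.zeros(np_)])
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    X = (X - loc) / scale  # gradients below run on standardized inputs
    # per-sample weights summing to 1, matching the 1/(2|B_c|) loss terms
    w = np.concatenate([np.full(nj, 0.5 / nj), np.full(np_, 0.5 / np_)])
    n_total = nj + np_

    out = model.copy()
    out.n_joint_train, out.n_prod_train = nj, np_
    out.trained = True
    out.input_loc, out.input_scale = loc, scale
    best = out.copy()
    best_loss = empirical_loss(out, joint_train, prod_train)

    mb = n_total if config.minibatch == "full" else min(int(config.minibatch), n_total)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A11]))
    params = out.weights + out.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for _ in range(config.epochs):
        perm = rng.permutation(n_total)
        for lo in range(0, n_total, mb):
            sel = perm[lo : lo + mb]
            grads = _bce_gradients(out, X[sel], t[sel], w[sel])
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1.0 - beta2**step) / (1.0 - beta1**step)
            )
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1.0 - beta1) * g
                vi *= beta2
                vi += (1.0 - beta2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + eps)
        loss = empirical_loss(out, joint_train, prod_train)
        if loss < best_loss:
            best_loss = loss
            best = out.copy()
    return best


def _bce_gradients(
    model: RatioModel, X: np.ndarray, targets: np.ndarray, sample_w: np.ndarray
) -> list[np.ndarray]:
    """Gradient of the weighted BCE w.r.t. [weights..., biases...].

    Weighted loss = sum_i w_i * [softplus(logit_i) - t_i * logit_i]; the
    weights are global (sum to 1 over the full training set), so
    minibatch gradients are unbiased estimates scaled by n_total/|mb| —
    the constant factor is absorbed by Adam's per-parameter scaling.
    """
    acts = [X]
    a = X
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.maximum(a @ W + b, 0.0)
        acts.append(a)
    logit = (a @ model.weights[-1] + model.biases[-1]).ravel()
    delta = (sample_w * (_sigmoid(logit) - targets))[:, None]

    gW = [np.empty(0)] * len(model.weights)
    gb = [np.empty(0)] * len(model.biases)
    gW[-1] = acts[-1].T @ delta
    gb[-1] = delta.sum(axis=0)
    d = delta @ model.weights[-1].T
    for layer in range(len(model.weights) - 2, -1, -1):
        d = d * (acts[layer + 1] > 0)
        gW[layer] = acts[layer].T @ d
        gb[layer] = d.sum(axis=0)
        if layer > 0:
            d = d @ model.weights[layer].T
    return gW + gb


def density_ratio(
    model: RatioModel,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
) -> np.ndarray | float:
    """Estimated density ratio ``Gamma_hat`` at one or many points.

    ``Gamma_hat = w/(1-w)`` with ``w`` clipped to ``[tau, 1-tau]``, hence
    bounded in ``[tau/(1-tau), (1-tau)/tau]``; multiplied by the
    training-balance coefficient when the training batches differed in
    size.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z.reshape(x.shape[0], -1) if z.size else np.empty((x.shape[0], 0))
    inputs = np.hstack([x, y, z])
    if not np.all(np.isfinite(inputs)):
        raise ValueError("inputs must be finite")
    out = np.exp(model.log_ratio(inputs))
    return float(out[0]) if out.size == 1 else out


def save_model(model: RatioModel, path) -> None:
    """Serialise parameters + config + dims to a portable JSON checkpoint."""
    payload = {
        "config": asdict(model.config),
        "input_dims": list(model.input_dims),
        "trained": model.trained,
        "n_joint_train": model.n_joint_train,
        "n_prod_train": model.n_prod_train,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_loc": None if model.input_loc is None else model.input_loc.tolist(),
        "input_scale": None if model.input_scale is None else model.input_scale.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RatioModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg_dict = dict(payload["config"])
    cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
    config = ClassifierConfig(**cfg_dict)
    return RatioModel(
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        input_dims=tuple(payload["input_dims"]),
        config=config,
        trained=payload["trained"],
        n_joint_train=payload["n_joint_train"],
        n_prod_train=payload["n_prod_train"],
        input_loc=(None if payload.get("input_loc") is None
                   else np.asarray(payload["input_loc"], dtype=float)),
        input_scale=(None if payload.get("input_scale") is None
                     else np.asarray(payload["input_scale"], dtype=float)),
    )
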
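"""Feed-forward classifier trained with focal cross-entropy loss.

The model is deliberately small and written directly from the formulas: an
input layer over the reduced feature set, one (by default) hidden layer of 7
leaky-ReLU units, and a 2-unit softmax output giving P(Intact), P(Impaired).
Training minimizes the focal loss

    FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t)

by mini-batch Adam with exact analytic gradients, an internal stratified
validation split, and early stopping on validation loss with best-weight
restoration. The focal loss down-weights easy examples and, through the
per-class weights alpha = (alpha_Intact, alpha_Impaired), up-weights the
minority Impaired class; at gamma = 0 and alpha = (1, 1) it reduces to plain
cross-entropy.

One-hot column order is (Intact, Impaired) everywhere in this package.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import IMPAIRED, INTACT

__all__ = [
    "LABEL_ORDER",
    "NetworkParams",
    "FocalLossConfig",
    "TrainConfig",
    "TrainHistory",
    "init_network",
    "forward",
    "focal_loss",
    "focal_loss_gradient",
    "train",
    "predict",
    "predict_proba_impaired",
    "labels_to_onehot",
    "onehot_to_labels",
    "grid_search",
]

#: fixed one-hot / output-unit order
LABEL_ORDER = (INTACT, IMPAIRED)

_EPS = 1e-7  # probability clip inside the loss, prevents log(0)


@dataclass
class NetworkParams:
    """Weights and biases of the classifier.

    ``weights[i]`` has shape (fan_out, fan_in); the last layer always has 2
    output units (softmax over the two cognitive-status classes).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up")
        if self.weights[-1].shape[0] != 2:
            raise ValueError("output layer must have exactly 2 units")
        for prev, nxt in itertools.pairwise(self.weights):
            if nxt.shape[1] != prev.shape[0]:
                raise ValueError("layer shapes do not chain")
        for W, b in zip(self.weights, self.biases):
            if b.shape != (W.shape[0],):
                raise ValueError("bias shape mismatch")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.leaky_slope,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "leaky_slope": self.leaky_slope,
                "weights": [W.tolist() for W in self.weights],
                "biases": [b.tolist() for b in self.biases],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        obj = json.loads(text)
        return cls(
            [np.asarray(W, dtype=float) for W in obj["weights"]],
            [np.asarray(b, dtype=float) for b in obj["biases"]],
            float(obj["leaky_slope"]),
        )


@dataclass(frozen=True)
class FocalLossConfig:
    """alpha: per-class weights in (Intact, Impaired) order; gamma: focusing."""

    alpha: tuple[float, float] = (0.5, 2.0)
    gamma: float = 1.5

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alpha):
            raise ValueError("alpha components must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    max_epochs: int = 50
    early_stopping_patience: int = 5
    validation_fraction: float = 0.1
    optimizer_step_size: float = 1e-3
    optimizer_moment_decays: tuple[float, float] = (0.9, 0.999)
    optimizer_eps: float = 1e-8
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def init_network(
    n_inputs: int,
    hidden_sizes: list[int] | tuple[int, ...] = (7,),
    seed: int = 0,
    leaky_slope: float = 0.01,
) -> NetworkParams:
    """Symmetric scaled-uniform (Glorot) initialization, zero biases."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    hidden_sizes = list(hidden_sizes)
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be non-empty")
    rng = np.random.default_rng(seed)
    sizes = [n_inputs, *hidden_sizes, 2]
    weights, biases = [], []
    for fan_in, fan_out in itertools.pairwise(sizes):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases, leaky_slope)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cached(params: NetworkParams, X: np.ndarray):
    """Forward pass keeping pre-activations for backprop."""
    a = X
    pre_acts, acts = [], [a]
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ W.T + b
        pre_acts.append(z)
        a = _softmax(z) if i == len(params.weights) - 1 else _leaky(z, params.leaky_slope)
        acts.append(a)
    return acts, pre_acts


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Class probabilities, rows in (Intact, Impaired) order summing to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, network expects {params.n_inputs}"
        )
    acts, _ = _forward_cached(params, X)
    return acts[-1]


def _check_onehot(Y: np.ndarray) -> None:
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("labels must be one-hot with 2 columns")
    if not np.all(np.isin(Y, (0.0, 1.0))) or not np.all(Y.sum(axis=1) == 1):
        raise ValueError("label rows must be one-hot")


def focal_loss(
    probs: np.ndarray, labels: np.ndarray, config: FocalLossConfig | None = None
) -> float:
    """Mean focal loss -alpha_t (1-p_t)^gamma log p_t over samples."""
    config = config or FocalLossConfig()
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_onehot(labels)
    alpha = np.asarray(config.alpha)
    p_t = np.clip((probs * labels).sum(axis=1), _EPS, 1 - _EPS)
    a_t = labels @ alpha
    return float(np.mean(-a_t * (1 - p_t) ** config.gamma * np.log(p_t)))


def focal_loss_gradient(
    params: NetworkParams,
    X: np.ndarray,
    Y: np.ndarray,
    config: FocalLossConfig | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradient of the mean focal loss w.r.t. every weight and bias.

    Through the softmax, with t the true class:
        dL/dp_t = alpha_t [ gamma (1-p_t)^{gamma-1} log p_t - (1-p_t)^gamma / p_t ]
        dp_t/dz_k = p_t (delta_{tk} - p_k)
    and the rest is ordinary backprop through the leaky-ReLU layers.
    """
    config = config or FocalLossConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    _check_onehot(Y)
    n = X.shape[0]
    acts, pre_acts = _forward_cached(params, X)
    probs = acts[-1]
    alpha = np.asarray(config.alpha)
    g = config.gamma

    p_t_raw = (probs * Y).sum(axis=1)
    p_t = np.clip(p_t_raw, _EPS, 1 - _EPS)
    a_t = Y @ alpha
    one_m = 1 - p_t
    if g == 0:
        dL_dpt = -a_t / p_t
    else:
        dL_dpt = a_t * (g * one_m ** (g - 1) * np.log(p_t) - one_m**g / p_t)
    # loss is constant in p_t where the clip is active
    dL_dpt = np.where((p_t_raw > _EPS) & (p_t_raw < 1 - _EPS), dL_dpt, 0.0)
    # dp_t/dz = p_t * (onehot - probs), row-wise
    delta = dL_dpt[:, None] * p_t[:, None] * (Y - probs) / n

    grads_W: list[np.ndarray] = [None] * len(params.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(params.biases)  # type: ignore
    for i in range(len(params.weights) - 1, -1, -1):
        grads_W[i] = delta.T @ acts[i]
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            dact = np.where(pre_acts[i - 1] > 0, 1.0, params.leaky_slope)
            delta = (delta @ params.weights[i]) * dact
    return grads_W, grads_b


def labels_to_onehot(labels) -> np.ndarray:
    labels = np.asarray(labels)
    Y = np.zeros((len(labels), 2))
    for j, name in enumerate(LABEL_ORDER):
        Y[labels == name, j] = 1.0
    if not np.all(Y.sum(axis=1) == 1):
        bad = set(labels) - set(LABEL_ORDER)
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return Y


def onehot_to_labels(Y: np.ndarray) -> np.ndarray:
    return np.asarray(LABEL_ORDER)[np.argmax(Y, axis=1)]


def _accuracy(probs: np.ndarray, Y: np.ndarray) -> float:
    return float(np.mean(np.argmax(probs, axis=1) == np.argmax(Y, axis=1)))


def _stratified_holdout(Y: np.ndarray, fraction: float, seed: int):
    """Index split keeping both classes represented in both parts."""
    rng = np.random.default_rng(seed)
    labels = np.argmax(Y, axis=1)
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * len(idx))))
        if n_val >= len(idx):
            raise ValueError("class too small for the validation split")
        val_idx.append(idx[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(Y)), val)
    return train, val


def train(
    X: np.ndarray,
    Y: np.ndarray,
    train_config: TrainConfig | None = None,
    loss_config: FocalLossConfig | None = None,
    init_seed: int = 0,
    hidden_sizes: tuple[int, ...] = (7,),
) -> tuple[NetworkParams, TrainHistory]:
    """Mini-batch Adam on the focal loss with early stopping.

    A stratified ``validation_fraction`` of the data is held out internally;
    training stops when validation loss has not improved for
    ``early_stopping_patience`` epochs and the best-epoch weights are
    restored. Fully deterministic given ``init_seed`` and
    ``train_config.seed`` (per-epoch shuffling uses a per-epoch child seed).
    """
    tc = train_config or TrainConfig()
    lc = loss_config or FocalLossConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    _check_onehot(Y)
    if Y.sum(axis=0).min() < 1:
        raise ValueError("both classes must be present in the training data")

    tr_idx, val_idx = _stratified_holdout(Y, tc.validation_fraction, tc.seed)
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    params = init_network(X.shape[1], hidden_sizes, seed=init_seed)
    b1, b2 = tc.optimizer_moment_decays
    m_W = [np.zeros_like(W) for W in params.weights]
    v_W = [np.zeros_like(W) for W in params.weights]
    m_b = [np.zeros_like(b) for b in params.biases]
    v_b = [np.zeros_like(b) for b in params.biases]
    step = 0

    history = TrainHistory()
    best_loss = np.inf
    best_params = params.copy()
    since_best = 0

    for epoch in range(1, tc.max_epochs + 1):
        order = np.random.default_rng((tc.seed, epoch)).permutation(len(X_tr))
        for start in range(0, len(order), tc.batch_size):
            batch = order[start : start + tc.batch_size]
            gW, gb = focal_loss_gradient(params, X_tr[batch], Y_tr[batch], lc)
            step += 1
            for i in range(len(params.weights)):
                for g, m, v, target in (
                    (gW[i], m_W[i], v_W[i], params.weights[i]),
                    (gb[i], m_b[i], v_b[i], params.biases[i]),
                ):
                    m[...] = b1 * m + (1 - b1) * g
                    v[...] = b2 * v + (1 - b2) * g * g
                    m_hat = m / (1 - b1**step)
                    v_hat = v / (1 - b2**step)
                    target -= tc.optimizer_step_size * m_hat / (
                        np.sqrt(v_hat) + tc.optimizer_eps
                    )

        p_tr = forward(params, X_tr)
        p_val = forward(params, X_val)
        history.train_loss.append(focal_loss(p_tr, Y_tr, lc))
        history.val_loss.append(focal_loss(p_val, Y_val, lc))
        history.train_accuracy.append(_accuracy(p_tr, Y_tr))
        history.val_accuracy.append(_accuracy(p_val, Y_val))
        history.stopped_epoch = epoch

        if history.val_loss[-1] < best_loss:
            best_loss = history.val_loss[-1]
            best_params = params.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.early_stopping_patience:
                break

    return best_params, history


def predict_proba_impaired(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    return forward(params, X)[:, LABEL_ORDER.index(IMPAIRED)]


def predict(params: NetworkParams, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Impaired iff P(Impaired) >= threshold (ties go to Impaired)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p_imp = predict_proba_impaired(params, X)
    return np.where(p_imp >= threshold, IMPAIRED, INTACT)


def grid_search(
    X: np.ndarray,
    Y: np.ndarray,
    depths: tuple[int, ...] = (1, 2, 3),
    widths: tuple[int, ...] = (7, 9, 14),
    k: int = 5,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    loss_config: FocalLossConfig | None = None,
):
    """Cross-validated architecture comparison over depth x width.

    For each architecture, pooled held-out Impaired recall and Intact-class
    error count under k-fold stratified CV. Rows are sorted by recall
    (descending), then fewest Intact errors, then fewest parameters.
    """
    import pandas as pd

    from .evaluation import confusion_from_predictions, make_stratified_folds

    tc = train_config or TrainConfig()
    lc = loss_config or FocalLossConfig()
    labels = onehot_to_labels(np.asarray(Y))
    plan = make_stratified_folds(labels, k=k, seed=seed)

    rows = []
    for depth in depths:
        for width in widths:
            hidden = (width,) * depth
            tp = fn = fp = 0
            n_params = None
            for fold in range(k):
                test_mask = plan.assignments == fold
                params, _ = train(
                    X[~test_mask],
                    Y[~test_mask],
                    tc,
                    lc,
                    init_seed=seed + fold,
                    hidden_sizes=hidden,
                )
                n_params = params.n_parameters
                pred = predict(params, X[test_mask], tc.threshold)
                c = confusion_from_predictions(labels[test_mask], pred)
                tp += c.TP
                fn += c.FN
                fp += c.FP
            rows.append(
                {
                    "depth": depth,
                    "width": width,
                    "impaired_recall": tp / (tp + fn) if tp + fn else float("nan"),
                    "intact_errors": fp,
                    "n_parameters": n_params,
                }
            )
    report = pd.DataFrame(rows).sort_values(
        by=["impaired_recall", "intact_errors", "n_parameters"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return report.reset_index(drop=True)
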
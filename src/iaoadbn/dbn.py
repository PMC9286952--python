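"""Deep belief network: stacked Bernoulli RBMs plus a softmax output layer.

A restricted Boltzmann machine (RBM) is a bipartite energy-based model over
binary visible units v and hidden units h,

    E(v, h) = - v' W h - a' v - b' h,

whose conditionals factorize: P(h_j=1 | v) = sigmoid(sum_i W_ij v_i + b_j)
and symmetrically for the visible units. Each RBM is trained by one-step
contrastive divergence (CD-1): the positive statistics come from the data
and its hidden conditionals, the negative statistics from a single Gibbs
reconstruction, and parameters move by the learning rate times the
batch-mean difference.

The DBN trains greedily layer by layer (each layer's input is the previous
layer's hidden activation probabilities), then a 2-unit softmax output layer
is attached and the whole stack is fine-tuned by backpropagation of the
cross-entropy loss. Continuous inputs are min-max scaled to [0, 1] and
treated as visible-unit probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RbmParams",
    "DbnConfig",
    "DbnModel",
    "save_model",
    "load_model",
    "rbm_energy",
    "hidden_given_visible",
    "visible_given_hidden",
    "cd1_update",
    "pretrain",
    "finetune_and_predict",
    "train_dbn",
    "predict",
    "predict_proba",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RbmParams:
    """Weights and biases of one RBM (visible m x hidden n)."""

    weights: np.ndarray       # (m, n)
    visible_bias: np.ndarray  # (m,)
    hidden_bias: np.ndarray   # (n,)

    @classmethod
    def initialize(cls, m: int, n: int, rng: np.random.Generator, scale: float = 0.1):
        """Zero biases, small Gaussian weights ~ N(0, 0.01), i.e. sd 0.1."""
        return cls(rng.normal(0.0, scale, size=(m, n)), np.zeros(m), np.zeros(n))

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


@dataclass
class DbnConfig:
    """Hyperparameters of the stack.

    ``learning_rate`` (alpha) and ``batch_size`` (beta) are shared by the
    CD pretraining and the backprop fine-tuning; they are the two
    hyperparameters exposed to the metaheuristic search.
    """

    layer_sizes: tuple[int, ...] = (64, 32)
    learning_rate: float = 0.1
    batch_size: int = 16
    pretrain_epochs: int = 50
    finetune_epochs: int = 100
    cd_steps: int = 1
    momentum: float = 0.9
    seed: int = 0
    sample_hidden: bool = True

    def __post_init__(self):
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("hidden layer widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be at least 1")


@dataclass
class DbnModel:
    """Trained stack: RBM layers, softmax output layer, input scaling."""

    rbms: list[RbmParams]
    output_weights: np.ndarray  # (last_hidden, n_classes)
    output_bias: np.ndarray     # (n_classes,)
    feature_min: np.ndarray
    feature_max: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return np.clip((np.asarray(X, dtype=float) - self.feature_min) / span, 0.0, 1.0)


def rbm_energy(params: RbmParams, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = -v'Wh - a'v - b'h for a single configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError(
            f"expected v of shape ({params.n_visible},) and h of shape ({params.n_hidden},)"
        )
    return float(-v @ params.weights @ h - params.visible_bias @ v - params.hidden_bias @ h)


def hidden_given_visible(params: RbmParams, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) for one vector or a batch of rows."""
    return _sigmoid(np.asarray(v, dtype=float) @ params.weights + params.hidden_bias)


def visible_given_hidden(params: RbmParams, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h) for one vector or a batch of rows."""
    return _sigmoid(np.asarray(h, dtype=float) @ params.weights.T + params.visible_bias)


def cd1_update(
    params: RbmParams,
    batch: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    cd_steps: int = 1,
    sample_hidden: bool = True,
) -> RbmParams:
    """One contrastive-divergence parameter update on a batch (in place).

    The positive phase pairs the data with its hidden conditional
    probabilities; hidden states are Bernoulli-sampled only to drive the
    reconstruction (the standard variance-reduced estimator; disable with
    ``sample_hidden=False``). Gradients are batch means scaled by ``alpha``.
    """
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    if v0.shape[0] == 0:
        raise ValueError("empty batch")
    B = v0.shape[0]
    h0 = hidden_given_visible(params, v0)
    h_state = (rng.random(h0.shape) < h0).astype(float) if sample_hidden else h0
    vk = v0
    for _ in range(cd_steps):
        vk = visible_given_hidden(params, h_state)
        hk = hidden_given_visible(params, vk)
        h_state = (rng.random(hk.shape) < hk).astype(float) if sample_hidden else hk
    params.weights += alpha * (v0.T @ h0 - vk.T @ hk) / B
    params.visible_bias += alpha * (v0 - vk).mean(axis=0)
    params.hidden_bias += alpha * (h0 - hk).mean(axis=0)
    return params


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def pretrain(
    config: DbnConfig, data: np.ndarray, rng: np.random.Generator | None = None
) -> list[RbmParams]:
    """Greedy layer-wise CD training on data already scaled to [0, 1].

    Layer k is trained on the hidden activation probabilities of layer k-1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(data, dtype=float)
    stack: list[RbmParams] = []
    layer_input = X
    for width in config.layer_sizes:
        params = RbmParams.initialize(layer_input.shape[1], width, rng)
        for _ in range(config.pretrain_epochs):
            for idx in _minibatches(layer_input.shape[0], config.batch_size, rng):
                cd1_update(params, layer_input[idx], config.learning_rate, rng,
                           config.cd_steps, config.sample_hidden)
        stack.append(params)
        layer_input = hidden_given_visible(params, layer_input)
    return stack


def _forward(model: DbnModel, X01: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    acts = [X01]
    for rbm in model.rbms:
        acts.append(hidden_given_visible(rbm, acts[-1]))
    logits = acts[-1] @ model.output_weights + model.output_bias
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return acts, p


def _finetune(
    model: DbnModel,
    X01: np.ndarray,
    y: np.ndarray,
    config: DbnConfig,
    rng: np.random.Generator,
) -> DbnModel:
    """Backprop the softmax cross-entropy through every layer.

    Minibatch SGD with classical momentum (velocity accumulation), the
    standard recipe for fine-tuning CD-pretrained stacks; the CD updates
    themselves stay plain.
    """
    n_classes = model.output_weights.shape[1]
    Y = np.eye(n_classes)[y]
    mom = config.momentum
    velocity: dict[str, np.ndarray | float] = {}

    def step(key: str, param: np.ndarray, grad: np.ndarray) -> None:
        v = mom * velocity.get(key, 0.0) - config.learning_rate * grad
        velocity[key] = v
        param += v

    for _ in range(config.finetune_epochs):
        for idx in _minibatches(X01.shape[0], config.batch_size, rng):
            acts, p = _forward(model, X01[idx])
            delta = (p - Y[idx]) / len(idx)
            back = delta @ model.output_weights.T
            step("ow", model.output_weights, acts[-1].T @ delta)
            step("ob", model.output_bias, delta.sum(axis=0))
            for k in range(len(model.rbms) - 1, -1, -1):
                h = acts[k + 1]
                delta_k = back * h * (1.0 - h)
                if k > 0:
                    back = delta_k @ model.rbms[k].weights.T
                step(f"w{k}", model.rbms[k].weights, acts[k].T @ delta_k)
                step(f"b{k}", model.rbms[k].hidden_bias, delta_k.sum(axis=0))
    return model


def train_dbn(X: np.ndarray, y: np.ndarray, config: DbnConfig) -> DbnModel:
    """Full pipeline: scale to [0, 1], pretrain the stack, fine-tune with labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    X01 = (X - fmin) / span
    stack = pretrain(config, X01, rng)
    model = DbnModel(
        rbms=stack,
        output_weights=rng.normal(0.0, 0.1, size=(config.layer_sizes[-1], 2)),
        output_bias=np.zeros(2),
        feature_min=fmin,
        feature_max=fmax,
    )
    return _finetune(model, X01, y, config, rng)


def predict_proba(model: DbnModel, X: np.ndarray) -> np.ndarray:
    _, p = _forward(model, model.scale(X))
    return p


def predict(model: DbnModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(predict_proba(model, X), axis=1)]


def save_model(model: DbnModel, path) -> None:
    """Serialize a trained model (weights, biases, scaling) to one npz archive."""
    arrays = {"n_layers": np.array(len(model.rbms)),
              "output_weights": model.output_weights,
              "output_bias": model.output_bias,
              "feature_min": model.feature_min,
              "feature_max": model.feature_max,
              "classes": model.classes}
    for k, rbm in enumerate(model.rbms):
        arrays[f"w{k}"] = rbm.weights
        arrays[f"a{k}"] = rbm.visible_bias
        arrays[f"b{k}"] = rbm.hidden_bias
    np.savez(path, **arrays)


def load_model(path) -> DbnModel:
    with np.load(path) as z:
        rbms = [RbmParams(z[f"w{k}"], z[f"a{k}"], z[f"b{k}"])
                for k in range(int(z["n_layers"]))]
        return DbnModel(rbms, z["output_weights"], z["output_bias"],
                        z["feature_min"], z["feature_max"], z["classes"])


def finetune_and_predict(
    model: DbnModel,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    config: DbnConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Fine-tune a pretrained stack on ``train`` and score it on ``test``.

    Returns the predicted test labels and the test accuracy.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X_train, y_train = train
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    _finetune(model, model.scale(X_train), np.asarray(y_train).astype(int), config, rng)
    X_test, y_test = test
    pred = predict(model, X_test)
    return pred, float(np.mean(pred == np.asarray(y_test).astype(int)))
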
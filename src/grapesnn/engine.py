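"""From-scratch dense/convolutional network training with modulated credit
assignment.

Supports three credit-assignment schemes — standard backpropagation (BP),
feedback alignment (FA, fixed random matrices replacing transposed forward
weights in the delta recursion) and direct feedback alignment (DFA, the
output error delivered directly to every hidden layer) — each optionally
combined with importance-based modulation of the error signals in either
its *local* form (each layer's own update rescaled) or its *propagating*
form (the modulation folded into the backpropagated delta, so it also
affects all upstream layers).

Conventions
-----------
* Activations are row-major batches: ``h`` has shape (batch, features),
  dense weights have shape (out, in), so ``a = h @ W.T + b``.
* A delta ``δa^l`` is the gradient of the mean cross-entropy loss with
  respect to the pre-activation of layer ``l``.
* A weight update ``δW`` is a **descent** step (the negative gradient);
  parameters are updated as ``W ← W + η·δW``.
* The output-layer delta is never modulated unless explicitly requested.
* Modulation vectors are recomputed only after a parameter update (once
  per batch) and held constant for every sample within the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    conv_map_importance,
    importance_postsynaptic,
    importance_presynaptic,
    modulation_vector,
    tile_modulation,
)

__all__ = [
    "LayerSpec",
    "GrapesConfig",
    "OptimizerState",
    "NetworkModel",
    "build_network",
    "make_feedback_matrices",
    "forward_pass",
    "backward_bp",
    "grapes_propagating_backward",
    "backward_fa",
    "backward_dfa",
    "backward",
    "refresh_modulation",
    "sgd_update_modulated",
    "optimizer_step",
    "train_epoch",
    "evaluate",
]


# ---------------------------------------------------------------------------
# activations

def _relu(a):
    return np.maximum(a, 0.0)


def _relu_prime(a):
    return (a > 0.0).astype(a.dtype)


def _tanh_prime(a):
    return 1.0 - np.tanh(a) ** 2


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))


def _sigmoid_prime(a):
    s = _sigmoid(a)
    return s * (1.0 - s)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _relu_prime),
    "tanh": (np.tanh, _tanh_prime),
    "sigmoid": (_sigmoid, _sigmoid_prime),
    "linear": (lambda a: a, lambda a: np.ones_like(a)),
}


def softmax(a: np.ndarray) -> np.ndarray:
    z = a - a.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# layers

@dataclass
class LayerSpec:
    """Declarative description of one layer of the network."""

    kind: str                      # dense | conv | batchnorm | dropout | flatten
    units: int = 0                 # dense fan-out / conv output maps
    activation: str = "linear"
    rate: float = 0.0              # dropout rate
    kernel: tuple[int, int] = (3, 3)
    padding: int = 0

    def __post_init__(self):
        if self.kind not in ("dense", "conv", "batchnorm", "dropout", "flatten"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("dense", "conv") and self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "dropout" and not (0.0 <= self.rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")


class DenseLayer:
    trainable = True
    kind = "dense"

    def __init__(self, W: np.ndarray, b: np.ndarray, activation: str):
        self.W = W          # (out, in)
        self.b = b          # (out,)
        self.activation = activation
        self.f, self.f_prime = ACTIVATIONS[activation]

    @property
    def n_pre(self) -> int:
        return self.W.shape[1]

    def importance(self) -> np.ndarray:
        return importance_postsynaptic(self.W)

    def params(self):
        return [self.W, self.b]

    def set_params(self, values):
        self.W, self.b = values


class Conv2DLayer:
    """2-D convolution, stride 1, symmetric zero padding."""

    trainable = True
    kind = "conv"

    def __init__(self, F: np.ndarray, b: np.ndarray, activation: str, padding: int = 0):
        self.F = F          # (out maps, in maps, kh, kw)
        self.b = b          # (out maps,)
        self.activation = activation
        self.padding = padding
        self.f, self.f_prime = ACTIVATIONS[activation]

    @property
    def W(self):            # alias so generic parameter code is uniform
        return self.F

    @W.setter
    def W(self, value):
        self.F = value

    def importance(self) -> np.ndarray:
        return conv_map_importance(self.F)

    def params(self):
        return [self.F, self.b]

    def set_params(self, values):
        self.F, self.b = values


class BatchNormLayer:
    """Feature-wise batch normalization; parameters are never modulated."""

    trainable = True
    kind = "batchnorm"

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def importance(self):
        return None

    def params(self):
        return [self.gamma, self.beta]

    def set_params(self, values):
        self.gamma, self.beta = values


class DropoutLayer:
    trainable = False
    kind = "dropout"

    def __init__(self, rate: float):
        self.rate = rate


class FlattenLayer:
    trainable = False
    kind = "flatten"


# ---------------------------------------------------------------------------
# model construction

class NetworkModel:
    """An ordered stack of layers ending in a softmax/cross-entropy readout."""

    def __init__(self, layers: list, input_shape: tuple):
        self.layers = layers
        self.input_shape = input_shape

    def trainable_layers(self):
        return [l for l in self.layers if l.trainable]

    def modulated_layers(self):
        """Layers that participate in importance modulation (dense/conv)."""
        return [l for l in self.layers if l.trainable and l.kind in ("dense", "conv")]

    def parameters(self):
        return [p for layer in self.trainable_layers() for p in layer.params()]

    def set_parameters(self, values):
        it = iter(values)
        for layer in self.trainable_layers():
            layer.set_params([next(it) for _ in layer.params()])

    def copy(self) -> "NetworkModel":
        import copy
        return copy.deepcopy(self)


def _init_dense(n_out: int, n_in: int, activation: str, rng: np.random.Generator):
    if activation == "relu":
        W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
    else:
        limit = np.sqrt(6.0 / (n_in + n_out))
        W = rng.uniform(-limit, limit, size=(n_out, n_in))
    return W, np.zeros(n_out)


def _init_conv(n_out: int, n_in: int, kernel, activation: str, rng: np.random.Generator):
    kh, kw = kernel
    fan_in = n_in * kh * kw
    fan_out = n_out * kh * kw
    if activation == "relu":
        F = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(n_out, n_in, kh, kw))
    else:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        F = rng.uniform(-limit, limit, size=(n_out, n_in, kh, kw))
    return F, np.zeros(n_out)


def build_network(specs: Sequence[LayerSpec], input_shape, rng: np.random.Generator) -> NetworkModel:
    """Instantiate a network from layer specs.

    ``input_shape`` is (features,) for dense input or (channels, H, W) for
    image input.  ReLU layers use He-style normal init, tanh/linear/sigmoid
    layers Glorot-style uniform init.  The final dense layer is the softmax
    readout (use activation 'linear' for it).
    """
    shape = tuple(input_shape)
    layers: list = []
    for spec in specs:
        if spec.kind == "dense":
            if len(shape) != 1:
                raise ValueError("dense layer needs flat input; add a flatten layer")
            W, b = _init_dense(spec.units, shape[0], spec.activation, rng)
            layers.append(DenseLayer(W, b, spec.activation))
            shape = (spec.units,)
        elif spec.kind == "conv":
            if len(shape) != 3:
                raise ValueError("conv layer needs (channels, H, W) input")
            c, h, w = shape
            F, b = _init_conv(spec.units, c, spec.kernel, spec.activation, rng)
            layers.append(Conv2DLayer(F, b, spec.activation, spec.padding))
            kh, kw = spec.kernel
            shape = (spec.units, h + 2 * spec.padding - kh + 1, w + 2 * spec.padding - kw + 1)
        elif spec.kind == "batchnorm":
            layers.append(BatchNormLayer(shape[0]))
        elif spec.kind == "dropout":
            layers.append(DropoutLayer(spec.rate))
        elif spec.kind == "flatten":
            layers.append(FlattenLayer())
            shape = (int(np.prod(shape)),)
    return NetworkModel(layers, tuple(input_shape))


def mlp(widths: Sequence[int], n_in: int, n_out: int, activation: str = "relu",
        dropout: float = 0.0, rng: Optional[np.random.Generator] = None) -> NetworkModel:
    """Convenience constructor for a fully connected classifier."""
    rng = rng if rng is not None else np.random.default_rng()
    specs: list[LayerSpec] = []
    for w in widths:
        specs.append(LayerSpec("dense", units=w, activation=activation))
        if dropout > 0.0:
            specs.append(LayerSpec("dropout", rate=dropout))
    specs.append(LayerSpec("dense", units=n_out, activation="linear"))
    return build_network(specs, (n_in,), rng)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GrapesConfig:
    """How (and whether) importance modulation is applied.

    mode: 'off', 'local' (each layer's own update rescaled) or
    'propagating' (modulation folded into the backpropagated delta).
    grouping: 'postsynaptic' (incoming weights) or 'presynaptic'
    (outgoing weights of the downstream matrix; mandatory for DFA).

    With DFA the error reaches each hidden layer directly, so there is no
    upstream path for the modulation to ride on and 'propagating' behaves
    layer-locally by default.  ``dfa_carry`` enables an experimental
    variant that carries the modulated delta upstream through the forward
    weight transposes — note this reintroduces the weight transport that
    DFA exists to avoid.
    """

    mode: str = "off"
    grouping: str = "postsynaptic"
    modulate_output: bool = False
    dfa_carry: bool = False

    def __post_init__(self):
        if self.mode not in ("off", "local", "propagating"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.grouping not in ("postsynaptic", "presynaptic"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class OptimizerState:
    """Update rule plus its accumulators.

    ``kind`` is one of sgd, momentum, nag, rmsprop, adam.  Modulated
    gradients enter the rule *before* any accumulator update: the
    modulation adjusts the error signal, not the final step.
    """

    lr: float
    kind: str = "sgd"
    momentum: float = 0.9
    rho: float = 0.9          # rmsprop decay
    beta1: float = 0.9        # adam
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    slots: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.kind not in ("sgd", "momentum", "nag", "rmsprop", "adam"):
            raise ValueError(f"unknown optimizer kind {self.kind!r}")

    def _slot(self, name: str, i: int, like: np.ndarray) -> np.ndarray:
        key = (name, i)
        if key not in self.slots:
            self.slots[key] = np.zeros_like(like)
        return self.slots[key]


# ---------------------------------------------------------------------------
# error signals / gradients containers

@dataclass
class ErrorSignals:
    """Per-layer deltas (gradients w.r.t. pre-activations) for one batch."""

    deltas: list                 # aligned with model.layers; None for non-trainable
    delta_out: np.ndarray        # δa^y (output pre-activation gradient)
    modulated: list              # bool per layer


@dataclass
class GradientSet:
    """Descent-step update proposals, aligned with ``trainable_layers()``.

    Each entry is a list matching the layer's ``params()`` (e.g. [δW, δb]).
    """

    updates: list

    def scaled(self, factor: float) -> "GradientSet":
        return GradientSet([[factor * g for g in entry] for entry in self.updates])


# ---------------------------------------------------------------------------
# forward pass

def forward_pass(model: NetworkModel, x: np.ndarray,
                 rng: Optional[np.random.Generator] = None,
                 train: bool = False) -> dict:
    """Run the network on a batch; return the cache of intermediates.

    The cache records, per layer, the pre-activation ``a`` and activation
    ``h`` (plus masks/statistics for dropout and batchnorm), the input and
    the softmax output.  Dropout masks are drawn from ``rng`` only when
    ``train`` is true.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1:] != model.input_shape:
        raise ValueError(f"input shape {x.shape[1:]} != expected {model.input_shape}")
    records = []
    h = x
    for layer in model.layers:
        rec: dict = {"input": h}
        if layer.kind == "dense":
            a = h @ layer.W.T + layer.b
            h = layer.f(a)
            rec["a"], rec["h"] = a, h
        elif layer.kind == "conv":
            a = _conv_forward(h, layer)
            h = layer.f(a)
            rec["a"], rec["h"] = a, h
        elif layer.kind == "batchnorm":
            h, stats = _batchnorm_forward(h, layer, train)
            rec.update(stats)
            rec["h"] = h
        elif layer.kind == "dropout":
            if train and layer.rate > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                mask = (rng.random(h.shape) >= layer.rate) / (1.0 - layer.rate)
            else:
                mask = np.ones_like(h)
            h = h * mask
            rec["mask"], rec["h"] = mask, h
        elif layer.kind == "flatten":
            h = h.reshape(h.shape[0], -1)
            rec["h"] = h
        records.append(rec)
    y = softmax(h)
    return {"x": x, "records": records, "logits": h, "y": y}


def _conv_forward(x: np.ndarray, layer: Conv2DLayer) -> np.ndarray:
    p = layer.padding
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    kh, kw = layer.F.shape[2:]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (batch, in, H', W', kh, kw)
    return np.einsum("bchwij,ocij->bohw", win, layer.F, optimize=True) + layer.b[None, :, None, None]


def _batchnorm_forward(h, layer: BatchNormLayer, train: bool):
    axes = tuple(i for i in range(h.ndim) if i != 1)
    if train:
        mean = h.mean(axis=axes)
        var = h.var(axis=axes)
        layer.running_mean = layer.momentum * layer.running_mean + (1 - layer.momentum) * mean
        layer.running_var = layer.momentum * layer.running_var + (1 - layer.momentum) * var
    else:
        mean, var = layer.running_mean, layer.running_var
    shape = [1] * h.ndim
    shape[1] = -1
    inv = 1.0 / np.sqrt(var + layer.eps)
    xhat = (h - mean.reshape(shape)) * inv.reshape(shape)
    out = layer.gamma.reshape(shape) * xhat + layer.beta.reshape(shape)
    return out, {"xhat": xhat, "inv": inv, "mean": mean}


# ---------------------------------------------------------------------------
# modulation schedule

def refresh_modulation(model: NetworkModel, cfg: GrapesConfig) -> list:
    """Recompute per-layer modulation vectors from the current weights.

    Called once before training starts and once after every parameter
    update; the vectors are held fixed for all samples of the next batch.
    Returns a list aligned with ``model.modulated_layers()``; entries are
    all-ones vectors when modulation is off or the layer is exempt (the
    output layer, by default).
    """
    mod_layers = model.modulated_layers()
    vectors = []
    for idx, layer in enumerate(mod_layers):
        is_output = idx == len(mod_layers) - 1
        width = layer.W.shape[0]
        if cfg.mode == "off" or (is_output and not cfg.modulate_output):
            vectors.append(np.ones(width))
            continue
        if cfg.grouping == "postsynaptic":
            imp = layer.importance()
        else:
            nxt = mod_layers[idx + 1] if not is_output else None
            if nxt is None or nxt.kind != "dense":
                vectors.append(np.ones(width))
                continue
            imp = importance_presynaptic(nxt.W)
        vectors.append(modulation_vector(imp))
    return vectors


# ---------------------------------------------------------------------------
# backward passes

def _output_delta(cache: dict, targets: np.ndarray) -> np.ndarray:
    y = cache["y"]
    n, n_classes = y.shape
    targets = np.asarray(targets)
    if targets.min() < 0 or targets.max() >= n_classes:
        raise ValueError("targets out of class range")
    onehot = np.zeros_like(y)
    onehot[np.arange(n), targets] = 1.0
    return (y - onehot) / n


def backward(model: NetworkModel, cache: dict, targets: np.ndarray,
             cfg: Optional[GrapesConfig] = None,
             modvectors: Optional[list] = None,
             scheme: str = "bp",
             feedback: Optional[list] = None) -> tuple[ErrorSignals, GradientSet]:
    """Unified backward pass for BP / FA / DFA with optional modulation.

    For 'propagating' mode each hidden delta is multiplied per postsynaptic
    node by its modulation factor immediately after it is formed, so the
    adjustment is carried into every upstream layer.  For 'local' mode only
    the layer's own update is rescaled.  The output delta is left
    unmodulated unless ``cfg.modulate_output`` is set (then its update is
    rescaled in local style).
    """
    cfg = cfg or GrapesConfig()
    if scheme == "dfa" and cfg.mode != "off" and cfg.grouping == "postsynaptic":
        raise ValueError("DFA requires presynaptic grouping of the importance")
    mod_layers = model.modulated_layers()
    if cfg.mode != "off":
        if modvectors is None:
            raise ValueError("modulation vectors required when mode != 'off'")
        if len(modvectors) != len(mod_layers):
            raise ValueError("modulation vectors misaligned with layers")
    mod_of = {id(l): (modvectors[i] if modvectors is not None else None)
              for i, l in enumerate(mod_layers)}
    n_mod = len(mod_layers)
    if scheme in ("fa", "dfa"):
        if feedback is None or len(feedback) != n_mod - 1:
            raise ValueError("need one feedback matrix per hidden layer")

    delta_out = _output_delta(cache, targets)
    records = cache["records"]
    deltas: list = [None] * len(model.layers)
    modulated: list = [False] * len(model.layers)
    grads_by_layer: dict = {}
    # mod index (0-based from the input side) of each dense/conv layer
    mod_idx = {id(l): i for i, l in enumerate(mod_layers)}

    # walk layers deepest-first, carrying the gradient w.r.t. each layer output
    d_out = None
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        rec = records[li]
        if layer.kind in ("dense", "conv"):
            k = mod_idx[id(layer)]
            is_output = k == n_mod - 1
            if is_output:
                delta = delta_out
            elif scheme == "dfa" and d_out is None:
                delta = (delta_out @ feedback[k].T) * layer.f_prime(rec["a"])
            else:
                delta = d_out * layer.f_prime(rec["a"])
            m = mod_of[id(layer)]
            exempt = is_output and not cfg.modulate_output
            if cfg.mode == "propagating" and m is not None and not exempt:
                delta = _apply_node_factors(delta, m)
                modulated[li] = True
            deltas[li] = delta
            grads_by_layer[li] = _layer_gradients(layer, rec, delta)
            if cfg.mode == "local" and m is not None and not exempt:
                grads_by_layer[li] = _modulate_gradients(layer, grads_by_layer[li], m)
                modulated[li] = True
            # carry the gradient to the upstream layer's output
            if scheme == "dfa":
                # every hidden delta comes straight from the output unless
                # the experimental weight-transport carry is enabled
                d_out = _input_gradient(layer, rec, delta) \
                    if (cfg.mode == "propagating" and cfg.dfa_carry
                        and not is_output) else None
            elif scheme == "fa":
                # the fixed matrix of the upstream hidden layer replaces W^T
                d_out = delta @ feedback[k - 1].T if k >= 1 else None
            else:
                d_out = _input_gradient(layer, rec, delta)
        elif layer.kind == "batchnorm":
            if d_out is None:   # DFA: delta re-enters at the next dense layer
                grads_by_layer[li] = [np.zeros_like(layer.gamma),
                                      np.zeros_like(layer.beta)]
            else:
                d_out, g = _batchnorm_backward(d_out, layer, rec)
                grads_by_layer[li] = g
        elif layer.kind == "dropout":
            if d_out is not None:
                d_out = d_out * rec["mask"]
        elif layer.kind == "flatten":
            if d_out is not None:
                d_out = d_out.reshape(rec["input"].shape)

    updates = [grads_by_layer[li] for li, layer in enumerate(model.layers) if layer.trainable]
    errors = ErrorSignals(deltas=deltas, delta_out=delta_out, modulated=modulated)
    return errors, GradientSet(updates)


def _apply_node_factors(delta: np.ndarray, m: np.ndarray) -> np.ndarray:
    if delta.ndim == 2:        # dense: (batch, nodes)
        return delta * m[None, :]
    return delta * m[None, :, None, None]  # conv: (batch, maps, H, W)


def _layer_gradients(layer, rec, delta):
    """Descent-step gradients [δW, δb] for a dense or conv layer."""
    h_prev = rec["input"]
    if layer.kind == "dense":
        dW = -(delta.T @ h_prev)
        db = -delta.sum(axis=0)
        return [dW, db]
    # conv
    p = layer.padding
    x = h_prev
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    kh, kw = layer.F.shape[2:]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    dF = -np.einsum("bohw,bchwij->ocij", delta, win, optimize=True)
    db = -delta.sum(axis=(0, 2, 3))
    return [dF, db]


def _modulate_gradients(layer, grads, m):
    if layer.kind == "dense":
        M = tile_modulation(m, layer.n_pre)
        return [grads[0] * M, grads[1] * m]
    # conv: one factor broadcast over each output map's whole filter update
    return [grads[0] * m[:, None, None, None], grads[1] * m]


def _input_gradient(layer, rec, delta):
    """Gradient w.r.t. the layer input (the downstream term of the recursion)."""
    if layer.kind == "dense":
        return delta @ layer.W
    # conv: full correlation with the flipped filters
    kh, kw = layer.F.shape[2:]
    p = layer.padding
    pad = (kh - 1 - p, kw - 1 - p)
    d = np.pad(delta, ((0, 0), (0, 0), (pad[0], pad[0]), (pad[1], pad[1])))
    win = np.lib.stride_tricks.sliding_window_view(d, (kh, kw), axis=(2, 3))
    F_flip = layer.F[:, :, ::-1, ::-1]
    return np.einsum("bohwij,ocij->bchw", win, F_flip, optimize=True)


def _batchnorm_backward(d_out, layer: BatchNormLayer, rec):
    xhat, inv = rec["xhat"], rec["inv"]
    axes = tuple(i for i in range(d_out.ndim) if i != 1)
    n = d_out.size // d_out.shape[1]
    shape = [1] * d_out.ndim
    shape[1] = -1
    dgamma = (d_out * xhat).sum(axis=axes)
    dbeta = d_out.sum(axis=axes)
    g = layer.gamma.reshape(shape)
    dxhat = d_out * g
    dx = (inv.reshape(shape) / n) * (
        n * dxhat
        - dxhat.sum(axis=axes).reshape(shape)
        - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
    )
    return dx, [-dgamma, -dbeta]


# --- public wrappers -------------------------------------------------------

def backward_bp(model, cache, targets, cfg: Optional[GrapesConfig] = None,
                modvectors=None):
    """Backpropagation; optional local modulation via ``cfg``."""
    cfg = cfg or GrapesConfig()
    if cfg.mode == "propagating":
        raise ValueError("use grapes_propagating_backward for propagating mode")
    return backward(model, cache, targets, cfg, modvectors, scheme="bp")


def grapes_propagating_backward(model, cache, targets, cfg: GrapesConfig,
                                modvectors):
    """Propagating modulation: each hidden delta is rescaled per node before
    it is carried upstream, so the adjustment compounds through the layers."""
    if cfg.mode != "propagating":
        raise ValueError("config mode must be 'propagating'")
    return backward(model, cache, targets, cfg, modvectors, scheme="bp")


def backward_fa(model, cache, targets, feedback, cfg: Optional[GrapesConfig] = None,
                modvectors=None):
    """Feedback alignment: fixed random matrices replace the transposed
    forward weights in the delta recursion; modulation applies as in BP."""
    return backward(model, cache, targets, cfg, modvectors, scheme="fa",
                    feedback=feedback)


def backward_dfa(model, cache, targets, feedback, cfg: Optional[GrapesConfig] = None,
                 modvectors=None):
    """Direct feedback alignment: the output delta reaches each hidden layer
    through its own fixed random matrix; modulation uses presynaptic
    grouping of the downstream weights and stays layer-local."""
    return backward(model, cache, targets, cfg, modvectors, scheme="dfa",
                    feedback=feedback)


def make_feedback_matrices(model: NetworkModel, scheme: str,
                           rng: np.random.Generator,
                           scale: float = 0.05) -> list:
    """Fixed random feedback matrices, one per hidden dense layer.

    FA: B^l shaped like the transposed downstream weight matrix.
    DFA: B^l maps the output delta straight to layer l's width.
    Frozen after creation — the caller must never update them.
    """
    dense = [l for l in model.modulated_layers()]
    if any(l.kind != "dense" for l in dense):
        raise ValueError("feedback alignment supported for dense networks only")
    hidden, out = dense[:-1], dense[-1]
    mats = []
    for i, layer in enumerate(hidden):
        if scheme == "fa":
            nxt = dense[i + 1]
            shape = (nxt.W.shape[1], nxt.W.shape[0])   # like W^{l+1,T}
        elif scheme == "dfa":
            shape = (layer.W.shape[0], out.W.shape[0])
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        mats.append(rng.normal(0.0, scale, size=shape))
    return mats


# ---------------------------------------------------------------------------
# parameter updates

def sgd_update_modulated(model: NetworkModel, grads: GradientSet,
                         opt: OptimizerState) -> None:
    """Plain SGD on (possibly modulated) descent steps: W ← W + η·δW."""
    if opt.lr <= 0:
        raise ValueError("learning rate must be positive")
    for layer, entry in zip(model.trainable_layers(), grads.updates):
        new = [p + opt.lr * g for p, g in zip(layer.params(), entry)]
        layer.set_params(new)
    opt.t += 1


def optimizer_step(model: NetworkModel, grads: GradientSet,
                   opt: OptimizerState) -> None:
    """Apply the configured update rule; accumulators advance once per call.

    Modulation enters through ``grads`` before the accumulators, so e.g.
    Adam's moments track the modulated error signal.
    """
    if opt.kind == "sgd":
        sgd_update_modulated(model, grads, opt)
        return
    opt.t += 1
    i = 0
    for layer, entry in zip(model.trainable_layers(), grads.updates):
        new_params = []
        for p, g in zip(layer.params(), entry):
            if opt.kind == "momentum":
                v = opt._slot("v", i, p)
                v *= opt.momentum
                v += g
                step = opt.lr * v
            elif opt.kind == "nag":
                v = opt._slot("v", i, p)
                v *= opt.momentum
                v += g
                step = opt.lr * (g + opt.momentum * v)
            elif opt.kind == "rmsprop":
                s = opt._slot("s", i, p)
                s *= opt.rho
                s += (1 - opt.rho) * g * g
                step = opt.lr * g / (np.sqrt(s) + opt.eps)
            elif opt.kind == "adam":
                m = opt._slot("m", i, p)
                v = opt._slot("v", i, p)
                m *= opt.beta1
                m += (1 - opt.beta1) * g
                v *= opt.beta2
                v += (1 - opt.beta2) * g * g
                mhat = m / (1 - opt.beta1 ** opt.t)
                vhat = v / (1 - opt.beta2 ** opt.t)
                step = opt.lr * mhat / (np.sqrt(vhat) + opt.eps)
            new_params.append(p + step)
            i += 1
        layer.set_params(new_params)


# ---------------------------------------------------------------------------
# training loop

def cross_entropy(y: np.ndarray, targets: np.ndarray) -> float:
    n = y.shape[0]
    p = np.clip(y[np.arange(n), targets], 1e-12, None)
    return float(-np.log(p).mean())


def evaluate(model: NetworkModel, X: np.ndarray, y: np.ndarray,
             batch_size: int = 256) -> float:
    """Test accuracy in percent."""
    correct = 0
    for start in range(0, len(X), batch_size):
        out = forward_pass(model, X[start:start + batch_size])["y"]
        correct += int((out.argmax(axis=1) == y[start:start + batch_size]).sum())
    return 100.0 * correct / len(X)


def _run_backward(model, cache, targets, scheme, cfg, modvectors, feedback):
    if scheme == "bp":
        if cfg.mode == "propagating":
            return grapes_propagating_backward(model, cache, targets, cfg, modvectors)
        return backward_bp(model, cache, targets, cfg, modvectors)
    if scheme == "fa":
        return backward_fa(model, cache, targets, feedback, cfg, modvectors)
    if scheme == "dfa":
        return backward_dfa(model, cache, targets, feedback, cfg, modvectors)
    raise ValueError(f"unknown credit-assignment scheme {scheme!r}")


def train_epoch(model: NetworkModel, X: np.ndarray, y: np.ndarray,
                opt: OptimizerState, cfg: GrapesConfig,
                rng: np.random.Generator,
                batch_size: int = 64,
                scheme: str = "bp",
                feedback: Optional[list] = None,
                test: Optional[tuple] = None,
                modvectors: Optional[list] = None) -> dict:
    """One full pass over the training set with per-batch modulation refresh.

    Returns an epoch log with the mean training loss, test accuracy (if a
    test split is given) and the per-layer modulation mean/std observables.
    The modulation vectors are refreshed after every parameter update and
    stay constant within a batch; pass the previous epoch's vectors to
    continue a schedule, else they are computed from the current weights.
    """
    if len(X) == 0:
        raise ValueError("empty dataset")
    if modvectors is None:
        modvectors = refresh_modulation(model, cfg)
    order = rng.permutation(len(X))
    losses = []
    for start in range(0, len(X), batch_size):
        idx = order[start:start + batch_size]
        cache = forward_pass(model, X[idx], rng=rng, train=True)
        losses.append(cross_entropy(cache["y"], y[idx]))
        _, grads = _run_backward(model, cache, y[idx], scheme, cfg, modvectors, feedback)
        optimizer_step(model, grads, opt)
        modvectors = refresh_modulation(model, cfg)
    log = {
        "train_loss": float(np.mean(losses)),
        "modulation_mean": [float(v.mean()) for v in modvectors],
        "modulation_std": [float(v.std()) for v in modvectors],
        "modvectors": modvectors,
    }
    if test is not None:
        log["test_accuracy"] = evaluate(model, *test)
    return log
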
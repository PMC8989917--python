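"""Spiking neural units (SNU/sSNU): rate coding, unrolled dynamics, BPTT.

An SNU abstracts a leaky integrate-and-fire neuron into a recurrent unit:

    s_t = g( W x_t + decay * retained(s_{t-1}, y_{t-1}) )
    y_t = h( s_t + b )

with state nonlinearity g = ReLU, output nonlinearity h either a step
function (SNU: binary spikes; trained with a straight-through surrogate
gradient) or a sigmoid (sSNU: graded outputs), and an output bias b that
plays the role of a negative firing threshold.  ``retained`` implements
the reset after a spike: multiplicative, s*(1-y), or soft, a subtraction
of the threshold magnitude floored at zero — the soft variant smooths
training.  Images enter as rate-coded spike trains: each pixel spikes
independently per step with probability equal to its intensity.

Classification readout: a linear layer maps the top SNU layer's output at
every step; the loss is softmax cross-entropy on the time-averaged readout
pre-activation, so a single-step (N_s=1), decay-free sigmoid network
reduces exactly to an ordinary feedforward classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .core import importance_postsynaptic, modulation_vector

__all__ = [
    "SNUConfig",
    "SNULayer",
    "SNUNetwork",
    "rate_encode",
    "snu_step",
    "snu_forward",
    "snu_backward",
    "train_snu_grapes",
    "evaluate_snu",
]


@dataclass
class SNUConfig:
    """Unit dynamics and presentation settings.

    decay: membrane retention factor l(tau), in [0, 1).
    output: 'step' (SNU, binary spikes) or 'sigmoid' (sSNU).
    reset: 'soft' (subtract threshold magnitude, floored at 0) or
           'multiplicative' (scale by 1 - y).
    n_steps: presentation steps N_s (e.g. 20 during training, 300 at test).
    surrogate_width: window of the straight-through step derivative.
    """

    decay: float = 0.8
    output: str = "sigmoid"
    reset: str = "soft"
    n_steps: int = 20
    n_steps_test: int = 300
    surrogate_width: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.decay < 1.0):
            raise ValueError("decay must be in [0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.output not in ("step", "sigmoid"):
            raise ValueError(f"unknown output nonlinearity {self.output!r}")
        if self.reset not in ("soft", "multiplicative"):
            raise ValueError(f"unknown reset kind {self.reset!r}")


def rate_encode(images: np.ndarray, n_steps: int,
                rng: np.random.Generator) -> np.ndarray:
    """Rate-code intensities in [0,1] into a binary (steps, batch, pixels)
    spike train: each pixel fires independently per step with probability
    equal to its intensity."""
    x = np.asarray(images, dtype=float).reshape(len(images), -1)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("intensities must lie in [0, 1]")
    return (rng.random((n_steps,) + x.shape) < x[None]).astype(float)


class SNULayer:
    trainable = True
    kind = "snu"

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = W   # (out, in)
        self.b = b   # (out,), acts as negative threshold

    def importance(self) -> np.ndarray:
        return importance_postsynaptic(self.W)

    def params(self):
        return [self.W, self.b]

    def set_params(self, values):
        self.W, self.b = values


class SNUNetwork:
    """SNU/sSNU hidden layers plus a linear softmax readout."""

    def __init__(self, widths, n_in: int, n_out: int, cfg: SNUConfig,
                 rng: np.random.Generator, threshold: float = 1.0):
        self.cfg = cfg
        self.hidden: list[SNULayer] = []
        fan = n_in
        for w in widths:
            W = rng.normal(0.0, np.sqrt(2.0 / fan), size=(w, fan))
            b = np.full(w, -threshold)
            self.hidden.append(SNULayer(W, b))
            fan = w
        limit = np.sqrt(6.0 / (fan + n_out))
        self.readout_W = rng.uniform(-limit, limit, size=(n_out, fan))
        self.readout_b = np.zeros(n_out)

    # parameter API compatible with engine.optimizer_step
    class _Readout:
        trainable = True
        kind = "dense"

        def __init__(self, net):
            self.net = net

        def params(self):
            return [self.net.readout_W, self.net.readout_b]

        def set_params(self, values):
            self.net.readout_W, self.net.readout_b = values

    def trainable_layers(self):
        return [*self.hidden, SNUNetwork._Readout(self)]

    def copy(self):
        import copy
        return copy.deepcopy(self)


def _output_fn(cfg: SNUConfig):
    if cfg.output == "sigmoid":
        def h(z):
            return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

        def h_prime(z):
            s = h(z)
            return s * (1.0 - s)
    else:
        def h(z):
            return (z > 0.0).astype(float)

        def h_prime(z):
            return (np.abs(z) < cfg.surrogate_width / 2.0).astype(float)
    return h, h_prime


def snu_step(state: tuple, x_t: np.ndarray, layer: SNULayer,
             cfg: SNUConfig) -> tuple:
    """One step of the unit recursion; ``state`` is (s, y), zeros at t=0.

    Returns the new (s, y).  The reset acts on the *retained* membrane
    before the decay gate: multiplicative scales by (1 - y), soft
    subtracts the threshold magnitude |b| and floors at zero.
    """
    s_prev, y_prev = state
    if cfg.reset == "multiplicative":
        retained = s_prev * (1.0 - y_prev)
    else:
        retained = np.maximum(s_prev - y_prev * np.abs(layer.b), 0.0)
    u = x_t @ layer.W.T + cfg.decay * retained
    s = np.maximum(u, 0.0)               # g = ReLU
    h, _ = _output_fn(cfg)
    y = h(s + layer.b)
    return s, y


def snu_forward(model: SNUNetwork, spikes: np.ndarray) -> dict:
    """Unroll the network over the spike train; cache everything BPTT needs.

    ``spikes``: (steps, batch, pixels).  Returns the cache with per-layer,
    per-step inputs, pre-states u, states s, outputs y and retained terms,
    plus the time-averaged readout pre-activation and softmax output.
    """
    cfg = model.cfg
    n_steps, batch = spikes.shape[:2]
    caches = []
    x_seq = spikes
    for layer in model.hidden:
        width = layer.W.shape[0]
        s = np.zeros((batch, width))
        y = np.zeros((batch, width))
        rec = {"x": x_seq, "u": [], "s": [], "y": [], "s_prev": [], "y_prev": []}
        outs = []
        for t in range(n_steps):
            rec["s_prev"].append(s)
            rec["y_prev"].append(y)
            if cfg.reset == "multiplicative":
                retained = s * (1.0 - y)
            else:
                retained = np.maximum(s - y * np.abs(layer.b), 0.0)
            u = x_seq[t] @ layer.W.T + cfg.decay * retained
            s = np.maximum(u, 0.0)
            h, _ = _output_fn(cfg)
            y = h(s + layer.b)
            rec["u"].append(u)
            rec["s"].append(s)
            rec["y"].append(y)
            outs.append(y)
        caches.append(rec)
        x_seq = np.stack(outs)
    a_mean = x_seq.mean(axis=0) @ model.readout_W.T + model.readout_b
    return {"layer_caches": caches, "top": x_seq,
            "a_mean": a_mean, "y": engine.softmax(a_mean),
            "n_steps": n_steps}


def snu_backward(model: SNUNetwork, cache: dict, targets: np.ndarray,
                 cfg_grapes: engine.GrapesConfig | None = None,
                 modvectors: list | None = None) -> engine.GradientSet:
    """Backpropagation through time; returns descent-step updates.

    The error signal of each hidden layer (the per-step gradient at its
    pre-state) is rescaled per node by its modulation factor when
    modulation is on; the readout is never modulated.  In 'propagating'
    mode the rescaled signal is also what flows to the upstream layer; in
    'local' mode only the layer's own accumulated update is rescaled.
    """
    cfg = model.cfg
    grapes = cfg_grapes or engine.GrapesConfig()
    n_steps = cache["n_steps"]
    batch, n_out = cache["y"].shape
    onehot = np.zeros_like(cache["y"])
    onehot[np.arange(batch), np.asarray(targets)] = 1.0
    delta_out = (cache["y"] - onehot) / batch

    top = cache["top"]                       # (steps, batch, width)
    dWy = delta_out.T @ top.mean(axis=0)
    dby = delta_out.sum(axis=0)
    # gradient reaching the top layer's outputs, identical at every step
    dy_ext_top = (delta_out @ model.readout_W) / n_steps
    _, h_prime = _output_fn(cfg)

    updates_rev = [[-dWy, -dby]]
    dy_ext_seq = np.broadcast_to(dy_ext_top, (n_steps,) + dy_ext_top.shape)
    for li in range(len(model.hidden) - 1, -1, -1):
        layer = model.hidden[li]
        rec = cache["layer_caches"][li]
        theta = np.abs(layer.b)
        dW = np.zeros_like(layer.W)
        db = np.zeros_like(layer.b)
        dx_seq = np.zeros_like(rec["x"])
        du_next = None                       # du at step t+1
        for t in range(n_steps - 1, -1, -1):
            s, y, u = rec["s"][t], rec["y"][t], rec["u"][t]
            s_prev, y_prev = rec["s_prev"][t], rec["y_prev"][t]
            dy = dy_ext_seq[t].copy()
            dr = None
            if du_next is not None:
                dr = cfg.decay * du_next     # r_t feeds u_{t+1}
                if cfg.reset == "multiplicative":
                    dy += dr * (-s)
                else:
                    gate = (s - y * theta > 0).astype(float)
                    dy += dr * (-theta) * gate
            z = s + layer.b
            dz = dy * h_prime(z)
            db += dz.sum(axis=0)
            ds = dz.copy()
            if dr is not None:
                if cfg.reset == "multiplicative":
                    ds += dr * (1.0 - y)
                else:
                    ds += dr * gate
                    # theta = |b| also appears inside the soft reset
                    db += (dr * (-_soft_reset_db_term(y, layer.b, gate))).sum(axis=0)
            du = ds * (u > 0.0)
            if grapes.mode != "off" and modvectors is not None:
                m = modvectors[li]
                if grapes.mode == "propagating":
                    du = du * m[None, :]
            dW += du.T @ rec["x"][t]
            dx_seq[t] = du @ layer.W
            du_next = du
        if grapes.mode == "local" and modvectors is not None:
            m = modvectors[li]
            dW = dW * m[:, None]
            db = db * m
        updates_rev.append([-dW, -db])
        dy_ext_seq = dx_seq                  # feeds the layer below
    return engine.GradientSet(list(reversed(updates_rev)))


def _soft_reset_db_term(y, b, gate):
    """d(retained)/db contribution of the soft reset: theta = |b| depends
    on b, so the subtraction y*|b| contributes y*sign(b) inside the gate."""
    return y * np.sign(b) * gate


def snu_modulation(model: SNUNetwork, cfg: engine.GrapesConfig) -> list:
    """Per-hidden-layer modulation vectors from each input weight matrix."""
    out = []
    for layer in model.hidden:
        if cfg.mode == "off":
            out.append(np.ones(layer.W.shape[0]))
        else:
            out.append(modulation_vector(layer.importance()))
    return out


def evaluate_snu(model: SNUNetwork, images, labels,
                 rng: np.random.Generator,
                 n_steps: int | None = None,
                 batch_size: int = 256) -> float:
    """Test accuracy (percent) with freshly rate-coded inputs."""
    n_steps = n_steps if n_steps is not None else model.cfg.n_steps_test
    labels = np.asarray(labels)
    correct = 0
    for start in range(0, len(images), batch_size):
        chunk = images[start:start + batch_size]
        spikes = rate_encode(chunk, n_steps, rng)
        y = snu_forward(model, spikes)["y"]
        correct += int((y.argmax(axis=1) == labels[start:start + batch_size]).sum())
    return 100.0 * correct / len(images)


def train_snu_grapes(model: SNUNetwork, train_images, train_labels,
                     opt: engine.OptimizerState,
                     cfg_grapes: engine.GrapesConfig,
                     rng: np.random.Generator,
                     epochs: int = 1, batch_size: int = 64,
                     test: tuple | None = None,
                     test_steps: int | None = None) -> dict:
    """BPTT training over rate-coded presentations, modulation per batch.

    Modulation vectors come from each layer's input weight matrix and are
    refreshed only after each parameter update.  Returns per-epoch losses
    and (if a test split is given) test accuracies in percent.
    """
    X = np.asarray(train_images, dtype=float).reshape(len(train_images), -1)
    y = np.asarray(train_labels)
    losses, accs = [], []
    modvectors = snu_modulation(model, cfg_grapes)
    for _ in range(epochs):
        order = rng.permutation(len(X))
        batch_losses = []
        for start in range(0, len(X), batch_size):
            idx = order[start:start + batch_size]
            spikes = rate_encode(X[idx], model.cfg.n_steps, rng)
            cache = snu_forward(model, spikes)
            batch_losses.append(engine.cross_entropy(cache["y"], y[idx]))
            grads = snu_backward(model, cache, y[idx], cfg_grapes, modvectors)
            engine.optimizer_step(model, grads, opt)
            modvectors = snu_modulation(model, cfg_grapes)
        losses.append(float(np.mean(batch_losses)))
        if test is not None:
            accs.append(evaluate_snu(model, test[0], test[1], rng,
                                     n_steps=test_steps))
    return {"train_loss": losses, "test_accuracy": accs}
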
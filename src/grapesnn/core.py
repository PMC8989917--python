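"""Node importance and modulation factors.

The central idea: a node's *importance* is the total absolute synaptic
strength grouped per node — either the sum of absolute incoming weights
(postsynaptic grouping) or of absolute outgoing weights of the next layer
(presynaptic grouping, used with direct feedback alignment).  Normalizing
the importance vector of a layer by its maximum, doubling it and
lower-bounding at 1 gives a per-node *modulation factor* in [1, 2] that
rescales the error signal (and hence the weight update) of that node.
Importance depends only on the weights, never on the current input, so it
is a network-driven (as opposed to input-driven) measure of responsibility.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "importance_postsynaptic",
    "importance_presynaptic",
    "modulation_vector",
    "tile_modulation",
    "modulate_update",
    "conv_map_importance",
]


def _as_validated_array(values, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def importance_postsynaptic(W) -> np.ndarray:
    """Importance of each postsynaptic node: sum of absolute incoming weights.

    ``W`` is a weight matrix indexed [postsynaptic, presynaptic]; the result
    has one non-negative entry per row.
    """
    W = _as_validated_array(W, 2, "weight matrix")
    return np.abs(W).sum(axis=1)


def importance_presynaptic(W_next) -> np.ndarray:
    """Importance of each presynaptic node of the *next* layer's matrix.

    For node n of layer l the importance is the sum of the absolute strength
    of all layer-(l+1) weights outgoing from n, i.e. a column sum of
    ``|W_next|``.  This grouping is the one compatible with direct feedback
    alignment, where the error arrives with the layer's own dimensionality.
    """
    W_next = _as_validated_array(W_next, 2, "weight matrix")
    return np.abs(W_next).sum(axis=0)


def conv_map_importance(F) -> np.ndarray:
    """Importance of each output feature map of a convolutional filter bank.

    ``F`` is indexed [output map, input map, kernel row, kernel col]; filters
    are grouped by the postsynaptic (output) map, so the result has one
    entry per output map.
    """
    F = _as_validated_array(F, 4, "filter bank")
    return np.abs(F).sum(axis=(1, 2, 3))


def modulation_vector(importance) -> np.ndarray:
    """Per-node modulation factors in [1, 2] from an importance vector.

    The importance vector is normalized by its maximum, multiplied by 2 and
    lower-bounded by 1, so the most important node receives exactly 2 and no
    node is damped below 1.  An all-zero importance vector (a degenerate
    layer carrying no responsibility signal) maps to all ones, i.e. the
    modulation is a no-op.
    """
    i = np.asarray(importance, dtype=float)
    if i.ndim != 1 or i.size == 0:
        raise ValueError("importance must be a non-empty 1-D vector")
    if not np.all(np.isfinite(i)):
        raise ValueError("importance contains non-finite entries")
    if np.any(i < 0):
        raise ValueError("importance entries must be non-negative")
    top = i.max()
    if top == 0.0:
        return np.ones_like(i)
    return np.maximum(2.0 * i / top, 1.0)


def tile_modulation(m, n_pre: int) -> np.ndarray:
    """Tile a modulation vector into a matrix with one constant row per node.

    The result has the shape of the weight matrix it modulates: entry
    [n, pre] equals m[n] for every presynaptic index, since all weights
    converging on the same postsynaptic node share one factor.
    """
    m = _as_validated_array(m, 1, "modulation vector")
    n_pre = int(n_pre)
    if n_pre < 1:
        raise ValueError("presynaptic population size must be >= 1")
    return np.tile(m[:, None], (1, n_pre))


def modulate_update(dW, M) -> np.ndarray:
    """Hadamard product of a weight update with its modulation matrix."""
    dW = np.asarray(dW, dtype=float)
    M = np.asarray(M, dtype=float)
    if dW.shape != M.shape:
        raise ValueError(
            f"update shape {dW.shape} != modulation shape {M.shape}"
        )
    return dW * M
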
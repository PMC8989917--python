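"""Learning-curve summaries: the plateau fit and accuracy conventions.

A test-accuracy curve is summarized by a Michaelis-Menten-like saturating
form,

    accuracy(epochs) = max_accuracy * epochs / (slowness + epochs),

whose *slowness* parameter is the number of epochs needed to reach half of
the maximum accuracy — the smaller, the faster the convergence.  The fit is
performed over a fixed window (first 100 epochs by default) so slowness
values of different runs are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["PlateauFit", "plateau_eval", "plateau_fit", "report_metrics"]


@dataclass
class PlateauFit:
    max_accuracy: float     # percent, in (0, 100]
    slowness: float         # epochs, > 0
    window: int
    residual_norm: float
    boundary: bool = False  # True when the fit pinned a parameter at a bound


def plateau_eval(max_accuracy: float, slowness: float, epochs) -> np.ndarray | float:
    """Evaluate the plateau curve; ``slowness`` must be positive."""
    if slowness <= 0:
        raise ValueError("slowness must be positive")
    epochs = np.asarray(epochs, dtype=float)
    out = max_accuracy * epochs / (slowness + epochs)
    return float(out) if out.ndim == 0 else out


def plateau_fit(curve, window: int = 100) -> PlateauFit:
    """Least-squares fit of the plateau curve to per-epoch test accuracies.

    ``curve`` holds accuracies in percent for epochs 1, 2, ...; only the
    first ``window`` epochs enter the fit.  Initial guesses: the observed
    maximum, and the first epoch exceeding half of it.  Parameters are
    bounded (max_accuracy in (0, 100], slowness > 0) to keep the fit from
    diverging; a solution pinned at a bound is flagged, and a degenerate
    all-zero curve raises instead of returning a silent failure.
    """
    y = np.asarray(curve, dtype=float)[:window]
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need at least 3 epochs inside the fit window")
    if np.any(y < 0) or np.any(y > 100):
        raise ValueError("accuracies must be in [0, 100] percent")
    if np.all(y == 0):
        raise ValueError("degenerate all-zero curve: plateau fit undefined")
    epochs = np.arange(1, len(y) + 1, dtype=float)
    a0 = y.max()
    above = np.nonzero(y > a0 / 2)[0]
    s0 = float(epochs[above[0]]) if len(above) else float(len(y))
    lo, hi = [1e-9, 1e-9], [100.0, 1e6]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            lambda e, a, s: a * e / (s + e), epochs, y,
            p0=[np.clip(a0, lo[0], hi[0]), np.clip(s0, lo[1], hi[1])],
            bounds=(lo, hi), maxfev=10000,
        )
    a, s = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(y - a * epochs / (s + epochs)))
    boundary = bool(
        np.isclose(a, hi[0]) or a < 1e-6 or s < 1e-6 or np.isclose(s, hi[1])
    )
    return PlateauFit(a, s, window=len(y), residual_norm=resid, boundary=boundary)


def report_metrics(curve, convention: str = "mean_last_10") -> float:
    """Summary accuracy of a test curve under a stated convention.

    ``mean_last_10``: mean test accuracy over the last 10 epochs (used for
    convergence comparisons); ``best_overall``: best test accuracy across
    the whole run (used when training with augmentation).  A curve shorter
    than 10 epochs is averaged in full, with a warning.
    """
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("curve must be a non-empty 1-D sequence")
    if convention == "mean_last_10":
        if len(y) < 10:
            warnings.warn("curve shorter than 10 epochs; averaging all of it")
            return float(y.mean())
        return float(y[-10:].mean())
    if convention == "best_overall":
        return float(y.max())
    raise ValueError(f"unknown convention {convention!r}")
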
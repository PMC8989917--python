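"""Permuted-pixel task families and sequential (continual) training.

A task is defined by a random subset of N_p pixel positions and a random
permutation of that subset; applying it to every train/test image yields a
new classification problem with identical label structure.  Training the
same network on a sequence of such tasks, with no replay and no reset,
probes catastrophic forgetting: after each epoch the network is tested on
the current and all previously learnt tasks (retention), and after each
task on all not-yet-seen tasks (per-task-future-accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .data import LabeledImageSet

__all__ = [
    "PermutationTask",
    "TaskSequence",
    "AccuracyMatrix",
    "make_permutation_task",
    "apply_permutation",
    "run_sequential_training",
    "per_task_future_accuracy",
]


@dataclass
class PermutationTask:
    """A bijection on a subset of flat pixel indices; other pixels fixed."""

    n_permuted: int
    subset: np.ndarray       # flat indices of the permuted pixels
    permutation: np.ndarray  # subset[i] receives the value of permutation[i]
    seed: int | None = None

    def full_index(self, n_pixels: int) -> np.ndarray:
        """The permutation extended to the full flat pixel grid."""
        idx = np.arange(n_pixels)
        idx[self.subset] = self.permutation
        return idx

    def inverse(self) -> "PermutationTask":
        order = np.empty_like(self.permutation)
        # value at subset[i] came from permutation[i]; invert that mapping
        inv = dict(zip(self.permutation.tolist(), self.subset.tolist()))
        order = np.array([inv[s] for s in self.subset.tolist()])
        return PermutationTask(self.n_permuted, self.subset.copy(), order, self.seed)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "n_permuted": int(self.n_permuted),
            "subset": self.subset.tolist(),
            "permutation": self.permutation.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PermutationTask":
        d = json.loads(text)
        return cls(d["n_permuted"], np.array(d["subset"]),
                   np.array(d["permutation"]), d["seed"])


@dataclass
class TaskSequence:
    tasks: list
    epochs_per_task: int

    def __post_init__(self):
        if not self.tasks:
            raise ValueError("task sequence must be non-empty")
        if self.epochs_per_task < 1:
            raise ValueError("epochs_per_task must be >= 1")


@dataclass
class AccuracyMatrix:
    """Retention and future-accuracy tables from a sequential run.

    ``retention[e, j]`` is the test accuracy (percent) on task j measured
    after global epoch e+1; entries for tasks not yet started are NaN, so
    the populated part is lower-triangular in task blocks.  ``future[k, j]``
    (strictly upper in task index) is the accuracy on unseen task j > k
    evaluated with the snapshot taken after finishing task k.
    """

    retention: np.ndarray
    future: np.ndarray
    epochs_per_task: int

    def task_accuracy_after(self, task_trained: int, task_tested: int) -> float:
        """Accuracy on ``task_tested`` right after finishing ``task_trained``."""
        e = (task_trained + 1) * self.epochs_per_task - 1
        return float(self.retention[e, task_tested])


def make_permutation_task(n_permuted: int, image_shape,
                          rng: np.random.Generator,
                          seed: int | None = None) -> PermutationTask:
    """Draw a uniformly random subset of N_p pixels and permute it.

    Both the subset and its permutation are drawn fresh from ``rng``; with
    ``n_permuted`` equal to the total pixel count every pixel is subject to
    permutation, so independent tasks share no fixed pixels.
    """
    n_pixels = int(np.prod(image_shape))
    if not (0 <= n_permuted <= n_pixels):
        raise ValueError(f"n_permuted must be in [0, {n_pixels}]")
    subset = rng.choice(n_pixels, size=n_permuted, replace=False)
    permutation = rng.permutation(subset)
    return PermutationTask(n_permuted, subset, permutation, seed)


def apply_permutation(dataset: LabeledImageSet, task: PermutationTask) -> LabeledImageSet:
    """Permute pixels of every image; labels and pixel multisets unchanged."""
    shape = dataset.images.shape[1:]
    n_pixels = int(np.prod(shape))
    if task.n_permuted and task.subset.max() >= n_pixels:
        raise ValueError("task geometry does not match the dataset")
    idx = task.full_index(n_pixels)
    flat = dataset.images.reshape(len(dataset), n_pixels)
    images = flat[:, idx].reshape(dataset.images.shape)
    return LabeledImageSet(images, dataset.labels.copy(),
                           split=dataset.split, seed=dataset.seed)


def run_sequential_training(model: engine.NetworkModel,
                            train: LabeledImageSet, test: LabeledImageSet,
                            sequence: TaskSequence,
                            opt: engine.OptimizerState,
                            cfg: engine.GrapesConfig,
                            rng: np.random.Generator,
                            batch_size: int = 64,
                            scheme: str = "bp",
                            feedback: list | None = None) -> AccuracyMatrix:
    """Train one model through the task sequence; no reset, no replay.

    After every epoch the model is tested on the current task and on every
    previously learnt task (retention matrix); after each task's final
    epoch a snapshot is evaluated on all unseen tasks (future matrix).
    """
    tasks = sequence.tasks
    n_tasks = len(tasks)
    n_epochs = n_tasks * sequence.epochs_per_task
    train_views = [apply_permutation(train, t) for t in tasks]
    test_views = [apply_permutation(test, t) for t in tasks]
    retention = np.full((n_epochs, n_tasks), np.nan)
    future = np.full((n_tasks, n_tasks), np.nan)
    modvectors = engine.refresh_modulation(model, cfg)
    e = 0
    for k in range(n_tasks):
        X, y = train_views[k].flat(), train_views[k].labels
        for _ in range(sequence.epochs_per_task):
            log = engine.train_epoch(model, X, y, opt, cfg, rng,
                                     batch_size=batch_size, scheme=scheme,
                                     feedback=feedback, modvectors=modvectors)
            modvectors = log["modvectors"]
            for j in range(k + 1):
                retention[e, j] = engine.evaluate(
                    model, test_views[j].flat(), test_views[j].labels)
            e += 1
        for j in range(k + 1, n_tasks):
            future[k, j] = engine.evaluate(
                model, test_views[j].flat(), test_views[j].labels)
    return AccuracyMatrix(retention, future, sequence.epochs_per_task)


def per_task_future_accuracy(snapshots: list, test: LabeledImageSet,
                             sequence: TaskSequence) -> np.ndarray:
    """Future-accuracy table from explicit model snapshots.

    ``snapshots[k]`` is the model state after finishing task k; entry
    (k, j) holds its test accuracy on unseen task j > k (percent), NaN
    elsewhere.  E.g. after learning task 1 the row lists the accuracy on
    the still-unseen tasks 2, 3, 4, 5.
    """
    tasks = sequence.tasks
    n_tasks = len(tasks)
    if len(snapshots) != n_tasks:
        raise ValueError("need one snapshot per task")
    test_views = [apply_permutation(test, t) for t in tasks]
    future = np.full((n_tasks, n_tasks), np.nan)
    for k, model in enumerate(snapshots):
        for j in range(k + 1, n_tasks):
            future[k, j] = engine.evaluate(
                model, test_views[j].flat(), test_views[j].labels)
    return future
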
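"""Experiment orchestration: configuration, seeding, result bundles.

Every experiment is described by an :class:`ExperimentConfig` (loadable
from YAML/JSON), runs deterministically under its master seed, and emits
plain CSV/JSON artifacts: a per-epoch log (loss, test accuracy, per-layer
modulation mean/std), a plateau-fit summary, and — for the continual
protocol — the retention and future-accuracy matrices.  One independent
RNG stream per concern (weight init, shuffling/dropout, feedback matrices,
rate coding, task generation, data generation) is spawned from the master
seed, so no module consumes another's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import continual, data, engine, metrics, snu

__all__ = ["ExperimentConfig", "rng_streams", "run_experiment", "compare_runs",
           "load_config", "PRESETS"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run."""

    protocol: str = "standard"          # standard | continual | snu
    widths: tuple = (64, 64, 64)
    activation: str = "relu"
    dropout: float = 0.0
    scheme: str = "bp"                  # bp | fa | dfa
    optimizer: str = "sgd"
    lr: float = 0.001
    momentum: float = 0.9
    grapes_mode: str = "off"            # off | local | propagating
    grapes_grouping: str = "postsynaptic"
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0
    n_train: int = 5000
    n_test: int = 1000
    n_classes: int = 10
    side: int = 28
    idx_images: str | None = None       # optional real data (IDX pair)
    idx_labels: str | None = None
    idx_test_images: str | None = None
    idx_test_labels: str | None = None
    # continual protocol
    n_tasks: int = 2
    n_permuted: int = 784
    epochs_per_task: int = 1
    # snu protocol
    snu_output: str = "sigmoid"
    snu_decay: float = 0.8
    snu_reset: str = "soft"
    n_steps: int = 20
    n_steps_test: int = 300

    def validate(self) -> list[str]:
        problems = []
        if self.protocol not in ("standard", "continual", "snu"):
            problems.append(f"unknown protocol {self.protocol!r}")
        if self.scheme not in ("bp", "fa", "dfa"):
            problems.append(f"unknown scheme {self.scheme!r}")
        if self.scheme == "dfa" and self.grapes_mode != "off" \
                and self.grapes_grouping != "presynaptic":
            problems.append("DFA requires presynaptic grouping")
        if self.lr <= 0:
            problems.append("learning rate must be positive")
        if not (0 <= self.dropout < 1):
            problems.append("dropout must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            problems.append("epochs and batch size must be >= 1")
        try:
            engine.GrapesConfig(self.grapes_mode, self.grapes_grouping)
        except ValueError as exc:
            problems.append(str(exc))
        return problems

    def grapes_config(self) -> engine.GrapesConfig:
        grouping = self.grapes_grouping
        if self.scheme == "dfa":
            grouping = "presynaptic"
        return engine.GrapesConfig(self.grapes_mode, grouping)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["widths"] = list(self.widths)
        return d


# Presets mirroring the study conditions at their stated scales.
PRESETS: dict[str, dict] = {
    # small run logging the modulation mean/std observables
    "modulation-observables": dict(protocol="standard", widths=(64, 64),
                                   epochs=3, grapes_mode="propagating",
                                   lr=0.001),
    # sequential permuted-pixel benchmark: all pixels permuted, momentum,
    # one epoch per task, 2x256 ReLU
    "continual-benchmark": dict(protocol="continual", widths=(256, 256),
                                optimizer="momentum", lr=0.001, dropout=0.1,
                                n_permuted=784, epochs_per_task=1, n_tasks=5),
    # custom overlap setting: 600 permuted pixels, plain SGD, 10 epochs
    # per task, 3x256 ReLU, 10% dropout
    "continual-overlap": dict(protocol="continual", widths=(256, 256, 256),
                              optimizer="sgd", lr=0.001, dropout=0.1,
                              n_permuted=600, epochs_per_task=10, n_tasks=5),
    # spiking presets at their tuned depths and learning rates
    "snu": dict(protocol="snu", widths=(256, 256, 256), snu_output="step",
                lr=0.1, n_steps=20, n_steps_test=300),
    "ssnu": dict(protocol="snu", widths=(256, 256), snu_output="sigmoid",
                 lr=0.2, n_steps=20, n_steps_test=300),
}


def load_config(path) -> ExperimentConfig:
    """Read a YAML or JSON config file into an ExperimentConfig."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "widths" in raw:
        raw["widths"] = tuple(raw["widths"])
    return ExperimentConfig(**raw)


def rng_streams(seed: int, names=("init", "shuffle", "feedback", "rate",
                                  "tasks", "data")) -> dict:
    """Independent named RNG streams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _code_version() -> str:
    """Hash of this package's source files, embedded for provenance."""
    h = hashlib.sha256()
    pkg = Path(__file__).parent
    for f in sorted(pkg.glob("*.py")):
        h.update(f.read_bytes())
    return h.hexdigest()[:12]


def _load_data(cfg: ExperimentConfig, rng_data):
    if cfg.idx_images:
        train = data.load_idx_dataset(cfg.idx_images, cfg.idx_labels, "train")
        test = data.load_idx_dataset(cfg.idx_test_images, cfg.idx_test_labels, "test")
        return train, test
    ss = rng_data.bit_generator.seed_seq.spawn(2)
    train = data.generate_digits(cfg.n_train, cfg.n_classes, cfg.side,
                                 rng=np.random.default_rng(ss[0]), split="train")
    test = data.generate_digits(cfg.n_test, cfg.n_classes, cfg.side,
                                rng=np.random.default_rng(ss[1]), split="test")
    return train, test


def run_experiment(cfg: ExperimentConfig, outdir=None, progress=False) -> dict:
    """Run one experiment end to end; deterministic under cfg.seed.

    Returns a result bundle: the resolved config, a per-epoch log table,
    the plateau fit (standard protocol), the retention/future accuracy
    matrices (continual protocol).  When ``outdir`` is given the bundle is
    also written as CSV/JSON files.
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    rngs = rng_streams(cfg.seed)
    train, test = _load_data(cfg, rngs["data"])
    n_in = int(np.prod(train.images.shape[1:]))
    bundle: dict = {"config": cfg.to_dict(), "code_version": _code_version()}

    if cfg.protocol == "snu":
        snu_cfg = snu.SNUConfig(decay=cfg.snu_decay, output=cfg.snu_output,
                                reset=cfg.snu_reset, n_steps=cfg.n_steps,
                                n_steps_test=cfg.n_steps_test)
        model = snu.SNUNetwork(cfg.widths, n_in, cfg.n_classes, snu_cfg,
                               rngs["init"])
        opt = engine.OptimizerState(cfg.lr, cfg.optimizer, momentum=cfg.momentum)
        log = snu.train_snu_grapes(
            model, train.flat(), train.labels, opt, cfg.grapes_config(),
            rngs["shuffle"], epochs=cfg.epochs, batch_size=cfg.batch_size,
            test=(test.flat(), test.labels), test_steps=cfg.n_steps_test)
        table = pd.DataFrame({
            "epoch": np.arange(1, cfg.epochs + 1),
            "train_loss": log["train_loss"],
            "test_accuracy": log["test_accuracy"],
        })
        bundle["log"] = table
    else:
        model = engine.mlp(cfg.widths, n_in, cfg.n_classes, cfg.activation,
                           cfg.dropout, rngs["init"])
        opt = engine.OptimizerState(cfg.lr, cfg.optimizer, momentum=cfg.momentum)
        gcfg = cfg.grapes_config()
        feedback = None
        if cfg.scheme in ("fa", "dfa"):
            feedback = engine.make_feedback_matrices(model, cfg.scheme,
                                                     rngs["feedback"])
        if cfg.protocol == "continual":
            tasks = [continual.make_permutation_task(
                cfg.n_permuted, train.images.shape[1:], rngs["tasks"])
                for _ in range(cfg.n_tasks)]
            seq = continual.TaskSequence(tasks, cfg.epochs_per_task)
            acc = continual.run_sequential_training(
                model, train, test, seq, opt, gcfg, rngs["shuffle"],
                batch_size=cfg.batch_size, scheme=cfg.scheme,
                feedback=feedback)
            bundle["accuracy_matrix"] = acc
            bundle["tasks"] = [t.to_json() for t in tasks]
        else:
            rows = []
            modvectors = engine.refresh_modulation(model, gcfg)
            for epoch in range(1, cfg.epochs + 1):
                log = engine.train_epoch(
                    model, train.flat(), train.labels, opt, gcfg,
                    rngs["shuffle"], batch_size=cfg.batch_size,
                    scheme=cfg.scheme, feedback=feedback,
                    test=(test.flat(), test.labels), modvectors=modvectors)
                modvectors = log["modvectors"]
                rows.append({
                    "epoch": epoch,
                    "train_loss": log["train_loss"],
                    "test_accuracy": log["test_accuracy"],
                    **{f"mod_mean_l{i}": v for i, v in enumerate(log["modulation_mean"])},
                    **{f"mod_std_l{i}": v for i, v in enumerate(log["modulation_std"])},
                })
                if progress:
                    print(f"epoch {epoch}: loss {log['train_loss']:.4f} "
                          f"test acc {log['test_accuracy']:.2f}%")
            table = pd.DataFrame(rows)
            bundle["log"] = table
            if len(table) >= 3:
                try:
                    fit = metrics.plateau_fit(table["test_accuracy"].to_numpy())
                    bundle["plateau_fit"] = fit
                except ValueError:
                    bundle["plateau_fit"] = None
    bundle["model"] = model
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": bundle["config"], "code_version": bundle["code_version"]}
    if "log" in bundle:
        bundle["log"].to_csv(out / "log.csv", index=False)
    fit = bundle.get("plateau_fit")
    if fit is not None:
        meta["plateau_fit"] = dataclasses.asdict(fit)
    if "accuracy_matrix" in bundle:
        acc = bundle["accuracy_matrix"]
        pd.DataFrame(acc.retention).to_csv(out / "retention.csv", index=False)
        pd.DataFrame(acc.future).to_csv(out / "future_accuracy.csv", index=False)
        (out / "tasks.json").write_text(json.dumps(bundle["tasks"]))
    (out / "result.json").write_text(json.dumps(meta, indent=2))


def compare_runs(bundle_a: dict, bundle_b: dict) -> dict:
    """Paired comparison of two standard-protocol bundles.

    Requires matching protocol and dataset seed; reports the difference in
    summary accuracy (mean over the last 10 epochs) and fitted slowness,
    B minus A.
    """
    ca, cb = bundle_a["config"], bundle_b["config"]
    if ca["protocol"] != cb["protocol"]:
        raise ValueError("bundles use different protocols")
    if ca["seed"] != cb["seed"]:
        raise ValueError("bundles use different seeds")
    curve_a = bundle_a["log"]["test_accuracy"].to_numpy()
    curve_b = bundle_b["log"]["test_accuracy"].to_numpy()
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc_a = metrics.report_metrics(curve_a)
        acc_b = metrics.report_metrics(curve_b)
    out = {"delta_accuracy": acc_b - acc_a}
    fa, fb = bundle_a.get("plateau_fit"), bundle_b.get("plateau_fit")
    if fa is not None and fb is not None:
        out["delta_slowness"] = fb.slowness - fa.slowness
        out["slowness_a"] = fa.slowness
        out["slowness_b"] = fb.slowness
    out["accuracy_a"] = acc_a
    out["accuracy_b"] = acc_b
    return out
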
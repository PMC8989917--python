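# grapesnn

Training deep networks with backpropagation attributes error to each unit
from the current input alone.  Biological neurons do something more: how
strongly a cell can drive its downstream targets depends on the standing
distribution of its synaptic strengths, independent of any particular
stimulus.  `grapesnn` implements that idea as a weight-distribution-based
modulation of training error signals, inside a small, self-contained
NumPy training framework, together with the evaluation machinery needed
to study it: a learning-curve "plateau" statistic for convergence speed,
a permuted-pixel continual-learning protocol for catastrophic forgetting,
and spiking neural units trained with BPTT on rate-coded input.

## The model

For a fully connected layer *l* with weight matrix *W^l* (rows =
postsynaptic nodes), the **node importance** of node *n* is the summed
absolute strength of its incoming weights,

    i_n^l = Σ_pre |W^l[n, pre]| .

Normalizing the importance vector by its layer maximum, doubling it and
lower-bounding at 1 gives the **modulation vector**

    m^l = max( 2 · i^l / max(i^l), 1 )  ∈  [1, 2]^n ,

so the most important node is boosted by exactly 2 and no node is damped.
Tiled across the presynaptic dimension this becomes a modulation matrix
*M^l* with constant rows, and the weight update is rescaled by a Hadamard
product, δW_M^l = δW_o^l ⊙ M^l, with SGD then applying
W^l(t+1) = W^l(t) + η·δW_M^l(t).  In the **local** variant only each
layer's own update is rescaled; in the **propagating** variant (the
default in experiments) the per-node factors multiply the backpropagated
delta itself, so the adjustment compounds through all upstream layers.
Modulation factors depend only on the weights, are recomputed once per
parameter update, and are held fixed within a batch.

The same grouping idea covers convolutional layers (filters grouped by
output map) and direct feedback alignment (importance grouped by
*outgoing* weights, since DFA delivers the output error directly to each
hidden layer).  Feedback alignment, DFA, momentum/NAG/RMSprop/Adam, and
spiking (SNU/sSNU) layers all consume the same modulation machinery.

Convergence speed is summarized by fitting per-epoch test accuracy to the
plateau curve `accuracy = max_accuracy · epochs / (slowness + epochs)`;
*slowness* is the number of epochs to reach half the maximum accuracy —
lower is faster.

All experiments run on a built-in synthetic digit generator (balanced
10-class, 28×28, intensities in [0, 1], equal per-class stroke mass so
that permuted-pixel tasks are genuinely disjoint), so nothing needs to be
downloaded; MNIST-layout IDX files can be used instead where available.

## Worked example

Train the same 2×64 ReLU network on synthetic digits with plain SGD and
with propagating modulation (η = 0.001, 15 epochs, 2,000/500 split):

```python
import dataclasses
from grapesnn import workbench

cfg = workbench.ExperimentConfig(widths=(64, 64), epochs=15, lr=0.001,
                                 n_train=2000, n_test=500, seed=1)
sgd = workbench.run_experiment(cfg)
grapes = workbench.run_experiment(
    dataclasses.replace(cfg, grapes_mode="propagating"))
print(workbench.compare_runs(sgd, grapes))
```

which prints (B = modulated run, A = plain SGD):

```
{'delta_accuracy': 32.6, 'delta_slowness': -8.47,
 'slowness_a': 11.53, 'slowness_b': 3.06,
 'accuracy_a': 47.88, 'accuracy_b': 80.48}
```

The modulated run reaches half its asymptotic accuracy in ≈3 epochs where
plain SGD needs ≈11.5, and its mean test accuracy over the last 10 epochs
is 32.6 percentage points higher — the convergence speed-up the
modulation is designed to deliver.  Each run's per-epoch log also records
the per-layer modulation mean/std (all within [1, 2]).

The same experiments are available from the shell:

```bash
grapesnn train --seed 1 --epochs 15 --widths 64,64 --grapes-mode propagating
grapesnn continual --preset continual-benchmark --seed 0 --out run/
grapesnn snu --preset ssnu --epochs 3 --n-train 1000
grapesnn fit-plateau run/log.csv
```

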
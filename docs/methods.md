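# Methods

## Importance-based modulation

The core quantity is per-node importance: the summed absolute synaptic
strength of a node's grouped connections.  Three groupings are used:

* **postsynaptic** (dense layers, BP/FA): row sums of |W^l| — the
  incoming strength of each node;
* **presynaptic** (DFA): column sums of |W^{l+1}| — the outgoing strength
  of each node into the next layer, needed because DFA's error terms have
  the layer's own dimensionality;
* **per output map** (convolutional layers): the absolute sum over each
  output map's full filter bank.

The modulation vector is `max(2·i/max(i), 1)`.  The doubling and the
lower bound confine every factor to [1, 2]: the most important node is
amplified exactly ×2, no node is attenuated.  An all-zero importance
vector (a layer with all-zero weights) has no well-defined normalization;
it maps to all ones, i.e. the modulation is a no-op.  No epsilon is added
to the denominator — the degenerate case is handled explicitly, and ties
at the maximum need no tie-break since only the maximal *value* enters.
The normalization is scale invariant (`c·W` gives the same vector for any
`c ≠ 0`), and normalizing by the mean or the sum before rescaling to the
same top value is algebraically identical.

Bias parameters do not contribute to the importance sums (the importance
is a property of the incoming *weights*); each bias update is scaled by
its node's factor, like every other update converging on that node.
Dropout masks are per-sample, importance is per-batch, so importance
always uses the full weight matrix.

**Local vs propagating.**  Local modulation multiplies each layer's own
update matrix row-wise (equivalently, its delta), leaving the recursion
untouched.  Propagating modulation multiplies the per-node deltas inside
the backward recursion, so a deep layer's adjustment is carried into
every upstream layer's delta and update.  On a single-hidden-layer
network the two coincide exactly.  The output layer is never modulated by
default (its delta enters the recursion unmodified); a flag exists for
completeness.

**Schedule.**  Modulation vectors are functions of the weights only.
They are computed once from the initial weights and then refreshed only
after each parameter update; every sample within a batch sees the same
vectors.

**DFA.**  With direct feedback alignment each hidden delta comes straight
from the output error through a fixed random matrix, so there is no
upstream path for a modulated delta to ride on: propagating mode behaves
layer-locally by default.  An experimental flag (`dfa_carry`) instead
carries the modulated delta upstream through forward-weight transposes;
this reintroduces the weight transport DFA exists to avoid and is not
used in any default configuration.

**Optimizers.**  The modulation rescales the raw error signal, so it is
applied *before* the momentum/RMSprop/Adam accumulators: the accumulators
track the modulated gradient.  SGD with modulation is literally
`W ← W + η·(δW ⊙ M)` with δW the descent step.

## Training engine

A small NumPy engine with dense, convolutional (stride 1, symmetric zero
padding), batchnorm, dropout and flatten layers; softmax/cross-entropy
readout; He-style normal init for ReLU layers and Glorot-style uniform
init otherwise.  Unmodulated backpropagation is verified against central
finite differences (worst relative error below 1e-5 over dense, conv and
batchnorm architectures; exactly-zero gradients, such as a bias feeding
batchnorm, are shielded by an absolute floor in the error metric).
Feedback matrices for FA/DFA are drawn once (normal, scale 0.05) and
frozen.  Batchnorm parameters are trainable but never modulated.

## Spiking units

SNU/sSNU layers abstract leaky integrate-and-fire dynamics into a
recurrent unit: `s_t = g(W x_t + decay · retained(s_{t-1}, y_{t-1}))`,
`y_t = h(s_t + b)` with `g = ReLU`; `h` is a step (SNU) or sigmoid
(sSNU); `b` acts as a negative firing threshold.  Two resets are
implemented: multiplicative (`s·(1−y)`) and soft (subtract `|b|·y`,
floored at 0 — smoother to train).  The step function's derivative is a
straight-through surrogate: 1 inside a unit-width window around
threshold, else 0.  BPTT is exact with respect to this computational
graph, including the reset path and the dependence of the soft-reset
threshold on `b` (verified by finite differences for both resets).

Inputs are rate-coded: each pixel spikes independently per step with
probability equal to its intensity, over N_s = 20 steps during training
and N_s = 300 at test, so the empirical rate approaches the intensity
within binomial error.  The classification readout is a linear layer
applied per step; the loss is softmax cross-entropy on the time-averaged
readout pre-activation.  With N_s = 1 and decay 0 an sSNU network is
exactly a feedforward network (sigmoid-of-ReLU hidden units into a linear
softmax readout), which anchors the BPTT implementation to the dense
engine.  Modulation uses each layer's input weight matrix and follows the
same per-batch refresh schedule.  Preset depths/learning rates: three
hidden layers with η = 0.1 for SNU, two with η = 0.2 for sSNU.

## Continual-learning protocol

A task is a uniformly random subset of N_p pixel positions plus a
uniformly random permutation of that subset; with N_p equal to the pixel
count every pixel is permuted and tasks share no fixed pixels.  The
subset and permutation are drawn fresh per task (independent draws, so
overlap between tasks is itself random).  One model is trained through
the task sequence with no reset and no replay; after every epoch it is
evaluated on the current and all previously learnt tasks (retention
matrix), and after each task's final epoch on all unseen tasks
(per-task-future-accuracy, e.g. after task 1 the row lists unseen tasks
2–5).  Chance level is 1/(number of classes); the generator keeps test
sets class-balanced.  Two presets mirror the studied settings: all-pixel
permutations with momentum SGD and one epoch per task on 2×256 ReLU
nets, and 600-pixel permutations with plain SGD, ten epochs per task,
3×256 ReLU and 10% dropout, both at η = 0.001.

## Plateau statistic

`accuracy = max_accuracy · epochs / (slowness + epochs)` — a
Michaelis–Menten-style saturating curve whose *slowness* is the epoch
count at which half the maximum accuracy is reached.  Fits are unweighted
bounded least squares (`scipy.optimize.curve_fit`; max_accuracy in
(0, 100], slowness > 0) over a fixed window (first 100 epochs by
default), with initial guesses taken from the observed maximum and the
first epoch above half of it.  Solutions pinned at a bound are flagged
rather than silently returned; an all-zero curve raises.  Accuracies are
in percent throughout.  Two reporting conventions are provided: the mean
test accuracy over the last 10 epochs (convergence comparisons) and the
best test accuracy of the run (used with augmented training data).

## Synthetic data

The generator emulates an MNIST-like task without any download: ten
distinct stroke-pattern glyphs on a 7×7 grid, bilinearly upscaled to
28×28, with per-sample affine jitter (rotation ≤12°, shift ≤2 px, scale
±12%) and additive Gaussian pixel noise (σ = 0.15), clipped to [0, 1].
Classes are exactly balanced when the sample count divides by the class
count, and generation is deterministic under a seed.

Every glyph carries exactly 20 of 49 template cells.  This is deliberate:
a pixel permutation preserves each image's pixel multiset, so if classes
differed in total ink or histogram shape, permuted tasks would be
solvable by permutation-invariant shortcuts and sequential training on
them would show spurious transfer instead of forgetting.  With equal
stroke mass, a network trained on one fully permuted task performs at
chance on another — the property the permuted-digit protocol presumes.

What the generator does *not* emulate: handwriting style diversity,
stroke-thickness variation, or correlated background structure.  The
synthetic task is easier than real digits, so passing directional tests
(faster convergence, reduced forgetting) demonstrates the mechanism under
controlled conditions, not benchmark-level accuracy on real data.
Affine-plus-elastic augmentation (Gaussian-smoothed random displacement
field; magnitude and smoothing in pixels; zero magnitude is exactly the
identity) is available for training-set enlargement, and MNIST-layout IDX
files (big-endian container, uint8 images scaled by 1/255) can replace
the generator everywhere.

## Problem sizes and numerical choices

Experiments in the test suite run at deliberately reduced scale, chosen
as the smallest sizes at which the studied effects are stable across
seeds: convergence comparisons use 3×64 ReLU nets on 5,000/1,000
synthetic samples for 30 epochs at η = 0.001 across 10 paired seeds; the
forgetting protocol uses two fully permuted tasks, 2×64 nets, 3,000/1,000
samples, ten epochs per task at η = 0.001 across 5 seeds (at that
learning rate a scaled-down net is still underfit after only a few
epochs per task, so the per-task epoch count follows the ten-epoch
custom protocol).  Full-size benchmark accuracies on real datasets are
out of scope.

Randomness is organized as one independent stream per concern (weight
init, shuffling/dropout, feedback matrices, rate coding, task generation,
data generation), all spawned from a single master seed; reruns with the
same configuration are bit-identical.  Result bundles embed the resolved
configuration and a hash of the package source for provenance, and all
outputs are plain CSV/JSON.

## Known limitations

* The modulation interval is fixed at [1, 2]; alternative intervals are
  not explored.
* Propagating modulation for convolutional stacks multiplies the per-map
  delta; architectures with residual connections are not modeled.
* The SNU implementation is rate-coded and clock-driven; event-driven
  execution and refractory dynamics are out of scope.
* FA/DFA support dense networks only.
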
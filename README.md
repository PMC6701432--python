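# fbseg — feedback-gated CNNs for patch-based medical image segmentation

`fbseg` is a small, self-contained toolkit for studying **top-down feedback
in convolutional networks** and for running a **patch-based segmentation
pipeline** on lesion-bearing grayscale slices.  It is aimed at researchers
who want a fully inspectable (pure numpy) implementation of gate-switch
feedback — every ReLU on/off decision and every max-pool argmax is exposed,
optimizable and testable — rather than production-scale segmentation.

## The model

A feedforward CNN stacks convolutions
`y_{c'} = Σ_c k_{c'c} ∗ x_c + b_{c'}`, rectifications `y = max(0, x)` and
max-pooling `y_{ijc} = max_{(u,v)∈N} x_{i+u, j+v, c}`.  Both `max(·)`
selections can be re-read as banks of **binary switches** ("feedback
neurons"): `y = z ∘ x` with `z ∈ {0,1}`.  Given a trained network, an input
image `I` and a target class logit `S = f(I, Z)`, the *feedback problem* is

```
max_Z  S = f(I, Z) − λ‖Z‖₁ ,   z_{ijc}^l ∈ {0,1}
```

— open only the switches that support the target.  With all switches frozen
the image→logit map is affine, so restricted to one ReLU layer the objective
is `S = Σ_k α_k z_k x_k + const`, where the **contribution weight**
`α_k = ∂S/∂(z_k x_k)` sums the weight products over all connecting pathways
from neuron `k` to the target.  Two greedy solvers update one layer at a
time with the per-layer maximizer `z_k = 1 ⇔ α_k x_k > 0`:

* **FR (feedback recovery)** — top-down sweeps, contributions re-derived
  after each layer update;
* **FS (feedback selective)** — bottom-up sweeps; a layer's contributions
  depend only on the gates above it, so within a sweep the coefficients are
  exactly those in force when the sweep began.

Both trajectories are provably non-decreasing and terminate; an exhaustive
`2^n` gate enumeration is included as an independent oracle for small
networks.  From the converged gates, backpropagating a unit gradient from
the target logit yields a **gradient map** in image space, displayed as a
min-max rescaled **visualization map** (`255·(x−min)/(max−min)`) or reduced
to a unit-L2 **energy map** (channel-absolute sums).

The segmentation pipeline classifies the 25×25 patch centred on every pixel
(after min-max normalization `f' = (f−min)/(max−min)`), trains the
classifier by denoising layer-wise pretraining plus supervised fine-tuning,
and refines the resulting mask twice: an intensity band-pass keeping
foreground pixels within `μ ± kσ` of the foreground gray distribution, then
morphological opening and closing.  Overlap is scored with
`Dice = 2|A∩B|/(|A|+|B|)` and `IoU = |A∩B|/|A∪B|`.

Because clinical volumes are not shipped, a seeded generator produces
lesion-bearing scenes (elliptical bright lesions on darker tissue, smooth
intensity inhomogeneity, Gaussian noise) with pixel-accurate ground truth;
see `docs/methods.md` for what these scenes do and do not demonstrate.

## Worked example

Feedback recovery on a seeded micro-network (12 gates, two feedback
layers):

```python
import numpy as np
from fbseg.net_core import LayerSpec, build_network
from fbseg.gated_feedback import FeedbackProblem, feedback_recovery

specs = [LayerSpec.conv(3, 1, 2), LayerSpec.relu(), LayerSpec.flatten(),
         LayerSpec.dense(8, 4), LayerSpec.relu(), LayerSpec.dense(4, 3),
         LayerSpec.softmax()]
model = build_network(specs, (4, 4, 1), seed=0, weight_scale=2.0)
img = np.random.default_rng(7).standard_normal((4, 4, 1))
res = feedback_recovery(FeedbackProblem(model, img, target_index=0))
print("trajectory:", [round(s, 4) for s in res.objective_trajectory])
print("converged:", res.converged, " closed fraction per layer:",
      {k: round(v, 3) for k, v in res.closed_fraction.items()})
```

```
trajectory: [-1.1678, 0.0816, 0.1008, 0.1217, 0.3161, 0.3897, 0.3897, 0.3897, 0.3897]
converged: True  closed fraction per layer: {1: 0.5, 4: 0.25}
```

The target logit starts at −1.17 under the feedforward gates, rises
monotonically as each layer update closes the gates working against the
target (half of the first ReLU layer, a quarter of the second), and
converges once a sweep changes nothing.

The canonical segmentation benchmark — 20 synthetic 64×64 scenes, 14 used
to train the default two-stage classifier, 6 held out — runs in under a
minute on one CPU:

```python
from fbseg.cli import run_benchmark
r = run_benchmark(benchmark_seed=7, train_seed=0)
print("mean initial Dice:", round(r["mean_initial_dice"], 3))
print("mean final Dice:  ", round(r["mean_final_dice"], 3))
```

```
mean initial Dice: 0.952
mean final Dice:   0.973
mean final IoU:    0.949
pixel accuracy:    0.993
```

The raw per-pixel classification already reaches Dice ≈ 0.95 on held-out
scenes; the intensity band-pass plus open/close refinement removes spurious
specks and fills pinholes, lifting mean Dice to ≈ 0.97.

The same workflows are available from the shell via the `fbseg` entry point
(`fbseg make-data`, `train`, `feedback`, `visualize`, `segment`,
`evaluate`); each subcommand accepts a flat YAML config and emits JSON-line
metrics on stdout.

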
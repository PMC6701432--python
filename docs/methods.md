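# Methods

This note records the modelling choices behind `fbseg`: the gate
reinterpretation of a CNN, the greedy feedback solvers and their
guarantees, the segmentation pipeline, what the synthetic scenes emulate,
and the numerical conventions a reader would otherwise have to reverse
engineer from the code.

## Network engine

The engine (`fbseg.net_core`) supports six layer kinds — convolution,
ReLU, max-pool, flatten, dense, softmax — in `(height, width, channels)`
layout, all in float64 numpy.  Conventions that the literature leaves open
and we had to fix:

* **Convolution is cross-correlation** (no kernel flip), stride 1, with
  `valid` (default) or zero-padded `same` padding.  Nothing downstream
  depends on the flip convention; it is fixed once and documented here.
* **Max-pool stride defaults to the window size** (non-overlapping);
  overlapping strides are supported and gradient-checked.
* **Biases** exist per conv/dense output channel.  They belong to the fixed
  affine maps, never to the gated quantities: a feedback gate multiplies a
  neuron's signal, while bias contributions flow through with an implicit
  always-open gate.  Weight init is zero-mean uniform scaled by
  `1/sqrt(fan_in)`; biases start at zero; every draw is seeded.
* The forward pass records everything the feedback machinery needs: each
  layer's input/output, each ReLU's strict-positivity pattern and each
  pool's in-window argmax (`numpy` argmax tie-break: first, i.e.
  row-major-lowest, winning position).

Training is plain mini-batch SGD on the softmax cross-entropy; no momentum,
no schedules — at this scale they buy nothing and cost determinism
bookkeeping.  Supervised training is preceded by greedy denoising
pretraining: each parameterized layer except the classifier head is trained
in sequence to reconstruct its clean input from a Gaussian-corrupted copy
through a temporary linear decoder (one dense layer); decoders are
discarded, earlier blocks stay frozen while later ones train.  The decoder
form is a deliberate minimal choice — the scheme only needs a
reconstruction path, not a symmetric autoencoder.

The default patch classifier is
`conv(5×5,1→8) → relu → pool(2) → conv(5×5,8→16) → relu → pool(2) →
flatten → dense(→64) → relu → dense(→2) → softmax` on 25×25 single-channel
patches: the smallest stack with two convolutional feedback layers that
still segments the synthetic scenes comfortably.

## Gate reinterpretation and the feedback objective

Each ReLU's `max(0, x)` and each pool's argmax selection is re-read as a
binary switch bank.  Two semantics were possible for a ReLU whose gate is
forced open on a negative pre-activation: pass the raw value, or pass its
rectification.  We pass the **raw pre-activation** (`y = z ∘ x`), because
only then is the frozen-switch network *exactly affine* in the input —
first-order expansion has zero error, gradients are state-independent, and
the objective restricted to one layer is exactly
`S = Σ_k α_k z_k x_k + const`.  The suite verifies this affineness at
random probe points, not just near the anchor.

Consequences adopted throughout:

* **Feedback layers are the ReLU layers only**; max-pool switches stay
  frozen at their feedforward argmax during optimization.  The target
  neuron is the **pre-softmax class logit** (softmax would break
  affineness; argmax is unaffected).
* **Feedforward gates**: open iff the pre-activation is strictly positive.
  A zero pre-activation gate stays closed — it cannot contribute.
* **Contribution weights** `α` are computed as a gradient query on the
  frozen-switch network, stopping at the layer's gated output (the layer's
  own gate is excluded, since it is the variable being chosen).  This
  equals the sum over connecting pathways of path-weight products; the
  equivalence is pinned by finite-difference and hand-built two-path tests.
* **Per-layer update rule**: `z_k = 1 ⇔ α_k x_k > 0`.  This is the exact
  maximizer of the layer-restricted objective, so every layer update —
  hence every FR/FS trajectory — is non-decreasing by construction, and
  with finitely many gate states the sweeps terminate.  When all gated
  inputs are non-negative (the usual situation under feedforward-reachable
  states) the rule reduces to the simpler "keep iff `α > 0`" sign rule;
  the `α x` form extends the guarantee to arbitrary gate states, where a
  forced-open gate can carry a negative raw value.  Boundary `α x = 0` →
  closed, keeping the sparsity intent of the L1-regularized formulation
  (the regularizer itself is dropped by the solvers, as zero-contribution
  gates are closed anyway; `lambda_reg` is carried in the problem object
  for API stability).
* **FR vs FS**: FR sweeps top-down and recomputes `α` after each layer
  update; FS sweeps bottom-up, and because `α` at a layer depends only on
  gates *above* it, all coefficients used within an FS sweep are those in
  force at sweep entry — the "don't re-derive coefficients mid-iteration"
  behaviour falls out structurally rather than by caching.
* **Convergence**: a sweep that changes no gate, or improves the objective
  by less than `tolerance` (default 1e-9 absolute), with a `max_sweeps`
  cap (default 10).  On all tested micro-instances both solvers converge
  within two sweeps.

Greedy ascent reaches a local optimum only; the brute-force enumerator
(`≤ 16` gates) exists to measure that gap in tests, never to stand in for
the solvers.  On instances with a single feedback layer the objective is
separable and the greedy result equals the global optimum; with two layers
the suite only asserts the bracket
`feedforward ≤ greedy ≤ exhaustive optimum`.

## Saliency

The gradient map backpropagates a unit gradient from the target logit
through the gated network to the image plane.  The visualization map
rescales it to `[0, 255]` with min/max taken **jointly over channels**
(per-channel rescaling would destroy inter-channel contrast); the division
happens before the 255 multiplication so the extremes are exactly 0
and 255.  A constant map raises an explicit degenerate-range error rather
than emitting NaNs.  The energy map sums absolute values across channels
and normalizes the whole map to unit L2 norm, making it invariant to any
nonzero rescaling of the gradient.  Maps stay real-valued; 8-bit
quantization (round-half-even) happens only at PNG export, so tests can
assert on exact real values.

## Segmentation pipeline

1. **Normalization**: whole-image min-max to `[0, 1]`.  The same per-image
   normalization is used when cutting training patches and at inference,
   so train/test intensity statistics agree.
2. **Dense prediction**: every stride-spaced pixel is classified from its
   reflect-padded 25×25 patch (reflection keeps border intensity
   statistics unbiased); with stride > 1, skipped pixels take their
   nearest evaluated centre's class.
3. **Intensity band-pass**: keep mask pixels with normalized intensity in
   `μ ± kσ` (closed interval; `k = 2` by default) of the predicted
   foreground distribution.  Operating on normalized rather than raw
   intensities keeps the band consistent with what the classifier saw.
   The stage only removes pixels; an empty input mask passes through with
   a warning rather than an error.
4. **Morphology**: opening then closing (that order by default — first
   drop specks, then fill pinholes) with a square structuring element of
   side `2·radius+1`, radius 1 by default.  Both operations are idempotent
   and opening never adds pixels; both facts are property-tested.

Metrics: Dice, IoU (`Dice = 2·IoU/(1+IoU)` is asserted as an algebraic
identity on random masks) and pixel accuracy; two empty masks score 1.0 —
correctly predicting "no lesion" is a success, not a 0/0.

Masks are `{0,1}` images with 0-based `(row, col)` coordinates; PNG mask
I/O maps 255→1.  Multi-class masks are representable via
`class_of_interest`, but the shipped pipeline and tests are binary
foreground/background.

## Synthetic scenes

Each scene is `background + (foreground − background)·mask +
inhomogeneity + noise`, clipped to `[0, 1]`:

* lesions are anti-overlapping axis-aligned ellipses (radii 5–12 px on a
  64×64 canvas, 1–3 per scene), rasterized exactly into the ground-truth
  mask — the simplest shape with a nontrivial curved boundary for the
  morphology stages to act on;
* the inhomogeneity is a sum of 2–3 low-frequency cosine components with
  seeded phases and orientations, amplitude 0.05 — a cheap, deterministic
  stand-in for the smooth bias fields of MR acquisition;
* defaults: foreground 0.75, background 0.35, noise σ = 0.08.  At these
  settings a midpoint threshold on a noiseless scene recovers the mask
  exactly (the pipeline's Dice ceiling is 1), while at the default noise
  the task is separable but not trivial for a patch classifier.

The canonical benchmark is 20 scenes split 70/30 by scene (14 train /
6 test), patch sets of 1500 per class sampled without replacement within
class, 2 pretraining epochs (noise 0.1) and 10 supervised epochs at
learning rate 0.1, batch 32.  These sizes keep a full run (including the
determinism re-run) around a minute on one CPU while leaving clear margin
over the Dice acceptance floor.

**What passing here does not show**: the scenes have piecewise-constant
tissue classes, no partial-volume boundaries, no anatomy-correlated
texture, no modality physics, and binary labels.  Results on them
demonstrate that the pipeline and its refinement stages behave as
specified — not clinical-grade segmentation; published clinical accuracy
figures require external datasets and much larger trained networks, and
are out of scope here.

## Degenerate inputs and numeric edges

* Constant images/maps: explicit `DegenerateRangeError` from
  normalization, visualization and energy maps.
* Empty initial mask: warned, propagated as empty.
* Infeasible lesion packing: `GenerationError` after 200 placement
  retries per lesion.
* Gate masks are validated for shape and binarity; brute-force enumeration
  refuses more than 16 gates; enumeration ties break toward the
  lexicographically smallest gate vector.
* Gradient checks use central differences at `eps = 1e-6` and a
  norm-relative error below 1e-4 (observed ≈ 1e-9).
* Monotonicity assertions allow a 1e-9 absolute float slack on
  mathematically non-decreasing trajectories.

## Known limitations

* Single-channel pipelines throughout (the saliency code accepts
  3-channel gradients, the generator emits grayscale only).
* Greedy feedback gives local optima; no stochastic or relaxation-based
  solver is provided.
* No data augmentation is applied in the training recipe; the benchmark
  has ample training pixels, so augmentation (e.g. elastic deformation)
  was left out rather than half-specified.
* No 3-D volumes, DICOM/NIfTI I/O, GPU execution or autodiff frameworks —
  the engine is deliberately small enough to verify by finite differences
  and exhaustive enumeration.
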
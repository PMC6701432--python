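"""Minimal convolutional-network engine with full activation tracing.

The networks built here are small stacks of convolution, rectification
(ReLU), max-pooling, flatten, dense and softmax layers operating on 2-D
grayscale (or few-channel) images in ``(height, width, channels)`` layout.
Everything is plain float64 numpy: the point of the engine is not speed but
complete access to the internal state of a forward pass — every layer's
input/output, every ReLU's on/off pattern and every max-pool's winning
position — because the feedback machinery reinterprets those selections as
binary gates.

Conventions (documented, since the field is split on them):

* convolution is cross-correlation (no kernel flip), stride 1, padding
  ``valid`` or ``same`` (zero padding);
* max-pooling stride defaults to the window size (non-overlapping);
* conv/dense layers carry a bias per output channel; biases live inside the
  fixed affine maps and are never gated;
* all randomness flows through explicit integer seeds via
  :func:`numpy.random.default_rng`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, ShapeError, TrainingError

__all__ = [
    "LayerSpec",
    "NetworkModel",
    "ActivationTrace",
    "TrainConfig",
    "build_network",
    "forward",
    "backward_input_gradient",
    "train_supervised",
    "layerwise_pretrain",
    "save_model",
    "load_model",
    "save_patches",
    "load_patches",
    "infer_shapes",
    "run_forward",
    "run_backward",
    "default_classifier_specs",
]

_KINDS = ("conv", "relu", "maxpool", "flatten", "dense", "softmax")


# ---------------------------------------------------------------------------
# layer specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer.

    Use the classmethod constructors (:meth:`conv`, :meth:`relu`, ...) rather
    than filling fields by hand; they validate the kind-specific invariants
    (kernel_size >= 1, pool window >= 2, positive dense dims).
    """

    kind: str
    kernel_size: int = 0
    in_channels: int = 0
    out_channels: int = 0
    padding: str = "valid"
    pool_size: int = 0
    stride: int = 0
    in_dim: int = 0
    out_dim: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")

    @classmethod
    def conv(cls, kernel_size: int, in_channels: int, out_channels: int,
             padding: str = "valid") -> "LayerSpec":
        if kernel_size < 1:
            raise ConfigurationError("conv kernel_size must be >= 1")
        if padding not in ("valid", "same"):
            raise ConfigurationError(f"unknown padding mode {padding!r}")
        if in_channels < 1 or out_channels < 1:
            raise ConfigurationError("conv channel counts must be >= 1")
        return cls("conv", kernel_size=kernel_size, in_channels=in_channels,
                   out_channels=out_channels, padding=padding)

    @classmethod
    def relu(cls) -> "LayerSpec":
        return cls("relu")

    @classmethod
    def maxpool(cls, pool_size: int, stride: int | None = None) -> "LayerSpec":
        if pool_size < 2:
            raise ConfigurationError("maxpool window must be >= 2")
        stride = pool_size if stride is None else stride
        if stride < 1:
            raise ConfigurationError("maxpool stride must be >= 1")
        return cls("maxpool", pool_size=pool_size, stride=stride)

    @classmethod
    def flatten(cls) -> "LayerSpec":
        return cls("flatten")

    @classmethod
    def dense(cls, in_dim: int, out_dim: int) -> "LayerSpec":
        if in_dim < 1 or out_dim < 1:
            raise ConfigurationError("dense dims must be >= 1")
        return cls("dense", in_dim=in_dim, out_dim=out_dim)

    @classmethod
    def softmax(cls) -> "LayerSpec":
        return cls("softmax")

    @property
    def has_params(self) -> bool:
        return self.kind in ("conv", "dense")


def _output_shape(spec: LayerSpec, shape: tuple[int, ...],
                  index: int) -> tuple[int, ...]:
    """Shape produced by *spec* applied to input *shape*; raises on mismatch."""

    def bad(msg: str) -> ConfigurationError:
        return ConfigurationError(
            f"layer {index} ({spec.kind}): {msg} (incoming shape {shape})")

    if spec.kind == "conv":
        if len(shape) != 3:
            raise bad("expects a (H, W, C) input")
        h, w, c = shape
        if c != spec.in_channels:
            raise bad(f"in_channels {spec.in_channels} != incoming channels {c}")
        if spec.padding == "same":
            return (h, w, spec.out_channels)
        ho, wo = h - spec.kernel_size + 1, w - spec.kernel_size + 1
        if ho < 1 or wo < 1:
            raise bad(f"kernel {spec.kernel_size} too large for {h}x{w}")
        return (ho, wo, spec.out_channels)
    if spec.kind in ("relu", "softmax"):
        return shape
    if spec.kind == "maxpool":
        if len(shape) != 3:
            raise bad("expects a (H, W, C) input")
        h, w, c = shape
        if h < spec.pool_size or w < spec.pool_size:
            raise bad(f"window {spec.pool_size} too large for {h}x{w}")
        ho = (h - spec.pool_size) // spec.stride + 1
        wo = (w - spec.pool_size) // spec.stride + 1
        return (ho, wo, c)
    if spec.kind == "flatten":
        return (int(np.prod(shape)),)
    if spec.kind == "dense":
        if len(shape) != 1:
            raise bad("expects a flat input; insert a flatten layer")
        if shape[0] != spec.in_dim:
            raise bad(f"in_dim {spec.in_dim} != incoming dim {shape[0]}")
        return (spec.out_dim,)
    raise bad("unreachable")


def infer_shapes(specs: Sequence[LayerSpec],
                 input_shape: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Per-layer output shapes; index 0 is the first layer's output."""
    shapes = []
    shape = tuple(int(s) for s in input_shape)
    for i, spec in enumerate(specs):
        shape = _output_shape(spec, shape, i)
        shapes.append(shape)
    return shapes


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """An ordered layer stack plus its parameter tensors.

    ``params[i]`` exists exactly for the conv and dense layers and holds
    ``{"W": ..., "b": ...}``; conv weights are ``(K, K, C_in, C_out)``,
    dense weights ``(in_dim, out_dim)``.
    """

    specs: tuple[LayerSpec, ...]
    params: dict[int, dict[str, np.ndarray]]
    input_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self._shapes = infer_shapes(self.specs, self.input_shape)
        for i, spec in enumerate(self.specs):
            if spec.has_params and i not in self.params:
                raise ConfigurationError(f"layer {i} ({spec.kind}) lacks params")

    @property
    def layer_shapes(self) -> list[tuple[int, ...]]:
        return list(self._shapes)

    @property
    def output_dim(self) -> int:
        return int(np.prod(self._shapes[-1]))

    @property
    def relu_layers(self) -> list[int]:
        return [i for i, s in enumerate(self.specs) if s.kind == "relu"]

    @property
    def maxpool_layers(self) -> list[int]:
        return [i for i, s in enumerate(self.specs) if s.kind == "maxpool"]

    @property
    def logits_layer(self) -> int:
        """Index of the layer producing the class logits (pre-softmax)."""
        n = len(self.specs)
        if self.specs[-1].kind == "softmax":
            return n - 2
        return n - 1

    def copy(self) -> "NetworkModel":
        params = {i: {k: v.copy() for k, v in p.items()}
                  for i, p in self.params.items()}
        return NetworkModel(self.specs, params, self.input_shape)


def build_network(specs: Sequence[LayerSpec],
                  input_shape: tuple[int, int, int],
                  seed: int,
                  weight_scale: float = 1.0) -> NetworkModel:
    """Validate the layer chain and initialize parameters.

    Weights are drawn i.i.d. uniform on ``[-a, a]`` with
    ``a = weight_scale / sqrt(fan_in)``; biases start at zero.  The draw
    order is fixed, so the same seed rebuilds bit-identical parameters.
    """
    specs = tuple(specs)
    infer_shapes(specs, input_shape)  # raises ConfigurationError on mismatch
    rng = np.random.default_rng(seed)
    params: dict[int, dict[str, np.ndarray]] = {}
    for i, spec in enumerate(specs):
        if spec.kind == "conv":
            fan_in = spec.kernel_size ** 2 * spec.in_channels
            a = weight_scale / np.sqrt(fan_in)
            w = rng.uniform(-a, a, size=(spec.kernel_size, spec.kernel_size,
                                         spec.in_channels, spec.out_channels))
            params[i] = {"W": w, "b": np.zeros(spec.out_channels)}
        elif spec.kind == "dense":
            a = weight_scale / np.sqrt(spec.in_dim)
            w = rng.uniform(-a, a, size=(spec.in_dim, spec.out_dim))
            params[i] = {"W": w, "b": np.zeros(spec.out_dim)}
    return NetworkModel(specs, params, tuple(input_shape))


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

@dataclass
class ActivationTrace:
    """Complete record of one forward pass (single image, no batch axis).

    ``relu_patterns[i]`` is the boolean positivity pattern of layer *i*'s
    pre-activation; ``pool_switches[i]`` stores, per output cell, the flat
    index (in ``[0, window**2)``) of the winning element inside its window.
    """

    inputs: list[np.ndarray]
    outputs: list[np.ndarray]
    relu_patterns: dict[int, np.ndarray]
    pool_switches: dict[int, np.ndarray]

    @property
    def output(self) -> np.ndarray:
        return self.outputs[-1]


def _conv_forward(x: np.ndarray, spec: LayerSpec, w: np.ndarray,
                  b: np.ndarray) -> np.ndarray:
    k = spec.kernel_size
    if spec.padding == "same":
        lo = (k - 1) // 2
        hi = k - 1 - lo
        x = np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,H',W',C,k,k)
    return np.einsum("nijckl,klcm->nijm", win, w, optimize=True) + b


def _conv_backward(x: np.ndarray, d_y: np.ndarray, spec: LayerSpec,
                   w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (d_x, d_w, d_b) for a stride-1 cross-correlation."""
    k = spec.kernel_size
    if spec.padding == "same":
        lo = (k - 1) // 2
        hi = k - 1 - lo
        xp = np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0)))
    else:
        lo = hi = 0
        xp = x
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    d_w = np.einsum("nijckl,nijm->klcm", win, d_y, optimize=True)
    d_b = d_y.sum(axis=(0, 1, 2))
    d_xp = np.zeros_like(xp)
    ho, wo = d_y.shape[1], d_y.shape[2]
    for u in range(k):
        for v in range(k):
            d_xp[:, u:u + ho, v:v + wo, :] += np.einsum(
                "nijm,cm->nijc", d_y, w[u, v], optimize=True)
    if lo or hi:
        d_x = d_xp[:, lo:d_xp.shape[1] - hi, lo:d_xp.shape[2] - hi, :]
    else:
        d_x = d_xp
    return d_x, d_w, d_b


def _pool_windows(x: np.ndarray, spec: LayerSpec) -> np.ndarray:
    win = sliding_window_view(x, (spec.pool_size, spec.pool_size), axis=(1, 2))
    return win[:, ::spec.stride, ::spec.stride]  # (N,H',W',C,w,w)


def _pool_gather(x: np.ndarray, spec: LayerSpec, idx: np.ndarray) -> np.ndarray:
    """Read each pooled output at its recorded in-window argmax position."""
    n = x.shape[0]
    ho, wo, c = idx.shape[-3:]
    idx_b = np.broadcast_to(idx, (n, ho, wo, c))
    rows = (np.arange(ho) * spec.stride)[None, :, None, None] + idx_b // spec.pool_size
    cols = (np.arange(wo) * spec.stride)[None, None, :, None] + idx_b % spec.pool_size
    ni = np.arange(n)[:, None, None, None]
    ci = np.arange(c)[None, None, None, :]
    return x[ni, rows, cols, ci]


def _pool_scatter(d_y: np.ndarray, x_shape: tuple[int, ...], spec: LayerSpec,
                  idx: np.ndarray) -> np.ndarray:
    n, ho, wo, c = d_y.shape
    idx_b = np.broadcast_to(idx, d_y.shape)
    rows = (np.arange(ho) * spec.stride)[None, :, None, None] + idx_b // spec.pool_size
    cols = (np.arange(wo) * spec.stride)[None, None, :, None] + idx_b % spec.pool_size
    ni = np.broadcast_to(np.arange(n)[:, None, None, None], d_y.shape)
    ci = np.broadcast_to(np.arange(c)[None, None, None, :], d_y.shape)
    d_x = np.zeros(x_shape)
    np.add.at(d_x, (ni, rows, cols, ci), d_y)
    return d_x


def _softmax(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def run_forward(model: NetworkModel, xb: np.ndarray,
                relu_gates: dict[int, np.ndarray] | None = None,
                pool_switches: dict[int, np.ndarray] | None = None,
                stop_after: int | None = None) -> list[dict]:
    """Batched forward pass; the workhorse behind both the plain and the
    gated network evaluation.

    Returns one record per layer: ``{"spec", "x", "y", "route"}`` where
    ``route`` is the ReLU multiplier pattern / pool argmax actually used (the
    information needed to re-route a backward pass identically).  When
    ``relu_gates``/``pool_switches`` supply a layer's gates or switch
    positions, the layer becomes a pure switch: ReLU passes the raw
    pre-activation wherever the gate is 1 (and 0 elsewhere), max-pool reads
    the value at the recorded position instead of recomputing the argmax.
    """
    records: list[dict] = []
    h = xb
    last = len(model.specs) - 1 if stop_after is None else stop_after
    for i, spec in enumerate(model.specs[:last + 1]):
        x = h
        route = None
        if spec.kind == "conv":
            p = model.params[i]
            y = _conv_forward(x, spec, p["W"], p["b"])
        elif spec.kind == "relu":
            if relu_gates is not None and i in relu_gates:
                z = np.asarray(relu_gates[i], dtype=float)
                if z.shape != x.shape[1:]:
                    raise ShapeError(
                        f"gate for layer {i} has shape {z.shape}, "
                        f"layer output is {x.shape[1:]}")
                y = x * z
                route = z
            else:
                mask = x > 0
                y = np.maximum(x, 0.0)
                route = mask
        elif spec.kind == "maxpool":
            if pool_switches is not None and i in pool_switches:
                idx = pool_switches[i]
                y = _pool_gather(x, spec, idx)
                route = idx
            else:
                win = _pool_windows(x, spec)
                flat = win.reshape(win.shape[:4] + (-1,))
                idx = flat.argmax(axis=-1)
                y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
                route = idx
        elif spec.kind == "flatten":
            y = x.reshape(x.shape[0], -1)
        elif spec.kind == "dense":
            p = model.params[i]
            y = x @ p["W"] + p["b"]
        elif spec.kind == "softmax":
            y = _softmax(x)
        records.append({"spec": spec, "x": x, "y": y, "route": route})
        h = y
    return records


def run_backward(model: NetworkModel, records: list[dict], d_out: np.ndarray,
                 want_param_grads: bool = False,
                 stop_layer: int = 0) -> tuple[np.ndarray, dict]:
    """Propagate ``d_out`` back through *records* down to the INPUT of layer
    ``stop_layer``; ReLU/max-pool gradients are routed by the recorded
    patterns, so the pass differentiates exactly the function the forward
    pass computed (switches frozen)."""
    grads: dict[int, dict[str, np.ndarray]] = {}
    d = d_out
    for i in range(len(records) - 1, stop_layer - 1, -1):
        rec = records[i]
        spec = rec["spec"]
        if spec.kind == "conv":
            d, d_w, d_b = _conv_backward(rec["x"], d, spec, model.params[i]["W"])
            if want_param_grads:
                grads[i] = {"W": d_w, "b": d_b}
        elif spec.kind == "relu":
            d = d * rec["route"]
        elif spec.kind == "maxpool":
            d = _pool_scatter(d, rec["x"].shape, spec, rec["route"])
        elif spec.kind == "flatten":
            d = d.reshape(rec["x"].shape)
        elif spec.kind == "dense":
            w = model.params[i]["W"]
            if want_param_grads:
                grads[i] = {"W": rec["x"].T @ d, "b": d.sum(axis=0)}
            d = d @ w.T
        elif spec.kind == "softmax":
            p = rec["y"]
            d = p * (d - (d * p).sum(axis=-1, keepdims=True))
    return d, grads


def _apply_layers(model: NetworkModel, h: np.ndarray, lo: int,
                  hi: int) -> np.ndarray:
    """Plain feedforward application of layers ``lo..hi`` (inclusive) to a
    batch; no tracing."""
    for i in range(lo, hi + 1):
        spec = model.specs[i]
        if spec.kind == "conv":
            p = model.params[i]
            h = _conv_forward(h, spec, p["W"], p["b"])
        elif spec.kind == "relu":
            h = np.maximum(h, 0.0)
        elif spec.kind == "maxpool":
            win = _pool_windows(h, spec)
            h = win.reshape(win.shape[:4] + (-1,)).max(axis=-1)
        elif spec.kind == "flatten":
            h = h.reshape(h.shape[0], -1)
        elif spec.kind == "dense":
            p = model.params[i]
            h = h @ p["W"] + p["b"]
        elif spec.kind == "softmax":
            h = _softmax(h)
    return h


def forward(model: NetworkModel, image: np.ndarray) -> ActivationTrace:
    """Standard feedforward pass with full activation tracing."""
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(model.input_shape):
        raise ShapeError(
            f"input shape {image.shape} != model input_shape {model.input_shape}")
    records = run_forward(model, image[None])
    inputs = [r["x"][0] for r in records]
    outputs = [r["y"][0] for r in records]
    relu_patterns = {i: r["route"][0] for i, r in enumerate(records)
                     if r["spec"].kind == "relu"}
    pool_switches = {i: r["route"][0] for i, r in enumerate(records)
                     if r["spec"].kind == "maxpool"}
    return ActivationTrace(inputs, outputs, relu_patterns, pool_switches)


def _records_from_trace(model: NetworkModel,
                        trace: ActivationTrace) -> list[dict]:
    records = []
    for i, spec in enumerate(model.specs):
        route = None
        if spec.kind == "relu":
            route = trace.relu_patterns[i][None]
        elif spec.kind == "maxpool":
            route = trace.pool_switches[i][None]
        records.append({"spec": spec, "x": trace.inputs[i][None],
                        "y": trace.outputs[i][None], "route": route})
    return records


def backward_input_gradient(model: NetworkModel, trace: ActivationTrace,
                            target_index: int) -> np.ndarray:
    """Gradient of the final output's ``target_index`` component with respect
    to the input pixels, with ReLU/max-pool routing frozen to the trace."""
    out = trace.output
    if not (0 <= target_index < out.shape[-1]):
        raise IndexError(
            f"target_index {target_index} out of range for output dim {out.shape[-1]}")
    records = _records_from_trace(model, trace)
    d_out = np.zeros_like(out[None])
    d_out[0, ..., target_index] = 1.0
    d_in, _ = run_backward(model, records, d_out)
    return d_in[0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters for SGD training; the seed is mandatory so that every
    run is reproducible."""

    seed: int
    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 10
    weight_scale: float = 1.0
    l2: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "images") and hasattr(dataset, "labels"):
        return np.asarray(dataset.images, dtype=float), np.asarray(dataset.labels)
    x, y = dataset
    return np.asarray(x, dtype=float), np.asarray(y)


def _sgd_update(model: NetworkModel, grads: dict, lr: float, l2: float) -> None:
    for i, g in grads.items():
        p = model.params[i]
        p["W"] -= lr * (g["W"] + l2 * p["W"])
        p["b"] -= lr * g["b"]


def train_supervised(model: NetworkModel, dataset,
                     config: TrainConfig) -> tuple[NetworkModel, list[float]]:
    """Mini-batch SGD on the softmax cross-entropy; returns a trained copy of
    the model and the per-epoch mean training loss."""
    images, labels = _as_xy(dataset)
    if images.shape[0] == 0:
        raise TrainingError("empty training dataset")
    if model.specs[-1].kind != "softmax":
        raise ConfigurationError("supervised training requires a softmax head")
    labels = labels.astype(int)
    n_classes = model.output_dim
    if labels.min() < 0 or labels.max() >= n_classes:
        raise TrainingError(
            f"labels must lie in 0..{n_classes - 1}; got range "
            f"[{labels.min()}, {labels.max()}]")

    model = model.copy()
    rng = np.random.default_rng(config.seed)
    logits_layer = model.logits_layer
    n = images.shape[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, yb = images[sel], labels[sel]
            records = run_forward(model, xb, stop_after=logits_layer)
            logits = records[-1]["y"]
            shifted = logits - logits.max(axis=1, keepdims=True)
            logz = np.log(np.exp(shifted).sum(axis=1)) + logits.max(axis=1)
            loss = float(np.mean(logz - logits[np.arange(len(yb)), yb]))
            losses.append(loss)
            probs = _softmax(logits)
            d_logits = probs.copy()
            d_logits[np.arange(len(yb)), yb] -= 1.0
            d_logits /= len(yb)
            _, grads = run_backward(model, records, d_logits,
                                    want_param_grads=True)
            _sgd_update(model, grads, config.learning_rate, config.l2)
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        history.append(epoch_loss)
    return model, history


def layerwise_pretrain(model: NetworkModel, unlabeled, noise_sigma: float,
                       config: TrainConfig) -> NetworkModel:
    """Greedy denoising pretraining of the encoder blocks.

    Each parameterized layer except the classifier head is trained in
    sequence as a denoising reconstructor: its (clean) input activations are
    corrupted with additive Gaussian noise, pushed through the block (layer +
    its following ReLU, if any), decoded by a temporary linear layer, and
    fitted by SGD to reconstruct the clean input.  Earlier blocks are frozen
    (and feed the next block its inputs) while later ones train; the decoders
    are discarded.

    The returned model carries a ``pretrain_losses`` attribute mapping each
    block's layer index to its (initial, final) clean-input reconstruction
    loss, for inspection.
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    if hasattr(unlabeled, "images"):
        images = np.asarray(unlabeled.images, dtype=float)
    else:
        images = np.asarray(unlabeled, dtype=float)
    if images.shape[0] == 0:
        raise TrainingError("empty pretraining dataset")

    model = model.copy()
    param_layers = [i for i, s in enumerate(model.specs) if s.has_params]
    blocks = param_layers[:-1]  # the final dense is the classifier head
    rng = np.random.default_rng(config.seed)

    h = images  # activations entering the next unprocessed layer
    done = 0    # layers [0, done) already applied to h
    losses: dict[int, tuple[float, float]] = {}
    for li in blocks:
        # advance h through the frozen layers preceding this block
        h = _apply_layers(model, h, done, li - 1)
        done = li
        clean_flat = h.reshape(h.shape[0], -1)

        # block = layer li (+ immediately following relu), then linear decoder
        block_specs = [model.specs[li]]
        if li + 1 < len(model.specs) and model.specs[li + 1].kind == "relu":
            block_specs.append(LayerSpec.relu())
        shapes = infer_shapes(tuple(block_specs), h.shape[1:])
        hdim = int(np.prod(shapes[-1]))
        block_specs += [LayerSpec.flatten(),
                        LayerSpec.dense(hdim, clean_flat.shape[1])]
        dec_seed = int(rng.integers(0, 2**31 - 1))
        tmp = build_network(block_specs, h.shape[1:], seed=dec_seed,
                            weight_scale=config.weight_scale)
        tmp.params[0] = {k: v.copy() for k, v in model.params[li].items()}

        def recon_loss() -> float:
            out = _apply_layers(tmp, h, 0, len(tmp.specs) - 1)
            return float(np.mean((out - clean_flat) ** 2))

        init_loss = recon_loss()
        n = h.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                sel = order[start:start + config.batch_size]
                xb = h[sel]
                noisy = xb + noise_sigma * rng.standard_normal(xb.shape)
                records = run_forward(tmp, noisy)
                out = records[-1]["y"]
                resid = out - clean_flat[sel]
                if not np.isfinite(resid).all():
                    raise TrainingError(f"non-finite reconstruction in block {bi}")
                d_out = 2.0 * resid / resid.size
                _, grads = run_backward(tmp, records, d_out,
                                        want_param_grads=True)
                _sgd_update(tmp, grads, config.learning_rate, config.l2)
        losses[li] = (init_loss, recon_loss())
        model.params[li] = {k: v.copy() for k, v in tmp.params[0].items()}
    model.pretrain_losses = losses
    return model


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path) -> None:
    """Single-file array archive: a JSON layer-spec header + parameter
    tensors; the round trip is bit-exact."""
    header = json.dumps({
        "input_shape": list(model.input_shape),
        "specs": [dataclasses.asdict(s) for s in model.specs],
    })
    arrays = {"header": np.array(header)}
    for i, p in model.params.items():
        arrays[f"W{i}"] = p["W"]
        arrays[f"b{i}"] = p["b"]
    np.savez(path, **arrays)


def load_model(path) -> NetworkModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["header"][()]))
        specs = tuple(LayerSpec(**s) for s in meta["specs"])
        params = {}
        for i, spec in enumerate(specs):
            if spec.has_params:
                params[i] = {"W": npz[f"W{i}"], "b": npz[f"b{i}"]}
    return NetworkModel(specs, params, tuple(meta["input_shape"]))


def save_patches(path, images: np.ndarray, labels: np.ndarray) -> None:
    np.savez(path, images=np.asarray(images), labels=np.asarray(labels))


def load_patches(path) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path, allow_pickle=False) as npz:
        return npz["images"], npz["labels"]


def default_classifier_specs(n_classes: int = 2,
                             patch_size: int = 25) -> list[LayerSpec]:
    """The repository's default patch classifier: two conv/ReLU/pool stages,
    a 64-unit hidden dense layer and a softmax head, on single-channel
    ``patch_size`` square inputs."""
    shape = (patch_size, patch_size, 1)
    specs = [
        LayerSpec.conv(5, 1, 8),
        LayerSpec.relu(),
        LayerSpec.maxpool(2),
        LayerSpec.conv(5, 8, 16),
        LayerSpec.relu(),
        LayerSpec.maxpool(2),
        LayerSpec.flatten(),
    ]
    flat = int(np.prod(infer_shapes(tuple(specs), shape)[-1]))
    specs += [
        LayerSpec.dense(flat, 64),
        LayerSpec.relu(),
        LayerSpec.dense(64, n_classes),
        LayerSpec.softmax(),
    ]
    return specs
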
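"""Gate-switch reinterpretation of ReLU/max layers and greedy feedback
optimization.

A trained feedforward CNN selects information bottom-up: each ReLU passes a
neuron iff its pre-activation is positive, each max-pool passes the largest
element of its window.  Both selections can be read as banks of binary
switches ("feedback neurons") multiplying the signal.  Given a target output
neuron (a class logit), the feedback problem asks for the switch
configuration Z that maximizes that logit — top-down attention: only the
pathways that support the target stay open.

Exact maximization over Z is combinatorial, so two greedy layer-by-layer
schemes are provided:

* **Feedback Recovery (FR)** sweeps the ReLU (feedback) layers from the top
  (nearest the output) down, re-deriving each layer's contribution weights
  under the gate state produced by the layers already updated in the sweep.
* **Feedback Selective (FS)** sweeps bottom-up; because a layer's
  contribution weights depend only on the gates *above* it, the coefficients
  a sweep uses are exactly those in force when the sweep began — they are
  never re-derived mid-sweep.

Both work on the *linearized* network: with every ReLU replaced by a pure
switch (y = z∘x on the raw pre-activation) and every max-pool frozen to its
feedforward argmax, the image→logit map is affine, so the target logit
restricted to one layer's gates is S = Σ_k α_k z_k x_k + const with
contribution weight α_k = ∂S/∂(gated output k).  Each layer visit sets
z_k = 1 iff α_k·x_k > 0, the exact maximizer of that expression, which makes
the objective trajectory non-decreasing and the sweeps terminate.

A brute-force enumeration over all 2^n gate configurations is included as an
independent test oracle for small problems.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GateBudgetError, ShapeError
from .net_core import (ActivationTrace, NetworkModel, forward, run_backward,
                       run_forward)

__all__ = [
    "GateState",
    "FeedbackProblem",
    "ContributionMap",
    "FeedbackResult",
    "gates_from_trace",
    "gated_forward",
    "linearize",
    "LinearizedNetwork",
    "contributions",
    "objective",
    "feedback_recovery",
    "feedback_selective",
    "brute_force_gate_search",
    "save_gates",
    "load_gates",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gate state
# ---------------------------------------------------------------------------

@dataclass
class GateState:
    """Binary masks for every ReLU (feedback) layer plus the recorded
    max-pool switch positions.

    ``relu_gates[i]`` is a {0,1} float array shaped like layer *i*'s output;
    ``max_switches[i]`` stores each pooled cell's winning in-window flat
    index.  ``provenance`` records how the state was produced
    (feedforward / fr / fs / manual).
    """

    relu_gates: dict[int, np.ndarray]
    max_switches: dict[int, np.ndarray]
    provenance: str = "manual"

    def copy(self) -> "GateState":
        return GateState({i: g.copy() for i, g in self.relu_gates.items()},
                         {i: s.copy() for i, s in self.max_switches.items()},
                         self.provenance)

    def closed_fraction(self) -> dict[int, float]:
        return {i: float(1.0 - g.mean()) for i, g in self.relu_gates.items()}

    def n_gates(self) -> int:
        return int(sum(g.size for g in self.relu_gates.values()))


def gates_from_trace(trace: ActivationTrace) -> GateState:
    """Feedforward gate state: a ReLU gate is open iff its pre-activation is
    strictly positive (ties at zero stay closed); max switches are copied."""
    gates = {i: (pre > 0).astype(float)
             for i, pre in trace.relu_patterns.items()}
    switches = {i: s.copy() for i, s in trace.pool_switches.items()}
    return GateState(gates, switches, provenance="feedforward")


@dataclass
class FeedbackProblem:
    """One feedback-optimization instance.

    ``lambda_reg`` is the L1 sparsity weight of the full feedback objective;
    the greedy solvers work on the simplified objective that drops the
    regularizer (zero-contribution gates are closed anyway), so the value is
    carried for API stability but unused by FR/FS.
    """

    model: NetworkModel
    image: np.ndarray
    target_index: int
    lambda_reg: float = 0.0
    max_sweeps: int = 10
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        n_out = int(np.prod(self.model.layer_shapes[self.model.logits_layer]))
        if not (0 <= self.target_index < n_out):
            raise IndexError(
                f"target_index {self.target_index} out of range "
                f"for {n_out} output neurons")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class ContributionMap:
    """Per-neuron contribution weights α for one feedback layer: the partial
    derivative of the target logit w.r.t. each neuron's gated output through
    the currently gated pathways above the layer."""

    layer_id: int
    alpha: np.ndarray


@dataclass
class FeedbackResult:
    gates: GateState
    objective_trajectory: list[float]
    sweeps_used: int
    converged: bool
    closed_fraction: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gated evaluation and linearization
# ---------------------------------------------------------------------------

def _check_gates(model: NetworkModel, gates: GateState) -> None:
    shapes = model.layer_shapes
    for i, g in gates.relu_gates.items():
        if model.specs[i].kind != "relu":
            raise ShapeError(f"layer {i} is not a ReLU layer")
        if g.shape != shapes[i]:
            raise ShapeError(
                f"gate mask for layer {i} has shape {g.shape}, expected {shapes[i]}")
        vals = np.unique(g)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ShapeError(f"gate mask for layer {i} is not binary")


def gated_forward(model: NetworkModel, image: np.ndarray, gates: GateState,
                  return_records: bool = False):
    """Evaluate the network with every ReLU realized purely by its switch
    (y = z∘pre-activation) and every max-pool reading its recorded position.

    With the feedforward gate state this reproduces the plain forward pass
    exactly; with arbitrary gates it evaluates the linearized network the
    feedback objective is defined on.  Returns the final output (softmax
    included if present), optionally with the full layer records.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(model.input_shape):
        raise ShapeError(
            f"input shape {image.shape} != model input_shape {model.input_shape}")
    _check_gates(model, gates)
    records = run_forward(model, image[None],
                          relu_gates=gates.relu_gates,
                          pool_switches=gates.max_switches)
    out = records[-1]["y"][0]
    if return_records:
        return out, records
    return out


@dataclass
class LinearizedNetwork:
    """The network with all switches frozen at a given gate state.

    The map input → target logit is then affine, so first-order expansion
    around the anchor image is exact and gradients are state-independent.
    """

    model: NetworkModel
    image: np.ndarray
    gates: GateState
    records: list = field(repr=False, default=None)
    target_index: int | None = None

    @property
    def logits_layer(self) -> int:
        return self.model.logits_layer

    def value(self, target_index: int, image: np.ndarray | None = None) -> float:
        """Target logit of the frozen-switch network at ``image`` (defaults
        to the anchor)."""
        img = self.image if image is None else np.asarray(image, dtype=float)
        records = run_forward(self.model, img[None],
                              relu_gates=self.gates.relu_gates,
                              pool_switches=self.gates.max_switches,
                              stop_after=self.logits_layer)
        return float(records[-1]["y"][0, target_index])

    def gradient_wrt_input(self, target_index: int) -> np.ndarray:
        d_out = np.zeros((1,) + self.records[self.logits_layer]["y"].shape[1:])
        d_out[0, target_index] = 1.0
        d_in, _ = run_backward(self.model, self.records[:self.logits_layer + 1],
                               d_out)
        return d_in[0]

    def gradient_wrt_layer_output(self, layer_id: int,
                                  target_index: int) -> np.ndarray:
        """∂(target logit)/∂(layer ``layer_id`` output), switches frozen,
        i.e. through the gated pathways strictly above ``layer_id``."""
        d_out = np.zeros((1,) + self.records[self.logits_layer]["y"].shape[1:])
        d_out[0, target_index] = 1.0
        d, _ = run_backward(self.model, self.records[:self.logits_layer + 1],
                            d_out, stop_layer=layer_id + 1)
        return d[0]


def linearize(model: NetworkModel, image: np.ndarray, gates: GateState,
              target_index: int | None = None) -> LinearizedNetwork:
    """Freeze all ReLU/max switches at ``gates`` and return the resulting
    affine view of the network, anchored at ``image``."""
    image = np.asarray(image, dtype=float)
    _check_gates(model, gates)
    records = run_forward(model, image[None],
                          relu_gates=gates.relu_gates,
                          pool_switches=gates.max_switches)
    return LinearizedNetwork(model, image, gates, records, target_index)


def contributions(linearized: LinearizedNetwork, layer_id: int,
                  target_index: int | None = None) -> ContributionMap:
    """Contribution weights α of one feedback (ReLU) layer: the gradient of
    the target logit w.r.t. that layer's gated outputs, equivalently the sum
    over all connecting pathways above the layer of their weight products."""
    if linearized.model.specs[layer_id].kind != "relu":
        raise ValueError(f"layer {layer_id} is not a feedback (ReLU) layer")
    if target_index is None:
        target_index = linearized.target_index
    if target_index is None:
        raise ValueError("no target neuron: pass target_index or linearize "
                         "with one")
    alpha = linearized.gradient_wrt_layer_output(layer_id, target_index)
    return ContributionMap(layer_id, alpha)


def objective(model: NetworkModel, image: np.ndarray, gates: GateState,
              target_index: int) -> float:
    """The feedback objective S: the target logit of the gated (linearized)
    network.  With the feedforward gate state this equals the plain forward
    target logit."""
    records = run_forward(model, np.asarray(image, dtype=float)[None],
                          relu_gates=gates.relu_gates,
                          pool_switches=gates.max_switches,
                          stop_after=model.logits_layer)
    return float(records[-1]["y"][0, target_index])


# ---------------------------------------------------------------------------
# greedy feedback optimizers
# ---------------------------------------------------------------------------

def _greedy_feedback(problem: FeedbackProblem, top_down: bool,
                     provenance: str) -> FeedbackResult:
    model, image = problem.model, problem.image
    trace = forward(model, image)
    gates = gates_from_trace(trace)
    gates.provenance = provenance
    feedback_layers = [i for i in model.relu_layers
                       if i <= model.logits_layer]
    order = sorted(feedback_layers, reverse=top_down)

    traj = [objective(model, image, gates, problem.target_index)]
    converged = False
    sweeps = 0
    for sweep in range(problem.max_sweeps):
        sweeps = sweep + 1
        sweep_start = traj[-1]
        changed = False
        for li in order:
            lin = linearize(model, image, gates, problem.target_index)
            alpha = contributions(lin, li).alpha
            x = lin.records[li]["x"][0]  # raw pre-activation entering the gate
            new_z = (alpha * x > 0).astype(float)
            if not np.array_equal(new_z, gates.relu_gates[li]):
                changed = True
            gates.relu_gates[li] = new_z
            s = objective(model, image, gates, problem.target_index)
            if not np.isfinite(s):
                raise FloatingPointError(
                    f"non-finite feedback objective at layer {li}")
            traj.append(s)
            logger.info("%s sweep %d layer %d: S = %.6g",
                        provenance.upper(), sweep + 1, li, s)
        if not changed or (traj[-1] - sweep_start) < problem.tolerance:
            converged = True
            break
    return FeedbackResult(gates, traj, sweeps, converged,
                          gates.closed_fraction())


def feedback_recovery(problem: FeedbackProblem) -> FeedbackResult:
    """Top-down greedy feedback optimization (FR).

    Sweeps the feedback layers from the one nearest the output downwards;
    each layer's contribution weights are recomputed under the gate state
    left by the layers already visited, the layer's gates are set to the
    per-layer maximizer, and the linearized objective is recorded after
    every layer update.  The trajectory is non-decreasing and the sweep loop
    stops when a sweep changes no gate (or improves less than the
    tolerance)."""
    return _greedy_feedback(problem, top_down=True, provenance="fr")


def feedback_selective(problem: FeedbackProblem) -> FeedbackResult:
    """Bottom-up greedy feedback optimization (FS).

    Identical per-layer update, but layers are visited from the input
    upwards.  A layer's contribution weights depend only on gates above it,
    so every coefficient used within a sweep is the one in force when the
    sweep entered that layer — coefficients are never re-derived mid-sweep
    for already-visited layers."""
    return _greedy_feedback(problem, top_down=False, provenance="fs")


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_gate_search(problem: FeedbackProblem,
                            gate_budget: int = 16) -> tuple[GateState, float]:
    """Exhaustive enumeration of all 2^n ReLU-gate configurations (max-pool
    switches frozen at their feedforward positions); returns the argmax of
    the linearized objective.  Ties break toward the lexicographically
    smallest gate vector.  Intended purely as a test oracle — refuses more
    than ``gate_budget`` gates."""
    model, image = problem.model, problem.image
    trace = forward(model, image)
    ff = gates_from_trace(trace)
    n = ff.n_gates()
    if n > gate_budget:
        raise GateBudgetError(
            f"{n} optimizable gates exceed the brute-force budget {gate_budget}")
    layers = sorted(ff.relu_gates)
    shapes = {i: ff.relu_gates[i].shape for i in layers}
    sizes = [ff.relu_gates[i].size for i in layers]

    best_bits = None
    best_val = -np.inf
    gates = ff.copy()
    for bits in itertools.product((0.0, 1.0), repeat=n):
        pos = 0
        for i, sz in zip(layers, sizes):
            gates.relu_gates[i] = np.asarray(
                bits[pos:pos + sz]).reshape(shapes[i])
            pos += sz
        val = objective(model, image, gates, problem.target_index)
        if val > best_val:  # strict: first (lexicographically smallest) wins
            best_val = val
            best_bits = bits
    pos = 0
    best = ff.copy()
    best.provenance = "manual"
    for i, sz in zip(layers, sizes):
        best.relu_gates[i] = np.asarray(
            best_bits[pos:pos + sz]).reshape(shapes[i])
        pos += sz
    return best, float(best_val)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_gates(gates: GateState, path) -> None:
    arrays = {"provenance": np.array(gates.provenance)}
    for i, g in gates.relu_gates.items():
        arrays[f"relu{i}"] = g
    for i, s in gates.max_switches.items():
        arrays[f"pool{i}"] = s
    np.savez(path, **arrays)


def load_gates(path) -> GateState:
    relu, pool = {}, {}
    with np.load(path, allow_pickle=False) as npz:
        prov = str(npz["provenance"][()])
        for key in npz.files:
            if key.startswith("relu"):
                relu[int(key[4:])] = npz[key]
            elif key.startswith("pool"):
                pool[int(key[4:])] = npz[key]
    return GateState(relu, pool, prov)
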
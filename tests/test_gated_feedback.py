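"""Tests for the gate reinterpretation, linearization, contribution weights
and the greedy feedback optimizers, checked against finite differences and
exhaustive gate enumeration."""

import numpy as np
import pytest

from fbseg.exceptions import GateBudgetError, ShapeError
from fbseg.gated_feedback import (FeedbackProblem, GateState,
                                  brute_force_gate_search, contributions,
                                  feedback_recovery, feedback_selective,
                                  gated_forward, gates_from_trace, linearize,
                                  load_gates, objective, save_gates)
from fbseg.net_core import LayerSpec, build_network, forward
from helpers import (fd_gradient, micro_conv_net, micro_pool_net,
                     micro_single_relu_net, rel_err)


def _logit(model, trace, k):
    return trace.outputs[model.logits_layer][k]


# ---------------------------------------------------------------------------
# gates from the feedforward pass
# ---------------------------------------------------------------------------

class TestGatesFromTrace:
    def test_positivity_pattern(self):
        model = build_network([LayerSpec.relu()], (1, 1, 3), seed=0)
        trace = forward(model, np.array([[[-1.0, 0.0, 2.0]]]))
        gates = gates_from_trace(trace)
        # the zero pre-activation gate stays closed
        assert np.array_equal(gates.relu_gates[0], [[[0.0, 0.0, 1.0]]])
        assert gates.provenance == "feedforward"

    def test_all_positive_gives_all_ones(self):
        model = build_network([LayerSpec.relu()], (1, 1, 4), seed=0)
        trace = forward(model, np.ones((1, 1, 4)))
        assert gates_from_trace(trace).relu_gates[0].min() == 1.0


class TestGatedForward:
    @pytest.mark.parametrize("factory,shape", [
        (micro_conv_net, (4, 4, 1)), (micro_pool_net, (5, 5, 1))])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_consistency_identity(self, factory, shape, seed):
        """Feedforward gates reproduce the plain forward pass exactly:
        ReLU/max selection is fully captured by the switches."""
        model = factory(seed)
        img = np.random.default_rng(seed).standard_normal(shape)
        trace = forward(model, img)
        out = gated_forward(model, img, gates_from_trace(trace))
        assert np.array_equal(out, trace.output)

    def test_all_closed_zero_bias_gives_zero_logits(self):
        model = micro_conv_net(2)  # biases are zero at initialization
        img = np.random.default_rng(0).standard_normal((4, 4, 1))
        gates = gates_from_trace(forward(model, img))
        for i in gates.relu_gates:
            gates.relu_gates[i] = np.zeros_like(gates.relu_gates[i])
        assert objective(model, img, gates, 0) == 0.0

    def test_hand_set_gate_pattern_matches_hand_computation(self):
        # 1 -> dense(w=2) -> relu gate z -> dense(w=3): logit = 6z
        model = build_network([LayerSpec.dense(1, 1), LayerSpec.relu(),
                               LayerSpec.dense(1, 1)], (1,), seed=0)
        model.params[0]["W"] = np.array([[2.0]])
        model.params[2]["W"] = np.array([[3.0]])
        trace = forward(model, np.array([1.0]))
        gates = gates_from_trace(trace)
        assert gated_forward(model, np.array([1.0]), gates) == [6.0]
        gates.relu_gates[1] = np.array([0.0])
        assert gated_forward(model, np.array([1.0]), gates) == [0.0]

    def test_wrong_gate_shape_rejected(self):
        model = micro_conv_net(0)
        img = np.zeros((4, 4, 1))
        gates = gates_from_trace(forward(model, img))
        gates.relu_gates[1] = np.zeros((3, 3, 2))
        with pytest.raises(ShapeError):
            gated_forward(model, img, gates)


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

class TestLinearize:
    def test_exact_at_anchor(self):
        model = micro_pool_net(3)
        img = np.random.default_rng(3).standard_normal((5, 5, 1))
        gates = gates_from_trace(forward(model, img))
        lin = linearize(model, img, gates)
        assert lin.value(0) == objective(model, img, gates, 0)

    def test_homogeneity_with_zero_bias(self):
        """With frozen switches and zero biases the logit map is linear."""
        model = micro_conv_net(4)
        img = np.random.default_rng(4).standard_normal((4, 4, 1))
        gates = gates_from_trace(forward(model, img))
        lin = linearize(model, img, gates)
        assert lin.value(1, 2.0 * img) == pytest.approx(2.0 * lin.value(1),
                                                        rel=1e-12)

    def test_affine_in_input(self):
        """First-order expansion of the frozen-switch network is exact at
        arbitrary probe points, not just near the anchor."""
        model = micro_pool_net(5)
        rng = np.random.default_rng(5)
        img = rng.standard_normal((5, 5, 1))
        gates = gates_from_trace(forward(model, img))
        lin = linearize(model, img, gates)
        g = lin.gradient_wrt_input(0)
        for _ in range(5):
            probe = rng.standard_normal((5, 5, 1))
            predicted = lin.value(0) + float(((probe - img) * g).sum())
            assert lin.value(0, probe) == pytest.approx(predicted, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        model = micro_conv_net(6)
        img = np.random.default_rng(6).standard_normal((4, 4, 1))
        gates = gates_from_trace(forward(model, img))
        lin = linearize(model, img, gates)
        fd = fd_gradient(lambda x: objective(model, x, gates, 1), img)
        assert rel_err(lin.gradient_wrt_input(1), fd) < 1e-4


# ---------------------------------------------------------------------------
# contribution weights
# ---------------------------------------------------------------------------

class TestContributions:
    def test_two_path_toy(self):
        """A hidden neuron reaching the target along two weighted paths has
        contribution w1*w3 + w2*w4 (path-weight product sum)."""
        specs = [LayerSpec.dense(1, 1), LayerSpec.relu(),
                 LayerSpec.dense(1, 2), LayerSpec.relu(),
                 LayerSpec.dense(2, 1)]
        model = build_network(specs, (1,), seed=0)
        model.params[0]["W"] = np.array([[1.0]])
        model.params[2]["W"] = np.array([[2.0, 3.0]])  # w1, w2
        model.params[4]["W"] = np.array([[1.0], [4.0]])  # w3, w4
        img = np.array([1.0])
        gates = gates_from_trace(forward(model, img))
        lin = linearize(model, img, gates, target_index=0)
        alpha = contributions(lin, 1).alpha
        assert alpha == pytest.approx([2.0 * 1.0 + 3.0 * 4.0])
        # finite-difference oracle: perturb the gated output of layer 1
        eps = 1e-6
        base = objective(model, img, gates, 0)
        pert = objective(model, img + 0, gates, 0)  # sanity: deterministic
        assert base == pert
        # vary the neuron's input through the input pixel (weight 1 chain)
        fd = (objective(model, img + eps, gates, 0)
              - objective(model, img - eps, gates, 0)) / (2 * eps)
        assert fd == pytest.approx(alpha[0], rel=1e-6)

    def test_single_chain_alpha_is_weight(self):
        specs = [LayerSpec.dense(1, 1), LayerSpec.relu(),
                 LayerSpec.dense(1, 1)]
        model = build_network(specs, (1,), seed=0)
        model.params[0]["W"] = np.array([[1.0]])
        model.params[2]["W"] = np.array([[5.0]])
        img = np.array([1.0])
        lin = linearize(model, img, gates_from_trace(forward(model, img)), 0)
        assert contributions(lin, 1).alpha == pytest.approx([5.0])

    def test_closed_upward_gates_zero_alpha(self):
        specs = [LayerSpec.dense(1, 2), LayerSpec.relu(),
                 LayerSpec.dense(2, 2), LayerSpec.relu(),
                 LayerSpec.dense(2, 1)]
        model = build_network(specs, (1,), seed=1, weight_scale=2.0)
        img = np.array([1.0])
        gates = gates_from_trace(forward(model, img))
        gates.relu_gates[3] = np.zeros_like(gates.relu_gates[3])
        lin = linearize(model, img, gates, 0)
        assert np.allclose(contributions(lin, 1).alpha, 0.0)

    def test_non_feedback_layer_rejected(self):
        model = micro_conv_net(0)
        img = np.zeros((4, 4, 1))
        lin = linearize(model, img, gates_from_trace(forward(model, img)), 0)
        with pytest.raises(ValueError, match="not a feedback"):
            contributions(lin, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_decomposes_over_layer(self, seed):
        """S = sum_k alpha_k z_k x_k + const for every feedback layer: the
        linearized objective is affine in each layer's gated outputs."""
        model = micro_conv_net(seed)
        img = np.random.default_rng(seed + 50).standard_normal((4, 4, 1))
        gates = gates_from_trace(forward(model, img))
        for li in model.relu_layers:
            lin = linearize(model, img, gates, 0)
            alpha = contributions(lin, li).alpha
            x = lin.records[li]["x"][0]
            z = gates.relu_gates[li]
            closed = gates.copy()
            closed.relu_gates[li] = np.zeros_like(z)
            const = objective(model, img, closed, 0)
            s = objective(model, img, gates, 0)
            assert s == pytest.approx(const + float((alpha * z * x).sum()),
                                      abs=1e-9)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class TestObjective:
    def test_feedforward_gates_equal_forward_logit(self):
        model = micro_pool_net(8)
        img = np.random.default_rng(8).standard_normal((5, 5, 1))
        trace = forward(model, img)
        gates = gates_from_trace(trace)
        for k in range(2):
            assert objective(model, img, gates, k) == _logit(model, trace, k)


# ---------------------------------------------------------------------------
# greedy optimizers
# ---------------------------------------------------------------------------

class TestFeedbackOptimizers:
    def _positive_net(self):
        """All-positive weights: every contribution is non-negative."""
        specs = [LayerSpec.dense(2, 3), LayerSpec.relu(),
                 LayerSpec.dense(3, 2), LayerSpec.softmax()]
        model = build_network(specs, (2,), seed=0)
        rng = np.random.default_rng(0)
        for i in (0, 2):
            model.params[i]["W"] = rng.uniform(0.1, 1.0,
                                               model.params[i]["W"].shape)
        return model

    def test_all_positive_alpha_keeps_gates(self):
        model = self._positive_net()
        img = np.array([1.0, 2.0])
        res = feedback_recovery(FeedbackProblem(model, img, 0))
        ff = gates_from_trace(forward(model, img))
        assert np.array_equal(res.gates.relu_gates[1], ff.relu_gates[1])
        assert res.converged and res.sweeps_used == 1
        traj = res.objective_trajectory
        assert max(traj) - min(traj) < 1e-12

    def test_fs_positive_net_closes_nothing(self):
        model = self._positive_net()
        img = np.array([0.5, 1.5])
        res = feedback_selective(FeedbackProblem(model, img, 1))
        ff = gates_from_trace(forward(model, img))
        assert np.array_equal(res.gates.relu_gates[1], ff.relu_gates[1])

    def test_single_feedback_layer_fr_equals_fs(self):
        for seed in range(4):
            model = micro_single_relu_net(seed)
            img = np.random.default_rng(seed + 10).standard_normal((4, 4, 1))
            fr = feedback_recovery(FeedbackProblem(model, img, 0))
            fs = feedback_selective(FeedbackProblem(model, img, 0))
            assert np.array_equal(fr.gates.relu_gates[1],
                                  fs.gates.relu_gates[1])

    @pytest.mark.parametrize("solver", [feedback_recovery, feedback_selective])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_monotone_and_bounded_by_oracle(self, solver, seed):
        model = micro_conv_net(seed)
        img = np.random.default_rng(seed + 20).standard_normal((4, 4, 1))
        problem = FeedbackProblem(model, img, seed % 3)
        res = solver(problem)
        traj = np.array(res.objective_trajectory)
        assert np.all(np.diff(traj) >= -1e-9)
        assert res.converged
        _, opt = brute_force_gate_search(
            FeedbackProblem(model, img, seed % 3), gate_budget=12)
        assert traj[0] <= traj[-1] + 1e-9
        assert traj[-1] <= opt + 1e-9

    def test_target_out_of_range(self):
        model = micro_conv_net(0)
        with pytest.raises(IndexError):
            FeedbackProblem(model, np.zeros((4, 4, 1)), 7)


class TestBruteForce:
    def test_budget_refusal_counts_gates(self):
        model = micro_conv_net(0)  # 12 gates
        problem = FeedbackProblem(model, np.zeros((4, 4, 1)), 0)
        with pytest.raises(GateBudgetError, match="12"):
            brute_force_gate_search(problem, gate_budget=8)

    def test_one_gate_sign_rule(self):
        # logit = 5 * z * x with x = 1 > 0: open wins
        specs = [LayerSpec.dense(1, 1), LayerSpec.relu(),
                 LayerSpec.dense(1, 1)]
        model = build_network(specs, (1,), seed=0)
        model.params[0]["W"] = np.array([[1.0]])
        model.params[2]["W"] = np.array([[5.0]])
        best, val = brute_force_gate_search(
            FeedbackProblem(model, np.array([1.0]), 0), gate_budget=1)
        assert val == 5.0 and best.relu_gates[1] == [1.0]

    def test_separable_layer_matches_per_gate_sign_rule(self):
        """With one feedback layer the optimum opens exactly the gates whose
        contribution-weighted input is positive."""
        for seed in range(3):
            model = micro_single_relu_net(seed)
            img = np.random.default_rng(seed).standard_normal((4, 4, 1))
            problem = FeedbackProblem(model, img, 1)
            best, opt = brute_force_gate_search(problem, gate_budget=8)
            gates = gates_from_trace(forward(model, img))
            lin = linearize(model, img, gates, 1)
            alpha = contributions(lin, 1).alpha
            x = lin.records[1]["x"][0]
            expect = (alpha * x > 0).astype(float)
            assert np.array_equal(best.relu_gates[1], expect)
            fr = feedback_recovery(problem)
            assert fr.objective_trajectory[-1] == pytest.approx(opt, abs=1e-9)


def test_gate_roundtrip(tmp_path):
    model = micro_pool_net(1)
    img = np.random.default_rng(1).standard_normal((5, 5, 1))
    gates = gates_from_trace(forward(model, img))
    save_gates(gates, tmp_path / "g.npz")
    loaded = load_gates(tmp_path / "g.npz")
    assert loaded.provenance == gates.provenance
    for i in gates.relu_gates:
        assert np.array_equal(gates.relu_gates[i], loaded.relu_gates[i])
    for i in gates.max_switches:
        assert np.array_equal(gates.max_switches[i], loaded.max_switches[i])
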
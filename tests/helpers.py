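"""Shared fixtures-in-code: micro-network factories and independent
finite-difference / enumeration oracles used across the suite."""

import numpy as np

from fbseg.net_core import LayerSpec, NetworkModel, build_network


def micro_conv_net(seed: int, weight_scale: float = 2.0) -> NetworkModel:
    """Two feedback (ReLU) layers, 12 gates total: conv on 4x4 input plus a
    small dense stack.  Small enough for exhaustive gate enumeration."""
    specs = [
        LayerSpec.conv(3, 1, 2),
        LayerSpec.relu(),
        LayerSpec.flatten(),
        LayerSpec.dense(8, 4),
        LayerSpec.relu(),
        LayerSpec.dense(4, 3),
        LayerSpec.softmax(),
    ]
    return build_network(specs, (4, 4, 1), seed=seed, weight_scale=weight_scale)


def micro_pool_net(seed: int, weight_scale: float = 2.0) -> NetworkModel:
    """Micro-net exercising max-pooling: 11 gates over two ReLU layers."""
    specs = [
        LayerSpec.conv(2, 1, 2),
        LayerSpec.maxpool(2),
        LayerSpec.relu(),
        LayerSpec.flatten(),
        LayerSpec.dense(8, 3),
        LayerSpec.relu(),
        LayerSpec.dense(3, 2),
        LayerSpec.softmax(),
    ]
    return build_network(specs, (5, 5, 1), seed=seed, weight_scale=weight_scale)


def micro_single_relu_net(seed: int, weight_scale: float = 2.0) -> NetworkModel:
    """Exactly one feedback layer (8 gates): the per-layer objective is
    separable, so greedy updates must reach the global optimum."""
    specs = [
        LayerSpec.conv(3, 1, 2),
        LayerSpec.relu(),
        LayerSpec.flatten(),
        LayerSpec.dense(8, 3),
        LayerSpec.softmax(),
    ]
    return build_network(specs, (4, 4, 1), seed=seed, weight_scale=weight_scale)


def fd_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def rel_err(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    denom = max(np.linalg.norm(a), np.linalg.norm(b), 1e-12)
    return float(np.linalg.norm(a - b) / denom)
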
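"""Visualization and energy maps from a converged feedback gate state.

Once the feedback optimization has screened the target-relevant neurons,
the gradient of the target logit is propagated through the gated network
back to the image plane ("the gradient of the target neuron is set to 1").
Two summaries of that gradient map are produced:

* a **visualization map** — a per-map min-max rescale to [0, 255] for
  direct grayscale display;
* an **energy map** — the per-pixel channel-wise sum of absolute gradient
  values, normalized so the whole map has unit L2 norm; a scale-invariant
  measure of each pixel's relevance to the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateRangeError
from .gated_feedback import GateState, linearize
from .net_core import NetworkModel

__all__ = ["GradientMap", "EnergyMap", "gradient_map", "visualization_map",
           "energy_map", "export_png", "export_energy"]


@dataclass
class GradientMap:
    """∂(target logit)/∂(input pixels) through a gated network; same
    height/width/channels as the input image."""

    values: np.ndarray


@dataclass
class EnergyMap:
    """Single-channel non-negative relevance map with unit L2 norm."""

    values: np.ndarray


def gradient_map(model: NetworkModel, image: np.ndarray, gates: GateState,
                 target_index: int) -> GradientMap:
    """Backpropagate a unit gradient from the target logit to the image
    plane, with all ReLU/max switches frozen at ``gates``."""
    lin = linearize(model, image, gates, target_index)
    return GradientMap(lin.gradient_wrt_input(target_index))


def visualization_map(g: GradientMap) -> np.ndarray:
    """Min-max rescale of the gradient map to [0, 255]: 255·(x−min)/(max−min),
    with min/max taken jointly over all channels.  Values stay real; 8-bit
    quantization happens only at PNG export."""
    v = np.asarray(g.values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateRangeError(
            "constant gradient map: min-max rescale is undefined")
    # divide before scaling so the extremes map to exactly 0 and 255
    return (v - lo) / (hi - lo) * 255.0


def energy_map(g: GradientMap) -> EnergyMap:
    """Channel-absolute-sum of the gradient map, L2-normalized over the
    whole image.  Invariant to rescaling of the gradient map."""
    v = np.asarray(g.values, dtype=float)
    if v.ndim == 2:
        e = np.abs(v)
    else:
        e = np.abs(v).sum(axis=-1)
    norm = float(np.sqrt((e ** 2).sum()))
    if norm == 0.0:
        raise DegenerateRangeError(
            "all-zero gradient map: energy normalization is undefined")
    return EnergyMap(e / norm)


def export_png(values: np.ndarray, path) -> None:
    """Write a real-valued map in [0, 255] as 8-bit grayscale PNG
    (round-half-even quantization)."""
    import imageio.v3 as iio

    arr = np.rint(np.asarray(values, dtype=float)).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    iio.imwrite(path, arr, extension=".png")


def export_energy(em: EnergyMap, path) -> None:
    np.savez(path, energy=em.values)
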
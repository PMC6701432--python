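"""Synthetic lesion-bearing grayscale scenes with pixel-accurate masks.

The generator emulates the statistical structure the segmentation pipeline
assumes of a single medical slice: roughly elliptical lesions whose mean
intensity contrasts with the surrounding tissue, a smooth low-frequency
intensity inhomogeneity (a cheap stand-in for an MRI bias field), and
additive Gaussian noise.  It makes no attempt at modality physics —
no MRI sequence simulation, no CT Hounsfield calibration — so results on
these scenes demonstrate pipeline correctness, not clinical performance.

All randomness flows through the single seed carried by each
:class:`SceneConfig`; identical configs regenerate bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, GenerationError, SamplingError
from .segmentation import _padded_windows, normalize_image

__all__ = [
    "SceneConfig",
    "LabeledImage",
    "PatchDataset",
    "generate_scene",
    "make_patch_dataset",
    "benchmark_suite",
]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic slice.

    Intensities live on the [0, 1] gray scale.  Defaults: bright lesions
    (0.75) on darker tissue (0.35), noise σ = 0.08, a mild ±0.05 smooth
    inhomogeneity — separable but not trivially so for a 25×25-patch
    classifier.
    """

    seed: int
    image_size: int = 64
    n_lesions: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (5.0, 12.0)
    foreground_mean: float = 0.75
    background_mean: float = 0.35
    noise_sigma: float = 0.08
    inhomogeneity_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.foreground_mean <= 1.0
                and 0.0 <= self.background_mean <= 1.0):
            raise ConfigurationError("means must lie in [0, 1]")
        if self.foreground_mean == self.background_mean:
            raise ConfigurationError("foreground and background means equal")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.n_lesions[0] < 0 or self.n_lesions[1] < self.n_lesions[0]:
            raise ConfigurationError("invalid n_lesions range")
        if self.lesion_radius[0] <= 0 or self.lesion_radius[1] < self.lesion_radius[0]:
            raise ConfigurationError("invalid lesion_radius range")


@dataclass
class LabeledImage:
    image: np.ndarray
    mask: np.ndarray
    provenance: SceneConfig


@dataclass
class PatchDataset:
    """Class-balanced labeled patches, (n, p, p, 1) in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    centers: np.ndarray = None  # (n, 3): scene index, row, col


def _ellipse_mask(size: int, cr: float, cc: float, a: float,
                  b: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:size, 0:size]
    return ((rr - cr) / a) ** 2 + ((cc_ - cc) / b) ** 2 <= 1.0


def generate_scene(config: SceneConfig, max_retries: int = 200) -> LabeledImage:
    """Place anti-overlapping axis-aligned ellipses, then compose
    background + contrast·mask + inhomogeneity + noise, clipped to [0, 1]."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    n = int(rng.integers(config.n_lesions[0], config.n_lesions[1] + 1))

    mask = np.zeros((size, size), dtype=bool)
    placed = 0
    for _ in range(n):
        ok = False
        for _ in range(max_retries):
            a = rng.uniform(*config.lesion_radius)
            b = rng.uniform(*config.lesion_radius)
            cr = rng.uniform(a, size - 1 - a)
            cc = rng.uniform(b, size - 1 - b)
            lesion = _ellipse_mask(size, cr, cc, a, b)
            if not (lesion & mask).any():
                mask |= lesion
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place lesion {placed + 1}/{n} after "
                f"{max_retries} retries (packing infeasible)")
        placed += 1

    image = np.full((size, size), config.background_mean)
    image += (config.foreground_mean - config.background_mean) * mask

    if config.inhomogeneity_amplitude > 0:
        # 2-3 low-frequency cosine components with seeded phases/orientations
        rr, cc_ = np.mgrid[0:size, 0:size] / size
        n_comp = int(rng.integers(2, 4))
        fld = np.zeros((size, size))
        for _ in range(n_comp):
            fx, fy = rng.uniform(0.5, 2.0, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            fld += np.cos(2 * np.pi * (fx * rr + fy * cc_) + phase)
        fld /= n_comp
        image += config.inhomogeneity_amplitude * fld

    if config.noise_sigma > 0:
        image += config.noise_sigma * rng.standard_normal((size, size))

    image = np.clip(image, 0.0, 1.0)
    return LabeledImage(image, mask.astype(np.uint8), config)


def make_patch_dataset(scenes: list[LabeledImage], n_per_class: int,
                       patch_size: int = 25, seed: int = 0) -> PatchDataset:
    """Sample ``n_per_class`` patch centres per class, without replacement
    within a class, pooled over all scenes; patches are cut from the
    min-max-normalized images with reflect padding at borders and labeled by
    the mask value at their centre."""
    if not scenes:
        raise SamplingError("no scenes given")
    rng = np.random.default_rng(seed)
    norm_windows = [
        _padded_windows(normalize_image(s.image), patch_size) for s in scenes
    ]
    coords = {0: [], 1: []}
    for si, scene in enumerate(scenes):
        for cls in (0, 1):
            rs, cs = np.nonzero(scene.mask == cls)
            coords[cls].append(
                np.column_stack([np.full(rs.shape, si), rs, cs]))
    images, labels, centers = [], [], []
    for cls in (0, 1):
        pool = np.concatenate(coords[cls], axis=0)
        if pool.shape[0] < n_per_class:
            raise SamplingError(
                f"class {cls}: requested {n_per_class} patches but only "
                f"{pool.shape[0]} pixels available")
        sel = rng.choice(pool.shape[0], size=n_per_class, replace=False)
        for si, r, c in pool[sel]:
            images.append(norm_windows[si][r, c])
            labels.append(cls)
            centers.append((si, r, c))
    images = np.asarray(images, dtype=float)[..., None]
    return PatchDataset(images, np.asarray(labels, dtype=int),
                        np.asarray(centers, dtype=int))


def benchmark_suite(seed: int, n_scenes: int = 20,
                    train_fraction: float = 0.7,
                    base: SceneConfig | None = None
                    ) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """The repository's canonical desk-scale benchmark: ``n_scenes`` 64×64
    scenes at the default contrast/noise, split 70/30 by scene into train
    and test; each scene's config (with its derived seed) is recorded in its
    provenance."""
    rng = np.random.default_rng(seed)
    if base is None:
        base = SceneConfig(seed=0)
    scenes = []
    for _ in range(n_scenes):
        child = int(rng.integers(0, 2**31 - 1))
        scenes.append(generate_scene(replace(base, seed=child)))
    n_train = int(round(train_fraction * n_scenes))
    return scenes[:n_train], scenes[n_train:]
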
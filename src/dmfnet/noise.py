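"""Additive Gaussian noise protocol: Y = X + eta.

Noise levels are quoted on the 0-255 intensity scale (the convention of the
denoising literature) and divided by 255 in the internal [0, 1] domain.
Two modes are supported:

* ``specific`` — a fixed sigma (15, 20 or 25 are the standard test levels);
* ``blind``   — sigma drawn uniformly from a range (default [0, 55]) per
  image, so a trained model must cope without knowing the level.

The noisy image is *not* clipped to [0, 1]: residual learning predicts the
raw noise field and clipping the input would bias that target.  Clipping is
applied only when writing 8-bit output files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "sample_sigma", "add_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise configuration; sigma values on the 0-255 intensity scale."""

    mode: str = "blind"  # specific | blind
    sigma: float = 25.0
    sigma_range: tuple = (0.0, 55.0)

    def validate(self) -> None:
        if self.mode not in ("specific", "blind"):
            raise ValueError(f"noise mode must be 'specific' or 'blind', got {self.mode!r}")
        if self.mode == "specific" and self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        lo, hi = self.sigma_range
        if lo < 0 or lo > hi:
            raise ValueError(f"invalid sigma_range {self.sigma_range}")


def sample_sigma(spec: NoiseSpec, seed: int) -> float:
    """Noise level for one image: fixed in specific mode, uniform in blind mode."""
    spec.validate()
    if spec.mode == "specific":
        return float(spec.sigma)
    lo, hi = spec.sigma_range
    return float(np.random.default_rng(seed).uniform(lo, hi))


def add_noise(image: np.ndarray, spec: NoiseSpec, seed: int) -> np.ndarray:
    """Return ``image + eta`` with i.i.d. zero-mean Gaussian noise.

    The standard deviation is ``sigma / 255`` in the internal domain; in
    blind mode sigma is drawn (from the same seed stream) before the field.
    The input is never modified; sigma 0 returns an exact copy.
    """
    spec.validate()
    image = np.asarray(image)
    rng = np.random.default_rng(seed)
    if spec.mode == "specific":
        sigma = float(spec.sigma)
    else:
        sigma = float(rng.uniform(*spec.sigma_range))
    if sigma == 0.0:
        return image.copy()
    eta = rng.normal(0.0, sigma / 255.0, image.shape)
    return (image + eta).astype(image.dtype, copy=False)
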
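"""Image quality metrics (MSE, PSNR, SSIM) and batch evaluation.

PSNR = 20*log10(MAX_f / sqrt(MSE)), with MAX_f the peak representable value
(1.0 in the internal domain).  SSIM follows the standard windowed
luminance/contrast/structure comparison with constants c1 = (0.01*L)^2 and
c2 = (0.03*L)^2; the window is the de-facto standard 11x11 Gaussian with
sigma 1.5 (a uniform window is available for cross-checking).  Metrics are
computed in the [0, 1] domain after clipping model output — the score an
8-bit export would receive — and PSNR is scale-invariant in any case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .model import DMFNet
from .noise import NoiseSpec, add_noise

__all__ = ["MetricReport", "mse", "psnr", "ssim", "evaluate"]

log = logging.getLogger("dmfnet.metrics")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Mean squared per-pixel difference."""
    a, b = _check_pair(reference, estimate)
    d = a - b
    return float(np.mean(d * d))


def psnr(reference: np.ndarray, estimate: np.ndarray, max_f: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if max_f <= 0:
        raise ValueError(f"max_f must be positive, got {max_f}")
    err = mse(reference, estimate)
    if err == 0.0:
        return float("inf")
    return float(20.0 * np.log10(max_f) - 10.0 * np.log10(err))


def ssim(
    reference: np.ndarray,
    estimate: np.ndarray,
    max_f: float = 1.0,
    window: str = "gaussian",
) -> float:
    """Mean structural similarity over local windows, in [-1, 1].

    ``window='gaussian'`` uses the standard 11x11 Gaussian (sigma 1.5)
    weighting with population statistics; ``'uniform'`` uses an unweighted
    11x11 window.
    """
    a, b = _check_pair(reference, estimate)
    if min(a.shape) < 11:
        raise ValueError(f"image {a.shape} smaller than the 11x11 SSIM window")
    if window == "gaussian":
        return float(
            structural_similarity(
                a, b, data_range=max_f, gaussian_weights=True, sigma=1.5,
                win_size=11, use_sample_covariance=False,
            )
        )
    if window == "uniform":
        return float(
            structural_similarity(
                a, b, data_range=max_f, gaussian_weights=False,
                win_size=11, use_sample_covariance=False,
            )
        )
    raise ValueError(f"unknown window {window!r}")


@dataclass(frozen=True)
class MetricReport:
    """Averaged metrics at one noise level, for noisy inputs and denoised outputs."""

    sigma: float
    n_images: int
    max_f: float
    mse_denoised: float
    psnr_denoised: float
    ssim_denoised: float
    psnr_noisy: float
    ssim_noisy: float
    n_inf_excluded: int = 0


def _finite_mean(values: list[float]) -> tuple[float, int]:
    arr = np.asarray(values, dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    n_inf = int(arr.size - finite.size)
    return (float(finite.mean()) if finite.size else float("inf")), n_inf


def evaluate(
    model,
    images: list,
    sigmas=(15.0, 20.0, 25.0),
    seed: int = 0,
    max_f: float = 1.0,
    window: str = "gaussian",
) -> list[MetricReport]:
    """Noisy-baseline and denoised metrics averaged over a test set.

    ``model`` is a :class:`DMFNet` or a checkpoint path.  For each sigma the
    noise is synthesised with per-image seeds derived from ``seed``, the
    model denoises each noisy image, and PSNR/SSIM are averaged against the
    clean originals (both noisy input and model output are clipped to
    [0, 1] before scoring).  Infinite PSNR values (perfect reconstruction)
    are excluded from means and counted.
    """
    if not images:
        raise ValueError("evaluation requires at least one test image")
    if not isinstance(model, DMFNet):
        model = DMFNet.load(model)
    reports = []
    for si, sigma in enumerate(sigmas):
        spec = NoiseSpec(mode="specific", sigma=float(sigma))
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), si]))
        p_n, s_n, p_d, s_d, m_d = [], [], [], [], []
        for img in images:
            noisy = add_noise(img, spec, int(rng.integers(2**31)))
            den = np.clip(model.denoise(noisy), 0.0, 1.0)
            noisy_c = np.clip(noisy, 0.0, 1.0)
            p_n.append(psnr(img, noisy_c, max_f))
            s_n.append(ssim(img, noisy_c, max_f, window))
            p_d.append(psnr(img, den, max_f))
            s_d.append(ssim(img, den, max_f, window))
            m_d.append(mse(img, den))
        mean_pn, inf_n = _finite_mean(p_n)
        mean_pd, inf_d = _finite_mean(p_d)
        n_inf = inf_n + inf_d
        if n_inf:
            log.info("sigma %.4g: excluded %d infinite PSNR values from means", sigma, n_inf)
        reports.append(
            MetricReport(
                sigma=float(sigma),
                n_images=len(images),
                max_f=max_f,
                mse_denoised=float(np.mean(m_d)),
                psnr_denoised=mean_pd,
                ssim_denoised=float(np.mean(s_d)),
                psnr_noisy=mean_pn,
                ssim_noisy=float(np.mean(s_n)),
                n_inf_excluded=n_inf,
            )
        )
    return reports
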
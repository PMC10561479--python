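"""Chest-like synthetic phantoms, augmentation, and dataset splits.

The phantom recipe emulates the gross structure of a chest radiograph or CT
slice — a smoothly varying soft-tissue background, dark elliptical lung
fields, and bright curvilinear rib-like arcs — so that denoising quality
metrics (PSNR/SSIM) are meaningful without any external data.  It makes no
attempt at anatomical realism; it only provides edges, smooth regions and
contrast at the scales a denoiser cares about.

All randomness is driven by an explicit integer seed: generation is a pure
function of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "DatasetSplit",
    "generate_phantom",
    "generate_phantoms",
    "augment",
    "apply_transform",
    "augment_dataset",
    "make_split",
    "TRANSFORM_NAMES",
]

#: The dihedral transforms used for augmentation: identity, left-right flip,
#: up-down flip, and rotations by 90/180/270 degrees.
TRANSFORM_NAMES = ("identity", "fliplr", "flipud", "rot90", "rot180", "rot270")

_TRANSFORMS = (
    lambda a: a,
    np.fliplr,
    np.flipud,
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic chest phantom.

    Parameters
    ----------
    size : pixels per side (square image), minimum 16; 128 is the canonical
        training size.
    n_ellipses : number of dark elliptical "lung field" regions.
    n_ridges : number of bright rib-like arcs.
    background_smoothness : Gaussian blur scale (pixels) of the soft-tissue
        background texture.
    contrast_range : overall contrast as a fraction of full scale; 0 yields a
        constant mid-gray image.
    """

    size: int = 128
    n_ellipses: int = 3
    n_ridges: int = 6
    background_smoothness: float = 8.0
    contrast_range: float = 0.7

    def validate(self) -> None:
        if self.size < 16:
            raise ValueError(f"phantom size must be >= 16, got {self.size}")
        if self.n_ellipses < 0 or self.n_ridges < 0:
            raise ValueError("n_ellipses and n_ridges must be non-negative")
        if not 0.0 <= self.contrast_range <= 1.0:
            raise ValueError(f"contrast_range must be in [0, 1], got {self.contrast_range}")


@dataclass
class DatasetSplit:
    """Disjoint train/val/test image lists."""

    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)
    ratio: float = 0.9


def generate_phantom(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Deterministically generate one phantom in [0, 1] as float32."""
    spec.validate()
    rng = np.random.default_rng(seed)
    s = spec.size
    c = spec.contrast_range

    bg = rng.standard_normal((s, s))
    if spec.background_smoothness > 0:
        bg = gaussian_filter(bg, spec.background_smoothness, mode="reflect")
    bg = bg / (bg.std() + 1e-12)
    img = 0.5 + 0.08 * c * bg

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(spec.n_ellipses):
        cy, cx = rng.uniform(0.25 * s, 0.75 * s, 2)
        ay = rng.uniform(0.12, 0.28) * s
        ax = rng.uniform(0.18, 0.35) * s
        theta = rng.uniform(0, np.pi)
        depth = rng.uniform(0.35, 0.65) * c
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / ax) ** 2 + (v / ay) ** 2
        mask = np.clip((1.0 - r2) / 0.15, 0.0, 1.0)  # soft-edged ellipse
        img -= depth * mask

    for _ in range(spec.n_ridges):
        cy, cx = rng.uniform(-0.2 * s, 1.2 * s, 2)
        radius = rng.uniform(0.3, 0.7) * s
        thickness = rng.uniform(1.5, 3.0)
        height = rng.uniform(0.25, 0.45) * c
        dist = np.hypot(yy - cy, xx - cx) - radius
        img += height * np.exp(-((dist / thickness) ** 2))

    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_phantoms(n: int, spec: PhantomSpec | None = None, seed: int = 0) -> list[np.ndarray]:
    """Generate ``n`` phantoms with per-image seeds derived from ``seed``."""
    spec = spec or PhantomSpec()
    child = np.random.SeedSequence(seed).generate_state(n)
    return [generate_phantom(spec, int(s)) for s in child]


def apply_transform(image: np.ndarray, k: int) -> np.ndarray:
    """Apply dihedral transform ``k`` (index into :data:`TRANSFORM_NAMES`)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if k in (3, 5) and image.shape[0] != image.shape[1]:
        raise ValueError("90/270-degree rotation of a non-square image would change its shape")
    return np.ascontiguousarray(_TRANSFORMS[k](image))


def augment(image: np.ndarray, seed: int) -> np.ndarray:
    """One of the six dihedral transforms, chosen uniformly by ``seed``.

    The pixel multiset is preserved exactly.  Non-square images are rejected
    because 90/270-degree rotations would change the training shape.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"augmentation requires a square 2-D image, got shape {image.shape}")
    k = int(np.random.default_rng(seed).integers(len(_TRANSFORMS)))
    return apply_transform(image, k)


def augment_dataset(images: list, seed: int = 0) -> list:
    """Offline augmentation: each image plus one random non-identity transform.

    Roughly doubles the dataset, mirroring how the flip/rotation augmented
    training folders are assembled.
    """
    rng = np.random.default_rng(seed)
    out = list(images)
    for img in images:
        k = int(rng.integers(1, len(_TRANSFORMS)))
        out.append(apply_transform(img, k))
    return out


def make_split(images: list, ratio: float = 0.9, seed: int = 0) -> DatasetSplit:
    """Deterministic train/validation split of an image pool.

    ``ratio`` is the training fraction; the validation count is
    ``round((1 - ratio) * n)`` (the conventional 90:10 split by default).
    """
    if len(images) == 0:
        raise ValueError("cannot split an empty image list")
    if len(images) < 10:
        raise ValueError(f"need at least 10 images to split, got {len(images)}")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(images)
    n_val = int(round((1.0 - ratio) * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = [images[i] for i in perm[: n - n_val]]
    val = [images[i] for i in perm[n - n_val :]]
    return DatasetSplit(train=train, val=val, test=[], ratio=ratio)
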
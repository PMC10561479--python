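"""Grayscale image reading/writing.

Internal intensity domain is float in [0, 1]; integer files are scaled by
their bit depth on read (8-bit / 255, 16-bit / 65535) so sigma-on-0-255
conventions convert through exactly one point.  PNG (8-bit) and TIFF
(8/16-bit integer or float) are supported; DICOM is an optional read path
that applies only the rescale slope/intercept from the header.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image"]


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        # luminance of an RGB(A) file; medical exports are often RGB-coded gray
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def _load_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading DICOM files requires the optional 'pydicom' dependency") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def load_image(path) -> np.ndarray:
    """Read a grayscale image as float32.

    Integer formats are mapped to [0, 1]; float TIFFs pass through unscaled;
    DICOM returns rescaled raw values (no window mapping is applied).
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path).astype(np.float32)
    arr = _to_gray(np.asarray(iio.imread(path)))
    if np.issubdtype(arr.dtype, np.integer):
        peak = float(np.iinfo(arr.dtype).max)
        return (arr.astype(np.float32) / peak).astype(np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path} contains non-finite pixel values")
    return arr.astype(np.float32)


def save_image(path, image: np.ndarray, float_tiff: bool = False) -> None:
    """Write an image; 8-bit PNG by default (clipped to [0, 1]), or float TIFF."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if float_tiff:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("float output requires a .tif/.tiff filename")
        iio.imwrite(path, image.astype(np.float32))
        return
    data = np.clip(image, 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255.0).astype(np.uint8))
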
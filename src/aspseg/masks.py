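"""Mask containers, validation and file I/O.

Predicted probability masks are real-valued H×W arrays in [0, 1]; ground
truth masks are binary H×W arrays.  Both are plain ``numpy`` arrays
throughout the package — these helpers validate them and move them to and
from grayscale PNG files (8-bit for binary/display, 16-bit for
probabilities) or ``.npy`` float containers.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .autodiff import Tensor
from .exceptions import DimensionError, DomainError

#: threshold applied to 8-bit ground-truth PNGs on read
GT_READ_THRESHOLD = 128
#: scale used for 16-bit probability PNGs
PROB_PNG_SCALE = 65535


def _data(mask) -> np.ndarray:
    return mask.data if isinstance(mask, Tensor) else np.asarray(mask)


def validate_prob_mask(pred) -> np.ndarray:
    """Check an H×W probability mask; returns its ndarray view."""
    arr = _data(pred)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"probability mask must be 2-D H×W, got shape {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise DomainError("probability mask values must lie in [0, 1]")
    return arr


def validate_bin_mask(gt) -> np.ndarray:
    """Check an H×W binary mask; returns a float ndarray of {0.0, 1.0}."""
    arr = np.asarray(_data(gt), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"binary mask must be 2-D H×W, got shape {arr.shape}")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise DomainError("binary mask values must be exactly 0 or 1")
    return arr


def check_same_shape(pred, gt) -> None:
    a, b = _data(pred), _data(gt)
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")


def read_bin_mask(path) -> np.ndarray:
    """Read a ground-truth mask PNG, thresholding grayscale at 128."""
    img = np.asarray(Image.open(path).convert("I"))
    return (img >= GT_READ_THRESHOLD).astype(float)


def write_bin_mask(path, mask) -> None:
    arr = validate_bin_mask(mask)
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


def read_prob_mask(path) -> np.ndarray:
    """Read a probability mask from 16-bit PNG (÷65535) or a ``.npy`` file."""
    path = str(path)
    if path.endswith(".npy"):
        arr = np.load(path).astype(float)
    else:
        img = Image.open(path)
        arr = np.asarray(img, dtype=float)
        arr = arr / (PROB_PNG_SCALE if img.mode in ("I", "I;16") else 255.0)
    return validate_prob_mask(arr)


def write_prob_mask(path, pred) -> None:
    """Write a probability mask: ``.npy`` verbatim, else 16-bit PNG."""
    arr = validate_prob_mask(pred)
    path = str(path)
    if path.endswith(".npy"):
        np.save(path, arr.astype(np.float32))
    else:
        Image.fromarray(np.round(arr * PROB_PNG_SCALE).astype(np.uint16)).save(path)


def write_image(path, image) -> None:
    """Write a [0,1] grayscale image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
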
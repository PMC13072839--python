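"""Raster types, file I/O and color conversions for candling images.

Images are plain numpy arrays, row-major with the origin at the top-left:

* RGB image  -- ``(H, W, 3)`` uint8, interpreted as sRGB (D65 white point).
* Gray image -- ``(H, W)`` uint8 luma.
* Lab image  -- ``(H, W, 3)`` float64; L* in [0, 100], a*/b* roughly
  [-128, 127].
* Binary mask -- ``(H, W)`` uint8 with values {0, 1}, same shape as the
  image it was derived from.

Transmission (candling) photographs are captured at fixed camera settings
inside a dark box, so no ICC/EXIF handling is attempted: files are decoded
as-is and treated as sRGB.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as _skcolor

from .errors import ImageIOError, ValidationError

#: BT.601 luma weights used for RGB -> gray conversion. This matches the
#: conventional grayscale conversion of mainstream image-processing
#: environments and is fixed by design (candling rigs do not calibrate color).
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def _require_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValidationError("image must be at least 1x1")
    return img


def _require_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"expected (H, W) mask, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("mask must contain only values 0 and 1")
    return mask.astype(np.uint8, copy=False)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/JPEG/TIFF file as an ``(H, W, 3)`` uint8 RGB array.

    Grayscale and paletted files are expanded to three channels; an alpha
    channel, if present, is dropped.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError, ValueError) as exc:
        raise ImageIOError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    return _require_rgb(arr)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image; the format follows the file extension."""
    img = _require_rgb(img)
    Image.fromarray(img.astype(np.uint8), mode="RGB").save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert RGB to 8-bit luma with BT.601 weights (0.2989/0.5870/0.1140)."""
    img = _require_rgb(img).astype(np.float64)
    r, g, b = LUMA_WEIGHTS
    gray = r * img[..., 0] + g * img[..., 1] + b * img[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an sRGB image to CIELAB (D65).

    Uses the standard sRGB -> XYZ -> L*a*b* transform; returns float64
    with L* in [0, 100].
    """
    img = _require_rgb(img)
    return _skcolor.rgb2lab(img.astype(np.float64) / 255.0)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    mask = _require_mask(mask)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def load_mask(path: str | os.PathLike, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a mask PNG; gray values > 127 map to 1, the rest to 0.

    If ``expected_shape`` is given, a shape mismatch raises
    :class:`~ovograde.errors.ValidationError`.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, UnidentifiedImageError, SyntaxError, ValueError) as exc:
        raise ImageIOError(f"cannot read mask file {os.fspath(path)!r}: {exc}") from exc
    mask = (arr > 127).astype(np.uint8)
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValidationError(
            f"mask shape {mask.shape} does not match expected {tuple(expected_shape)}"
        )
    return mask
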
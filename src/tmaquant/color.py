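"""Colour-channel transforms used by the quantification pipeline.

Two grayscale "working channels" are derived from each RGB cylinder image:

* the CIE L* lightness channel, rescaled from its native [0, 100] range to
  [0, 255], used to separate the dark tissue cylinder from the bright
  scanner background;
* the *brown channel*, ``B - 0.3 * (R + G)``, an empirical single-formula
  colour translation in which DAB (diaminobenzidine) stained pixels take
  low values.

Both channels are returned as rounded 8-bit images so that integer
threshold semantics (e.g. "values from 0 to 70") are unambiguous.

Conventions: RGB input is assumed to be sRGB-encoded (sRGB primaries, D65
white point, standard sRGB transfer function), the common default of
scientific imaging software. L* is computed through the sRGB -> XYZ(D65)
-> L*a*b* path.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

__all__ = ["to_lightness_channel", "brown_channel", "validate_rgb"]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return np.floor(x + 0.5)


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Validate an RGB image array and return it as uint8 (H, W, 3).

    Raises
    ------
    ValueError
        If the array is empty, not three-channel, or holds values outside
        [0, 255].
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB array, got shape {img.shape}"
        )
    if img.size == 0:
        raise ValueError("empty image (0 pixels)")
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ValueError("RGB intensities must lie in [0, 255]")
        if not np.issubdtype(img.dtype, np.integer) and not np.allclose(
            img, np.round(img)
        ):
            raise ValueError("RGB intensities must be integers")
        img = img.astype(np.uint8)
    return img


def to_lightness_channel(img: np.ndarray) -> np.ndarray:
    """CIE L* lightness of each pixel, rescaled to [0, 255] as uint8.

    Black (0,0,0) maps to 0 and reference white (255,255,255) to 255.
    The rescale is linear (L* * 255 / 100) with half-up rounding, so the
    returned channel can be thresholded with closed integer intervals.
    """
    img = validate_rgb(img)
    lstar = rgb2lab(img)[..., 0]  # in [0, 100]
    scaled = _round_half_up(lstar * (255.0 / 100.0))
    return np.clip(scaled, 0, 255).astype(np.uint8)


def brown_channel(img: np.ndarray) -> np.ndarray:
    """Brown (DAB) channel: ``B - 0.3 * (R + G)``, clamped to [0, 255].

    DAB-stained pixels take low values; saturated blue maps to 255. The
    formula can go as low as -153 for strongly brown pixels; negatives are
    clamped to 0 so that maximally brown pixels fall inside the standard
    [0, 70] stain window. Computed in real arithmetic and rounded half-up
    before clamping.
    """
    img = validate_rgb(img)
    r = img[..., 0].astype(np.float64)
    g = img[..., 1].astype(np.float64)
    b = img[..., 2].astype(np.float64)
    raw = b - 0.3 * (r + g)
    return np.clip(_round_half_up(raw), 0, 255).astype(np.uint8)
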
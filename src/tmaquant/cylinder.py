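"""Step one of the pipeline: find the tissue cylinder and count its pixels.

The tissue core is much darker than the scanner background, so after a
3x3 median filter the lightness channel is thresholded at <= 238 and the
connected component larger than ``min_object_area`` pixels (1,000,000 by
default, matching 2-mm cores scanned at 0.25 um/pixel) is taken as the
cylinder. Its pixel count is the denominator of the percent-positive
statistic.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "CylinderSegmentation",
    "CylinderNotFoundError",
    "median_filter_3x3",
    "segment_cylinder",
]


class CylinderNotFoundError(RuntimeError):
    """No connected component exceeded ``min_object_area``.

    Signals a failed scan, an empty image, or a ``min_object_area`` that
    does not match the image scale. ``largest_area`` holds the area of the
    biggest rejected candidate (0 if none).
    """

    def __init__(self, largest_area: int, min_object_area: int):
        self.largest_area = int(largest_area)
        self.min_object_area = int(min_object_area)
        super().__init__(
            f"no object larger than {min_object_area} px found; "
            f"largest candidate has {largest_area} px"
        )


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and size filters for both segmentation steps.

    Defaults are the published operating point for 2-mm TMA cores at
    0.25 um/pixel. ``min_object_area`` scales with image resolution:
    desk-scale synthetic fixtures use proportionally smaller values.

    Attributes
    ----------
    lightness_threshold_high:
        Pixels with rescaled L* in the closed interval
        [0, lightness_threshold_high] belong to tissue. Default 238.
    median_size:
        Window size of the square median filter applied to the lightness
        channel. Default 3 (a 3x3 window).
    min_object_area:
        A tissue component must be strictly larger than this many pixels
        to qualify as the cylinder. Default 1,000,000.
    brown_threshold_high:
        Pixels with brown-channel value in [0, brown_threshold_high] count
        as DAB stain. Default 70.
    min_stain_object_area:
        A stain object must be strictly larger than this many pixels to be
        retained (excludes background speckle and artefacts). Default 1000.
    connectivity:
        Pixel connectivity for component labelling, 4 or 8. Default 8
        (the ImageJ particle-analysis convention).
    """

    lightness_threshold_high: int = 238
    median_size: int = 3
    min_object_area: int = 1_000_000
    brown_threshold_high: int = 70
    min_stain_object_area: int = 1000
    connectivity: int = 8

    def __post_init__(self):
        if not (0 <= self.lightness_threshold_high <= 255):
            raise ValueError("lightness_threshold_high must be in [0, 255]")
        if not (0 <= self.brown_threshold_high <= 255):
            raise ValueError("brown_threshold_high must be in [0, 255]")
        if self.min_object_area <= 0 or self.min_stain_object_area <= 0:
            raise ValueError("object-area thresholds must be positive")
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be a positive odd integer")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        """Labelling structure element matching ``connectivity``."""
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)

    @classmethod
    def from_file(cls, path) -> "SegmentationConfig":
        """Load a config from a TOML key/value file.

        Unknown keys raise, so typos cannot silently fall back to defaults.
        """
        if sys.version_info >= (3, 11):
            import tomllib
        else:  # pragma: no cover
            import tomli as tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CylinderSegmentation:
    """The selected cylinder object.

    ``mask`` is True inside the cylinder; ``total_area`` is its pixel
    count (the percentage denominator); ``n_candidate_objects`` counts the
    components that passed the size filter (normally 1).
    """

    mask: np.ndarray
    total_area: int
    n_candidate_objects: int
    selected_object_id: int
    warnings: list = field(default_factory=list)


def median_filter_3x3(g: np.ndarray, size: int = 3) -> np.ndarray:
    """Square median filter with replicate-edge padding.

    Each pixel is replaced by the median of its ``size`` x ``size``
    neighbourhood (including itself). Edges are padded by replication; any
    consistent border rule affects only a one-pixel rim of a
    multi-megapixel mask.
    """
    g = np.asarray(g)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    return ndimage.median_filter(g, size=size, mode="nearest")


def segment_cylinder(
    l_filtered: np.ndarray, cfg: SegmentationConfig | None = None
) -> CylinderSegmentation:
    """Select the cylinder object from the median-filtered lightness image.

    Pixels with value <= ``cfg.lightness_threshold_high`` (closed interval,
    so exactly 238 is inside) are tissue candidates; connected components
    strictly larger than ``cfg.min_object_area`` qualify. Normally exactly
    one qualifies; if several do (debris, split cores) the largest is
    selected and a warning is recorded rather than failing the image.

    Raises
    ------
    CylinderNotFoundError
        If no component exceeds ``cfg.min_object_area``.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    l_filtered = np.asarray(l_filtered)
    if l_filtered.ndim != 2 or l_filtered.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")

    binary = l_filtered <= cfg.lightness_threshold_high
    labels, n = ndimage.label(binary, structure=cfg.structure)
    if n == 0:
        raise CylinderNotFoundError(0, cfg.min_object_area)

    areas = np.bincount(labels.ravel())[1:]  # skip background
    qualifying = np.flatnonzero(areas > cfg.min_object_area) + 1
    if qualifying.size == 0:
        raise CylinderNotFoundError(int(areas.max()), cfg.min_object_area)

    warnings_list: list[str] = []
    if qualifying.size > 1:
        msg = (
            f"{qualifying.size} objects exceed min_object_area="
            f"{cfg.min_object_area}; selecting the largest"
        )
        logger.warning(msg)
        warnings_list.append(msg)

    selected = int(qualifying[np.argmax(areas[qualifying - 1])])
    mask = labels == selected
    return CylinderSegmentation(
        mask=mask,
        total_area=int(areas[selected - 1]),
        n_candidate_objects=int(qualifying.size),
        selected_object_id=selected,
        warnings=warnings_list,
    )
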
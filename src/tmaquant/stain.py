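"""Step two of the pipeline: segment DAB-brown objects and measure area.

Brown-channel pixels in [0, 70] inside the cylinder are labelled into
objects; objects larger than 1000 pixels survive (smaller ones are
background speckle and artefacts). Two area variants are reported:

* **method A** counts only the brown pixels of the retained objects —
  enclosed unstained regions (gland lumina, nuclei) are excluded;
* **method B** additionally counts those enclosed regions, by filling
  each object's holes before counting, and is therefore always >= A.

The percent-positive statistic is 100 * positive_pixels / cylinder_pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .color import brown_channel, to_lightness_channel, validate_rgb
from .cylinder import (
    CylinderSegmentation,
    SegmentationConfig,
    median_filter_3x3,
    segment_cylinder,
)

__all__ = [
    "StainObjects",
    "StainQuantification",
    "segment_stain",
    "area_method_A",
    "area_method_B",
    "percent_positive",
    "quantify_image",
]


@dataclass
class StainObjects:
    """Labelled stain objects inside the cylinder.

    ``labels`` is 0 for background; every retained object is strictly
    larger than the size filter and lies entirely within ``cylinder_mask``.
    """

    labels: np.ndarray
    object_areas: dict[int, int]
    n_objects: int
    cylinder_mask: np.ndarray
    connectivity: int = 8


@dataclass
class StainQuantification:
    """Per-image result of the full two-step procedure."""

    image_id: str
    total_area: int
    positive_area_A: int
    positive_area_B: int
    percent_A: float
    percent_B: float
    n_objects: int
    warnings: list = field(default_factory=list)


def segment_stain(
    brown: np.ndarray,
    cyl: CylinderSegmentation,
    cfg: SegmentationConfig | None = None,
) -> StainObjects:
    """Label brown objects inside the cylinder and apply the size filter.

    Brown-channel values in the closed interval
    [0, ``cfg.brown_threshold_high``] are stain candidates; candidates
    outside the cylinder mask are discarded *before* labelling, so the
    numerator and denominator share one spatial support. Components with
    area <= ``cfg.min_stain_object_area`` are dropped ("greater than 1000
    pixels" is strict: a 1000-pixel object is rejected, 1001 retained).
    """
    if cfg is None:
        cfg = SegmentationConfig()
    brown = np.asarray(brown)
    if brown.shape != cyl.mask.shape:
        raise ValueError(
            f"brown channel shape {brown.shape} does not match cylinder "
            f"mask shape {cyl.mask.shape}"
        )
    candidate = (brown <= cfg.brown_threshold_high) & cyl.mask
    labels, n = ndimage.label(candidate, structure=cfg.structure)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas > cfg.min_stain_object_area) + 1
        # relabel kept objects 1..m, zero the rest
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
        object_areas = {
            int(new): int(areas[old - 1])
            for new, old in zip(range(1, keep.size + 1), keep)
        }
    else:
        object_areas = {}
    return StainObjects(
        labels=labels,
        object_areas=object_areas,
        n_objects=len(object_areas),
        cylinder_mask=cyl.mask,
        connectivity=cfg.connectivity,
    )


def area_method_A(objs: StainObjects) -> int:
    """Sum of brown pixels over retained objects (holes excluded)."""
    return int(sum(objs.object_areas.values()))


def _fill_object_holes(objs: StainObjects) -> np.ndarray:
    """Union of per-object hole-filled masks.

    A hole is a background region with no path (at the complementary
    connectivity: 4-connected background for 8-connected objects) to the
    exterior of the object; regions opening onto the object's outside
    boundary are not holes. Filling is per object, on its bounding box —
    an enclosed hole can never touch the bounding box border, so the
    restricted fill is exact. The union avoids double counting when one
    object sits inside another object's hole.
    """
    filled = np.zeros_like(objs.labels, dtype=bool)
    hole_structure = ndimage.generate_binary_structure(
        2, 1 if objs.connectivity == 8 else 2
    )
    slices = ndimage.find_objects(objs.labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        obj = objs.labels[sl] == lab
        filled[sl] |= ndimage.binary_fill_holes(obj, structure=hole_structure)
    # stay inside the measured support; in practice holes lie within it
    return filled & objs.cylinder_mask


def area_method_B(objs: StainObjects) -> int:
    """Brown pixels plus enclosed holes (gland lumina, nuclei); >= method A."""
    return int(_fill_object_holes(objs).sum())


def percent_positive(positive: int, total: int) -> float:
    """Percent-positive area: ``100 * positive / total``."""
    if total <= 0:
        raise ValueError("total cylinder area must be positive")
    if not 0 <= positive <= total:
        raise RuntimeError(
            f"positive area {positive} outside [0, total={total}]: "
            "internal inconsistency"
        )
    return 100.0 * positive / total


def quantify_image(
    img: np.ndarray,
    cfg: SegmentationConfig | None = None,
    image_id: str = "",
) -> StainQuantification:
    """Run the full two-step procedure on one RGB cylinder image.

    Pipeline: lightness channel -> median filter -> cylinder selection ->
    brown channel -> stain labelling -> areas under methods A and B ->
    percentages.

    Raises
    ------
    CylinderNotFoundError
        Propagated from cylinder selection.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    img = validate_rgb(img)
    lightness = to_lightness_channel(img)
    filtered = median_filter_3x3(lightness, size=cfg.median_size)
    cyl = segment_cylinder(filtered, cfg)
    brown = brown_channel(img)
    objs = segment_stain(brown, cyl, cfg)
    area_a = area_method_A(objs)
    area_b = area_method_B(objs)
    return StainQuantification(
        image_id=image_id,
        total_area=cyl.total_area,
        positive_area_A=area_a,
        positive_area_B=area_b,
        percent_A=percent_positive(area_a, cyl.total_area),
        percent_B=percent_positive(area_b, cyl.total_area),
        n_objects=objs.n_objects,
        warnings=list(cyl.warnings),
    )
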
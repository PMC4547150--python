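"""Synthetic TMA-cylinder images and ratings tables with exact ground truth.

The image generator emulates what the quantification pipeline actually
sees in a scanned tissue-microarray core: a large dark circular tissue
disk on a bright (near-white) scanner background, brown DAB-stained
regions inside the tissue, and enclosed unstained "holes" within the
stained regions standing in for gland lumina and nuclei. Optional
Gaussian pixel noise emulates scanner noise. Every scene carries
pixel-exact ground-truth masks and counts computed from the pre-noise
rasterization, so the pipeline's output can be checked exactly.

One subtlety: the pipeline median-filters the lightness channel before
thresholding, which on a binary tissue/background boundary acts as a 3x3
majority vote. So that "pixel-exact" is well defined, the generator draws
a *median-stable* core mask (the rasterized disk iterated to the majority
filter's fixed point — for disks this converges in at most one pass and
moves at most a handful of boundary pixels).

The ratings generator draws complete subject x rater tables from the
two-way random-effects model value(i,j) = mu + s_i + r_j + e_ij with
independent zero-mean Gaussian components, for which the population
single-rating absolute-agreement ICC is s^2 / (s^2 + r^2 + e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .agreement import DegenerateDataError, RatingsTable
from .color import brown_channel, to_lightness_channel

__all__ = [
    "StainRegion",
    "CylinderScene",
    "GroundTruth",
    "SceneValidationError",
    "generate_cylinder_image",
    "generate_ratings",
    "single_disk_scene",
    "random_scene",
]

# Default palette, chosen so class separations are robust under the
# pipeline's actual transforms (validated in CylinderScene.validate()):
#   background: scanner white, lightness 255 > 238
#   tissue:     pale hematoxylin blue-violet, lightness 195, brown 103 > 70
#   stain:      DAB brown, brown channel clamps to 0 <= 70
#   hole:       pale gland-lumen gray, lightness 228 <= 238, brown 90 > 70
BACKGROUND_RGB = (255, 255, 255)
TISSUE_RGB = (190, 185, 215)
STAIN_RGB = (150, 90, 60)
HOLE_RGB = (225, 225, 225)


class SceneValidationError(ValueError):
    """A scene violates geometric or colour-separation constraints."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid scene: " + "; ".join(violations))


@dataclass(frozen=True)
class StainRegion:
    """A circular stained region with optional enclosed holes.

    ``n_holes`` holes with radii drawn uniformly from
    ``hole_radius_range`` are placed (deterministically per scene seed)
    strictly inside the region, leaving at least a 2-pixel stained rim so
    every hole is genuinely enclosed.
    """

    center: tuple[float, float]  # (x, y)
    radius: float
    n_holes: int = 0
    hole_radius_range: tuple[float, float] = (4.0, 10.0)


@dataclass(frozen=True)
class CylinderScene:
    image_size: tuple[int, int] = (420, 420)  # (height, width)
    core_radius: float = 150.0
    core_center: tuple[float, float] | None = None  # (x, y); None = centre
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    tissue_rgb: tuple[int, int, int] = TISSUE_RGB
    stain_rgb: tuple[int, int, int] = STAIN_RGB
    hole_rgb: tuple[int, int, int] = HOLE_RGB
    stain_regions: tuple[StainRegion, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.core_center is not None:
            return self.core_center
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def validate(self) -> None:
        """Raise SceneValidationError listing every violated constraint.

        Colour constraints are checked through the actual pipeline
        transforms, not against assumed values.
        """
        bad: list[str] = []
        h, w = self.image_size
        cx, cy = self.center
        if self.core_radius <= 0:
            bad.append("core_radius must be positive")
        if (
            cx - self.core_radius < 0
            or cy - self.core_radius < 0
            or cx + self.core_radius > w - 1
            or cy + self.core_radius > h - 1
        ):
            bad.append("core does not fit inside the image")
        for idx, reg in enumerate(self.stain_regions):
            rx, ry = reg.center
            d = np.hypot(rx - cx, ry - cy)
            if d + reg.radius > self.core_radius - 2:
                bad.append(f"stain region {idx} not inside the core")
            if reg.n_holes < 0:
                bad.append(f"stain region {idx}: negative hole count")
            lo, hi = reg.hole_radius_range
            if reg.n_holes > 0 and (lo <= 0 or hi < lo):
                bad.append(f"stain region {idx}: bad hole_radius_range")
            if reg.n_holes > 0 and hi > reg.radius - 3:
                bad.append(
                    f"stain region {idx}: holes too large to be enclosed"
                )
        for i, a in enumerate(self.stain_regions):
            for j, b in enumerate(self.stain_regions[i + 1 :], start=i + 1):
                dd = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if dd < a.radius + b.radius + 3:
                    bad.append(f"stain regions {i} and {j} overlap or touch")
        if self.noise_sd < 0:
            bad.append("noise_sd must be non-negative")

        def one(rgb):
            return np.array([[rgb]], dtype=np.uint8)

        if brown_channel(one(self.stain_rgb))[0, 0] > 70:
            bad.append("stain_rgb does not map below the brown threshold")
        for name, rgb in [("tissue_rgb", self.tissue_rgb), ("hole_rgb", self.hole_rgb)]:
            if brown_channel(one(rgb))[0, 0] <= 70:
                bad.append(f"{name} maps into the brown-stain window")
            if to_lightness_channel(one(rgb))[0, 0] > 238:
                bad.append(f"{name} lightness exceeds the tissue threshold")
        if to_lightness_channel(one(self.stain_rgb))[0, 0] > 238:
            bad.append("stain_rgb lightness exceeds the tissue threshold")
        if to_lightness_channel(one(self.background_rgb))[0, 0] <= 238:
            bad.append("background_rgb lightness not above the tissue threshold")
        if bad:
            raise SceneValidationError(bad)


@dataclass
class GroundTruth:
    """Exact masks and counts from the pre-noise rasterization."""

    cylinder_mask: np.ndarray
    stain_mask_unfilled: np.ndarray
    stain_mask_filled: np.ndarray
    cylinder_px: int = 0
    stain_px_A: int = 0
    stain_px_B: int = 0
    true_percent_A: float = 0.0
    true_percent_B: float = 0.0
    hole_px: int = 0

    def __post_init__(self):
        self.cylinder_px = int(self.cylinder_mask.sum())
        self.stain_px_A = int(self.stain_mask_unfilled.sum())
        self.stain_px_B = int(self.stain_mask_filled.sum())
        self.hole_px = self.stain_px_B - self.stain_px_A
        self.true_percent_A = 100.0 * self.stain_px_A / self.cylinder_px
        self.true_percent_B = 100.0 * self.stain_px_B / self.cylinder_px


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _median_stabilize(mask: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Iterate the 3x3 binary majority filter to its fixed point."""
    m = mask
    for _ in range(max_iter):
        m2 = ndimage.median_filter(m.astype(np.uint8), size=3, mode="nearest") > 0
        if np.array_equal(m2, m):
            return m
        m = m2
    return m


def generate_cylinder_image(
    scene: CylinderScene,
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a scene into an RGB image plus exact ground truth.

    Deterministic for a fixed ``scene.seed`` (hole placement and pixel
    noise both draw from one seeded generator). Ground-truth masks and
    counts come from the pre-noise rasterization; noise never moves them.
    """
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    h, w = scene.image_size
    cx, cy = scene.center

    core = _median_stabilize(_disk_mask((h, w), cx, cy, scene.core_radius))

    stain_filled = np.zeros((h, w), dtype=bool)
    holes = np.zeros((h, w), dtype=bool)
    for reg in scene.stain_regions:
        rx, ry = reg.center
        stain_filled |= _disk_mask((h, w), rx, ry, reg.radius)
        lo, hi = reg.hole_radius_range
        placed: list[tuple[float, float, float]] = []
        attempts = 0
        # holes are pairwise separated by >= 2 px of stain so they can
        # never fragment the stained region into sub-filter slivers
        while len(placed) < reg.n_holes and attempts < 100 * max(reg.n_holes, 1):
            attempts += 1
            hr = rng.uniform(lo, hi)
            # fully inside the region, leaving a 2-px stained rim
            max_d = reg.radius - hr - 2
            if max_d <= 0:
                continue
            ang = rng.uniform(0, 2 * np.pi)
            d = max_d * np.sqrt(rng.uniform())
            hx, hy = rx + d * np.cos(ang), ry + d * np.sin(ang)
            if any(
                np.hypot(hx - px, hy - py) < hr + pr + 2 for px, py, pr in placed
            ):
                continue
            placed.append((hx, hy, hr))
        for hx, hy, hr in placed:
            holes |= _disk_mask((h, w), hx, hy, hr)

    stain_filled &= core
    holes &= stain_filled
    stain_unfilled = stain_filled & ~holes

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = scene.background_rgb
    img[core] = scene.tissue_rgb
    img[stain_unfilled] = scene.stain_rgb
    img[holes] = scene.hole_rgb

    if scene.noise_sd > 0:
        noisy = img.astype(np.float64) + rng.normal(0, scene.noise_sd, img.shape)
        img = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        cylinder_mask=core,
        stain_mask_unfilled=stain_unfilled,
        stain_mask_filled=stain_filled,
    )
    return img, truth


def single_disk_scene(
    stain_fraction: float,
    n_holes: int = 0,
    hole_radius_range: tuple[float, float] = (6.0, 12.0),
    image_size: tuple[int, int] = (420, 420),
    core_radius: float = 150.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CylinderScene:
    """A core with one centred stain disk covering ~``stain_fraction`` of it.

    ``stain_fraction`` is the *filled* (method-B) fraction of the core
    area; the disk radius is core_radius * sqrt(fraction). Fractions up to
    ~0.95 fit inside the required 2-px tissue margin.
    """
    if not 0 <= stain_fraction < 1:
        raise ValueError("stain_fraction must be in [0, 1)")
    regions: tuple[StainRegion, ...] = ()
    if stain_fraction > 0:
        r = core_radius * np.sqrt(stain_fraction)
        r = min(r, core_radius - 3)
        regions = (
            StainRegion(
                center=((image_size[1] - 1) / 2.0, (image_size[0] - 1) / 2.0),
                radius=r,
                n_holes=n_holes,
                hole_radius_range=hole_radius_range,
            ),
        )
    return CylinderScene(
        image_size=image_size,
        core_radius=core_radius,
        stain_regions=regions,
        noise_sd=noise_sd,
        seed=seed,
    )


def random_scene(
    seed: int,
    image_size: tuple[int, int] = (420, 420),
    core_radius_range: tuple[float, float] = (130.0, 170.0),
    n_regions_range: tuple[int, int] = (0, 4),
    region_radius_range: tuple[float, float] = (22.0, 60.0),
    n_holes_range: tuple[int, int] = (0, 3),
    noise_sd: float = 0.0,
) -> CylinderScene:
    """A randomized valid scene: seeded core size and non-overlapping
    stained regions with 0-3 holes each (rejection-sampled placement)."""
    rng = np.random.default_rng(seed)
    h, w = image_size
    core_r = rng.uniform(*core_radius_range)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    n_regions = int(rng.integers(n_regions_range[0], n_regions_range[1] + 1))
    regions: list[StainRegion] = []
    attempts = 0
    while len(regions) < n_regions and attempts < 300:
        attempts += 1
        rr = rng.uniform(*region_radius_range)
        max_d = core_r - rr - 3
        if max_d <= 0:
            continue
        ang = rng.uniform(0, 2 * np.pi)
        d = max_d * np.sqrt(rng.uniform())
        rx, ry = cx + d * np.cos(ang), cy + d * np.sin(ang)
        if any(
            np.hypot(rx - q.center[0], ry - q.center[1]) < rr + q.radius + 4
            for q in regions
        ):
            continue
        n_holes = int(rng.integers(n_holes_range[0], n_holes_range[1] + 1))
        hole_hi = min(12.0, rr / 2.5)
        regions.append(
            StainRegion(
                center=(rx, ry),
                radius=rr,
                n_holes=n_holes,
                hole_radius_range=(3.0, max(3.5, hole_hi)),
            )
        )
    return CylinderScene(
        image_size=image_size,
        core_radius=core_r,
        stain_regions=tuple(regions),
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_ratings(
    n_subjects: int,
    k_raters: int,
    sigma_subject: float,
    sigma_rater: float,
    sigma_error: float,
    grand_mean: float = 50.0,
    seed: int = 0,
) -> RatingsTable:
    """Draw a complete ratings table from the two-way random model.

    value(i, j) = grand_mean + s_i + r_j + e_ij with s, r, e independent
    zero-mean Gaussians of the given SDs, clamped to [0, 100]. The
    population single-rating absolute-agreement ICC of the unclamped model
    is sigma_subject^2 / (sigma_subject^2 + sigma_rater^2 + sigma_error^2).
    Deterministic per seed.
    """
    if n_subjects < 2 or k_raters < 2:
        raise ValueError("need n_subjects >= 2 and k_raters >= 2")
    if min(sigma_subject, sigma_rater, sigma_error) < 0:
        raise ValueError("standard deviations must be non-negative")
    if sigma_subject == sigma_rater == sigma_error == 0:
        raise DegenerateDataError(
            "all variance components zero: the table would be constant"
        )
    rng = np.random.default_rng(seed)
    s = rng.normal(0, sigma_subject, n_subjects)
    r = rng.normal(0, sigma_rater, k_raters)
    e = rng.normal(0, sigma_error, (n_subjects, k_raters))
    values = np.clip(grand_mean + s[:, None] + r[None, :] + e, 0, 100)
    return RatingsTable(
        values=values,
        subject_ids=[f"img{i:04d}" for i in range(n_subjects)],
        rater_ids=[f"rater{j}" for j in range(k_raters)],
    )
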
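"""Synthetic farm scenes, altitude variants, and simulated detector outputs.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage — enhancement, tiling, detection, fusion, evaluation
— is testable end-to-end without UAV data or a trained model.

The scene emulates a grid-planted banana farm seen from above: star-shaped
green canopies (a filled polar rose with 5-8 lobes, echoing the multiple
leaf tips of a young plant, optionally with a small "sword sucker" blob
beside the pseudostem) at ~1.5 m spacing on a textured grass background,
rendered at the ground resolutions of the three flight altitudes
(1.78 / 2.03 / 2.54 cm/px at 40 / 50 / 60 m). Canopy colours are chosen so
plant pixels always have strictly higher broadband TGI than any background
pixel, which makes the classical reference detector exact on noiseless
scenes.

The detector simulator emits the stochastic per-tile outputs of an
imperfect detector: each plant is found with a per-variant probability
(independently in every tile that covers it), box centres carry Gaussian
localization noise, and false positives arrive per tile at a Poisson rate.

All randomness flows from explicit integer seeds; identical specs and
seeds reproduce outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .detection import BoundingBox, DetectionSet
from .evaluation import GroundTruthSet
from .fusion import AltitudeTransform
from .raster import VARIANT_TAGS, RasterImage
from .tiling import TileGrid, tile_name

__all__ = [
    "FarmSpec",
    "SimDetectorSpec",
    "render_farm",
    "render_altitude_variant",
    "simulate_detections",
]

# grass base colour / canopy base colour (R, G, B digital numbers); the
# canopy's broadband TGI exceeds the background's even at worst-case
# speckle and jitter, keeping the two classes strictly separable
_BACKGROUND_RGB = (95, 108, 82)
_PLANT_RGB = (60, 170, 55)


@dataclasses.dataclass(frozen=True)
class FarmSpec:
    """Layout and appearance of a synthetic grid-planted farm.

    spacing_m: planting distance (1.5 m is typical for banana).
    resolution_cm_per_px: ground sampling distance; 1.78/2.03/2.54 cm/px
    correspond to 40/50/60 m flights. plant_radius_px: canopy radius range
    (a young plant spans well under 50x50 px at the 40 m resolution).
    lobes: range of leaf-tip counts of the star shape. position_jitter_px:
    uniform integer jitter of each plant off its grid node. missing_prob:
    independent probability a planted position lost its plant.
    sucker_prob: probability of a sword-sucker blob beside a plant.
    speckle: amplitude of the uniform per-pixel grass noise.
    """

    rows: int = 8
    cols: int = 10
    spacing_m: float = 1.5
    resolution_cm_per_px: float = 1.78
    plant_radius_px: tuple[int, int] = (10, 18)
    lobes: tuple[int, int] = (5, 8)
    position_jitter_px: float = 4.0
    missing_prob: float = 0.0
    sucker_prob: float = 0.2
    background_rgb: tuple[int, int, int] = _BACKGROUND_RGB
    plant_rgb: tuple[int, int, int] = _PLANT_RGB
    speckle: int = 8
    seed: int = 0

    @property
    def spacing_px(self) -> float:
        return self.spacing_m * 100.0 / self.resolution_cm_per_px

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.spacing_px <= 2 * self.plant_radius_px[1]:
            raise ValueError(
                "plant spacing in pixels must exceed twice the maximum canopy "
                f"radius (spacing {self.spacing_px:.1f} px, "
                f"max radius {self.plant_radius_px[1]} px)"
            )
        if not 0.0 <= self.missing_prob <= 1.0 or not 0.0 <= self.sucker_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")


def _star_mask(radius: int, lobes: int, phase: float) -> np.ndarray:
    """Filled polar rose r(theta) = R (0.55 + 0.45 |cos(k theta / 2)|)."""
    n = 2 * radius + 1
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    theta = np.arctan2(yy, xx) + phase
    rmax = radius * (0.55 + 0.45 * np.abs(np.cos(lobes * theta / 2.0)))
    return np.hypot(yy, xx) <= rmax


def _paint(canvas: np.ndarray, mask: np.ndarray, cy: int, cx: int, color: np.ndarray) -> None:
    r = mask.shape[0] // 2
    h, w = canvas.shape[:2]
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    sub = mask[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
    canvas[y0:y1, x0:x1][sub] = color


def render_farm(spec: FarmSpec) -> tuple[RasterImage, GroundTruthSet]:
    """Render the farm scene and return it with its ground-truth centres.

    Plants sit on a rows x cols grid with integer jitter, dropped
    independently with ``missing_prob``; ground truth lists the surviving
    plant centres (the actual rendered star centres) in mosaic pixel
    coordinates. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing_px
    margin = sp
    width = int(round(2 * margin + (spec.cols - 1) * sp)) + 1
    height = int(round(2 * margin + (spec.rows - 1) * sp)) + 1
    if width < 2 * spec.plant_radius_px[1] or height < 2 * spec.plant_radius_px[1]:
        raise ValueError("canvas too small for the requested grid")

    base = np.array(spec.background_rgb, dtype=float)
    canvas = base + rng.integers(
        -spec.speckle, spec.speckle + 1, size=(height, width, 3)
    )
    canvas = np.clip(canvas, 0, 255)

    jit = int(round(spec.position_jitter_px))
    gt: list[tuple[float, float]] = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            # draw every per-plant random regardless of survival so the
            # rendered layout is stable under changes to missing_prob
            dx, dy = rng.integers(-jit, jit + 1, size=2) if jit else (0, 0)
            radius = int(rng.integers(spec.plant_radius_px[0], spec.plant_radius_px[1] + 1))
            lobes = int(rng.integers(spec.lobes[0], spec.lobes[1] + 1))
            phase = float(rng.uniform(0, 2 * math.pi))
            g_jitter = int(rng.integers(-8, 9))
            has_sucker = rng.uniform() < spec.sucker_prob
            sucker_angle = float(rng.uniform(0, 2 * math.pi))
            missing = rng.uniform() < spec.missing_prob
            if missing:
                continue

            cx = int(round(margin + c * sp)) + int(dx)
            cy = int(round(margin + r * sp)) + int(dy)
            color = np.array(spec.plant_rgb, dtype=float) + np.array([0, g_jitter, 0])
            _paint(canvas, _star_mask(radius, lobes, phase), cy, cx, color)
            if has_sucker:
                sr = max(2, int(round(radius * 0.35)))
                sx = cx + int(round(radius * math.cos(sucker_angle)))
                sy = cy + int(round(radius * math.sin(sucker_angle)))
                _paint(canvas, _star_mask(sr, 4, 0.0), sy, sx, color)
            gt.append((float(cx), float(cy)))

    img = RasterImage(
        np.clip(canvas, 0, 255).astype(np.uint8),
        resolution_cm_per_px=spec.resolution_cm_per_px,
        variant_tag="RGB",
    )
    return img, GroundTruthSet(np.array(gt, dtype=float).reshape(-1, 2))


def render_altitude_variant(
    img: RasterImage,
    gt: GroundTruthSet,
    target_resolution_cm_per_px: float,
    shift_px: tuple[float, float] = (0.0, 0.0),
) -> tuple[RasterImage, GroundTruthSet, AltitudeTransform]:
    """Re-image the reference scene at a coarser ground resolution.

    The image is downscaled by ``reference / target`` resolution ratio and
    translated by ``shift_px`` (emulating the lateral offset between
    independently produced orthomosaics); ground truth follows the same
    map. Returns the exact :class:`AltitudeTransform` that carries variant
    coordinates back to the reference frame, i.e. the inverse scale
    ``target / reference`` with shift ``-shift * target / reference``.
    """
    ref = img.resolution_cm_per_px
    if ref is None:
        raise ValueError("reference image needs resolution_cm_per_px metadata")
    if target_resolution_cm_per_px < ref:
        raise ValueError("target resolution must be >= reference resolution")
    scale = ref / target_resolution_cm_per_px
    sx, sy = shift_px

    out_h = max(1, int(round(img.height * scale)))
    out_w = max(1, int(round(img.width * scale)))
    small = resize(
        img.pixels.astype(float), (out_h, out_w) + img.pixels.shape[2:],
        anti_aliasing=scale < 1.0, preserve_range=True,
    )
    shifted = np.empty_like(small)
    if small.ndim == 2:
        ndimage.shift(small, (sy, sx), output=shifted, order=1, mode="nearest")
    else:
        for b in range(small.shape[2]):
            ndimage.shift(small[:, :, b], (sy, sx), output=shifted[:, :, b], order=1, mode="nearest")
    variant = RasterImage(
        np.clip(np.round(shifted), 0, 255).astype(np.uint8),
        resolution_cm_per_px=target_resolution_cm_per_px,
        variant_tag=img.variant_tag,
    )
    var_gt = GroundTruthSet(gt.points * scale + np.array([sx, sy]))
    inv = 1.0 / scale
    back = AltitudeTransform(x_scale=inv, y_scale=inv, x_shift=-sx * inv, y_shift=-sy * inv)
    return variant, var_gt, back


@dataclasses.dataclass(frozen=True)
class SimDetectorSpec:
    """Stochastic model of an imperfect per-tile detector.

    per_variant_detect_prob: probability a plant is detected on a given
    enhancement variant (each covering tile draws independently).
    loc_noise_sigma_px: Gaussian sigma of the box-centre localization
    error. fp_per_tile: Poisson rate of spurious boxes per tile.
    box_size_px: detected box side-length range. shared_miss_corr: with
    this probability a plant's detection draw reuses a shared (across
    variants) uniform instead of an independent one — correlated misses
    that weaken the multi-variant fusion gain (0 = fully independent;
    the marginal detection probability is unchanged either way).
    """

    per_variant_detect_prob: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"LCS": 0.8, "SCT": 0.8, "TGI": 0.8}
    )
    loc_noise_sigma_px: float = 2.0
    fp_per_tile: float = 0.0
    box_size_px: tuple[int, int] = (24, 40)
    shared_miss_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v, p in self.per_variant_detect_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detect prob for {v!r} must lie in [0, 1]")
        if self.loc_noise_sigma_px < 0 or self.fp_per_tile < 0:
            raise ValueError("noise sigma and fp rate must be >= 0")
        if not 0.0 <= self.shared_miss_corr <= 1.0:
            raise ValueError("shared_miss_corr must lie in [0, 1]")


def simulate_detections(
    gt: GroundTruthSet,
    grid: TileGrid,
    spec: SimDetectorSpec,
    variant: str,
    altitude_tag: str = "40m",
) -> DetectionSet:
    """Simulated per-tile detector output for one enhancement variant.

    Every ground-truth plant, in every tile whose window contains it, emits
    a box with probability ``per_variant_detect_prob[variant]``, centred at
    the plant plus Gaussian noise, with side lengths drawn from
    ``box_size_px`` and clipped to the tile. Each tile also receives
    ``Poisson(fp_per_tile)`` false boxes at uniform positions. Different
    variants use disjoint random substreams of ``spec.seed``, so their
    errors are independent (up to ``shared_miss_corr``).
    """
    if variant not in VARIANT_TAGS:
        raise ValueError(f"unknown variant tag {variant!r}; expected one of {VARIANT_TAGS}")
    if variant not in spec.per_variant_detect_prob:
        raise ValueError(f"no detection probability configured for variant {variant!r}")
    p = spec.per_variant_detect_prob[variant]
    vidx = VARIANT_TAGS.index(variant)
    rng = np.random.default_rng([spec.seed, vidx])
    shared_rng = np.random.default_rng([spec.seed, 1000])

    ts = grid.tile_size
    records: list[tuple[str, BoundingBox]] = []
    pts = gt.points
    # shared per-plant uniforms, one per (plant, covering-tile) emission slot,
    # drawn identically for every variant
    shared_u = {}

    for x0, y0 in grid.origins():
        name = tile_name(x0, y0)
        in_tile = np.where(
            (pts[:, 0] >= x0) & (pts[:, 0] < x0 + ts)
            & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + ts)
        )[0]
        for i in in_tile:
            u_ind = rng.uniform()
            use_shared = rng.uniform() < spec.shared_miss_corr
            if use_shared:
                key = (int(i), x0, y0)
                if key not in shared_u:
                    shared_u[key] = shared_rng.uniform()
                u = shared_u[key]
            else:
                u = u_ind
            noise = rng.normal(0.0, spec.loc_noise_sigma_px, size=2)
            w = int(rng.integers(spec.box_size_px[0], spec.box_size_px[1] + 1))
            h = int(rng.integers(spec.box_size_px[0], spec.box_size_px[1] + 1))
            score = float(rng.uniform(0.5, 1.0))
            if u >= p:
                continue
            cx = pts[i, 0] - x0 + noise[0]
            cy = pts[i, 1] - y0 + noise[1]
            box = _clipped_box(cx, cy, w, h, ts, score)
            if box is not None:
                records.append((name, box))
        n_fp = int(rng.poisson(spec.fp_per_tile))
        for _ in range(n_fp):
            cx, cy = rng.uniform(0, ts, size=2)
            w = int(rng.integers(spec.box_size_px[0], spec.box_size_px[1] + 1))
            h = int(rng.integers(spec.box_size_px[0], spec.box_size_px[1] + 1))
            box = _clipped_box(cx, cy, w, h, ts, float(rng.uniform(0.0, 1.0)))
            if box is not None:
                records.append((name, box))
    return DetectionSet(records, variant_tag=variant, altitude_tag=altitude_tag)


def _clipped_box(
    cx: float, cy: float, w: int, h: int, tile_size: int, score: float
) -> BoundingBox | None:
    xmin = max(0.0, cx - w / 2.0)
    ymin = max(0.0, cy - h / 2.0)
    xmax = min(float(tile_size), cx + w / 2.0)
    ymax = min(float(tile_size), cy + h / 2.0)
    if xmax - xmin < 1.0 or ymax - ymin < 1.0:
        return None
    return BoundingBox(xmin, ymin, xmax, ymax, score=score)
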
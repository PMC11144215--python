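"""Tile extraction and quality-control scoring.

Every slide is cut into a non-overlapping grid of 224x224 tiles at 10x.
Each tile receives a QC score in [0, 1) combining how much of it is
tissue (neither pen mark nor gray background), how close the tissue hue
sits to the hematoxylin-purple / eosin-pink arc, and how saturated the
tissue is:

    score = 1 - 10 / (10 + tissue_percent^2
                          * ln(1 + color_factor * saturation_factor
                                   * quantity_factor) / 100)

Tiles with score strictly above 0.75 enter the prediction bag; if none
survive, the slide fails QC with the device's insufficient-tissue error.

The pen and background detectors are relational channel rules in the
style of the open-source WSI preprocessing filters this pipeline is
modeled on: a pixel is a pen mark when any of a small bank of per-color
threshold triples fires, and background when all pairwise channel
differences fall within a gray tolerance. The numeric constants here are
reconstruction choices collected in :class:`QCConfig`; they are not
claimed to be bit-compatible with any production device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .errors import InsufficientTissueError
from .slideio import SlideImage, compute_thumbnail

# ---------------------------------------------------------------------------
# configuration

# (r_max, g_min, b_min): green-bluish ink — red low, green and blue high
GREEN_PEN_RULES = (
    (150, 160, 140),
    (70, 110, 110),
    (45, 115, 100),
    (30, 75, 60),
    (195, 220, 210),
    (100, 183, 65),
)
# (r_max, g_max, b_min): blue ink — red and green low, blue high
BLUE_PEN_RULES = (
    (60, 120, 190),
    (120, 170, 200),
    (175, 210, 230),
    (37, 95, 160),
    (30, 65, 130),
    (90, 90, 140),
)
# (r_min, g_max, b_max): red ink — red high, green and blue low
RED_PEN_RULES = (
    (150, 80, 90),
    (110, 20, 30),
    (185, 65, 105),
    (195, 85, 125),
    (220, 115, 145),
    (125, 40, 70),
)


@dataclass(frozen=True)
class QCConfig:
    """All reconstruction constants of the QC stage in one place."""

    tile_size: int = 224
    thumbnail_divisor: int = 32
    gray_tolerance: int = 15
    score_threshold: float = 0.75
    # purple-pink hue arc, degrees on the HSV circle
    hue_arc_low: float = 250.0
    hue_arc_high: float = 345.0
    green_pen_rules: tuple = GREEN_PEN_RULES
    blue_pen_rules: tuple = BLUE_PEN_RULES
    red_pen_rules: tuple = RED_PEN_RULES


DEFAULT_QC_CONFIG = QCConfig()


@dataclass(frozen=True)
class TileRef:
    """Grid position of one tile; 0-based top-left origin at 10x."""

    slide_id: str
    x: int
    y: int
    size: int = 224


@dataclass(frozen=True)
class TileQCRecord:
    tile: TileRef
    tissue_percent: float
    quantity_factor: float
    color_factor: float
    saturation_factor: float
    score: float
    passed: bool


class Masks(NamedTuple):
    pen_mask: np.ndarray
    background_mask: np.ndarray


# ---------------------------------------------------------------------------
# masks


def pen_and_background_masks(image: np.ndarray, config: QCConfig = DEFAULT_QC_CONFIG) -> Masks:
    """Boolean pen-mark and gray-background masks for an RGB image."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image")
    r = img[..., 0].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    b = img[..., 2].astype(np.int16)

    pen = np.zeros(img.shape[:2], dtype=bool)
    for r_max, g_min, b_min in config.green_pen_rules:
        pen |= (r < r_max) & (g > g_min) & (b > b_min)
    for r_max, g_max, b_min in config.blue_pen_rules:
        pen |= (r < r_max) & (g < g_max) & (b > b_min)
    for r_min, g_max, b_max in config.red_pen_rules:
        pen |= (r > r_min) & (g < g_max) & (b < b_max)

    tol = config.gray_tolerance
    background = (
        (np.abs(r - g) <= tol) & (np.abs(r - b) <= tol) & (np.abs(g - b) <= tol)
    )
    return Masks(pen_mask=pen, background_mask=background)


# ---------------------------------------------------------------------------
# tiling


def tile_locations(width_px: int, height_px: int, tile_size: int = 224, slide_id: str = "") -> list[TileRef]:
    """Non-overlapping row-major tile grid; partial edge tiles dropped."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    refs = []
    for y in range(0, height_px - tile_size + 1, tile_size):
        for x in range(0, width_px - tile_size + 1, tile_size):
            refs.append(TileRef(slide_id=slide_id, x=x, y=y, size=tile_size))
    return refs


# ---------------------------------------------------------------------------
# quality factors and score


def quantity_factor_from_percent(tissue_percent: float) -> float:
    """Bin tissue percentage into the quantity factor.

    0 -> 0.0; (0, 10) -> 0.1; [10, 80) -> 0.2; [80, 100] -> 1.0.
    """
    if tissue_percent <= 0.0:
        return 0.0
    if tissue_percent < 10.0:
        return 0.1
    if tissue_percent < 80.0:
        return 0.2
    return 1.0


def _hue_arc_distance(hue_deg: np.ndarray, low: float, high: float) -> np.ndarray:
    """Circular angular distance (degrees) from each hue to the [low, high] arc."""
    inside = (hue_deg >= low) & (hue_deg <= high)
    d_low = np.minimum(np.abs(hue_deg - low), 360.0 - np.abs(hue_deg - low))
    d_high = np.minimum(np.abs(hue_deg - high), 360.0 - np.abs(hue_deg - high))
    return np.where(inside, 0.0, np.minimum(d_low, d_high))


def tile_quality_factors(
    tile_pixels: np.ndarray,
    masks: Masks,
    config: QCConfig = DEFAULT_QC_CONFIG,
) -> tuple[float, float, float, float]:
    """(tissue_percent, quantity_factor, color_factor, saturation_factor).

    Tissue = pixels that are neither pen nor background (pen excluded
    before quantity binning). color_factor in [0, 2] rewards tissue hue
    on the purple-pink arc; saturation_factor in [0, 2] is the sum of
    mean HSV saturation and mean value over tissue pixels, penalizing
    washed-out tiles.
    """
    pen, background = masks
    if pen.shape != tile_pixels.shape[:2] or background.shape != tile_pixels.shape[:2]:
        raise ValueError("masks must cover the tile exactly")
    tissue = ~(pen | background)
    tissue_percent = 100.0 * float(tissue.mean())
    quantity = quantity_factor_from_percent(tissue_percent)
    if not tissue.any():
        return tissue_percent, quantity, 0.0, 0.0

    hsv = rgb2hsv(tile_pixels)
    hue_deg = hsv[..., 0][tissue] * 360.0
    dist = _hue_arc_distance(hue_deg, config.hue_arc_low, config.hue_arc_high)
    color_factor = 2.0 * max(0.0, 1.0 - float(dist.mean()) / 90.0)
    saturation_factor = float(hsv[..., 1][tissue].mean() + hsv[..., 2][tissue].mean())
    return tissue_percent, quantity, color_factor, saturation_factor


def qc_score(
    tissue_percent: float,
    color_factor: float,
    saturation_factor: float,
    quantity_factor: float,
) -> float:
    """Evaluate the tile QC score formula (natural logarithm)."""
    if not 0.0 <= tissue_percent <= 100.0:
        raise ValueError("tissue_percent must lie in [0, 100]")
    if min(color_factor, saturation_factor, quantity_factor) < 0.0:
        raise ValueError("quality factors must be non-negative")
    term = tissue_percent**2 * math.log1p(color_factor * saturation_factor * quantity_factor) / 100.0
    return 1.0 - 10.0 / (10.0 + term)


def score_tile(
    tile: TileRef,
    tile_pixels: np.ndarray,
    masks: Masks,
    config: QCConfig = DEFAULT_QC_CONFIG,
) -> TileQCRecord:
    tp, qf, cf, sf = tile_quality_factors(tile_pixels, masks, config)
    s = qc_score(tp, cf, sf, qf)
    return TileQCRecord(
        tile=tile,
        tissue_percent=tp,
        quantity_factor=qf,
        color_factor=cf,
        saturation_factor=sf,
        score=s,
        passed=s > config.score_threshold,
    )


def filter_tiles(records: list[TileQCRecord], threshold: float = 0.75) -> list[TileQCRecord]:
    """Keep tiles with score strictly above the threshold, preserving order.

    Raises :class:`InsufficientTissueError` when no tile survives.
    """
    kept = [r for r in records if r.score > threshold]
    if not kept:
        raise InsufficientTissueError()
    return kept


# ---------------------------------------------------------------------------
# slide-level pipeline


def qc_slide(slide: SlideImage, config: QCConfig = DEFAULT_QC_CONFIG) -> list[TileQCRecord]:
    """Score every grid tile of a slide.

    Masks are computed on a thumbnail (divisor ``config.thumbnail_divisor``)
    and nearest-neighbor upsampled back to tile coordinates — a large
    speed win at negligible cost for stroke-scale artifacts. Color and
    saturation factors use the full-resolution tile pixels.
    """
    d = config.thumbnail_divisor
    thumb = compute_thumbnail(slide, d)
    pen_t, bg_t = pen_and_background_masks(thumb, config)
    pen = np.repeat(np.repeat(pen_t, d, axis=0), d, axis=1)[: slide.height_px, : slide.width_px]
    bg = np.repeat(np.repeat(bg_t, d, axis=0), d, axis=1)[: slide.height_px, : slide.width_px]

    records = []
    for ref in tile_locations(slide.width_px, slide.height_px, config.tile_size, slide.slide_id):
        sl = np.s_[ref.y : ref.y + ref.size, ref.x : ref.x + ref.size]
        masks = Masks(pen_mask=pen[sl], background_mask=bg[sl])
        records.append(score_tile(ref, slide.pixels[sl], masks, config))
    return records


def qc_table(records: list[TileQCRecord]) -> pd.DataFrame:
    """Per-tile QC table matching the CSV output schema."""
    return pd.DataFrame(
        {
            "slide_id": [r.tile.slide_id for r in records],
            "x": [r.tile.x for r in records],
            "y": [r.tile.y for r in records],
            "tissue_percent": [r.tissue_percent for r in records],
            "quantity_factor": [r.quantity_factor for r in records],
            "color_factor": [r.color_factor for r in records],
            "saturation_factor": [r.saturation_factor for r in records],
            "score": [r.score for r in records],
            "passed": [r.passed for r in records],
        }
    )
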
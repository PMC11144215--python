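"""Synthetic H&E-like whole-slide images for end-to-end testing.

Real slides of muscle-invasive bladder cancer cannot ship with the
package, so this module fabricates slides that exercise every stage of
the pipeline: hematoxylin-purple nuclei on eosin-pink stroma, two
tile-level tumor morphologies (compact "solid nest" clusters versus
dispersed small nests, the morphological contrast associated with the
biomarker-positive versus -negative classes), near-white background,
saturated pen-mark strokes, and blurred tissue.

The generator is deliberately simple — flat-shaded blobs, no nuclear
texture, no scanner color profiles — but it is *plantable*: the
solid-nest/dispersed contrast is separable by construction (see
``cluster_compactness``), so a learner that works on these slides
demonstrably recovers a planted signal rather than noise.

Slides are written as single-resolution tiled TIFF at the 10x reference
scale with the magnification recorded in the image description; cohort
manifests are CSV.
"""

from __future__ import annotations

import json
import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

TILE = 224

TILE_KINDS = ("solid_nest", "dispersed", "background", "pen_mark", "blurred_tissue")

# H&E-ish palette (RGB, 8-bit). Stroma pink sits inside the purple-pink
# hue arc used by the QC color factor and has channel spreads > the gray
# tolerance so it never counts as background.
STROMA_RGB = (233, 208, 224)
NUCLEUS_HSV = (0.75, 0.50, 0.60)  # hematoxylin purple
PEN_COLORS = {
    "red": (200, 50, 70),
    "green": (60, 170, 145),
    "blue": (50, 90, 200),
}
BACKGROUND_GRAY = 238


def _hsv_rgb(h: float, s: float, v: float) -> np.ndarray:
    return np.array([round(c * 255) for c in colorsys.hsv_to_rgb(h, s, v)], dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    ``signal_fraction`` is the fraction of *tissue* tiles that carry the
    class morphology (solid nests on positive slides). ``artifact_rates``
    are fractions of all grid tiles rendered as pen-marked, blurred or
    background tiles. Identical spec + seed reproduce the slide
    byte-for-byte.
    """

    slide_id: str
    label: str  # "positive" | "negative"
    width_px: int = 1120
    height_px: int = 1120
    signal_fraction: float = 0.5
    artifact_rates: dict = field(
        default_factory=lambda: {
            "pen_fraction": 0.0,
            "blur_fraction": 0.04,
            "background_fraction": 0.2,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.width_px < TILE or self.height_px < TILE:
            raise ValueError("slide dimensions must fit at least one 224-px tile")
        fracs = [self.signal_fraction, *self.artifact_rates.values()]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")


def _stroma(rng: np.random.Generator, shape=(TILE, TILE)) -> np.ndarray:
    base = np.array(STROMA_RGB, dtype=float)
    img = base + rng.normal(0.0, 3.0, size=shape + (3,))
    return np.clip(img, 0, 255).astype(np.uint8)


def _disk_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint_nuclei(img: np.ndarray, rng: np.random.Generator, centers, radii) -> None:
    color = _hsv_rgb(*NUCLEUS_HSV).astype(float)
    for (cy, cx), r in zip(centers, radii):
        m = _disk_mask(img.shape[:2], cy, cx, r)
        jitter = rng.normal(0.0, 6.0, size=3)
        img[m] = np.clip(color + jitter, 0, 255).astype(np.uint8)


def _solid_nest(rng: np.random.Generator) -> np.ndarray:
    """Few large compact purple nests on pink stroma."""
    img = _stroma(rng)
    n_clusters = int(rng.integers(2, 5))
    for _ in range(n_clusters):
        cy, cx = rng.integers(50, TILE - 50, size=2)
        r = int(rng.integers(32, 52))
        _paint_nuclei(img, rng, [(cy, cx)], [r])
    return img


def _dispersed(rng: np.random.Generator) -> np.ndarray:
    """Many small scattered purple nests."""
    img = _stroma(rng)
    n = int(rng.integers(40, 70))
    centers = rng.integers(6, TILE - 6, size=(n, 2))
    radii = rng.integers(3, 7, size=n)
    _paint_nuclei(img, rng, [tuple(c) for c in centers], radii)
    return img


def _background(rng: np.random.Generator) -> np.ndarray:
    gray = BACKGROUND_GRAY + rng.normal(0.0, 2.0, size=(TILE, TILE))
    img = np.repeat(gray[..., None], 3, axis=2)
    img += rng.integers(-2, 3, size=(TILE, TILE, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def _pen_mark(rng: np.random.Generator) -> np.ndarray:
    img = _dispersed(rng)
    color = np.array(PEN_COLORS[list(PEN_COLORS)[int(rng.integers(0, 3))]], dtype=np.uint8)
    n_strokes = int(rng.integers(2, 4))
    for _ in range(n_strokes):
        # thick stroke from one tile edge to another
        p0 = rng.integers(0, TILE, size=2).astype(float)
        p1 = rng.integers(0, TILE, size=2).astype(float)
        width = int(rng.integers(7, 12))
        for t in np.linspace(0.0, 1.0, 300):
            cy, cx = p0 * (1 - t) + p1 * t
            m = _disk_mask(img.shape[:2], cy, cx, width)
            img[m] = color
    return img


def _blurred_tissue(rng: np.random.Generator) -> np.ndarray:
    img = _dispersed(rng).astype(float)
    for c in range(3):
        img[..., c] = ndi.gaussian_filter(img[..., c], sigma=8.0)
    return np.clip(img, 0, 255).astype(np.uint8)


_KIND_FUNCS = {
    "solid_nest": _solid_nest,
    "dispersed": _dispersed,
    "background": _background,
    "pen_mark": _pen_mark,
    "blurred_tissue": _blurred_tissue,
}


def generate_tile_texture(kind: str, seed: int) -> np.ndarray:
    """Render one 224x224 RGB tile of the given kind, deterministically."""
    if kind not in _KIND_FUNCS:
        raise ValueError(f"unknown tile kind {kind!r}; expected one of {TILE_KINDS}")
    rng = np.random.default_rng(seed)
    return _KIND_FUNCS[kind](rng)


def cluster_compactness(tile: np.ndarray) -> float:
    """Compactness statistic of the purple blob pattern in a tile.

    Mean connected-component area (in pixels) of the hematoxylin-purple
    mask. Solid nests yield few large components (large value), dispersed
    nests many small ones. This is the generator's own learnability
    statistic: the two planted morphologies must separate on it.
    """
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(tile)
    mask = (hsv[..., 0] > 0.62) & (hsv[..., 0] < 0.88) & (hsv[..., 1] > 0.3) & (hsv[..., 2] < 0.8)
    labels, n = ndi.label(mask)
    if n == 0:
        return 0.0
    areas = np.bincount(labels.ravel())[1:]
    return float(areas.mean())


def _tile_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble a slide mosaic and its tile-level truth map.

    Tile kind counts follow the spec's fractions exactly (after rounding);
    placement is a seeded permutation. On positive slides
    ``signal_fraction`` of the tissue tiles are solid nests (``is_signal``
    True); negative slides render all tissue tiles as dispersed.
    """
    gx = spec.width_px // TILE
    gy = spec.height_px // TILE
    n = gx * gy
    if n < 1:
        raise ValueError("slide dimensions must fit at least one tile")

    rates = spec.artifact_rates
    n_bg = round(rates.get("background_fraction", 0.0) * n)
    n_pen = round(rates.get("pen_fraction", 0.0) * n)
    n_blur = round(rates.get("blur_fraction", 0.0) * n)
    if n_bg + n_pen + n_blur > n:
        raise ValueError("artifact fractions exceed the tile budget")
    n_tissue = n - n_bg - n_pen - n_blur
    n_signal = round(spec.signal_fraction * n_tissue) if spec.label == "positive" else 0

    kinds = (
        ["background"] * n_bg
        + ["pen_mark"] * n_pen
        + ["blurred_tissue"] * n_blur
        + ["solid_nest"] * n_signal
        + ["dispersed"] * (n_tissue - n_signal)
    )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    placed = [None] * n
    for slot, kind in zip(order, kinds):
        placed[slot] = kind

    img = np.full((spec.height_px, spec.width_px, 3), BACKGROUND_GRAY, dtype=np.uint8)
    rows = []
    for idx, kind in enumerate(placed):
        iy, ix = divmod(idx, gx)
        x, y = ix * TILE, iy * TILE
        tile = generate_tile_texture(kind, _tile_seed(spec.seed, idx))
        img[y : y + TILE, x : x + TILE] = tile
        rows.append(
            {
                "slide_id": spec.slide_id,
                "tile_index": idx,
                "x": x,
                "y": y,
                "kind": kind,
                "is_signal": kind == "solid_nest" and spec.label == "positive",
            }
        )
    return img, pd.DataFrame(rows)


def write_slide_tiff(path, image: np.ndarray, slide_id: str, magnification: str = "10x") -> None:
    """Write an RGB slide as a tiled TIFF with magnification metadata."""
    meta = json.dumps({"slide_id": slide_id, "magnification": magnification})
    tifffile.imwrite(path, image, tile=(256, 256), photometric="rgb", description=meta)


def generate_cohort(
    n_slides: int,
    prevalence: float,
    template: SyntheticSlideSpec,
    seed: int,
    out_dir,
    cohort_name: str = "SYNTH",
) -> pd.DataFrame:
    """Generate a labeled cohort of slides plus a CSV manifest.

    The positive count is exact — ``round(n_slides * prevalence)`` — a
    stratified draw rather than Bernoulli sampling, so cohort composition
    is reproducible and count-exact. Per-slide seeds are derived by
    hashing (cohort seed, slide index).
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_pos = round(n_slides * prevalence)
    labels = ["positive"] * n_pos + ["negative"] * (n_slides - n_pos)
    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(n_slides)]

    rows = []
    for i, label in enumerate(labels):
        slide_id = f"{cohort_name}-{i:04d}"
        spec = replace(template, slide_id=slide_id, label=label, seed=_tile_seed(seed, i))
        image, truth = generate_slide(spec)
        path = out_dir / f"{slide_id}.tiff"
        write_slide_tiff(path, image, slide_id)
        truth.to_csv(out_dir / f"{slide_id}.truth.csv", index=False)
        rows.append(
            {
                "slide_id": slide_id,
                "file_path": str(path),
                "tissue_site": "Bladder",
                "disease_stage": "MIBC",
                "label": label,
                "cohort_name": cohort_name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
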
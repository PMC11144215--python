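"""Reading whole-slide images and producing thumbnails.

Slides are single-resolution tiled TIFFs (or plain PNG rasters) at a
stated base magnification; pyramidal scanner formats such as SVS can be
plugged in through the same :class:`SlideImage` contract by an external
adapter. The 10x working magnification is obtained from 20x/40x inputs
by factor-2/4 area-averaged downsampling when resampling is enabled;
otherwise a magnification error fires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.transform import downscale_local_mean
from skimage.measure import block_reduce

from .errors import CorruptedImageError, MagnificationError, UnsupportedImageError

SUPPORTED_EXTENSIONS = {".tif", ".tiff", ".png"}
_MAG_FACTORS = {"10x": 1, "20x": 2, "40x": 4}


@dataclass
class SlideImage:
    """In-memory RGB slide at the 10x reference scale."""

    pixels: np.ndarray  # H x W x 3 uint8
    base_magnification: str
    slide_id: str = ""
    path: str = ""

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    def region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        return self.pixels[y : y + h, x : x + w]


def read_slide(path, allow_resample: bool = False) -> SlideImage:
    """Read a slide file, enforcing the device's read-error contract.

    Raises :class:`UnsupportedImageError` for missing paths or unknown
    extensions, :class:`CorruptedImageError` for unreadable content, and
    :class:`MagnificationError` when no 10x level can be obtained (20x or
    40x inputs are area-downsampled to 10x only when ``allow_resample``).
    """
    if not path:
        raise UnsupportedImageError()
    p = Path(path)
    if p.suffix.lower() not in SUPPORTED_EXTENSIONS or not p.is_file():
        raise UnsupportedImageError()

    meta: dict = {}
    try:
        if p.suffix.lower() == ".png":
            with Image.open(p) as im:
                pixels = np.asarray(im.convert("RGB"))
        else:
            with tifffile.TiffFile(p) as tf:
                pixels = tf.asarray()
                desc = tf.pages[0].description
                if desc:
                    try:
                        meta = json.loads(desc)
                    except (ValueError, TypeError):
                        meta = {}
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("not an RGB raster")
    except Exception as exc:  # noqa: BLE001 - any read failure is "corrupted"
        raise CorruptedImageError() from exc

    mag = str(meta.get("magnification", "10x"))
    if mag not in _MAG_FACTORS:
        raise MagnificationError()
    factor = _MAG_FACTORS[mag]
    if factor > 1:
        if not allow_resample:
            raise MagnificationError()
        pixels = downscale_local_mean(pixels.astype(float), (factor, factor, 1))
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)

    return SlideImage(
        pixels=np.ascontiguousarray(pixels),
        base_magnification="10x",
        slide_id=str(meta.get("slide_id", p.stem)),
        path=str(p),
    )


def compute_thumbnail(slide: SlideImage | np.ndarray, scale_divisor: int = 32) -> np.ndarray:
    """Low-resolution thumbnail by block averaging.

    Output dimensions are ``ceil(original / scale_divisor)``; divisor 1
    returns the image unchanged.
    """
    if scale_divisor < 1:
        raise ValueError("scale_divisor must be >= 1")
    pixels = slide.pixels if isinstance(slide, SlideImage) else slide
    if scale_divisor == 1:
        return pixels.copy()
    h, w = pixels.shape[:2]
    pad_h = (-h) % scale_divisor
    pad_w = (-w) % scale_divisor
    padded = np.pad(pixels, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
    thumb = block_reduce(padded.astype(float), (scale_divisor, scale_divisor, 1), np.mean)
    return np.clip(np.round(thumb), 0, 255).astype(np.uint8)
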
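"""Tile feature extraction and stain augmentation.

A backbone is any callable mapping one RGB tile to a 512-vector; the
bag of tile embeddings (N x 512 with aligned tile references) is the
unit of prediction for the attention network. The default backbone is a
deterministic handcrafted descriptor — color/HSV/gradient histograms
plus nuclear-blob morphology statistics, mixed into 512 dimensions by a
fixed random projection. It needs no pretrained weights, runs on one
CPU, and is linear in the descriptor, so class structure that separates
in descriptor space stays separable in embedding space. Any pretrained
CNN exposing a 512-d pooled output satisfies the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.filters import sobel

from .qc import TileRef

FEATURE_DIM = 512
_PROJECTION_SEED = 914_852_103  # fixed: backbone must be frozen


@dataclass
class FeatureBag:
    """N x 512 tile-embedding matrix with aligned tile references."""

    features: np.ndarray
    tiles: list[TileRef]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.tiles):
            raise ValueError("features must be N x D aligned with tiles")
        if self.features.shape[0] < 1:
            raise ValueError("a feature bag needs at least one tile")
        if not np.isfinite(self.features).all():
            raise ValueError("feature bag contains non-finite entries")

    @property
    def n(self) -> int:
        return self.features.shape[0]


class HandcraftedBackbone:
    """Deterministic tile -> 512 descriptor backbone.

    Descriptor blocks: per-channel RGB and HSV histograms (16 bins),
    Sobel gradient-magnitude histogram, channel means/stds, and
    morphology of the hematoxylin-purple blob mask (component count,
    mean/max/std area) — the statistics that distinguish compact solid
    nests from dispersed small nests. The descriptor is projected to 512
    dimensions by a frozen Gaussian random matrix.
    """

    name = "handcrafted-v1"

    def __init__(self, out_dim: int = FEATURE_DIM):
        self.out_dim = out_dim
        self._projection: np.ndarray | None = None

    def _descriptor(self, tile: np.ndarray) -> np.ndarray:
        img = np.asarray(tile, dtype=np.float64) / 255.0
        hsv = rgb2hsv(img)
        parts = []
        for c in range(3):
            parts.append(np.histogram(img[..., c], bins=16, range=(0, 1))[0])
            parts.append(np.histogram(hsv[..., c], bins=16, range=(0, 1))[0])
        gray = img.mean(axis=2)
        grad = sobel(gray)
        parts.append(np.histogram(grad, bins=16, range=(0, 0.5))[0])
        npix = img.shape[0] * img.shape[1]
        hist = np.concatenate(parts) / npix

        blob = (
            (hsv[..., 0] > 0.62)
            & (hsv[..., 0] < 0.88)
            & (hsv[..., 1] > 0.3)
            & (hsv[..., 2] < 0.8)
        )
        labels, ncomp = ndi.label(blob)
        if ncomp:
            areas = np.bincount(labels.ravel())[1:] / npix
            morph = [
                blob.mean(),
                ncomp / 100.0,
                float(areas.mean()) * 100.0,
                float(areas.max()) * 100.0,
                float(areas.std()) * 100.0,
            ]
        else:
            morph = [0.0, 0.0, 0.0, 0.0, 0.0]
        stats = [img[..., c].mean() for c in range(3)] + [img[..., c].std() for c in range(3)]
        return np.concatenate([hist, morph, stats])

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        d = self._descriptor(tile)
        if self._projection is None or self._projection.shape[1] != d.shape[0]:
            rng = np.random.default_rng(_PROJECTION_SEED)
            self._projection = rng.normal(
                0.0, 1.0 / np.sqrt(d.shape[0]), size=(self.out_dim, d.shape[0])
            )
        return self._projection @ d


def extract_features(tiles, backbone, tile_refs=None) -> FeatureBag:
    """Embed a list of RGB tiles into an N x 512 feature bag."""
    tiles = list(tiles)
    if not tiles:
        raise ValueError("cannot extract features from an empty tile list")
    feats = np.stack([np.asarray(backbone(t), dtype=np.float64) for t in tiles])
    if tile_refs is None:
        tile_refs = [TileRef(slide_id="", x=0, y=i * 224) for i in range(len(tiles))]
    return FeatureBag(features=feats, tiles=list(tile_refs))


# ---------------------------------------------------------------------------
# stain augmentation

# Normalized stain-direction vectors in optical density space
# (hematoxylin, eosin, residual), the classic H&E deconvolution basis.
_STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
        [0.268, 0.570, 0.776],
    ]
)
_STAIN_MATRIX /= np.linalg.norm(_STAIN_MATRIX, axis=1, keepdims=True)
_STAIN_INV = np.linalg.inv(_STAIN_MATRIX)


def stain_augmentations(tile: np.ndarray, k: int, magnitude: float, seed: int) -> list[np.ndarray]:
    """Generate ``k`` stain-perturbed color variants of a tile.

    The tile is deconvolved into hematoxylin/eosin/residual optical
    densities; each stain channel is scaled by ``1 ± magnitude`` and
    shifted by a smaller offset, then reconvolved. Geometry is untouched
    and ``magnitude = 0`` returns exact copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0.0:
        return [tile.copy() for _ in range(k)]

    rng = np.random.default_rng(seed)
    od = -np.log10((tile.astype(np.float64) + 1.0) / 256.0)
    conc = od @ _STAIN_INV
    out = []
    for _ in range(k):
        alpha = rng.uniform(1.0 - magnitude, 1.0 + magnitude, size=3)
        beta = rng.uniform(-magnitude, magnitude, size=3) * 0.2
        od_new = (conc * alpha + beta) @ _STAIN_MATRIX
        img = 256.0 * np.power(10.0, -od_new) - 1.0
        out.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    return out
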
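"""Morphology front end: tissue masking, patch tiling, encoding, aggregation.

A slide image is reduced to an *embedding bag*: tissue is segmented from the
white background, the image is cut into non-overlapping ``patch_size`` square
patches anchored at the image origin (partial edge tiles discarded), tissue-
poor patches are dropped, and each retained patch is mapped through a
:class:`PatchEncoder` to a fixed-dimension vector.  Bags are the input to the
morphology encoder of the multimodal alignment stage.

No stain or colour normalisation is applied anywhere in this pipeline.
Magnification is the caller's responsibility (declared metadata; no
rescaling is performed here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from skimage.color import rgb2hsv, rgb2gray
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 256


class FormatError(ValueError):
    pass


class ContractError(RuntimeError):
    """A patch encoder violated its output contract."""


@dataclass
class TissueMask:
    """Binary tissue mask at ``downsample``:1 resolution relative to the source."""

    mask: np.ndarray
    downsample: int = 1


@dataclass
class PatchGrid:
    """Non-overlapping patch coordinates (0-based, half-open, row-major)."""

    patch_size: int
    coordinates: list[tuple[int, int]]
    tissue_fraction: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class EmbeddingBag:
    """Per-slide set of patch embeddings, rows aligned with coordinates."""

    embeddings: np.ndarray  # n_patches x d
    coordinates: list[tuple[int, int]]
    encoder_name: str


class PatchEncoder(Protocol):
    """Contract: deterministically map an RGB patch to a fixed-length vector."""

    name: str
    dim: int

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an RGB H x W x 3 image, got shape {image.shape}")
    if image.size == 0:
        raise FormatError("empty image")
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return image.astype(float)


def compute_tissue_mask(
    image: np.ndarray,
    saturation_threshold: float = 0.08,
    min_object_px: int = 16,
) -> TissueMask:
    """Segment tissue from background by HSV saturation.

    Grayscale background (white slide glass, grey artifacts) has near-zero
    saturation; a pixel is tissue iff its saturation exceeds the threshold.
    Connected components smaller than ``min_object_px`` are removed as
    speckle.  A pure-white image yields an empty mask.
    """
    rgb = _as_rgb(image)
    sat = rgb2hsv(rgb)[..., 1]
    mask = sat > saturation_threshold
    if min_object_px > 1 and mask.any():
        # keep components of >= min_object_px pixels (max_size removes <=)
        try:
            mask = remove_small_objects(mask, max_size=min_object_px - 1)
        except TypeError:  # older scikit-image
            mask = remove_small_objects(mask, min_size=min_object_px)
    return TissueMask(mask=mask, downsample=1)


def tile_slide(
    image: np.ndarray,
    mask: TissueMask,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_tissue_fraction: float = 0.5,
) -> PatchGrid:
    """Tile an image into non-overlapping tissue-bearing patches.

    The grid is anchored at (0, 0); partial tiles at the right/bottom edges
    are discarded; a patch is kept iff the fraction of tissue pixels inside
    it (from ``mask``) is at least ``min_tissue_fraction``.  Ordering is
    row-major over kept patches.
    """
    rgb = _as_rgb(image)
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    h, w = rgb.shape[:2]
    ds = mask.downsample
    if (
        abs(mask.mask.shape[0] * ds - h) > ds
        or abs(mask.mask.shape[1] * ds - w) > ds
    ):
        raise ValueError("mask is not aligned to the image")
    n_rows, n_cols = h // patch_size, w // patch_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"image {h}x{w} smaller than one {patch_size}px patch; empty grid",
            RuntimeWarning,
            stacklevel=2,
        )
        return PatchGrid(patch_size=patch_size, coordinates=[], tissue_fraction=[])
    coords: list[tuple[int, int]] = []
    fracs: list[float] = []
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * patch_size, j * patch_size
            sub = mask.mask[r // ds : (r + patch_size) // ds, c // ds : (c + patch_size) // ds]
            frac = float(sub.mean()) if sub.size else 0.0
            if frac >= min_tissue_fraction:
                coords.append((r, c))
                fracs.append(frac)
    return PatchGrid(patch_size=patch_size, coordinates=coords, tissue_fraction=fracs)


class ToyStatsEncoder:
    """Deterministic colour-statistics patch encoder (d = 22).

    Features: per-channel mean (3), per-channel standard deviation (3), and a
    16-bin grayscale intensity histogram normalised to sum 1 (16).  Fast,
    dependency-free, and sufficient to carry planted synthetic signal; any
    foundation model can be plugged in behind the same contract.
    """

    name = "toy"
    dim = 22

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        rgb = _as_rgb(patch)
        flat = rgb.reshape(-1, 3)
        gray = rgb2gray(rgb)
        hist, _ = np.histogram(gray, bins=16, range=(0.0, 1.0))
        hist = hist / max(hist.sum(), 1)
        return np.concatenate([flat.mean(axis=0), flat.std(axis=0), hist])


ENCODERS: dict[str, type] = {"toy": ToyStatsEncoder}


def encode_bag(
    image: np.ndarray, grid: PatchGrid, encoder: PatchEncoder
) -> EmbeddingBag:
    """Encode every retained patch; one row per patch in grid order."""
    if len(grid) == 0:
        raise ValueError("cannot encode an empty grid")
    rgb = _as_rgb(image)
    rows = []
    dim = None
    for r, c in grid.coordinates:
        patch = rgb[r : r + grid.patch_size, c : c + grid.patch_size]
        vec = np.asarray(encoder(patch), dtype=float)
        if vec.ndim != 1:
            raise ContractError("encoder must return a 1-D vector")
        if dim is None:
            dim = vec.shape[0]
        elif vec.shape[0] != dim:
            raise ContractError(
                f"encoder output dimension changed from {dim} to {vec.shape[0]}"
            )
        rows.append(vec)
    return EmbeddingBag(
        embeddings=np.vstack(rows),
        coordinates=list(grid.coordinates),
        encoder_name=getattr(encoder, "name", type(encoder).__name__),
    )


class GatedAttentionPool:
    """Gated attention pooling over a bag (trainable weights).

    score_i = w^T (tanh(V x_i) * sigmoid(U x_i)); attention = softmax(score);
    output = sum_i attention_i x_i -- a convex combination of patch rows.
    """

    def __init__(self, dim: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(dim)
        self.V = rng.uniform(-s, s, size=(dim, hidden))
        self.U = rng.uniform(-s, s, size=(dim, hidden))
        self.w = rng.uniform(-1.0 / np.sqrt(hidden), 1.0 / np.sqrt(hidden), size=hidden)

    def weights(self, bag: np.ndarray) -> np.ndarray:
        scores = (np.tanh(bag @ self.V) * (1.0 / (1.0 + np.exp(-(bag @ self.U))))) @ self.w
        scores = scores - scores.max()
        e = np.exp(scores)
        return e / e.sum()

    def __call__(self, bag: np.ndarray) -> np.ndarray:
        return self.weights(bag) @ bag


def aggregate_bag(
    bag: EmbeddingBag | np.ndarray,
    method: str = "mean",
    attention: GatedAttentionPool | None = None,
) -> np.ndarray:
    """Aggregate a bag into one slide-level vector.

    ``mean`` is the column-wise average (default); ``attention`` applies a
    :class:`GatedAttentionPool` (created on the fly when not supplied), whose
    softmax weights sum to 1 so the output is a convex combination of rows.
    """
    matrix = bag.embeddings if isinstance(bag, EmbeddingBag) else np.asarray(bag, float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("bag must be a nonempty n_patches x d matrix")
    if method == "mean":
        return matrix.mean(axis=0)
    if method == "attention":
        pool = attention if attention is not None else GatedAttentionPool(matrix.shape[1])
        return pool(matrix)
    raise ValueError(f"unknown aggregation method {method!r}")
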
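"""Image I/O, geometry and the preprocessing chain.

Pseudo-thermal frames are plain 8-bit rasters (intensity is a monotone proxy
for surface temperature).  The detection pipeline preprocesses each frame by
grayscale conversion, per-image median thresholding (suppresses ambient
thermal noise below the body signal) and contrast-limited adaptive histogram
equalization (CLAHE) so that the cooler feet retain enough local contrast for
shape-based detection.

Conventions: rasters are row-major ``numpy`` arrays with origin at the top
left; coordinates are 0-based; bounding boxes are half-open
``[x, x+w) x [y, y+h)``.  All transforms are pure — inputs are never
modified in place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import UnsupportedImageError

#: BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class BBox:
    """Rectangular region, half-open pixel convention ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError(f"box extent must be >= 1 pixel, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    def within(self, shape) -> bool:
        """True if the box lies fully inside an ``(H, W)`` raster."""
        H, W = shape[:2]
        return self.x >= 0 and self.y >= 0 and self.x2 <= W and self.y2 <= H


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes (0 when disjoint)."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass
class ThermalImage:
    """A pseudo-thermal frame with acquisition metadata."""

    pixels: np.ndarray  # HxW or HxWx3 uint8
    image_id: str = ""
    patient_id: str = ""
    timestamp: Optional["object"] = None  # pandas.Timestamp or datetime

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"expected HxW or HxWx3 raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        self.pixels = px


def load_image(path, image_id: str = "", patient_id: str = "", timestamp=None) -> ThermalImage:
    """Read an 8-bit PNG/TIFF into a :class:`ThermalImage`, bit-exactly.

    Raises :class:`UnsupportedImageError` for missing files, non-8-bit depth
    or modes other than grayscale/RGB.
    """
    path = Path(path)
    if not path.exists():
        raise UnsupportedImageError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode not in ("L", "RGB"):
                raise UnsupportedImageError(
                    f"unsupported image mode {mode!r} in {path}: only 8-bit grayscale (L) "
                    "or RGB images are supported"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except UnsupportedImageError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap PIL's zoo of errors
        raise UnsupportedImageError(f"cannot read {path}: {exc}") from exc
    return ThermalImage(arr, image_id=image_id or path.stem, patient_id=patient_id,
                        timestamp=timestamp)


def save_image(path, pixels: np.ndarray) -> None:
    """Write an 8-bit raster as PNG/TIFF (format from the file suffix)."""
    px = np.asarray(pixels)
    if px.dtype != np.uint8:
        raise ValueError("save_image expects uint8 pixels")
    Image.fromarray(px).save(path)


def to_grayscale(img) -> np.ndarray:
    """Luma-weighted (BT.601) grayscale conversion, rounded to nearest integer.

    Accepts a :class:`ThermalImage` or a bare array; 2-D input passes through
    unchanged (a copy is returned so callers can mutate safely).
    """
    px = img.pixels if isinstance(img, ThermalImage) else np.asarray(img)
    if px.ndim == 2:
        return px.copy()
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected HxW or HxWx3 raster, got shape {px.shape}")
    r, g, b = LUMA_WEIGHTS
    gray = r * px[..., 0].astype(np.float64) + g * px[..., 1] + b * px[..., 2]
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_threshold(img: np.ndarray) -> np.ndarray:
    """Zero every pixel strictly below the per-image median.

    Pixels equal to the median are kept, so the median pixel itself survives;
    this makes the operation exactly reproducible in tests.
    """
    px = np.asarray(img)
    if px.size == 0:
        raise ValueError("cannot threshold an empty image")
    med = np.median(px)
    out = px.copy()
    out[px < med] = 0
    return out


def enhance_contrast(img: np.ndarray, clip_limit: float = 2.0,
                     tile_grid: tuple = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit raster.

    Tile-wise clipped-histogram look-up tables with bilinear interpolation
    between neighbouring tile mappings.  ``clip_limit`` scales the per-tile
    histogram ceiling as ``clip_limit * tile_area / 256`` (the convention of
    the 8-bit CLAHE used in mainstream computer-vision tooling); excess mass
    is redistributed uniformly over all bins.  With a single tile and a large
    clip limit this reduces to plain histogram equalization
    ``v -> round(255 * cdf(v) / N)``.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    gh, gw = int(tile_grid[0]), int(tile_grid[1])
    if gh < 1 or gw < 1:
        raise ValueError(f"tile_grid must have >= 1 tile per side, got {tile_grid}")
    px = np.asarray(img)
    if px.ndim != 2:
        raise ValueError("enhance_contrast expects a 2-D grayscale raster")
    H, W = px.shape
    th = int(np.ceil(H / gh))
    tw = int(np.ceil(W / gw))
    padded = np.pad(px, ((0, gh * th - H), (0, gw * tw - W)), mode="edge")

    # Per-tile clipped-histogram LUTs.
    area = th * tw
    ceiling = max(1.0, clip_limit * area / 256.0)
    tiles = padded.reshape(gh, th, gw, tw).transpose(0, 2, 1, 3).reshape(gh, gw, area)
    luts = np.empty((gh, gw, 256), dtype=np.float64)
    for r in range(gh):
        for c in range(gw):
            hist = np.bincount(tiles[r, c], minlength=256).astype(np.float64)
            excess = np.clip(hist - ceiling, 0, None).sum()
            hist = np.minimum(hist, ceiling) + excess / 256.0
            luts[r, c] = np.rint(np.cumsum(hist) * 255.0 / area)
    luts = np.clip(luts, 0, 255)

    # Bilinear interpolation between the four surrounding tile centres.
    yy = (np.arange(gh * th) + 0.5) / th - 0.5
    xx = (np.arange(gw * tw) + 0.5) / tw - 0.5
    r0 = np.clip(np.floor(yy).astype(int), 0, gh - 1)
    r1 = np.clip(r0 + 1, 0, gh - 1)
    fr = np.clip(yy - np.floor(yy), 0.0, 1.0)
    fr[yy < 0] = 0.0
    c0 = np.clip(np.floor(xx).astype(int), 0, gw - 1)
    c1 = np.clip(c0 + 1, 0, gw - 1)
    fc = np.clip(xx - np.floor(xx), 0.0, 1.0)
    fc[xx < 0] = 0.0

    R0 = r0[:, None]
    R1 = r1[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    v00 = luts[R0, C0, padded]
    v01 = luts[R0, C1, padded]
    v10 = luts[R1, C0, padded]
    v11 = luts[R1, C1, padded]
    FR = fr[:, None]
    FC = fc[None, :]
    out = ((1 - FR) * ((1 - FC) * v00 + FC * v01) + FR * ((1 - FC) * v10 + FC * v11))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)[:H, :W]


def extract_patch(img: np.ndarray, box: BBox, target_side: int) -> np.ndarray:
    """Crop ``box``, zero-pad the shorter side symmetrically to a square, and
    resize (bilinear) to ``target_side`` x ``target_side``.

    Zero padding matches the background value after median thresholding.  An
    odd padding total puts the extra row/column at the bottom/right.
    """
    px = np.asarray(img)
    if px.ndim != 2:
        raise ValueError("extract_patch expects a 2-D grayscale raster")
    if not box.within(px.shape):
        raise ValueError(f"box {box} extends outside image of shape {px.shape}")
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    crop = px[box.y:box.y2, box.x:box.x2]
    h, w = crop.shape
    if h != w:
        side = max(h, w)
        dy, dx = side - h, side - w
        crop = np.pad(crop, ((dy // 2, dy - dy // 2), (dx // 2, dx - dx // 2)),
                      mode="constant", constant_values=0)
    if crop.shape[0] == target_side:
        return crop.astype(np.uint8, copy=True)
    out = _sk_resize(crop.astype(np.float64), (target_side, target_side),
                     order=1, preserve_range=True, anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess(gray: np.ndarray, clip_limit: float = 2.0,
               tile_grid: tuple = (8, 8)):
    """Full detection-path preprocessing: median threshold then CLAHE.

    Returns ``(thresholded, enhanced)``: the thresholded raster feeds the
    silhouette estimate, the enhanced raster feeds window scoring.  ROI median
    intensities are deliberately NOT taken from either output — they come from
    the raw grayscale raster (see :mod:`thermoshock.cpd`).
    """
    thresholded = median_threshold(gray)
    enhanced = enhance_contrast(thresholded, clip_limit=clip_limit, tile_grid=tile_grid)
    return thresholded, enhanced
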
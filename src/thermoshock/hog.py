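"""Histogram-of-oriented-gradients descriptor for fixed-size patches.

Thermal frames carry no usable texture or colour, so ROI detection relies on
shape alone: local gradient-orientation histograms summarise body-part
outlines while staying invariant to the absolute intensity level (and hence
to ambient temperature drift).

Descriptor layout: the patch is tiled into ``cell_side``-pixel cells (cells
that do not fully fit are discarded); each cell accumulates a
gradient-magnitude-weighted orientation histogram with linear interpolation
between the two nearest orientation bins; overlapping blocks of
``block_cells`` x ``block_cells`` cells are normalized independently and
concatenated in row-major block order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HOGParams:
    """Descriptor recipe.

    n_orientations: orientation bins over [0, 180) (unsigned) or [0, 360).
    cell_side: cell size in pixels.
    block_cells: cells per block side (blocks overlap).
    block_stride: block step in cells.
    signed_gradients: use the full [0, 360) orientation range.
    block_norm: "l2hys" (L2 norm, clip, renormalize) or "l2".
    hys_clip: clipping level for L2-Hys.
    """

    n_orientations: int = 9
    cell_side: int = 8
    block_cells: int = 2
    block_stride: int = 1
    signed_gradients: bool = False
    block_norm: str = "l2hys"
    hys_clip: float = 0.2

    def __post_init__(self):
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if self.cell_side < 2:
            raise ValueError("cell_side must be >= 2")
        if self.block_cells < 1:
            raise ValueError("block_cells must be >= 1")
        if self.block_stride < 1:
            raise ValueError("block_stride must be >= 1")
        if self.block_norm not in ("l2hys", "l2"):
            raise ValueError(f"unknown block_norm {self.block_norm!r}")

    def n_cells(self, shape) -> tuple:
        return shape[0] // self.cell_side, shape[1] // self.cell_side

    def n_blocks(self, shape) -> tuple:
        ncy, ncx = self.n_cells(shape)
        nby = (ncy - self.block_cells) // self.block_stride + 1
        nbx = (ncx - self.block_cells) // self.block_stride + 1
        return max(nby, 0), max(nbx, 0)

    def feature_length(self, shape) -> int:
        nby, nbx = self.n_blocks(shape)
        return nby * nbx * self.block_cells ** 2 * self.n_orientations


def _gradients(patch: np.ndarray):
    """Centered [-1, 0, 1] gradient filters; one-sided differences at borders."""
    p = patch.astype(np.float64)
    gx = np.empty_like(p)
    gy = np.empty_like(p)
    gx[:, 1:-1] = p[:, 2:] - p[:, :-2]
    gx[:, 0] = p[:, 1] - p[:, 0]
    gx[:, -1] = p[:, -1] - p[:, -2]
    gy[1:-1, :] = p[2:, :] - p[:-2, :]
    gy[0, :] = p[1, :] - p[0, :]
    gy[-1, :] = p[-1, :] - p[-2, :]
    return gx, gy


def cell_histograms(patch: np.ndarray, params: HOGParams) -> np.ndarray:
    """Per-cell orientation histograms, shape (ncy, ncx, n_orientations)."""
    ncy, ncx = params.n_cells(patch.shape)
    if ncy < 1 or ncx < 1:
        raise ValueError(
            f"patch {patch.shape} smaller than one {params.cell_side}px cell")
    used = patch[: ncy * params.cell_side, : ncx * params.cell_side]
    gx, gy = _gradients(used)
    mag = np.hypot(gx, gy)
    span = 360.0 if params.signed_gradients else 180.0
    ang = np.rad2deg(np.arctan2(gy, gx)) % span

    # Linear interpolation between the two nearest orientation-bin centres
    # (centres at (i + 0.5) * span / n, circular).
    n = params.n_orientations
    bin_width = span / n
    pos = ang / bin_width - 0.5
    lo = np.floor(pos).astype(int)
    w_hi = pos - lo
    bin_lo = lo % n
    bin_hi = (lo + 1) % n

    cs = params.cell_side
    rows = np.arange(used.shape[0]) // cs
    cols = np.arange(used.shape[1]) // cs
    cell_idx = rows[:, None] * ncx + cols[None, :]
    flat_lo = (cell_idx * n + bin_lo).ravel()
    flat_hi = (cell_idx * n + bin_hi).ravel()
    hist = np.bincount(flat_lo, weights=(mag * (1 - w_hi)).ravel(),
                       minlength=ncy * ncx * n)
    hist += np.bincount(flat_hi, weights=(mag * w_hi).ravel(),
                        minlength=ncy * ncx * n)
    return hist.reshape(ncy, ncx, n)


def compute_hog(patch: np.ndarray, params: HOGParams = HOGParams()) -> np.ndarray:
    """HOG feature vector of a grayscale patch.

    Raises ``ValueError`` when the patch cannot host a single block.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("compute_hog expects a 2-D grayscale patch")
    min_side = params.cell_side * params.block_cells
    if patch.shape[0] < min_side or patch.shape[1] < min_side:
        raise ValueError(
            f"patch {patch.shape} smaller than one block "
            f"({min_side}x{min_side} px)")

    hist = cell_histograms(patch, params)
    ncy, ncx, n = hist.shape
    bc, stride = params.block_cells, params.block_stride
    eps = 1e-10
    blocks = []
    for by in range(0, ncy - bc + 1, stride):
        for bx in range(0, ncx - bc + 1, stride):
            v = hist[by:by + bc, bx:bx + bc, :].ravel()
            norm = np.sqrt(np.sum(v * v) + eps)
            v = v / norm
            if params.block_norm == "l2hys":
                v = np.minimum(v, params.hys_clip)
                v = v / np.sqrt(np.sum(v * v) + eps)
            blocks.append(v)
    return np.concatenate(blocks) if blocks else np.empty(0)


def hog_matrix(patches, params: HOGParams = HOGParams()) -> np.ndarray:
    """Stack descriptors of equally sized patches into an (n, d) matrix."""
    return np.vstack([compute_hog(p, params) for p in patches])
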
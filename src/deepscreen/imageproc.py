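"""Raw tile images -> per-cluster integrated fluorescence intensities.

The quantification chain mirrors how flow-cell scans are reduced to cluster
photometry:

1. non-uniform illumination correction by subtracting a morphological opening
   (disk radius 25 px) from the tile,
2. cluster centroid detection as local maxima of a 3x3 dilation above a fixed
   intensity threshold (default 600),
3. coarse alignment of detected centroids against the known sequencing
   coordinates by FFT phase correlation, refined per 128x128 sub-tile into an
   offset map,
4. photometry: a 9x9 window centred on the offset-corrected coordinates is
   multiplied element-wise with an amplitude-1 Gaussian kernel (sigma 0.5) and
   summed.  Clusters whose window leaves the image are flagged rejected.

The Gaussian kernel is a weighting, not a normalized PSF: its centre weight is
exactly 1, so intensities are comparable across clusters but carry an
arbitrary global scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, opening

DEFAULT_PEAK_THRESHOLD = 600.0
DEFAULT_DISK_RADIUS = 25
DEFAULT_WINDOW = 9
DEFAULT_SIGMA = 0.5
DEFAULT_SUBTILE = 128
DEFAULT_MIN_POINTS = 10


def correct_illumination(img: np.ndarray, disk_radius: int = DEFAULT_DISK_RADIUS) -> np.ndarray:
    """Subtract the morphological opening of the tile from the tile.

    The opening with a disk wider than any cluster estimates the smooth
    background/gain structure; subtracting it flattens illumination while
    preserving features narrower than the disk.  Output is clipped at zero.
    """
    if img.ndim != 2:
        raise ValueError("expected a 2D tile image")
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    opened = opening(img, disk(disk_radius))
    out = img.astype(np.int64) - opened.astype(np.int64)
    return np.clip(out, 0, None).astype(img.dtype if img.dtype.kind == "u" else np.int64)


def detect_peaks(img: np.ndarray, threshold: float = DEFAULT_PEAK_THRESHOLD) -> np.ndarray:
    """Local maxima of a 3x3 dilation, strictly above ``threshold``.

    A pixel is a centroid when it equals its own value in the 3x3
    grey-dilated image and exceeds the threshold.  Plateau pixels all
    qualify; no deduplication is applied.  Returns an (n, 2) array of
    (x, y) = (column, row) in row-major scan order.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dil = ndimage.grey_dilation(img, size=(3, 3), mode="nearest")
    mask = (img == dil) & (img > threshold)
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys])


def _raster(points: np.ndarray, shape) -> np.ndarray:
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    pts = np.rint(np.asarray(points, dtype=float)).astype(int)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    img[pts[keep, 1], pts[keep, 0]] = 1.0
    return img


def _phase_correlate(moving: np.ndarray, reference: np.ndarray,
                     max_shift: int | None = None):
    """Integer shift (dx, dy) such that reference translated by it matches moving.

    ``max_shift`` restricts the admissible displacement; the FFT correlation
    is circular, so unbounded argmax on near-periodic point lattices can pick
    a wrapped alias of the true shift.
    """
    f1 = np.fft.fft2(moving)
    f2 = np.fft.fft2(reference)
    cross = f1 * np.conj(f2)
    denom = np.abs(cross)
    cross = np.where(denom > 1e-12, cross / np.maximum(denom, 1e-12), 0)
    corr = np.fft.ifft2(cross).real
    h, w = corr.shape
    sy = (np.arange(h) + h // 2) % h - h // 2
    sx = (np.arange(w) + w // 2) % w - w // 2
    if max_shift is not None:
        corr = corr.copy()
        corr[np.abs(sy) > max_shift, :] = -np.inf
        corr[:, np.abs(sx) > max_shift] = -np.inf
    dy, dx = np.unravel_index(np.argmax(corr), corr.shape)
    return int(sx[dx]), int(sy[dy])


def coarse_align(detected, reference, tile_shape) -> tuple:
    """Global integer-pixel offset between detected and sequencing coordinates.

    Both point sets are rasterized to binary occupancy images at 1 px
    resolution and registered by discrete-Fourier-transform phase
    correlation.  Returns (dx, dy) with detected ~= reference + (dx, dy).
    """
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if detected.size == 0 or reference.size == 0:
        raise ValueError("cannot align empty point sets")
    return _phase_correlate(_raster(detected, tile_shape), _raster(reference, tile_shape))


@dataclass
class OffsetMap:
    """Per-sub-tile (dx, dy) shifts from sequencing coordinates to the scan."""

    dx: np.ndarray           # (ny, nx) sub-tile grid
    dy: np.ndarray
    subtile: int
    global_offset: tuple

    def lookup(self, x: float, y: float) -> tuple:
        j = min(int(x // self.subtile), self.dx.shape[1] - 1)
        i = min(int(y // self.subtile), self.dx.shape[0] - 1)
        i, j = max(i, 0), max(j, 0)
        return float(self.dx[i, j]), float(self.dy[i, j])


def refine_offsets(
    img_points,
    ref_points,
    tile_shape,
    subtile: int = DEFAULT_SUBTILE,
    min_points: int = DEFAULT_MIN_POINTS,
    global_offset=None,
) -> OffsetMap:
    """Refine the global offset per non-overlapping sub-tile.

    Each ``subtile`` x ``subtile`` block is registered independently by phase
    correlation of the locally rasterized point sets (reference points are
    pre-shifted by the global offset).  Blocks with fewer than ``min_points``
    detected or reference points inherit the global offset.
    """
    img_points = np.asarray(img_points, dtype=float)
    ref_points = np.asarray(ref_points, dtype=float)
    if global_offset is None:
        global_offset = coarse_align(img_points, ref_points, tile_shape)
    gdx, gdy = global_offset
    h, w = tile_shape
    ny = max(1, math.ceil(h / subtile))
    nx = max(1, math.ceil(w / subtile))
    dx = np.full((ny, nx), float(gdx))
    dy = np.full((ny, nx), float(gdy))
    shifted_ref = ref_points + np.array([gdx, gdy], dtype=float)
    for i in range(ny):
        for j in range(nx):
            x0, y0 = j * subtile, i * subtile
            inb = lambda p: ((p[:, 0] >= x0) & (p[:, 0] < x0 + subtile)
                             & (p[:, 1] >= y0) & (p[:, 1] < y0 + subtile))
            det_loc = img_points[inb(img_points)]
            ref_loc = shifted_ref[inb(shifted_ref)]
            if len(det_loc) < min_points or len(ref_loc) < min_points:
                continue
            ldx, ldy = _phase_correlate(
                _raster(det_loc - [x0, y0], (subtile, subtile)),
                _raster(ref_loc - [x0, y0], (subtile, subtile)),
                max_shift=subtile // 8,
            )
            dx[i, j] = gdx + ldx
            dy[i, j] = gdy + ldy
    return OffsetMap(dx=dx, dy=dy, subtile=subtile, global_offset=(gdx, gdy))


@dataclass(frozen=True)
class PsfKernel:
    """Amplitude-1 Gaussian weighting window for cluster photometry."""

    size: int
    sigma: float
    weights: np.ndarray

    @property
    def half(self) -> int:
        return self.size // 2


def make_psf_kernel(size: int = DEFAULT_WINDOW, sigma: float = DEFAULT_SIGMA) -> PsfKernel:
    """Build the size x size Gaussian kernel exp(-d^2 / (2 sigma^2)).

    The centre weight is exactly 1 (the kernel is deliberately not
    normalized to unit sum; the constant cancels in relative comparisons).
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    return PsfKernel(size=size, sigma=sigma, weights=np.outer(g, g))


def extract_intensity(img: np.ndarray, x: float, y: float, kernel: PsfKernel,
                      offsets: OffsetMap | None = None):
    """Weighted-window photometry at one offset-corrected cluster centre.

    Returns ``(fi, rejected)``.  The centre is offset-corrected, rounded to
    the nearest integer pixel, and a size x size window is multiplied
    element-wise with the kernel and summed.  Centres closer than ``half``
    pixels to any border are flagged rejected (fi = NaN), not zeroed.
    """
    dx, dy = offsets.lookup(x, y) if offsets is not None else (0.0, 0.0)
    cx = int(round(x + dx))
    cy = int(round(y + dy))
    half = kernel.half
    h, w = img.shape
    if cx - half < 0 or cy - half < 0 or cx + half >= w or cy + half >= h:
        return float("nan"), True
    sub = img[cy - half:cy + half + 1, cx - half:cx + half + 1].astype(float)
    return float(np.sum(sub * kernel.weights)), False


def quantify_tile(
    img: np.ndarray,
    clusters: pd.DataFrame,
    condition: str,
    channel: str,
    threshold: float = DEFAULT_PEAK_THRESHOLD,
    disk_radius: int = DEFAULT_DISK_RADIUS,
    window: int = DEFAULT_WINDOW,
    sigma: float = DEFAULT_SIGMA,
    align: bool = True,
    subtile: int = DEFAULT_SUBTILE,
) -> pd.DataFrame:
    """Full single-tile chain: correct, detect, align, extract.

    ``clusters`` carries the sequencing coordinates (columns umi, tile, x, y).
    Returns one row per cluster with columns
    ``umi, tile, x, y, condition, channel, fi, rejected``.
    """
    corrected = correct_illumination(img, disk_radius)
    ref = clusters[["x", "y"]].to_numpy(dtype=float)
    offsets = None
    if align:
        peaks = detect_peaks(corrected, threshold)
        if len(peaks) > 0:
            offsets = refine_offsets(peaks, ref, img.shape, subtile=subtile)
    kernel = make_psf_kernel(window, sigma)
    fis = np.empty(len(clusters))
    rej = np.empty(len(clusters), dtype=bool)
    for i, (x, y) in enumerate(ref):
        fis[i], rej[i] = extract_intensity(corrected, x, y, kernel, offsets)
    out = clusters[["umi", "tile", "x", "y"]].copy()
    out["condition"] = condition
    out["channel"] = channel
    out["fi"] = fis
    out["rejected"] = rej
    return out
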
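"""Lesion delineation and the geometric primitives the clock sweep needs.

A dermoscopy image is reduced to grayscale, the pigmented lesion (darker
than the surrounding skin) is thresholded out, and the lesion is described
by its binary centroid plus the margin radius sampled on a clock-face angle
grid: angle 0 points straight up (12 o'clock) and angles increase
clockwise, so pi/2 is 3 o'clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label

__all__ = [
    "SegmentationError",
    "LesionMask",
    "to_grayscale",
    "otsu_threshold",
    "segment_lesion",
    "clock_angles",
    "clock_direction",
]

# Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class SegmentationError(ValueError):
    """Raised when no usable lesion mask can be extracted from an image."""


def clock_angles(n_angles: int) -> np.ndarray:
    """Uniform angle grid in radians, clockwise from 12 o'clock."""
    if n_angles < 4:
        raise ValueError(f"n_angles must be >= 4, got {n_angles}")
    return np.arange(n_angles) * (2.0 * np.pi / n_angles)


def clock_direction(theta):
    """Unit vector(s) (d_row, d_col) for clock angle theta.

    Row index grows downward, so 12 o'clock is -row and 3 o'clock is +col.
    """
    theta = np.asarray(theta, dtype=float)
    return -np.cos(theta), np.sin(theta)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold with a plateau-midpoint tie-break.

    When the histogram has an empty gap between the lesion and background
    modes, every split inside the gap maximises the between-class variance
    equally; taking the midpoint of that plateau keeps the threshold away
    from both intensity populations (the left edge of the plateau can sit
    a histogram bin inside the darker mode).
    """
    values = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts)[:-1]
    w1 = w0[-1] + counts[-1] - w0
    s0 = np.cumsum(counts * centers)[:-1]
    total = s0[-1] + counts[-1] * centers[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (total - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    best = np.flatnonzero(sigma_b >= sigma_b.max() * (1 - 1e-12))
    # contiguous plateau of equally optimal splits -> use its midpoint
    return float(edges[1:-1][best[len(best) // 2]])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel raster to a float64 grayscale image.

    3-channel input is combined with Rec. 601 luminance weights
    (0.299 R + 0.587 G + 0.114 B); single-channel input passes through.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        out = arr.copy()
    elif arr.ndim == 3 and arr.shape[-1] == 3:
        out = arr @ _LUMA
    elif arr.ndim == 3 and arr.shape[-1] == 1:
        out = arr[..., 0].copy()
    else:
        raise ValueError(
            f"unsupported channel count: expected 1 or 3 channels, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(out)):
        raise ValueError("image contains non-finite values")
    return out


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion support with centroid and per-angle margin radius.

    ``margin_radius[i]`` is the distance in pixels from the centroid to the
    *last* mask pixel along the ray at ``angles[i]`` — the peripheral
    margin, robust to concave borders.
    """

    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col)
    angles: np.ndarray
    margin_radius: np.ndarray
    threshold: float = field(default=np.nan)

    def __post_init__(self):
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if len(self.angles) != len(self.margin_radius):
            raise ValueError("angles and margin_radius must have equal length")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def margin_at(self, theta) -> np.ndarray:
        """Margin radius at arbitrary angles via circular linear interpolation."""
        theta = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        n = self.n_angles
        step = 2 * np.pi / n
        i0 = np.floor(theta / step).astype(int) % n
        i1 = (i0 + 1) % n
        frac = theta / step - np.floor(theta / step)
        return (1 - frac) * self.margin_radius[i0] + frac * self.margin_radius[i1]


def _trace_margin(
    mask: np.ndarray, centroid: tuple[float, float], angles: np.ndarray, step: float = 0.5
) -> np.ndarray:
    """Distance from centroid to the outermost margin point along each ray.

    The margin is the *last* crossing out of the mask (robust to concave
    borders).  A point counts as inside only when its full bilinear
    footprint (the up-to-four surrounding pixels) is in the mask, so that
    downstream interpolated sampling up to the margin never mixes in
    background intensity; this sits at most ~1 px inside the outermost
    mask pixel.
    """
    h, w = mask.shape
    cr, cc = centroid
    # farthest any lesion pixel can be from the centroid
    r_max = float(np.hypot(max(cr, h - 1 - cr), max(cc, w - 1 - cc)))
    radii = np.arange(0.0, r_max + step, step)
    drow, dcol = clock_direction(angles)
    rows = cr + np.outer(drow, radii)
    cols = cc + np.outer(dcol, radii)
    in_bounds = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 1)
    r1 = np.clip(r0 + 1, 0, h - 1)
    c1 = np.clip(c0 + 1, 0, w - 1)
    inside = (
        in_bounds & mask[r0, c0] & mask[r0, c1] & mask[r1, c0] & mask[r1, c1]
    )
    # index of the last True sample along each ray
    any_inside = inside.any(axis=1)
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    return np.where(any_inside, radii[last], 0.0)


def segment_lesion(
    image: np.ndarray,
    threshold: float | None = None,
    n_angles: int = 360,
) -> LesionMask:
    """Delineate the (darker) lesion and measure its clock-face geometry.

    Parameters
    ----------
    image
        2-D grayscale raster (see :func:`to_grayscale`).
    threshold
        Intensity threshold; pixels strictly below it are lesion candidates.
        When omitted, Otsu's criterion picks it from the image histogram.
    n_angles
        Number of uniformly spaced clock angles for the margin table.

    The largest 4-connected below-threshold component is kept and its holes
    filled; the centroid is the binary centroid of that component.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_lesion expects a 2-D grayscale image")
    if min(img.shape) < 64:
        raise ValueError(f"image too small: {img.shape}, need at least 64x64")

    if threshold is None:
        values = img.ravel()
        if np.ptp(values) == 0:
            raise SegmentationError(
                "uniform image: no lesion/background contrast (threshold undefined)"
            )
        threshold = otsu_threshold(img)

    below = img < threshold
    if not below.any():
        raise SegmentationError(
            f"empty mask: no pixels below threshold {threshold:.4g}"
        )

    labels = label(below, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(mask)

    idx = np.nonzero(mask)
    centroid = (float(idx[0].mean()), float(idx[1].mean()))
    if not mask[int(round(centroid[0])), int(round(centroid[1]))]:
        raise SegmentationError(
            f"centroid {centroid} falls outside the mask (threshold {threshold:.4g})"
        )

    angles = clock_angles(n_angles)
    margin = _trace_margin(mask, centroid, angles)
    if np.any(margin <= 0):
        raise SegmentationError(
            f"degenerate margin: zero radius at some angle (threshold {threshold:.4g})"
        )
    return LesionMask(
        mask=mask,
        centroid=centroid,
        angles=angles,
        margin_radius=margin,
        threshold=float(threshold),
    )
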
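"""Calibrated profile extraction from seed images.

Emulates the manual light-microscopy workflow: the image of an upright
(apex-up) tubercle is converted to 8-bit grayscale, thresholded, its outline
traced, and a single-valued profile y(x) read off the outline one pixel
column at a time — the "line graph" of the classic ImageJ protocol.  A ruler
of known physical length in the image provides the micron-per-pixel scale.

Coordinate convention: pixel centres, 0-based columns, y increasing upward
(image row 0 is the top of the picture; the tracer flips rows so extracted
profiles are apex-up in ordinary Cartesian coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure as _skmeasure
from skimage.filters import threshold_otsu

from .measurement import TubercleProfile

__all__ = [
    "CalibratedImage",
    "OutlineSegment",
    "calibrate_scale",
    "binarize",
    "trace_outline",
    "extract_profile",
    "segment_tubercle",
]

log = logging.getLogger(__name__)


def calibrate_scale(ruler_pixel_length: float, ruler_physical_length: float) -> float:
    """Microns per pixel from a ruler of known physical length (microns)."""
    if ruler_pixel_length <= 0 or ruler_physical_length <= 0:
        raise ValueError("ruler lengths must be positive")
    return float(ruler_physical_length) / float(ruler_pixel_length)


@dataclass
class CalibratedImage:
    """8-bit grayscale image with a known micron-per-pixel scale."""

    pixels: np.ndarray
    microns_per_pixel: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("image is empty")
        if px.ndim == 3:  # RGB(A) -> luma
            px = px[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
        if px.dtype != np.uint8:
            px = np.clip(np.round(px), 0, 255).astype(np.uint8)
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        self.pixels = px

    @classmethod
    def from_file(
        cls,
        path,
        microns_per_pixel: float | None = None,
        ruler_pixel_length: float | None = None,
        ruler_physical_length: float = 1000.0,
    ) -> "CalibratedImage":
        """Read a JPEG/PNG/TIFF image; scale either given directly or derived
        from a user-measured ruler length in pixels (default ruler 1 mm)."""
        import imageio.v3 as iio

        if microns_per_pixel is None:
            if ruler_pixel_length is None:
                raise ValueError("provide microns_per_pixel or ruler_pixel_length")
            microns_per_pixel = calibrate_scale(ruler_pixel_length, ruler_physical_length)
        px = iio.imread(path)
        return cls(px, microns_per_pixel, provenance={"filename": str(Path(path))})


def binarize(image: CalibratedImage | np.ndarray, threshold="otsu", foreground: str = "bright") -> np.ndarray:
    """Boolean foreground mask of an 8-bit image.

    ``threshold`` is an intensity in 0-255 or ``"otsu"``; ``foreground``
    selects whether material is brighter or darker than the background.
    Raises if the mask comes out empty.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    if px.dtype != np.uint8:
        raise ValueError("binarize expects an 8-bit image")
    if threshold == "otsu":
        if px.min() == px.max():
            thr = float(px.min()) - 0.5  # uniform image: everything foreground
        else:
            thr = float(threshold_otsu(px))
    else:
        thr = float(threshold)
    # skimage convention: foreground is strictly above the threshold
    mask = px > thr if foreground == "bright" else px < thr
    if isinstance(image, CalibratedImage):
        image.provenance.setdefault("threshold", thr)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    return mask


@dataclass(frozen=True)
class OutlineSegment:
    """Ordered boundary coordinates of one connected component.

    ``points`` is (m, 2) in pixel units with x = column, y = rows-from-bottom
    so that the apex of an upright tubercle points toward +y.
    """

    points: np.ndarray
    area_px: float = 0.0

    def __len__(self):
        return len(self.points)


def trace_outline(mask: np.ndarray) -> list[OutlineSegment]:
    """Ordered sub-pixel boundaries of all connected components, largest first."""
    mask = np.asarray(mask, dtype=bool)
    labels = _skmeasure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("mask has no connected component")
    segments = []
    h = mask.shape[0]
    for region in _skmeasure.regionprops(labels):
        comp = labels == region.label
        # pad so boundaries of components touching the border are closed
        padded = np.pad(comp, 1)
        contours = _skmeasure.find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        rows = contour[:, 0] - 1.0
        cols = contour[:, 1] - 1.0
        pts = np.column_stack([cols, (h - 1.0) - rows])
        segments.append(OutlineSegment(points=pts, area_px=float(region.area)))
    segments.sort(key=lambda s: s.area_px, reverse=True)
    return segments


def extract_profile(
    segment: OutlineSegment,
    microns_per_pixel: float = 1.0,
    smooth_window: int = 0,
    min_columns: int = 20,
) -> np.ndarray:
    """Single-valued profile y(x), in microns, from an outline segment.

    For every integer pixel column crossed by the boundary the topmost
    boundary y is taken (so overhangs are flattened, with a log message);
    columns the boundary does not touch are skipped.  Optional light
    smoothing (moving average over ``smooth_window`` columns) damps the pixel
    staircase before curve fitting.
    """
    pts = segment.points
    # prefer points on horizontal pixel edges (integer x): they carry the
    # column's own top boundary; vertical-edge points at x = c +- 0.5 would
    # leak the neighbouring column's top onto steep flanks
    frac = np.abs(pts[:, 0] - np.round(pts[:, 0]))
    centered = pts[frac < 0.25]
    if len(centered) >= min_columns:
        pts = centered
    cols = np.round(pts[:, 0]).astype(int)
    order = np.argsort(cols, kind="stable")
    cols_sorted, ys = cols[order], pts[order, 1]
    uniq, start = np.unique(cols_sorted, return_index=True)
    if len(uniq) < min_columns:
        raise ValueError(
            f"only {len(uniq)} usable pixel columns (need at least {min_columns}); "
            "degenerate or near-vertical outline"
        )
    top = np.maximum.reduceat(ys, start)
    bottom = np.minimum.reduceat(ys, start)
    if np.any(top - bottom > 2.0):
        log.debug("multi-valued columns detected; taking topmost boundary per column")
    x = uniq.astype(float)
    y = top
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: len(x)]
    return np.column_stack([x, y]) * float(microns_per_pixel)


def segment_tubercle(profile: np.ndarray, left_base: float, right_base: float) -> TubercleProfile:
    """Crop one tubercle from a profile and normalise its baseline.

    ``left_base``/``right_base`` are x positions (microns) of the two base
    points.  The cropped points are rigidly transformed so the chord through
    the base points becomes the x axis with the left base point at the
    origin; curvature and all distances are preserved.
    """
    pts = np.asarray(profile, dtype=float)
    if left_base >= right_base:
        raise ValueError("left_base must be smaller than right_base")
    x = pts[:, 0]
    if left_base < x.min() - 1e-9 or right_base > x.max() + 1e-9:
        raise ValueError("base points outside the profile span")
    sel = (x >= left_base - 1e-9) & (x <= right_base + 1e-9)
    crop = pts[sel]
    if len(crop) < 3:
        raise ValueError("fewer than 3 points inside the base interval")
    p0, p1 = crop[0], crop[-1]
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("base points coincide")
    u = chord / norm
    rot = np.array([[u[0], u[1]], [-u[1], u[0]]])  # rotates chord onto +x
    out = (crop - p0) @ rot.T
    return TubercleProfile(out, meta={"left_base": float(left_base), "right_base": float(right_base)})
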
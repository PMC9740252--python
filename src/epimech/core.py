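"""Calibrated images, stacks and ROI primitives shared by every pipeline.

Coordinate convention (used throughout the package): origin at the centre of
the top-left pixel, x increases rightward (columns), y increases downward
(rows), 0-based.  All ROIs are expressed in this frame, in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import LineString, Polygon


class InputError(ValueError):
    """Invalid input to a quantification operation."""


@dataclass
class IntensityImage:
    """A single-channel 2D image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities.
    pixel_size : float
        Pixel edge length in µm/px, strictly positive.
    channel : str
        Free-text channel label.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    channel: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InputError("pixels must be a non-empty 2D array")
        if np.any(self.pixels < 0):
            raise InputError("intensities must be non-negative")
        if not (self.pixel_size > 0):
            raise InputError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size ** 2


@dataclass
class ImageStack:
    """An ordered z-stack of same-shape :class:`IntensityImage` slices."""

    slices: list[IntensityImage]
    z_step: float = 1.0

    def __post_init__(self):
        if len(self.slices) == 0:
            raise InputError("stack must contain at least one slice")
        shape0 = self.slices[0].shape
        for s in self.slices:
            if s.shape != shape0:
                raise InputError("all slices must share the same shape")
        if len(self.slices) > 1 and not (self.z_step > 0):
            raise InputError("z_step must be > 0 for multi-slice stacks")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size


@dataclass
class LineROI:
    """A stroked polyline in pixel coordinates.

    ``width_px`` is the full stroke width; a pixel belongs to the stroke if
    its centre lies within ``width_px / 2`` (Euclidean) of the polyline.
    """

    vertices: np.ndarray
    width_px: int = 1

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise InputError("LineROI needs >= 2 (x, y) vertices")
        if int(self.width_px) < 1:
            raise InputError("width_px must be >= 1")
        self.width_px = int(self.width_px)

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)

    def translated(self, dx: float, dy: float) -> "LineROI":
        return LineROI(self.vertices + [dx, dy], self.width_px)


@dataclass
class RegionROI:
    """A simple closed polygon in pixel coordinates."""

    polygon: np.ndarray

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise InputError("RegionROI needs >= 3 (x, y) vertices")
        if not Polygon(self.polygon).is_valid:
            raise InputError("RegionROI polygon must be simple (non-self-intersecting)")

    def as_polygon(self) -> Polygon:
        return Polygon(self.polygon)


# ---------------------------------------------------------------------------
# focus metrics

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


def _highpass(pixels: np.ndarray) -> np.ndarray:
    return ndimage.convolve(pixels, _LAPLACIAN, mode="reflect")


def focus_score(image: IntensityImage) -> float:
    """Sharpness score: variance of the 3x3 Laplacian response.

    Defocus (Gaussian blur) strictly lowers the high-frequency content and
    hence this score, which is all the downstream selection logic needs.
    """
    return float(np.var(_highpass(image.pixels)))


def find_focused_slice(stack: ImageStack) -> int:
    """Index of the sharpest slice; ties broken by the lowest index."""
    scores = [focus_score(s) for s in stack.slices]
    return int(np.argmax(scores))  # argmax returns the first maximum


def extended_focus_projection(stack: ImageStack, window: int = 9) -> IntensityImage:
    """Per-pixel all-in-focus projection.

    Each output pixel takes the value of the slice that is locally sharpest
    around it, where local sharpness is the mean squared Laplacian response
    in a ``window`` x ``window`` neighbourhood.
    """
    if len(stack) == 1:
        s = stack.slices[0]
        return IntensityImage(s.pixels.copy(), s.pixel_size, s.channel)
    local_scores = np.stack(
        [ndimage.uniform_filter(_highpass(s.pixels) ** 2, size=window) for s in stack.slices]
    )
    best = np.argmax(local_scores, axis=0)
    data = np.stack([s.pixels for s in stack.slices])
    out = np.take_along_axis(data, best[None], axis=0)[0]
    first = stack.slices[0]
    return IntensityImage(out, first.pixel_size, first.channel)


# ---------------------------------------------------------------------------
# ROI sampling

def stroke_mask(image_shape: tuple[int, int], roi: LineROI) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the stroked polyline."""
    h, w = image_shape
    line = roi.as_linestring()
    r = roi.width_px / 2.0
    x0, y0, x1, y1 = line.bounds
    cmin = max(int(np.floor(x0 - r - 1)), 0)
    cmax = min(int(np.ceil(x1 + r + 1)), w - 1)
    rmin = max(int(np.floor(y0 - r - 1)), 0)
    rmax = min(int(np.ceil(y1 + r + 1)), h - 1)
    mask = np.zeros(image_shape, dtype=bool)
    if cmin > cmax or rmin > rmax:
        return mask
    xs, ys = np.meshgrid(np.arange(cmin, cmax + 1), np.arange(rmin, rmax + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = shapely.distance(pts, line).reshape(xs.shape)
    mask[rmin:rmax + 1, cmin:cmax + 1] = dist <= r
    return mask


def region_mask(image_shape: tuple[int, int], roi: RegionROI) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    h, w = image_shape
    poly = roi.as_polygon()
    x0, y0, x1, y1 = poly.bounds
    cmin = max(int(np.floor(x0)), 0)
    cmax = min(int(np.ceil(x1)), w - 1)
    rmin = max(int(np.floor(y0)), 0)
    rmax = min(int(np.ceil(y1)), h - 1)
    mask = np.zeros(image_shape, dtype=bool)
    if cmin > cmax or rmin > rmax:
        return mask
    xs, ys = np.meshgrid(np.arange(cmin, cmax + 1), np.arange(rmin, rmax + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.covers(poly, pts).reshape(xs.shape)
    mask[rmin:rmax + 1, cmin:cmax + 1] = inside
    return mask


def mean_intensity_along(image: IntensityImage, roi: LineROI) -> float:
    """Mean intensity over the stroked polyline."""
    mask = stroke_mask(image.shape, roi)
    if not mask.any():
        raise InputError("line ROI lies fully outside the image")
    return float(image.pixels[mask].mean())


def mean_intensity_in(image: IntensityImage, roi: RegionROI) -> float:
    """Mean intensity over a polygon region."""
    mask = region_mask(image.shape, roi)
    if not mask.any():
        raise InputError("region ROI lies fully outside the image")
    return float(image.pixels[mask].mean())


# ---------------------------------------------------------------------------
# I/O

def read_tiff(path, pixel_size: float = 1.0, channel: str = ""):
    """Read a grayscale TIFF as an IntensityImage (single page) or ImageStack.

    Pixel size is not parsed from metadata; supply it explicitly (e.g. from a
    sidecar config), matching how microscope calibration is usually recorded.
    """
    data = tifffile.imread(path)
    if data.ndim == 2:
        return IntensityImage(data, pixel_size, channel)
    if data.ndim == 3:
        return ImageStack([IntensityImage(p, pixel_size, channel) for p in data])
    raise InputError(f"unsupported TIFF dimensionality: {data.ndim}")


def write_tiff(path, image) -> None:
    if isinstance(image, ImageStack):
        tifffile.imwrite(path,
                         np.stack([s.pixels for s in image.slices]).astype(np.float32),
                         photometric="minisblack")
    else:
        tifffile.imwrite(path, image.pixels.astype(np.float32),
                         photometric="minisblack")


def read_rois(path) -> list:
    """Read ROI annotations from JSON.

    Format: a list (or single object) of
    ``{"type": "line"|"region", "vertices": [[x, y], ...], "width_px": int}``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    rois = []
    for item in payload:
        if item["type"] == "line":
            rois.append(LineROI(item["vertices"], item.get("width_px", 1)))
        elif item["type"] == "region":
            rois.append(RegionROI(item["vertices"]))
        else:
            raise InputError(f"unknown ROI type {item['type']!r}")
    return rois


def write_rois(path, rois: Sequence) -> None:
    payload = []
    for roi in rois:
        if isinstance(roi, LineROI):
            payload.append({"type": "line", "vertices": roi.vertices.tolist(),
                            "width_px": roi.width_px})
        else:
            payload.append({"type": "region", "vertices": roi.polygon.tolist()})
    with open(path, "w") as fh:
        json.dump(payload, fh)
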
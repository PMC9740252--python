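"""Line- and ROI-based junctional staining quantifications.

The central readout is the junctional formation index (JFI): the mean
fluorescence intensity along a line traced on the junction divided by the
average of the mean intensities of two lines traced in the adjacent
cytosol.  A JFI of 1 means no junctional enrichment.  Default stroke widths
follow the published protocol: 15 px for occludin-type stainings and 20 px
for p120-catenin-type stainings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .core import (InputError, IntensityImage, LineROI, RegionROI,
                   mean_intensity_along, region_mask, stroke_mask)

DEFAULT_STROKE_WIDTHS = {"occludin": 15, "p120": 20}


class UndefinedRatioError(InputError):
    """A ratio metric has a zero or undefined denominator."""


@dataclass
class JunctionMeasurement:
    jfi: float
    junction_line: LineROI
    cytosol_lines: tuple
    channel: str = ""
    junction_mean: float = float("nan")
    cytosol_means: tuple = (float("nan"), float("nan"))


def default_stroke_width(channel_type: str) -> int:
    try:
        return DEFAULT_STROKE_WIDTHS[channel_type]
    except KeyError:
        raise InputError(
            f"unknown channel type {channel_type!r}; expected one of "
            f"{sorted(DEFAULT_STROKE_WIDTHS)}") from None


def junction_formation_index(image: IntensityImage, junction: LineROI,
                             cytosol_a: LineROI, cytosol_b: LineROI) -> float:
    """JFI = mean(junction line) / mean of the two cytosolic line means."""
    m_j = mean_intensity_along(image, junction)
    m_a = mean_intensity_along(image, cytosol_a)
    m_b = mean_intensity_along(image, cytosol_b)
    denom = 0.5 * (m_a + m_b)
    if denom <= 0:
        raise UndefinedRatioError("cytosolic mean intensity is zero")
    return m_j / denom


def measure_junction(image: IntensityImage, junction: LineROI,
                     cytosol_a: LineROI, cytosol_b: LineROI) -> JunctionMeasurement:
    m_j = mean_intensity_along(image, junction)
    m_a = mean_intensity_along(image, cytosol_a)
    m_b = mean_intensity_along(image, cytosol_b)
    denom = 0.5 * (m_a + m_b)
    if denom <= 0:
        raise UndefinedRatioError("cytosolic mean intensity is zero")
    return JunctionMeasurement(jfi=m_j / denom, junction_line=junction,
                               cytosol_lines=(cytosol_a, cytosol_b),
                               channel=image.channel, junction_mean=m_j,
                               cytosol_means=(m_a, m_b))


def estimate_background(image: IntensityImage, bins: int = 256,
                        quantile: float = 0.9) -> float:
    """Background level: histogram mode over the lowest ``quantile`` of values."""
    vals = image.pixels.ravel()
    cut = np.quantile(vals, quantile)
    low = vals[vals <= cut]
    hist, edges = np.histogram(low, bins=bins)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _mean_integrated_density(image: IntensityImage, roi: RegionROI,
                             background: float) -> float:
    mask = region_mask(image.shape, roi)
    if not mask.any():
        raise InputError("region ROI lies fully outside the image")
    mean_above = max(float(image.pixels[mask].mean()) - background, 0.0)
    return mean_above * int(mask.sum())


def tricellular_accumulation(image: IntensityImage, corner_roi: RegionROI,
                             cell_roi: RegionROI,
                             background: float | None = None) -> float:
    """Corner (tricellular) signal normalised by the whole-cell signal.

    Both are mean integrated densities: background-subtracted mean intensity
    (clipped at 0) times ROI pixel area.  Background defaults to the image
    histogram mode over the lowest 90% of values.
    """
    if background is None:
        background = estimate_background(image)
    num = _mean_integrated_density(image, corner_roi, background)
    den = _mean_integrated_density(image, cell_roi, background)
    if den <= 0:
        raise UndefinedRatioError("cell ROI integrated density is zero")
    return num / den


def apical_basal_ratio(xz_image: IntensityImage, apical_roi: RegionROI,
                       basal_roi: RegionROI) -> float:
    """Mean apical over mean basal intensity in an xz cross-section, per cell."""
    mask_a = region_mask(xz_image.shape, apical_roi)
    mask_b = region_mask(xz_image.shape, basal_roi)
    if not mask_a.any() or not mask_b.any():
        raise InputError("ROI lies fully outside the image")
    m_b = float(xz_image.pixels[mask_b].mean())
    if m_b <= 0:
        raise UndefinedRatioError("basal mean intensity is zero")
    return float(xz_image.pixels[mask_a].mean()) / m_b


def junctional_segment_value(map_image: IntensityImage, segments,
                             background: float) -> list[float]:
    """Mean integrated density of each junctional line segment above background.

    Per segment: (mean within the stroke - background), clipped at 0, times
    the stroke pixel area.  NaN pixels (undefined map values, e.g. in FRET
    efficiency maps) are excluded from the mean and the area.
    """
    if background < 0:
        raise InputError("background must be >= 0")
    out = []
    for seg in segments:
        mask = stroke_mask(map_image.shape, seg)
        if not mask.any():
            raise InputError("segment lies fully outside the image")
        vals = map_image.pixels[mask]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            out.append(0.0)
            continue
        out.append(max(float(vals.mean()) - background, 0.0) * len(vals))
    return out


def mediatrix_line(center_a, center_b, half_length: float,
                   width_px: int = 1, clip_region: RegionROI | None = None) -> LineROI:
    """Perpendicular-bisector tracing line between two nucleus centres.

    Used when no junctional signal is visible between two cells: the line is
    drawn along the mediatrix of the segment joining the nucleus centroids,
    optionally clipped to the shared cell-pair region.  Whether to invoke it
    is the caller's (annotator's) decision.
    """
    a = np.asarray(center_a, dtype=float)
    b = np.asarray(center_b, dtype=float)
    d = b - a
    norm = np.hypot(*d)
    if norm == 0:
        raise InputError("nucleus centres coincide")
    n = np.array([-d[1], d[0]]) / norm
    mid = (a + b) / 2
    p0, p1 = mid - half_length * n, mid + half_length * n
    if clip_region is not None:
        inter = LineString([p0, p1]).intersection(clip_region.as_polygon())
        if inter.is_empty or inter.geom_type != "LineString" or inter.length == 0:
            raise InputError("mediatrix does not cross the clip region")
        coords = np.asarray(inter.coords)
        p0, p1 = coords[0], coords[-1]
    return LineROI([p0, p1], width_px)
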
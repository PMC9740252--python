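"""Cell-level morphometry from junctional stainings.

Covers: segmentation of cells from a junction-stained channel (ridge
enhancement of the bright junctional lines, skeletonisation, and labelling
of the enclosed regions), nuclei counting with the substrate-specific
density classification, focal-adhesion morphometrics (area and maximum
Feret diameter per object), and per-image feature percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, spatial
from skimage import filters, measure, morphology, restoration, segmentation
from skimage.feature import peak_local_max

from .core import InputError, IntensityImage

# reference field of view (µm²) to which nuclei counts are scaled before
# applying the density thresholds
REFERENCE_FIELD_AREA_UM2 = 1.6e4

# density threshold tables: (sparse_low, sparse_high, dense_over)
DENSITY_THRESHOLDS = {
    "glass": (10, 25, 40),
    "kPa40": (15, 30, 50),
}

_SUBSTRATE_ALIASES = {
    "glass": "glass",
    "kpa40": "kPa40", "40kpa": "kPa40", "40 kpa": "kPa40",
    "kpa1": "kPa1", "1kpa": "kPa1", "1 kpa": "kPa1",
}


@dataclass
class SegmentationMap:
    labels: np.ndarray          # per-pixel cell id; 0 = junction/background
    per_cell: pd.DataFrame      # id, area_um2, centroid_x, centroid_y, on_border
    pixel_size: float
    status: str = "ok"


@dataclass
class AdhesionSet:
    objects: pd.DataFrame       # id, area_um2, max_feret_um
    mean_area_um2: float
    mean_max_feret_um: float


@dataclass
class DensityCall:
    substrate: str
    nuclei_count: int
    call: str                   # sparse | dense | intermediate | not_classified
    scaled_count: float = float("nan")


# ---------------------------------------------------------------------------
# cell segmentation


def segment_cells(junction_image: IntensityImage,
                  min_cell_area_um2: float = 20.0,
                  ridge_sigmas=(1.0, 2.0), min_skeleton_object_px: int = 30,
                  closing_radius: int = 1,
                  exclude_border_cells: bool = True) -> SegmentationMap:
    """Cells as the regions enclosed by the junctional skeleton.

    Pipeline: Hessian-based ridge enhancement of the bright junction lines →
    threshold → skeletonise → clear small cytosolic objects → close small
    gaps → connected components of the complement.  Cells touching the
    image border are flagged (``on_border``) and, by default, excluded from
    the area table (their area is censored by the field of view).
    """
    px = junction_image.pixels
    # edge-pad before ridge filtering: the Hessian response is otherwise
    # suppressed near the frame and border-touching junctions vanish
    pad = int(np.ceil(4 * max(ridge_sigmas)))
    padded = np.pad(px, pad, mode="edge")
    response = filters.sato(padded, sigmas=ridge_sigmas,
                            black_ridges=False)[pad:-pad, pad:-pad]
    if response.max() <= 0:
        return SegmentationMap(np.zeros(px.shape, dtype=int),
                               _empty_cell_table(), junction_image.pixel_size,
                               status="no_junction_signal")
    mask = response > filters.threshold_otsu(response)
    # the ridge filter goes blind inside wide junctional patches (tricellular
    # blobs, wall crossings): a plain intensity threshold fills those in
    if px.max() > px.min():
        bright = px > filters.threshold_otsu(px)
        if 0 < bright.mean() < 0.5:
            mask |= bright
    # weak-response guard: junction pixels should be a minority of the image
    if mask.mean() > 0.9 or mask.sum() == 0:
        return SegmentationMap(np.zeros(px.shape, dtype=int),
                               _empty_cell_table(), junction_image.pixel_size,
                               status="no_junction_signal")
    skeleton = morphology.skeletonize(mask)
    skeleton = morphology.remove_small_objects(skeleton,
                                               max_size=min_skeleton_object_px - 1,
                                               connectivity=2)
    closed = skeleton.copy()
    # junctions at the field edge are cut by the frame; close the outline with
    # a band wide enough to absorb the ridge of a wall hugging the border
    band = closing_radius + 2
    closed[:band, :] = closed[-band:, :] = True
    closed[:, :band] = closed[:, -band:] = True
    if closing_radius > 0:
        closed = ndimage.binary_closing(
            closed, structure=morphology.disk(closing_radius),
            border_value=1)
    labels = measure.label(~closed, connectivity=1)
    # split the junction-line pixels between the neighbouring cells so a
    # cell's area is bounded by the junction midline, not the inner wall edge
    labels = segmentation.expand_labels(labels, distance=closing_radius + 1.5)

    rows = []
    pa = junction_image.pixel_area
    h, w = labels.shape
    for region in measure.regionprops(labels):
        area_um2 = region.area * pa
        if area_um2 < min_cell_area_um2:
            labels[labels == region.label] = 0
            continue
        minr, minc, maxr, maxc = region.bbox
        on_border = minr <= 1 or minc <= 1 or maxr >= h - 1 or maxc >= w - 1
        rows.append({"id": region.label, "area_um2": area_um2,
                     "centroid_x": region.centroid[1],
                     "centroid_y": region.centroid[0],
                     "on_border": on_border})
    table = pd.DataFrame(rows, columns=["id", "area_um2", "centroid_x",
                                        "centroid_y", "on_border"])
    status = "ok" if len(table) else "no_junction_signal"
    return SegmentationMap(labels, table, junction_image.pixel_size, status)


def _empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "area_um2", "centroid_x", "centroid_y",
                                 "on_border"])


def cell_area_stats(seg: SegmentationMap,
                    include_border: bool = False) -> pd.DataFrame:
    t = seg.per_cell
    return t if include_border else t[~t["on_border"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# nuclei


def count_nuclei(nuclei_image: IntensityImage, smooth_sigma: float = 2.0,
                 min_area_um2: float = 4.0,
                 min_separation_px: int = 5) -> int:
    """Count blob-like nuclei.

    Gaussian smoothing → Otsu threshold → fill holes → distance-transform
    watershed to split touching blobs → count objects above the size floor.
    (A classical replacement for learned nuclei segmentation; adequate for
    blob-over-dark-background images.)
    """
    px = filters.gaussian(nuclei_image.pixels, sigma=smooth_sigma)
    if px.max() <= 0 or np.allclose(px, px.flat[0]):
        return 0
    binary = px > filters.threshold_otsu(px)
    if not binary.any():
        return 0
    binary = ndimage.binary_fill_holes(binary)
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=min_separation_px, labels=binary)
    if len(peaks) == 0:
        return 0
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=binary)
    min_px = min_area_um2 / nuclei_image.pixel_area
    n = 0
    for region in measure.regionprops(labels):
        if region.area >= min_px:
            n += 1
    return n


def classify_density(count: int, substrate: str,
                     field_area_um2: float = REFERENCE_FIELD_AREA_UM2) -> DensityCall:
    """Sparse / dense / intermediate call from a field's nuclei count.

    Counts are scaled to the reference 1.6e4 µm² field before thresholding
    (assumption flagged in the returned record via ``scaled_count``).
    Thresholds: glass — sparse for 10-25, dense over 40; 40 kPa — sparse for
    15-30, dense over 50; everything between is intermediate.  Fields on
    1 kPa substrates are not classified.
    """
    if count < 0:
        raise InputError("count must be >= 0")
    if field_area_um2 <= 0:
        raise InputError("field area must be > 0")
    key = _SUBSTRATE_ALIASES.get(str(substrate).lower().replace("_", ""))
    if key is None:
        raise InputError(f"unknown substrate {substrate!r}")
    scaled = count * REFERENCE_FIELD_AREA_UM2 / field_area_um2
    if key == "kPa1":
        return DensityCall(key, count, "not_classified", scaled)
    lo, hi, dense = DENSITY_THRESHOLDS[key]
    if lo <= scaled <= hi:
        call = "sparse"
    elif scaled > dense:
        call = "dense"
    else:
        call = "intermediate"
    return DensityCall(key, count, call, scaled)


# ---------------------------------------------------------------------------
# focal adhesions


def max_feret_diameter(coords: np.ndarray) -> float:
    """Maximum Feret (caliper) diameter of a pixel-coordinate point set.

    Equals the maximum pairwise distance between convex-hull vertices
    (rotating-calipers result); in px.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 1:
        return 0.0
    unique = np.unique(coords, axis=0)
    if len(unique) < 3:
        d = spatial.distance.pdist(unique)
        return float(d.max()) if len(d) else 0.0
    try:
        hull = spatial.ConvexHull(unique)
        pts = unique[hull.vertices]
    except spatial.QhullError:  # collinear points
        pts = unique
    return float(spatial.distance.pdist(pts).max())


def feret_by_rotation(coords: np.ndarray, step_deg: float = 0.5) -> float:
    """Brute-force Feret: max projection extent over rotation angles (oracle)."""
    coords = np.asarray(coords, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = coords @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).max())


def adhesion_morphometrics(image: IntensityImage, min_area_um2: float = 0.1,
                           rolling_ball_radius: int = 50,
                           adaptive_window: int = 51,
                           adaptive_offset: float = 0.0,
                           watershed_h_px: float = 1.0) -> AdhesionSet:
    """Per-adhesion area and maximum Feret diameter, plus per-image means.

    Rolling-ball background subtraction → locally adaptive threshold →
    watershed splitting of fused objects (markers are h-maxima of the
    distance transform, so the flat ridge of a single elongated adhesion
    yields one marker, not a chain of splits) → per-object area (µm²) and
    maximum Feret diameter (µm, rotating calipers on the convex hull of
    pixel centres).
    """
    px = image.pixels
    bg = restoration.rolling_ball(px, radius=rolling_ball_radius)
    corrected = np.clip(px - bg, 0, None)
    if corrected.max() <= 0:
        return AdhesionSet(_empty_adhesion_table(), float("nan"), float("nan"))
    local_thr = filters.threshold_local(corrected, block_size=adaptive_window,
                                        offset=adaptive_offset)
    binary = corrected > np.maximum(local_thr, 0.05 * corrected.max())
    if not binary.any():
        return AdhesionSet(_empty_adhesion_table(), float("nan"), float("nan"))
    dist = ndimage.distance_transform_edt(binary)
    maxima = morphology.h_maxima(dist, watershed_h_px)
    markers, n_markers = ndimage.label(maxima)
    if n_markers:
        labels = segmentation.watershed(-dist, markers, mask=binary)
    else:
        labels = measure.label(binary)
    pa = image.pixel_area
    rows = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * pa
        if area_um2 < min_area_um2:
            continue
        coords_xy = region.coords[:, ::-1].astype(float)
        rows.append({"id": region.label, "area_um2": area_um2,
                     "max_feret_um": max_feret_diameter(coords_xy)
                     * image.pixel_size})
    table = pd.DataFrame(rows, columns=["id", "area_um2", "max_feret_um"])
    if len(table) == 0:
        return AdhesionSet(table, float("nan"), float("nan"))
    return AdhesionSet(table, float(table["area_um2"].mean()),
                       float(table["max_feret_um"].mean()))


def _empty_adhesion_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "area_um2", "max_feret_um"])


def feature_percentage(n_positive_cells: int, n_cells: int) -> float:
    """Percentage of cells in a field displaying a (manually counted) feature."""
    if n_cells <= 0:
        raise InputError("n_cells must be > 0")
    if not (0 <= n_positive_cells <= n_cells):
        raise InputError("need 0 <= n_positive_cells <= n_cells")
    return 100.0 * n_positive_cells / n_cells
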
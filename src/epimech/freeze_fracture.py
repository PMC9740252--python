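"""Morphometry of tight-junction strand networks from freeze-fracture replicas.

Input is vectorised annotation — polylines in nm traced on the electron
micrograph — not the raw image.  The measurements reproduce the manual
grid-based protocol: grid lines perpendicular to the most apical strand at
200 nm intervals, strand counts at the grid-line intersections, meshwork
depth as the apical-to-contra-apical extent, breaks as gaps > 20 nm, and the
particle/continuous appearance tally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiLineString

from .core import InputError

APPEARANCES = ("particle", "continuous")


@dataclass
class Strand:
    """One annotated strand: an ordered list of polyline segments (nm).

    Multiple segments encode interruptions of a single strand; consecutive
    segments are ordered along the strand so the gap between the end of one
    and the start of the next is the discontinuity length.
    """

    id: int
    segments: list
    appearance: str | None = None

    def __post_init__(self):
        if len(self.segments) < 1:
            raise InputError("strand needs at least one segment")
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        for s in self.segments:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 2:
                raise InputError("each segment needs >= 2 (x, y) vertices")

    def geometry(self) -> MultiLineString:
        return MultiLineString([LineString(s) for s in self.segments])

    def full_path(self) -> np.ndarray:
        """All vertices concatenated in order (gaps ignored)."""
        return np.vstack(self.segments)


@dataclass
class StrandNetwork:
    strands: list
    apical_id: int = 0

    def __post_init__(self):
        if len(self.strands) < 1:
            raise InputError("network needs at least one strand")
        ids = [s.id for s in self.strands]
        if self.apical_id not in ids:
            raise InputError(f"apical_id {self.apical_id} not among strand ids")

    def apical(self) -> Strand:
        return next(s for s in self.strands if s.id == self.apical_id)

    def bounds_diagonal(self) -> float:
        pts = np.vstack([s.full_path() for s in self.strands])
        return float(np.hypot(*(pts.max(axis=0) - pts.min(axis=0))))


@dataclass
class StrandMorphometry:
    counts_per_gridline: list
    mean_strand_number: float
    depth_nm: float
    n_breaks: int
    proportions: dict


# ---------------------------------------------------------------------------
# grid construction along the apical strand

def _arclength_param(path: np.ndarray):
    seglen = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    return s


def _point_at(path: np.ndarray, s_param: np.ndarray, s: float) -> np.ndarray:
    s = np.clip(s, 0.0, s_param[-1])
    i = np.searchsorted(s_param, s, side="right") - 1
    i = min(max(i, 0), len(path) - 2)
    seg = s_param[i + 1] - s_param[i]
    t = 0.0 if seg == 0 else (s - s_param[i]) / seg
    return path[i] + t * (path[i + 1] - path[i])


def grid_lines(net: StrandNetwork, interval_nm: float = 200.0,
               tangent_window_nm: float = 400.0, mode: str = "local"):
    """Grid lines perpendicular to the apical strand at fixed arclength steps.

    Returns a list of ``(anchor_point, normal_unit_vector)``.  ``mode`` is
    "local" (tangent smoothed over ``tangent_window_nm``, default — curved
    junctions) or "global" (one end-to-end orientation).
    """
    if interval_nm <= 0:
        raise InputError("interval must be > 0")
    path = net.apical().full_path()
    s_param = _arclength_param(path)
    total = s_param[-1]
    if total < interval_nm:
        warnings.warn("apical strand shorter than one grid interval; "
                      "falling back to a single grid line", stacklevel=2)
        stations = np.array([total / 2.0])
    else:
        stations = np.arange(interval_nm / 2.0, total, interval_nm)
    if mode == "global":
        tang = path[-1] - path[0]
        tangents = [tang] * len(stations)
    elif mode == "local":
        half = tangent_window_nm / 2.0
        tangents = [
            _point_at(path, s_param, s + half) - _point_at(path, s_param, s - half)
            for s in stations
        ]
    else:
        raise InputError(f"unknown mode {mode!r}")
    lines = []
    for s, tang in zip(stations, tangents):
        norm = np.hypot(*tang)
        if norm == 0:
            continue
        t = tang / norm
        n = np.array([-t[1], t[0]])  # perpendicular
        lines.append((_point_at(path, s_param, s), n))
    return lines


def _line_geometry(anchor: np.ndarray, direction: np.ndarray,
                   half_length: float) -> LineString:
    return LineString([anchor - half_length * direction,
                       anchor + half_length * direction])


def strand_counts(net: StrandNetwork, interval_nm: float = 200.0,
                  mode: str = "local"):
    """Distinct strands intersected by each grid line, and their mean.

    A strand crossed more than once by one grid line still counts once: the
    protocol counts strands, not crossings.
    """
    lines = grid_lines(net, interval_nm, mode=mode)
    half = net.bounds_diagonal() + 10 * interval_nm
    geoms = [(s.id, s.geometry()) for s in net.strands]
    counts = []
    for anchor, n in lines:
        probe = _line_geometry(anchor, n, half)
        counts.append(sum(1 for _, g in geoms if probe.intersects(g)))
    return counts, float(np.mean(counts))


def meshwork_depth(net: StrandNetwork, interval_nm: float = 200.0,
                   mode: str = "local") -> float:
    """Mean apical-to-contra-apical extent (nm) measured along the grid lines.

    Each grid line's intersections with the network are projected onto the
    line direction; the extent is the distance between the outermost two.
    A single-strand network has no extension and returns 0.
    """
    if len(net.strands) == 1:
        return 0.0
    lines = grid_lines(net, interval_nm, mode=mode)
    half = net.bounds_diagonal() + 10 * interval_nm
    geoms = [s.geometry() for s in net.strands]
    extents = []
    for anchor, n in lines:
        probe = _line_geometry(anchor, n, half)
        offsets = []
        for g in geoms:
            inter = probe.intersection(g)
            if inter.is_empty:
                continue
            for x, y in _iter_points(inter):
                offsets.append((x - anchor[0]) * n[0] + (y - anchor[1]) * n[1])
        if len(offsets) >= 2:
            extents.append(max(offsets) - min(offsets))
        else:
            extents.append(0.0)
    return float(np.mean(extents)) if extents else 0.0


def _iter_points(geom):
    """All coordinate pairs of a point/multipoint/line intersection result."""
    if geom.geom_type == "Point":
        yield geom.x, geom.y
    elif geom.geom_type in ("MultiPoint", "GeometryCollection",
                            "MultiLineString"):
        for g in geom.geoms:
            yield from _iter_points(g)
    elif geom.geom_type == "LineString":
        for xy in geom.coords:
            yield xy


def detect_breaks(net: StrandNetwork, min_gap_nm: float = 20.0) -> int:
    """Count strand discontinuities strictly longer than ``min_gap_nm``.

    A discontinuity is the Euclidean end-to-end distance between consecutive
    segments of the same annotated strand; the default 20 nm threshold is
    exclusive (a gap of exactly 20 nm is not a break).
    """
    n = 0
    for strand in net.strands:
        for a, b in zip(strand.segments[:-1], strand.segments[1:]):
            gap = float(np.hypot(*(b[0] - a[-1])))
            if gap > min_gap_nm:
                n += 1
    return n


def appearance_proportions(net: StrandNetwork) -> dict:
    """Fraction of strands annotated particle-type vs continuous-type."""
    tally = {a: 0 for a in APPEARANCES}
    for s in net.strands:
        if s.appearance not in APPEARANCES:
            raise InputError(f"strand {s.id} has no valid appearance label "
                             f"(got {s.appearance!r})")
        tally[s.appearance] += 1
    total = len(net.strands)
    return {a: tally[a] / total for a in APPEARANCES}


def morphometry(net: StrandNetwork, interval_nm: float = 200.0,
                min_gap_nm: float = 20.0, mode: str = "local") -> StrandMorphometry:
    """Full per-junction morphometry record."""
    counts, mean_n = strand_counts(net, interval_nm, mode=mode)
    return StrandMorphometry(
        counts_per_gridline=counts,
        mean_strand_number=mean_n,
        depth_nm=meshwork_depth(net, interval_nm, mode=mode),
        n_breaks=detect_breaks(net, min_gap_nm),
        proportions=appearance_proportions(net),
    )


# ---------------------------------------------------------------------------
# annotation I/O

def read_strand_network(path) -> StrandNetwork:
    """Read a strand annotation JSON file.

    Schema: ``{"pixel_size_nm": s, "strands": [{"id": i, "appearance":
    "particle"|"continuous", "segments": [[[x, y], ...], ...]}, ...],
    "apical_id": i}``.  Coordinates are multiplied by ``pixel_size_nm``
    (default 1, i.e. already in nm).
    """
    with open(path) as fh:
        payload = json.load(fh)
    scale = float(payload.get("pixel_size_nm", 1.0))
    strands = [
        Strand(id=s["id"],
               segments=[np.asarray(seg, dtype=float) * scale
                         for seg in s["segments"]],
               appearance=s.get("appearance"))
        for s in payload["strands"]
    ]
    return StrandNetwork(strands, apical_id=payload["apical_id"])


def write_strand_network(path, net: StrandNetwork) -> None:
    payload = {
        "pixel_size_nm": 1.0,
        "apical_id": net.apical_id,
        "strands": [
            {"id": s.id, "appearance": s.appearance,
             "segments": [seg.tolist() for seg in s.segments]}
            for s in net.strands
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
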
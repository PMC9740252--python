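"""Ground-truthed synthetic microscopy fixtures.

Every generator is a pure function of its parameters and a seed, and returns
the rendered image(s) together with a truth record, so every downstream
quantification can be validated against known ground truth without any
external data.  The generators emulate the image classes the pipelines
consume: junction-stained epithelial monolayers, Hoechst-like nuclei fields,
bright-field island colonies, TFM bead image pairs driven by the elastic
forward model, three-filter FRET channel triplets with known bleed-through,
elliptical focal adhesions, and tight-junction strand meshworks.

They emulate intensity structure, not optics: no aberrations, no shading,
and additive Gaussian noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, spatial
from skimage.morphology import disk, skeletonize
from skimage.segmentation import find_boundaries

from . import tfm as _tfm
from .core import InputError, IntensityImage, LineROI
from .freeze_fracture import Strand, StrandNetwork

# Default substrate for TFM fixtures: polyacrylamide TFM gels of average
# Young modulus 16.4 kPa; nu = 0.5 (incompressible) as the declared default.
DEFAULT_E_PA = 16400.0
DEFAULT_NU = 0.5
# Bead diameter (0.20 µm) is below the diffraction limit, so the rendered
# spot size is set by the PSF (Gaussian, sigma = 1 px), not the bead.
BEAD_PSF_SIGMA_PX = 1.0


# ---------------------------------------------------------------------------
# monolayer


@dataclass
class MonolayerTruth:
    label_map: np.ndarray            # per-pixel cell id (1..n)
    junction_mask: np.ndarray        # 1-px skeleton of cell-cell junctions
    per_cell_area: dict              # cell id -> area µm²
    intensities: tuple               # (J, C, B)
    nuclei_centers: np.ndarray       # (n, 2) (x, y) px
    junction_halfwidth: int
    pixel_size: float


def make_monolayer(n_cells: int = 16, shape: tuple[int, int] = (256, 256),
                   pixel_size: float = 0.3, J: float = 200.0, C: float = 100.0,
                   B: float = 0.0, noise_sigma: float = 0.0, seed: int = 0,
                   junction_halfwidth: int = 2, lloyd_iters: int = 2):
    """Voronoi-mosaic epithelial monolayer with a junction and a nuclei channel.

    The junction channel carries value ``J`` on the dilated junction skeleton
    (dilation radius ``junction_halfwidth``), ``C`` in cell interiors and
    ``B`` on any background; ``J > C > B >= 0`` is required.  Returns
    ``(channels, truth)`` where ``channels`` is a dict with keys
    ``"junction"`` and ``"nuclei"``.
    """
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    if min(shape) < 8 or pixel_size <= 0:
        raise InputError("image size and pixel size must be positive")
    if not (J > C > B >= 0):
        raise InputError("intensities must satisfy J > C > B >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 0.05
    pts = rng.uniform([margin * w, margin * h],
                      [(1 - margin) * w, (1 - margin) * h], size=(n_cells, 2))
    ys, xs = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xs.ravel(), ys.ravel()])
    for it in range(lloyd_iters + 1):
        _, lab = spatial.cKDTree(pts).query(pix)
        labels = lab.reshape(h, w)
        if it == lloyd_iters:
            break
        for i in range(n_cells):  # Lloyd relaxation toward a regular mosaic
            sel = labels == i
            if sel.any():
                pts[i] = [xs[sel].mean(), ys[sel].mean()]
    labels = labels + 1  # 1-based cell ids

    skeleton = skeletonize(find_boundaries(labels, mode="thick"))
    skeleton[0, :] = skeleton[-1, :] = True
    skeleton[:, 0] = skeleton[:, -1] = True

    wall = ndimage.binary_dilation(skeleton, structure=disk(junction_halfwidth))
    junction_px = np.full(shape, C, dtype=float)
    junction_px[wall] = J

    centers = np.zeros((n_cells, 2))
    nuclei_px = np.zeros(shape, dtype=float)
    mean_area = h * w / n_cells
    sigma_px = 0.15 * np.sqrt(mean_area)
    for i in range(n_cells):
        sel = labels == i + 1
        cx, cy = xs[sel].mean(), ys[sel].mean()
        centers[i] = (cx, cy)
        r2 = (xs - cx) ** 2 + (ys - cy) ** 2
        nuclei_px += 180.0 * np.exp(-r2 / (2 * sigma_px ** 2))

    if noise_sigma > 0:
        junction_px = junction_px + rng.normal(0, noise_sigma, shape)
        nuclei_px = nuclei_px + rng.normal(0, noise_sigma, shape)
    channels = {
        "junction": IntensityImage(np.clip(junction_px, 0, None), pixel_size,
                                   "junction"),
        "nuclei": IntensityImage(np.clip(nuclei_px, 0, None), pixel_size,
                                 "nuclei"),
    }
    areas = {i + 1: float((labels == i + 1).sum()) * pixel_size ** 2
             for i in range(n_cells)}
    truth = MonolayerTruth(labels, skeleton, areas, (J, C, B), centers,
                           junction_halfwidth, pixel_size)
    return channels, truth


def junction_rois_from_truth(truth: MonolayerTruth, offset_px: float = 10.0,
                             width_px: int = 3, min_len_px: float = 15.0,
                             trim: float = 0.25):
    """Junction / cytosol line triplets read off the generated mosaic.

    For every pair of adjacent cells whose shared boundary is long enough, a
    junction line is traced along the (straight) shared Voronoi edge, and
    two cytosolic lines are offset perpendicularly by ``offset_px`` into
    each neighbouring cell.  Triplets whose cytosolic lines would leave
    their cells are dropped.  Returns a list of
    ``(junction, cytosol_a, cytosol_b)`` LineROIs.
    """
    labels = truth.label_map
    h, w = labels.shape
    sk_r, sk_c = np.nonzero(truth.junction_mask)
    pair_pixels: dict = {}
    for r, c in zip(sk_r, sk_c):
        neigh = labels[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3]
        ids = np.unique(neigh)
        if len(ids) == 2:
            pair_pixels.setdefault(tuple(ids), []).append((c, r))
    triplets = []
    for (a, b), px_list in sorted(pair_pixels.items()):
        pts = np.asarray(px_list, dtype=float)
        if len(pts) < min_len_px:
            continue
        center = pts.mean(axis=0)
        d = pts - center
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        axis = vt[0]
        proj = d @ axis
        lo, hi = np.quantile(proj, [trim, 1 - trim])
        if hi - lo < min_len_px:
            continue
        p0 = center + lo * axis
        p1 = center + hi * axis
        normal = np.array([-axis[1], axis[0]])
        junction = LineROI([p0, p1], width_px)
        cyts = []
        for sign in (+1, -1):
            q0 = p0 + sign * offset_px * normal
            q1 = p1 + sign * offset_px * normal
            mid = (q0 + q1) / 2
            r_i, c_i = int(round(mid[1])), int(round(mid[0]))
            if not (0 <= r_i < h and 0 <= c_i < w):
                cyts = []
                break
            if labels[r_i, c_i] not in (a, b) or truth.junction_mask[r_i, c_i]:
                cyts = []
                break
            cyts.append(LineROI([q0, q1], width_px))
        if len(cyts) == 2:
            triplets.append((junction, cyts[0], cyts[1]))
    return triplets


# ---------------------------------------------------------------------------
# TFM


@dataclass
class TfmTruth:
    traction: _tfm.TractionField
    displacement: _tfm.DisplacementField
    bead_positions_relaxed: np.ndarray   # (n, 2) µm
    bead_positions_stressed: np.ndarray  # (n, 2) µm
    U_true: float                        # J, over the island mask
    substrate: tuple                     # (E Pa, nu)
    island_mask: np.ndarray              # grid-node mask covering the tractions
    pixel_size: float
    shape_px: tuple


def gaussian_traction_spots(spots, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Rasterise Gaussian traction spots onto the analysis grid.

    ``spots`` is a list of ``(cx_um, cy_um, amplitude_pa, width_um,
    (dx, dy))``; each contributes A * exp(-r^2 / 2w^2) along its unit
    direction.
    """
    GX, GY = np.meshgrid(gx, gy)
    T = np.zeros(GX.shape + (2,))
    for cx, cy, amp, width, direction in spots:
        direction = np.asarray(direction, dtype=float)
        norm = np.hypot(*direction)
        if norm == 0:
            raise InputError("traction spot direction must be non-zero")
        direction = direction / norm
        g = amp * np.exp(-((GX - cx) ** 2 + (GY - cy) ** 2) / (2 * width ** 2))
        T[..., 0] += g * direction[0]
        T[..., 1] += g * direction[1]
    return T


def dipole_spots(center: tuple[float, float], separation_um: float,
                 amplitude_pa: float, width_um: float, axis=(1.0, 0.0)):
    """A balanced, contractile pair of traction spots (net force ~ 0)."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    c = np.asarray(center, dtype=float)
    p1 = c - ax * separation_um / 2
    p2 = c + ax * separation_um / 2
    return [
        (p1[0], p1[1], amplitude_pa, width_um, tuple(ax)),       # pulls inward
        (p2[0], p2[1], amplitude_pa, width_um, tuple(-ax)),
    ]


def _render_beads(shape, positions_px, amplitude=200.0,
                  sigma=BEAD_PSF_SIGMA_PX, halfwidth=4):
    img = np.zeros(shape)
    if len(positions_px) == 0:
        return img
    x = positions_px[:, 0]
    y = positions_px[:, 1]
    ix = np.round(x).astype(int)
    iy = np.round(y).astype(int)
    offs = np.arange(-halfwidth, halfwidth + 1)
    OX, OY = np.meshgrid(offs, offs)
    dx = (OX[None] - (x - ix)[:, None, None])
    dy = (OY[None] - (y - iy)[:, None, None])
    stamps = amplitude * np.exp(-(dx ** 2 + dy ** 2) / (2 * sigma ** 2))
    rows = iy[:, None, None] + OY[None]
    cols = ix[:, None, None] + OX[None]
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(img, (rows[ok], cols[ok]), stamps[ok])
    return img


def _place_beads(rng, domain_um: float, density: float,
                 min_sep_um: float) -> np.ndarray:
    """Random bead positions with a minimum separation (sonicated beads:
    homogeneous, clump-free) via dart throwing with rejection."""
    target = rng.poisson(density * domain_um ** 2)
    pos: list = []
    cell = max(min_sep_um, 1e-6)
    grid: dict = {}
    tries = 0
    while len(pos) < target and tries < 50 * target + 1000:
        tries += 1
        cand = rng.uniform(0, domain_um, size=2)
        ci, cj = int(cand[0] / cell), int(cand[1] / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(cand - pos[k])) < min_sep_um:
                        ok = False
                        break
        if ok:
            grid.setdefault((ci, cj), []).append(len(pos))
            pos.append(cand)
    return np.asarray(pos) if pos else np.empty((0, 2))


def make_tfm_pair(spots, E: float = DEFAULT_E_PA, nu: float = DEFAULT_NU,
                  domain_um: float = 64.0, h: float = 2.6,
                  pixel_size: float = 0.1, bead_density: float = 1.0,
                  loc_noise_px: float = 0.0, image_noise: float = 0.0,
                  seed: int = 0, bead_amplitude: float = 200.0,
                  bead_min_sep_um: float = 0.7):
    """Bead image pair (relaxed / stressed) from the elastic forward model.

    Tractions are rasterised on the regular ``h`` grid, the displacement
    field is computed by the forward Boussinesq model (zero-padded FFT), and
    beads are placed uniformly at random (with a minimum separation — the
    physical beads are sonicated to prevent clumps), rendered as Gaussian
    PSF spots in their relaxed positions and in positions displaced by the
    interpolated field.  ``loc_noise_px`` jitters every rendered bead
    position independently in both images (localisation error).  Returns
    ``((relaxed, stressed), truth)``.
    """
    if not (0.0 <= nu <= 0.5):
        raise InputError("Poisson ratio must be in [0, 0.5]")
    if E <= 0:
        raise InputError("Young modulus must be > 0")
    rng = np.random.default_rng(seed)
    n_px = int(round(domain_um / pixel_size))
    shape_px = (n_px, n_px)
    gx, gy = _tfm.grid_coordinates(shape_px, pixel_size, h)
    T = gaussian_traction_spots(spots, gx, gy)
    traction = _tfm.TractionField(T, h, E, nu)
    u = _tfm.forward_displacement(traction, pad_factor=2, crop=True)

    pos_um = _place_beads(rng, domain_um, bead_density, bead_min_sep_um)
    itp_x = interpolate.RegularGridInterpolator((gy, gx), u.u[..., 0],
                                                bounds_error=False, fill_value=None)
    itp_y = interpolate.RegularGridInterpolator((gy, gx), u.u[..., 1],
                                                bounds_error=False, fill_value=None)
    q = pos_um[:, ::-1]  # (y, x) ordering for the interpolator
    disp_um = np.column_stack([itp_x(q), itp_y(q)])
    pos_stressed_um = pos_um + disp_um

    pos_rel_px = pos_um / pixel_size
    pos_str_px = pos_stressed_um / pixel_size
    if loc_noise_px > 0:
        pos_rel_px = pos_rel_px + rng.normal(0, loc_noise_px, pos_rel_px.shape)
        pos_str_px = pos_str_px + rng.normal(0, loc_noise_px, pos_str_px.shape)
    relaxed_px = _render_beads(shape_px, pos_rel_px, bead_amplitude)
    stressed_px = _render_beads(shape_px, pos_str_px, bead_amplitude)
    if image_noise > 0:
        relaxed_px = relaxed_px + rng.normal(0, image_noise, shape_px)
        stressed_px = stressed_px + rng.normal(0, image_noise, shape_px)
    relaxed = IntensityImage(np.clip(relaxed_px, 0, None), pixel_size, "beads")
    stressed = IntensityImage(np.clip(stressed_px, 0, None), pixel_size, "beads")

    tmag = np.hypot(T[..., 0], T[..., 1])
    if tmag.max() > 0:
        island = ndimage.binary_dilation(tmag > 0.01 * tmag.max(),
                                         iterations=2)
    else:
        island = np.ones(tmag.shape, dtype=bool)
    dot = (T[..., 0] * u.u[..., 0] + T[..., 1] * u.u[..., 1])[island]
    U_true = 0.5 * dot.sum() * h ** 2 * _tfm.PA_UM3_TO_J
    truth = TfmTruth(traction, u, pos_um, pos_stressed_um, float(U_true),
                     (E, nu), island, pixel_size, shape_px)
    return (relaxed, stressed), truth


# ---------------------------------------------------------------------------
# FRET


@dataclass
class FretTruth:
    efficiency: np.ndarray
    beta: float
    gamma: float


def make_fret_triplet(efficiency, beta: float, gamma: float,
                      donor=100.0, acceptor=None,
                      shape: tuple[int, int] = (64, 64),
                      noise_sigma: float = 0.0, pixel_size: float = 0.3,
                      seed: int = 0):
    """Three-filter FRET channel triplet (DD, DA, AA) with known crossover.

    Generative model: DD = donor * (1 - E); AA = acceptor abundance
    (defaults to the donor map — intramolecular 1:1 sensor); DA =
    donor * E + beta * DD + gamma * AA, plus optional Gaussian noise.
    Returns ``((DD, DA, AA), truth)``.
    """
    if beta < 0 or gamma < 0:
        raise InputError("crossover coefficients must be >= 0")
    eff = np.broadcast_to(np.asarray(efficiency, dtype=float), shape).copy()
    if np.any((eff < 0) | (eff > 1)):
        raise InputError("efficiency must lie in [0, 1]")
    donor = np.broadcast_to(np.asarray(donor, dtype=float), shape).copy()
    if acceptor is None:
        acceptor = donor
    acceptor = np.broadcast_to(np.asarray(acceptor, dtype=float), shape).copy()
    dd = donor * (1.0 - eff)
    aa = acceptor
    da = donor * eff + beta * dd + gamma * aa
    rng = np.random.default_rng(seed)
    imgs = []
    for px, name in ((dd, "DD"), (da, "DA"), (aa, "AA")):
        if noise_sigma > 0:
            px = px + rng.normal(0, noise_sigma, shape)
        imgs.append(IntensityImage(np.clip(px, 0, None), pixel_size, name))
    return tuple(imgs), FretTruth(eff, beta, gamma)


# ---------------------------------------------------------------------------
# strand networks


@dataclass
class StrandTruth:
    n_strands: int
    depth_nm: float
    breaks: list              # (strand id, gap length nm)
    appearance: list


def make_strand_network(n_strands: int = 4, depth_nm: float = 300.0,
                        breaks=(), jitter_nm: float = 10.0,
                        length_nm: float = 2000.0, wavelength_nm: float = 500.0,
                        appearance="continuous", seed: int = 0):
    """Roughly horizontal strand meshwork with optional gaps.

    Strands are stacked evenly over ``depth_nm`` (a single strand has depth
    0 by construction), share a common sinusoidal undulation of amplitude
    ``jitter_nm`` (so they stay parallel), and ``breaks`` — a list of
    ``(strand_id, gap_nm)`` — cuts gaps of the given end-to-end length at
    seeded random positions.  The apical strand is the top-most (id 0).
    Returns ``(StrandNetwork, StrandTruth)``.
    """
    if n_strands < 1:
        raise InputError("n_strands must be >= 1")
    if depth_nm < 0:
        raise InputError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    if n_strands == 1:
        depth_nm = 0.0
    spacing = depth_nm / (n_strands - 1) if n_strands > 1 else 0.0
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(0.0, length_nm + 1e-9, 10.0)
    wave = jitter_nm * np.sin(2 * np.pi * x / wavelength_nm + phase)
    if isinstance(appearance, str):
        appearance_list = [appearance] * n_strands
    else:
        appearance_list = list(appearance)
        if len(appearance_list) != n_strands:
            raise InputError("appearance list length must equal n_strands")

    gaps_by_strand: dict = {}
    for sid, gap in breaks:
        if gap <= 0:
            raise InputError("gap lengths must be > 0")
        gaps_by_strand.setdefault(int(sid), []).append(float(gap))

    strands = []
    recorded = []
    for i in range(n_strands):
        y = i * spacing + wave
        path = np.column_stack([x, y])
        segments = [path]
        for gap in gaps_by_strand.get(i, []):
            c = rng.uniform(0.2 * length_nm, 0.8 * length_nm)
            new_segments = []
            for seg in segments:
                if seg[0, 0] <= c <= seg[-1, 0] and (seg[-1, 0] - seg[0, 0]) > 2 * gap:
                    left = seg[seg[:, 0] <= c - gap / 2]
                    right = seg[seg[:, 0] >= c + gap / 2]
                    if len(left) >= 2 and len(right) >= 2:
                        # trim the right start so the end-to-end gap is exact
                        d = right[0] - left[-1]
                        scale = gap / np.hypot(*d)
                        right = right.copy()
                        right[0] = left[-1] + d * scale
                        new_segments.extend([left, right])
                        recorded.append((i, gap))
                        continue
                new_segments.append(seg)
            segments = new_segments
        strands.append(Strand(id=i, segments=segments,
                              appearance=appearance_list[i]))
    net = StrandNetwork(strands, apical_id=0)
    return net, StrandTruth(n_strands, depth_nm, recorded, appearance_list)


# ---------------------------------------------------------------------------
# focal adhesions


def make_adhesion_image(ellipses, shape: tuple[int, int] = (256, 256),
                        pixel_size: float = 0.1, background: float = 5.0,
                        intensity: float = 150.0, noise_sigma: float = 0.0,
                        seed: int = 0):
    """Elliptical focal adhesions on a dim background.

    ``ellipses`` is a list of ``(cx_um, cy_um, a_um, b_um, angle_rad)``.
    Truth records the closed-form area (pi a b), maximum Feret diameter
    (2 max(a, b)), and whether the ellipse overlaps another.  Returns
    ``(IntensityImage, truth_records)``.
    """
    import pandas as pd
    from shapely.affinity import rotate, scale
    from shapely.geometry import Point

    rng = np.random.default_rng(seed)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    X = xs * pixel_size
    Y = ys * pixel_size
    img = np.full(shape, background, dtype=float)
    geoms = []
    rows = []
    for i, (cx, cy, a, b, ang) in enumerate(ellipses):
        if a <= 0 or b <= 0:
            raise InputError("semi-axes must be > 0")
        ca, sa = np.cos(ang), np.sin(ang)
        u = (X - cx) * ca + (Y - cy) * sa
        v = -(X - cx) * sa + (Y - cy) * ca
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[inside] = intensity
        geoms.append(rotate(scale(Point(cx, cy).buffer(1.0, 64), a, b),
                            ang, origin=(cx, cy), use_radians=True))
        rows.append({"id": i, "area_um2": np.pi * a * b,
                     "max_feret_um": 2.0 * max(a, b)})
    truth = pd.DataFrame(rows, columns=["id", "area_um2", "max_feret_um"])
    truth["overlaps"] = [
        any(j != i and geoms[i].intersects(geoms[j]) for j in range(len(geoms)))
        for i in range(len(geoms))
    ]
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, shape)
    return IntensityImage(np.clip(img, 0, None), pixel_size, "vinculin"), truth


# ---------------------------------------------------------------------------
# bright-field islands


def make_island_field(n_islands: int = 5, coverage: float = 0.30,
                      shape: tuple[int, int] = (400, 400),
                      pixel_size: float = 1.0, background: float = 100.0,
                      texture_amp: float = 40.0, noise_sigma: float = 0.0,
                      seed: int = 0, max_tries: int = 20000):
    """Textured circular cell islands on a smooth bright-field background.

    Islands are equal-radius disks sized so their total area is ``coverage``
    of the image, placed at seeded random non-overlapping positions, and
    filled with speckle texture so edge detection finds them.  Returns
    ``(IntensityImage, truth)`` with truth ``{"mask", "n_islands",
    "coverage", "centers_px", "radius_px"}``.
    """
    if n_islands < 0 or not (0.0 <= coverage < 1.0):
        raise InputError("need n_islands >= 0 and coverage in [0, 1)")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    centers = []
    radius = 0.0
    if n_islands > 0 and coverage > 0:
        radius = np.sqrt(coverage * h * w / (n_islands * np.pi))
        margin = radius + 5
        sep = 2 * radius + 6
        tries = 0
        while len(centers) < n_islands:
            tries += 1
            if tries > max_tries:
                raise InputError("could not place non-overlapping islands; "
                                 "lower coverage or n_islands")
            cand = rng.uniform([margin, margin], [w - margin, h - margin])
            if all(np.hypot(*(cand - c)) >= sep for c in centers):
                centers.append(cand)
        ys, xs = np.mgrid[0:h, 0:w]
        for cx, cy in centers:
            mask |= (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
        texture = rng.normal(0, texture_amp, shape)
        img[mask] += texture[mask]
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, shape)
    truth = {"mask": mask, "n_islands": n_islands,
             "coverage": float(mask.sum() / (h * w)),
             "centers_px": np.asarray(centers), "radius_px": radius}
    return IntensityImage(np.clip(img, 0, None), pixel_size, "brightfield"), truth


# ---------------------------------------------------------------------------
# nuclei


def make_nuclei_image(n: int = 20, shape: tuple[int, int] = (256, 256),
                      pixel_size: float = 0.3, radius_um: float = 3.0,
                      min_sep_um: float = 9.0, amplitude: float = 180.0,
                      noise_sigma: float = 0.0, seed: int = 0,
                      centers_um=None):
    """Blob-like nuclei over a dark background.

    Nuclei are rendered as smooth Gaussian-profile blobs (sigma = 2/3 of the
    nominal radius).  Positions are seeded random with a minimum separation,
    or supplied explicitly via ``centers_um`` (which may overlap — used to
    exercise watershed splitting).  Returns ``(IntensityImage, centers_um)``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if centers_um is None:
        centers = []
        margin = radius_um + 1
        lim = (w * pixel_size - margin, h * pixel_size - margin)
        tries = 0
        while len(centers) < n:
            tries += 1
            if tries > 20000:
                raise InputError("could not place nuclei at this density")
            cand = rng.uniform([margin, margin], lim)
            if all(np.hypot(*(cand - c)) >= min_sep_um for c in centers):
                centers.append(cand)
        centers = np.asarray(centers) if centers else np.empty((0, 2))
    else:
        centers = np.asarray(centers_um, dtype=float)
    ys, xs = np.mgrid[0:h, 0:w]
    X = xs * pixel_size
    Y = ys * pixel_size
    img = np.zeros(shape)
    sigma = radius_um * 2.0 / 3.0
    for cx, cy in centers:
        img += amplitude * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2)
                                  / (2 * sigma ** 2))
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, shape)
    return IntensityImage(np.clip(img, 0, None), pixel_size, "nuclei"), centers
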
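"""Traction force microscopy on soft elastic substrates.

The substrate is modelled as an incompressible-to-compressible (0 <= nu <= 0.5)
linear elastic half-space (Boussinesq).  In Fourier space surface displacement
and surface traction are related per wavevector k = (kx, ky), k = |k|, by

    u_hat(k) = G(k) . T_hat(k),

    G(k) = 2 (1 + nu) / (E k^3) *
           [[(1 - nu) k^2 + nu ky^2,  -nu kx ky],
            [-nu kx ky,               (1 - nu) k^2 + nu kx^2]]

with E the Young modulus (Pa) and nu the Poisson ratio.  Unconstrained
Fourier-transform traction cytometry (FTTC) inverts this relation mode by
mode, with no regularisation; the zero-frequency (rigid translation /
net force) mode is set to zero.

Units: displacements in µm, tractions in Pa, grid spacing h in µm; strain
energy U = 1/2 * sum(T . u) * h^2 is reported in joules
(1 Pa µm^3 = 1e-18 J).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage, spatial

from .core import InputError, IntensityImage

PA_UM3_TO_J = 1e-18


class RegistrationError(RuntimeError):
    """Drift registration could not find a trustworthy correlation peak."""


@dataclass
class DisplacementField:
    """Substrate displacement on a regular grid.

    ``u`` has shape (ny, nx, 2) with components (ux, uy) in µm; ``h`` is the
    node spacing in µm (2.6 µm by default throughout the package).
    """

    u: np.ndarray
    h: float = 2.6

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != 2:
            raise InputError("u must have shape (ny, nx, 2)")
        if not (self.h > 0):
            raise InputError("grid spacing h must be > 0")
        if not np.all(np.isfinite(self.u)):
            raise InputError("displacement field contains non-finite values")


@dataclass
class TractionField:
    """Surface traction on the displacement grid, plus substrate elasticity."""

    T: np.ndarray
    h: float
    E: float
    nu: float

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 3 or self.T.shape[2] != 2:
            raise InputError("T must have shape (ny, nx, 2)")
        if not (self.E > 0):
            raise InputError("Young modulus must be > 0")
        if not (0.0 <= self.nu <= 0.5):
            raise InputError("Poisson ratio must be in [0, 0.5]")
        if not np.all(np.isfinite(self.T)):
            raise InputError("traction field contains non-finite values")


@dataclass
class IslandEnergy:
    """Strain energy bookkeeping for one cell island."""

    U: float                   # total strain energy, J
    area: float                # island xy area, µm²
    density: float             # U / area, J/µm²
    net_force_ratio: float     # |sum T| / sum |T| on the island
    island_id: int = 0

    @property
    def U_fJ(self) -> float:
        return self.U * 1e15


# ---------------------------------------------------------------------------
# elastic kernel

def boussinesq_kernel(kx: np.ndarray, ky: np.ndarray, E: float, nu: float):
    """Fourier-space Green tensor components (Gxx, Gxy, Gyy) in µm/Pa.

    The k = 0 entry is left at 0 (the rigid-translation mode carries no
    information and is pinned by the zero-mean convention).
    """
    k2 = kx ** 2 + ky ** 2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k ** 3)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky ** 2)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx ** 2)
        gxy = pref * (-nu * kx * ky)
    zero = k2 == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def _padded(a: np.ndarray, pad_factor: int) -> np.ndarray:
    if pad_factor == 1:
        return a
    ny, nx = a.shape
    out = np.zeros((ny * pad_factor, nx * pad_factor), dtype=a.dtype)
    out[:ny, :nx] = a
    return out


def forward_displacement(T: TractionField, pad_factor: int = 2,
                         crop: bool = True) -> DisplacementField:
    """Displacement produced by a traction field (forward Boussinesq model).

    The FFT is computed on a domain enlarged by ``pad_factor`` (zero-padded
    tractions) to suppress periodic wrap-around; the result is cropped back
    to the input grid unless ``crop`` is False.  The zero-frequency mode is
    set to zero, i.e. the returned field has zero mean over the padded
    domain (no rigid translation).
    """
    ny, nx = T.T.shape[:2]
    tx = _padded(T.T[:, :, 0], pad_factor)
    ty = _padded(T.T[:, :, 1], pad_factor)
    kx = 2 * np.pi * np.fft.fftfreq(tx.shape[1], d=T.h)
    ky = 2 * np.pi * np.fft.fftfreq(tx.shape[0], d=T.h)
    KX, KY = np.meshgrid(kx, ky)
    gxx, gxy, gyy = boussinesq_kernel(KX, KY, T.E, T.nu)
    tx_hat = np.fft.fft2(tx)
    ty_hat = np.fft.fft2(ty)
    ux = np.real(np.fft.ifft2(gxx * tx_hat + gxy * ty_hat))
    uy = np.real(np.fft.ifft2(gxy * tx_hat + gyy * ty_hat))
    if crop:
        ux, uy = ux[:ny, :nx], uy[:ny, :nx]
    return DisplacementField(np.stack([ux, uy], axis=-1), T.h)


def fttc(u: DisplacementField, E: float, nu: float, pad_factor: int = 1,
         window: str | None = None) -> TractionField:
    """Unconstrained Fourier-transform traction cytometry.

    Inverts the Boussinesq relation mode by mode with no regularisation.
    ``pad_factor`` zero-pads the displacement grid before the FFT and
    ``window`` ("hann") optionally tapers it; both default off so that the
    inverse is the exact adjoint of :func:`forward_displacement` on the same
    grid.  The zero-frequency traction is set to 0.
    """
    if not (E > 0):
        raise InputError("Young modulus must be > 0")
    if not (0.0 <= nu <= 0.5):
        raise InputError("Poisson ratio must be in [0, 0.5]")
    ny, nx = u.u.shape[:2]
    ux = u.u[:, :, 0].copy()
    uy = u.u[:, :, 1].copy()
    if window == "hann":
        wy = np.hanning(ny)[:, None]
        wx = np.hanning(nx)[None, :]
        taper = wy * wx
        ux, uy = ux * taper, uy * taper
    elif window is not None:
        raise InputError(f"unknown window {window!r}")
    ux = _padded(ux, pad_factor)
    uy = _padded(uy, pad_factor)
    kx = 2 * np.pi * np.fft.fftfreq(ux.shape[1], d=u.h)
    ky = 2 * np.pi * np.fft.fftfreq(ux.shape[0], d=u.h)
    KX, KY = np.meshgrid(kx, ky)
    gxx, gxy, gyy = boussinesq_kernel(KX, KY, E, nu)
    det = gxx * gyy - gxy ** 2
    ux_hat = np.fft.fft2(ux)
    uy_hat = np.fft.fft2(uy)
    with np.errstate(divide="ignore", invalid="ignore"):
        tx_hat = (gyy * ux_hat - gxy * uy_hat) / det
        ty_hat = (-gxy * ux_hat + gxx * uy_hat) / det
    zero = (KX ** 2 + KY ** 2) == 0
    tx_hat[zero] = 0.0
    ty_hat[zero] = 0.0
    tx = np.real(np.fft.ifft2(tx_hat))[:ny, :nx]
    ty = np.real(np.fft.ifft2(ty_hat))[:ny, :nx]
    return TractionField(np.stack([tx, ty], axis=-1), u.h, E, nu)


# ---------------------------------------------------------------------------
# drift registration

def _ncc_surface(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cyclic normalised cross-correlation of two mean-subtracted images."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        raise RegistrationError("one of the images is constant")
    cc = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
    return cc / denom


def _parabolic_peak(cc: np.ndarray) -> tuple[float, float]:
    ny, nx = cc.shape
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)

    def refine(cm, c0, cp):
        d = cm - 2 * c0 + cp
        return 0.0 if d == 0 else 0.5 * (cm - cp) / d

    dy = refine(cc[(iy - 1) % ny, ix], cc[iy, ix], cc[(iy + 1) % ny, ix])
    dx = refine(cc[iy, (ix - 1) % nx], cc[iy, ix], cc[iy, (ix + 1) % nx])
    sy = iy + dy
    sx = ix + dx
    if sy > ny / 2:
        sy -= ny
    if sx > nx / 2:
        sx -= nx
    return sx, sy


def register_drift(stressed: IntensityImage, relaxed: IntensityImage,
                   min_correlation: float = 0.15):
    """Rigid drift between a bead image pair, and the resampled relaxed image.

    Returns ``((dx, dy), relaxed_registered)`` where (dx, dy) is the
    translation (px, stressed minus relaxed frame) and the relaxed image has
    been resampled onto the stressed frame by spline interpolation.
    """
    cc = _ncc_surface(stressed.pixels, relaxed.pixels)
    if cc.max() < min_correlation:
        raise RegistrationError(
            f"correlation peak {cc.max():.3f} below floor {min_correlation}")
    dx, dy = _parabolic_peak(cc)
    shifted = ndimage.shift(relaxed.pixels, (dy, dx), order=3, mode="nearest")
    registered = IntensityImage(np.clip(shifted, 0, None),
                                relaxed.pixel_size, relaxed.channel)
    return (dx, dy), registered


# ---------------------------------------------------------------------------
# bead detection / displacement estimation

def detect_beads(pixels: np.ndarray, min_distance: int = 3,
                 threshold_rel: float = 0.2) -> np.ndarray:
    """Subpixel bead centres (x, y in px) by peak detection + iterated centroid."""
    from skimage.feature import peak_local_max

    peaks = peak_local_max(pixels, min_distance=min_distance,
                           threshold_rel=threshold_rel)
    if len(peaks) == 0:
        return np.empty((0, 2))
    half = 3
    ny, nx = pixels.shape
    centres = []
    for r, c in peaks:
        y, x = float(r), float(c)
        for _ in range(3):
            r0, r1 = int(round(y)) - half, int(round(y)) + half + 1
            c0, c1 = int(round(x)) - half, int(round(x)) + half + 1
            if r0 < 0 or c0 < 0 or r1 > ny or c1 > nx:
                break
            win = pixels[r0:r1, c0:c1]
            tot = win.sum()
            if tot <= 0:
                break
            ys, xs = np.mgrid[r0:r1, c0:c1]
            y = float((ys * win).sum() / tot)
            x = float((xs * win).sum() / tot)
        centres.append((x, y))
    return np.asarray(centres)


def _piv_coarse(stressed: np.ndarray, relaxed: np.ndarray, window: int,
                overlap: float):
    """Window-wise cross-correlation; returns centres (x, y) and shifts (dx, dy) px."""
    from skimage.registration import phase_cross_correlation

    step = max(int(window * (1 - overlap)), 1)
    ny, nx = stressed.shape
    centres, shifts = [], []
    for r0 in range(0, ny - window + 1, step):
        for c0 in range(0, nx - window + 1, step):
            win_s = stressed[r0:r0 + window, c0:c0 + window]
            win_r = relaxed[r0:r0 + window, c0:c0 + window]
            if win_r.std() == 0 or win_s.std() == 0:
                continue
            shift, _, _ = phase_cross_correlation(win_s, win_r,
                                                  upsample_factor=10,
                                                  normalization=None)
            centres.append((c0 + window / 2, r0 + window / 2))
            shifts.append((shift[1], shift[0]))
    return np.asarray(centres), np.asarray(shifts)


def displacement_field(stressed: IntensityImage, relaxed: IntensityImage,
                       h: float = 2.6, piv_window: int = 32,
                       piv_overlap: float = 0.5, match_radius: float = 2.0,
                       min_distance: int = 3) -> DisplacementField:
    """Displacement field from a drift-corrected bead image pair.

    Coarse PIV (windowed cross-correlation) predicts the local shift, which
    seeds nearest-neighbour matching of individually localised beads; the
    scattered bead displacements are then linearly interpolated onto a
    regular grid of spacing ``h`` (µm).
    """
    if stressed.shape != relaxed.shape:
        raise InputError("bead image pair must share a shape")
    px = stressed.pixel_size
    beads_r = detect_beads(relaxed.pixels, min_distance=min_distance)
    beads_s = detect_beads(stressed.pixels, min_distance=min_distance)
    if len(beads_r) == 0 or len(beads_s) == 0:
        raise InputError("no beads detected")
    n_windows = (stressed.shape[0] / piv_window) * (stressed.shape[1] / piv_window)
    if len(beads_r) < 4 * n_windows:
        warnings.warn("fewer than 4 beads per PIV window on average; "
                      "displacement field may be under-sampled", stacklevel=2)

    piv_centres, piv_shifts = _piv_coarse(stressed.pixels, relaxed.pixels,
                                          piv_window, piv_overlap)
    if len(piv_centres) > 0:
        predictor = interpolate.NearestNDInterpolator(piv_centres, piv_shifts)
        predicted = predictor(beads_r)
    else:
        predicted = np.zeros_like(beads_r)

    tree = spatial.cKDTree(beads_s)
    dist, idx = tree.query(beads_r + predicted,
                           distance_upper_bound=match_radius)
    ok = np.isfinite(dist)
    if ok.sum() == 0:
        raise InputError("no beads could be tracked between the two images")
    disp_px = beads_s[idx[ok]] - beads_r[ok]

    # interpolate scattered displacements (µm) onto the regular h-grid
    pos_um = beads_r[ok] * px
    disp_um = disp_px * px
    ny, nx = stressed.shape
    gx, gy = grid_coordinates((ny, nx), px, h)
    GX, GY = np.meshgrid(gx, gy)
    ux = interpolate.griddata(pos_um, disp_um[:, 0], (GX, GY), method="linear")
    uy = interpolate.griddata(pos_um, disp_um[:, 1], (GX, GY), method="linear")
    for comp in (ux, uy):
        nanmask = np.isnan(comp)
        if nanmask.any():
            comp[nanmask] = interpolate.griddata(
                pos_um, disp_um[:, 0 if comp is ux else 1],
                (GX[nanmask], GY[nanmask]), method="nearest")
    return DisplacementField(np.stack([ux, uy], axis=-1), h)


def grid_coordinates(shape_px: tuple[int, int], pixel_size: float,
                     h: float) -> tuple[np.ndarray, np.ndarray]:
    """1D physical coordinates (µm) of the regular analysis grid covering an image."""
    height = shape_px[0] * pixel_size
    width = shape_px[1] * pixel_size
    nx = max(int(np.floor(width / h)), 1)
    ny = max(int(np.floor(height / h)), 1)
    gx = (np.arange(nx) + 0.5) * h
    gy = (np.arange(ny) + 0.5) * h
    return gx, gy


# ---------------------------------------------------------------------------
# energy and island bookkeeping

def strain_energy(u: DisplacementField, T: TractionField,
                  island_mask: np.ndarray, island_id: int = 0) -> IslandEnergy:
    """Total strain energy, density and force balance of one island.

    U = 1/2 * sum_mask (T . u) h^2, converted from Pa µm^3 to J; the density
    divides by the island area (µm²).  ``net_force_ratio`` is the magnitude
    of the vector sum of tractions over the sum of traction magnitudes — the
    out-of-equilibrium fraction used for quality filtering.
    """
    island_mask = np.asarray(island_mask, dtype=bool)
    if u.u.shape[:2] != T.T.shape[:2] or island_mask.shape != u.u.shape[:2]:
        raise InputError("displacement, traction and mask must share the grid")
    if u.h != T.h:
        raise InputError("displacement and traction grids differ in spacing")
    if not island_mask.any():
        raise InputError("island mask is empty")
    h2 = u.h ** 2
    dot = (T.T[..., 0] * u.u[..., 0] + T.T[..., 1] * u.u[..., 1])[island_mask]
    U = 0.5 * dot.sum() * h2 * PA_UM3_TO_J
    area = island_mask.sum() * h2
    tmag = np.hypot(T.T[..., 0], T.T[..., 1])[island_mask]
    net = np.array([T.T[..., 0][island_mask].sum(),
                    T.T[..., 1][island_mask].sum()]) * h2
    denom = tmag.sum() * h2
    ratio = float(np.hypot(*net) / denom) if denom > 0 else 0.0
    return IslandEnergy(U=float(U), area=float(area),
                        density=float(U / area), net_force_ratio=ratio,
                        island_id=island_id)


def filter_islands(islands: list[IslandEnergy],
                   max_net_force_ratio: float = 0.10,
                   area_bounds: tuple[float, float] | None = None):
    """Quality filter: force balance within 10%, optional island-area bounds.

    Returns ``(kept, discarded)`` where discarded is a list of
    ``(IslandEnergy, reason)``.
    """
    kept, discarded = [], []
    for isl in islands:
        if isl.net_force_ratio > max_net_force_ratio:
            discarded.append((isl, "out_of_equilibrium"))
        elif area_bounds is not None and not (area_bounds[0] <= isl.area <= area_bounds[1]):
            discarded.append((isl, "area_out_of_bounds"))
        else:
            kept.append(isl)
    return kept, discarded


def fold_normalise(per_gel_densities: pd.DataFrame,
                   control_condition: str) -> pd.DataFrame:
    """Express per-gel mean strain-energy densities as folds of the control.

    ``per_gel_densities`` needs columns ``gel``, ``condition``,
    ``mean_density``; each gel batch must contain the control condition with
    a non-zero mean.
    """
    required = {"gel", "condition", "mean_density"}
    if not required.issubset(per_gel_densities.columns):
        raise InputError(f"table must have columns {sorted(required)}")
    out = []
    for gel, grp in per_gel_densities.groupby("gel"):
        ctrl = grp.loc[grp["condition"] == control_condition, "mean_density"]
        if ctrl.empty:
            raise InputError(f"gel {gel!r} lacks control condition "
                             f"{control_condition!r}")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise InputError(f"gel {gel!r} has a zero control mean")
        g = grp.copy()
        g["fold"] = g["mean_density"] / ctrl_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)
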
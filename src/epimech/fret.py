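"""Sensitized-emission FRET analysis for intramolecular tension sensors.

Three-filter notation: DD — donor excitation / donor emission; DA — donor
excitation / acceptor emission (the raw "FRET" channel); AA — acceptor
excitation / acceptor emission.  The DA channel is contaminated by donor
bleed-through (beta * DD) and direct acceptor cross-excitation (gamma * AA),
both calibrated from single-fluorophore reference samples.  The corrected
FRET signal is Fc = DA - beta*DD - gamma*AA and the apparent efficiency is

    E_app = Fc / (Fc + DD)

which exactly inverts a 1:1 intramolecular sensor's emission model.  E_app
is an index comparable within one instrument configuration, not an absolute
efficiency (no G-factor correction is applied: the sensor has fixed 1:1
donor:acceptor stoichiometry).  Sign convention for mechanics: a *lower*
junctional E_app means a more extended sensor, i.e. *higher* inferred
tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import InputError, IntensityImage


class CalibrationError(InputError):
    """Crossover calibration failed (insufficient above-background signal)."""


@dataclass
class CrossoverCalibration:
    beta: float    # donor bleed-through: DA/DD in a donor-only sample
    gamma: float   # acceptor cross-excitation: DA/AA in an acceptor-only sample

    def __post_init__(self):
        if not (np.isfinite(self.beta) and np.isfinite(self.gamma)):
            raise InputError("crossover coefficients must be finite")
        if self.beta < 0 or self.gamma < 0:
            raise InputError("crossover coefficients must be >= 0")


@dataclass
class EfficiencyMap:
    """Per-pixel apparent FRET efficiency; NaN where Fc + DD <= 0."""

    values: np.ndarray
    pixel_size: float = 1.0

    def as_image(self) -> IntensityImage:
        return IntensityImage(np.nan_to_num(self.values, nan=0.0),
                              self.pixel_size, "fret_efficiency")


def _slope_through_origin(x: np.ndarray, y: np.ndarray,
                          min_pixels: int = 16) -> float:
    sel = x > _soft_threshold(x)
    if sel.sum() < min_pixels:
        raise CalibrationError(
            f"only {int(sel.sum())} above-background pixels (need {min_pixels})")
    xs, ys = x[sel], y[sel]
    return float((xs * ys).sum() / (xs * xs).sum())


def _soft_threshold(x: np.ndarray) -> float:
    if x.max() <= 0:
        return 0.0
    try:
        return float(threshold_otsu(x))
    except ValueError:  # constant image
        return float(x.max()) / 2.0


def calibrate_crossover(donor_only: tuple[IntensityImage, IntensityImage],
                        acceptor_only: tuple[IntensityImage, IntensityImage]
                        ) -> CrossoverCalibration:
    """Crossover coefficients from single-fluorophore reference images.

    ``donor_only`` is the (DD, DA) pair of a sample expressing the donor
    alone; ``acceptor_only`` the (AA, DA) pair of an acceptor-only sample.
    Each coefficient is the least-squares slope through the origin of DA
    versus the direct channel, over pixels above an automatic (Otsu)
    background threshold in the direct channel.
    """
    dd, da_d = donor_only
    aa, da_a = acceptor_only
    beta = _slope_through_origin(dd.pixels.ravel(), da_d.pixels.ravel())
    gamma = _slope_through_origin(aa.pixels.ravel(), da_a.pixels.ravel())
    return CrossoverCalibration(beta=max(beta, 0.0), gamma=max(gamma, 0.0))


def fret_efficiency_map(DD: IntensityImage, DA: IntensityImage,
                        AA: IntensityImage, cal: CrossoverCalibration,
                        formula: str = "fc_over_fc_plus_dd") -> EfficiencyMap:
    """Per-pixel apparent FRET efficiency from a co-registered triplet.

    Fc = DA - beta*DD - gamma*AA, clipped at 0.  With the default formula
    E_app = Fc / (Fc + DD); pixels where Fc + DD <= 0 are emitted as NaN
    ("no signal"), never as 0 ("no FRET").  ``formula="fc_over_dd"`` gives
    the alternative monotone index Fc / DD.
    """
    if not (DD.shape == DA.shape == AA.shape):
        raise InputError("DD, DA, AA must share a shape")
    fc = np.clip(DA.pixels - cal.beta * DD.pixels - cal.gamma * AA.pixels,
                 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "fc_over_fc_plus_dd":
            denom = fc + DD.pixels
            values = np.where(denom > 0, fc / denom, np.nan)
        elif formula == "fc_over_dd":
            values = np.where(DD.pixels > 0, fc / DD.pixels, np.nan)
        else:
            raise InputError(f"unknown formula {formula!r}")
    return EfficiencyMap(values, DD.pixel_size)
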
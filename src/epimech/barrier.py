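"""Epithelial barrier metrics and the small statistics used alongside them.

TER (transepithelial electrical resistance) is blank-corrected and
normalised to the filter area (Ω·cm²).  Tracer flux across the monolayer is
summarised as the apparent permeability coefficient

    Papp = (dQ/dt) / (A * C0)       [cm/s]

with dQ/dt the receiver-compartment accumulation rate, A the filter area
(cm²) and C0 the donor concentration.  The module also exposes the
two-proportion Z-test and Holm-Bonferroni multiple-testing adjustment used
for strand-morphometry comparisons; omnibus nonparametric tests
(Kruskal-Wallis, Wilcoxon) are deliberately left to scipy in reporting
scripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core import InputError

# 24-well Transwell insert growth area (cm²); configurable per record
DEFAULT_FILTER_AREA_CM2 = 0.33


@dataclass
class TerRecord:
    r_sample: float            # Ω, filter with monolayer
    r_blank: float             # Ω, blank filter
    filter_area: float = DEFAULT_FILTER_AREA_CM2   # cm²

    def __post_init__(self):
        if self.filter_area <= 0:
            raise InputError("filter area must be > 0")
        if self.r_blank < 0 or self.r_sample < 0:
            raise InputError("resistances must be >= 0")


@dataclass
class FluxRecord:
    times: np.ndarray          # s
    readings: np.ndarray       # receiver fluorescence, arbitrary units
    standard_curve: np.ndarray  # (n, 2) columns (fluorescence, concentration)
    donor_c0: float            # concentration, same units as the curve
    volume: float              # receiver volume, mL
    area: float = DEFAULT_FILTER_AREA_CM2  # cm²
    tracer: str = "4kD"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        self.standard_curve = np.asarray(self.standard_curve, dtype=float)
        if len(self.times) != len(self.readings):
            raise InputError("times and readings must have equal length")
        if len(self.times) < 2:
            raise InputError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("readings must be time-ordered")
        sc = self.standard_curve
        if sc.ndim != 2 or sc.shape[1] != 2 or len(sc) < 2:
            raise InputError("standard curve needs >= 2 (fluorescence, conc) pairs")
        if np.any(np.diff(sc[:, 0]) <= 0) or np.any(np.diff(sc[:, 1]) <= 0):
            raise InputError("standard curve must be strictly monotone")
        if self.donor_c0 <= 0 or self.volume <= 0 or self.area <= 0:
            raise InputError("donor_c0, volume and area must be > 0")


def ter_unit_area(rec: TerRecord) -> float:
    """Blank-corrected, area-normalised TER: (R_sample - R_blank) * A, Ω·cm²."""
    corrected = rec.r_sample - rec.r_blank
    if corrected < 0:
        warnings.warn("sample resistance below blank; negative unit-area TER",
                      stacklevel=2)
    return corrected * rec.filter_area


def apparent_permeability(rec: FluxRecord) -> float:
    """Papp (cm/s) from receiver readings over time.

    Fluorescence is converted to concentration by linear interpolation on
    the standard curve, the accumulated amount Q = C * V is regressed on
    time (ordinary least squares over all points, i.e. the linear range —
    sink conditions assumed), and Papp = slope / (A * C0).  mL and cm³ are
    used interchangeably.
    """
    conc = np.interp(rec.readings, rec.standard_curve[:, 0],
                     rec.standard_curve[:, 1])
    amount = conc * rec.volume
    slope = stats.linregress(rec.times, amount).slope
    return float(slope / (rec.area * rec.donor_c0))


def flux_fit_quality(rec: FluxRecord) -> float:
    """R² of the linear receiver-accumulation fit behind the Papp estimate."""
    conc = np.interp(rec.readings, rec.standard_curve[:, 0],
                     rec.standard_curve[:, 1])
    r = stats.linregress(rec.times, conc * rec.volume).rvalue
    return float(r ** 2)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sided two-proportion Z-test; returns (z, p)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise InputError("sample sizes must be > 0")
        if not (0 <= k <= n):
            raise InputError("need 0 <= k <= n")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    if np.isnan(z):  # pooled proportion 0 or 1: no evidence of a difference
        return 0.0, 1.0
    return float(z), float(p)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the original order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InputError("pvals must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
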
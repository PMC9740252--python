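# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each `epimech` pipeline, and what the synthetic-data
generators do and do not emulate.

## Conventions and units

Images use a pixel-centre coordinate frame: origin at the centre of the
top-left pixel, x rightward (columns), y downward (rows), 0-based; all ROIs
live in this frame in pixel units. Physical calibration is a scalar
`pixel_size` in µm/px supplied by the caller (microscope TIFFs in this
domain rarely carry reliable resolution tags, so calibration is explicit
rather than parsed). Displacements are µm, tractions Pa, strand coordinates
nm, TER Ω·cm², permeability cm/s. Strain energy is converted from
Pa·µm³ to joules (1 Pa·µm³ = 10⁻¹⁸ J) and is most conveniently read in fJ.

## Traction force microscopy

**Elastic model.** The substrate is a linear-elastic half-space with Young
modulus E and Poisson ratio ν ∈ [0, 0.5]. Surface displacement and surface
traction are related per wavevector k = (kx, ky) by û(k) = G(k)·T̂(k) with

    G(k) = 2(1+ν)/(E k³) · [[(1−ν)k² + ν ky²,  −ν kx ky],
                            [−ν kx ky,          (1−ν)k² + ν kx²]].

The forward model (used by the bead-image generator) rasterises tractions
on the regular analysis grid (default spacing h = 2.6 µm), zero-pads the
domain by a factor 2 to suppress periodic wrap-around, multiplies by G in
Fourier space and sets the k = 0 mode to zero (zero-mean displacement, no
rigid translation). Unconstrained Fourier-transform traction cytometry
(FTTC) inverts the same relation mode by mode with no regularisation and
zero net traction at k = 0.

**Windowing and padding in the inverse.** `fttc` defaults to no window and
no padding, making it the exact inverse of the forward operator on a shared
grid — the round-trip identity is the pipeline's central self-check
(relative RMS ≈ 10⁻¹³ on a 128² grid). A Hann taper and factor-2
zero-padding are available behind flags for real recordings with strong
edge displacements, but both bias amplitude recovery and are therefore off
by default; any non-default choice should be reported alongside results.

**Displacement estimation.** Drift between the stressed and relaxed
recordings is removed by normalised cross-correlation with a parabolic
sub-pixel peak fit; a correlation peak below 0.15 raises a registration
error rather than returning a silent garbage shift. Displacements are then
estimated in two stages: coarse PIV (32-px windows, 50 % overlap,
Fourier cross-correlation with 0.1-px upsampling) predicts the local shift,
which seeds per-bead tracking — beads are localised by peak detection and
an iterated 7×7 centre-of-mass refinement, and matched to their displaced
partners by nearest neighbour within 2 px of the PIV prediction. The
scattered bead displacements are linearly interpolated onto the h-grid
(nearest-neighbour fill outside the convex hull).

**Energy and quality filters.** For an island mask M on the grid,
U = ½ Σ_M (T·u) h² and the strain-energy density is U divided by the island
area. The out-of-equilibrium fraction |Σ_M T h²| / Σ_M |T| h² must not
exceed 0.10 for an island to be kept; an optional area band supports
matching island pools across conditions and has deliberately no default —
it is an experiment-design choice. Per-gel means are expressed as folds of
the control condition of the same gel batch.

**Problem sizes.** The validation fixtures use a 96 µm field at
0.1 µm/px, a balanced contractile dipole (two opposing 400 Pa Gaussian
spots of 6 µm width, 24 µm apart), E = 16.4 kPa and ν = 0.5 (incompressible
polyacrylamide), bead density 1 µm⁻² with a 0.7 µm minimum bead separation
(the physical bead suspensions are sonicated against clumping), and
0.05 px bead localisation noise. Under these conditions the full
beads → displacement → traction → energy pipeline recovers the true
strain-energy density within ~4 % (well inside the 15 % test band), and the
wide empty margin around the island keeps spectral-leakage bias small — the
same reason the real experiments image islands surrounded by a large
no-displacement field.

## FRET sensitized emission

Three-filter notation: DD (donor/donor), DA (donor excitation, acceptor
emission), AA (acceptor/acceptor). Crossover coefficients are calibrated on
single-fluorophore references as least-squares slopes through the origin
(β = DA/DD on donor-only pixels, γ = DA/AA on acceptor-only pixels, pixels
selected by an Otsu threshold in the direct channel). The corrected FRET
signal is Fc = DA − β·DD − γ·AA (clipped at 0) and the apparent efficiency

    E_app = Fc / (Fc + DD),

which exactly inverts the emission model of a 1:1 intramolecular tension
sensor. Pixels with Fc + DD ≤ 0 are NaN ("no signal"), never 0 ("no
FRET") — conflating the two would bias junctional segment statistics. No
G-factor is applied: with fixed stoichiometry E_app is an index comparable
within one instrument configuration, not an absolute efficiency. Lower
junctional E_app corresponds to a more extended sensor and hence higher
inferred tension; this sign convention is documented, not computed.

## Junctional intensity metrics

The junctional formation index divides the mean intensity along a line
traced on the junction by the average of two lines traced in the adjacent
cytosol; stroke membership is centre-within-width/2 (Euclidean), making it
deterministic and resolution-independent. Default stroke widths are 15 px
for occludin-type and 20 px for p120-catenin-type stainings. The fixture
places the two cytosolic lines at a fixed 10 px normal offset — a
configurable choice, since annotators place them by eye. A mediatrix
helper constructs the perpendicular bisector between two nucleus centroids
for junctions without visible signal; when to invoke it is the annotator's
decision. Integrated densities subtract a background estimated as the
histogram mode over the lowest 90 % of intensities (robust and
deterministic); background-subtracted means clip at zero because densities
are physical quantities.

## Cell and adhesion morphometry

**Cell segmentation.** Junction-stained images are ridge-enhanced (Sato
vesselness, σ = 1–2 px, edge-padded because the Hessian response collapses
at the frame), thresholded (Otsu), OR-combined with a plain intensity
threshold (the ridge filter goes blind inside wide junctional patches),
skeletonised, cleared of small cytosolic objects (< 30 px), gap-closed
(radius-1 morphological closing, with the border treated as junction), and
the complement labelled. Junction-line pixels are then split between
adjacent cells by label expansion so areas are bounded by the junction
midline. Border-touching cells are flagged and excluded from area
statistics by default (their area is censored by the field of view). On
noise-free mosaics of 9–64 cells the label count matches truth exactly and
interior areas agree within ~1.5 %.

**Nuclei and density classes.** Nuclei are counted classically (Gaussian
smooth, Otsu, hole filling, distance-transform watershed); this replaces a
learned segmenter and is adequate for blob-over-dark-background images, not
for tissue sections. Field density calls use the fixed threshold table —
glass: sparse 10–25, dense > 40; 40 kPa: sparse 15–30, dense > 50; 1 kPa
fields are never classified — after scaling counts to the reference
1.6×10⁴ µm² field. Whether thresholds apply to raw or area-scaled counts is
ambiguous for non-reference fields; this implementation scales, and records
the scaled count in the output so the assumption is visible.

**Focal adhesions.** Rolling-ball background subtraction, locally adaptive
threshold (51-px window), and watershed splitting seeded by h-maxima of the
distance transform (h = 1 px) — plateau-merged maxima prevent a single
elongated adhesion from being chopped into fragments, while genuinely fused
objects with distinct cores still split. The maximum Feret diameter is the
rotating-calipers result, computed as the maximum pairwise distance between
convex-hull vertices of the pixel-centre cloud; tests pin it against a
0.5°-step projection sweep.

## 2D morphogenesis

Bright-field islands are segmented by a Sobel edge map, Otsu threshold,
3×3 median despeckle, one 3×3 dilation, hole filling, and a radius-2
morphological opening; components above 200 µm² (≈ one cell) count as
islands. Coverage is the summed island area as a percentage of the field;
the morphogenesis index MI = coverage % / island count rises when
fragments merge (fewer islands at equal coverage) and falls for
fragmented monolayers. Islands touching the border are counted. With no
islands the MI is NaN, not 0 — an empty field is not evidence of
fragmentation.

## Freeze-fracture strand morphometry

Input is vector annotation (polylines in nm, one entry per strand with an
ordered list of segments and a particle/continuous label), not raw
micrographs: strand tracing is left to the annotator or the generator, and
the package implements the measurement geometry exactly. Grid lines are
erected perpendicular to the most apical strand at 200 nm arclength
intervals; the perpendicular uses a local tangent smoothed over 400 nm
(default) or a single global orientation. Per grid line the number of
distinct strands intersected is counted — a strand crossed twice by one
line (U-turn) counts once. Meshwork depth is the mean extent, along the
grid-line direction, between the outermost intersections; a single-strand
network has no extension and returns 0 by definition. Discontinuities are
end-to-end gaps between consecutive segments of one strand and count as
breaks only when strictly greater than 20 nm. Tangential grazing contacts
at strand tips count as intersections; with 10 nm-resolution polylines this
affects at most one grid line per strand end. All outputs are invariant
under rigid rotation and translation of the annotation because orientation
derives from the apical strand, not the image axes.

## Barrier metrics and statistics

TER is blank-corrected and area-normalised, (R_sample − R_blank)·A, with
the filter area defaulting to 0.33 cm² (24-well Transwell inserts);
negative corrected values are returned with a warning, never silently.
Apparent permeability converts receiver fluorescence to concentration by
interpolation on a strictly monotone standard curve, regresses the
accumulated amount Q = C·V on time, and divides the slope by (A·C0); sink
conditions are assumed (receiver ≪ donor concentration), the fit R² is
exposed, and no sink-depletion correction is applied. The two-proportion
Z-test (pooled, two-sided) and Holm–Bonferroni step-down adjustment are
thin wrappers over statsmodels with input validation and a defined
degenerate-case answer (pooled proportion 0 or 1 → z = 0, p = 1); omnibus
nonparametric tests are left to scipy in user scripts.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed) and always emits a
truth record next to its images. The monolayer generator builds a
Lloyd-relaxed Voronoi mosaic (junction level J > cytosol C > background B;
defaults 200/100/0), a matching nuclei channel, and a 1-px junction
skeleton as truth; the image border is treated as part of the cell outline.
The TFM generator drives bead images through the elastic forward model
described above. The FRET generator produces DD/DA/AA triplets from a known
efficiency map and crossover pair. The strand generator stacks parallel
sinusoidally undulating strands over a stated depth and cuts gaps of exact
end-to-end length. Adhesion and island generators render analytic ellipses
and textured disks with closed-form truth.

None of this emulates real optics: no PSF beyond the bead spots, no shading
or chromatic shifts, Gaussian noise only, no out-of-focus light, and
mosaics are more regular than real epithelia. Passing the recovery tests
therefore demonstrates that the measurement algebra and geometry are
implemented correctly and are unbiased under the stated noise — not that
segmentation or tracking are robust to real-world image degradation.

## Numerical choices and degenerate inputs

Ties in focus selection resolve to the lowest slice index. Otsu is used
wherever an unsupervised threshold is needed, because it is deterministic;
constant images short-circuit to empty results instead of erroring inside
the threshold. Ratio metrics raise a dedicated undefined-ratio error on
zero denominators rather than returning infinities. `fttc` validates
0 ≤ ν ≤ 0.5 and E > 0; ν = 0.5 (incompressible) is the default for
polyacrylamide. Grid spacing h = 2.6 µm matches the published displacement
grid. Random placement loops (beads, nuclei, islands) are dart-throwing
with a try cap and raise an input error when the requested density is
unachievable, rather than looping forever.
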
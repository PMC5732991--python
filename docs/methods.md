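# Methods

## Scope and model

`retstereo` implements the computational side of a retinal-wholemount
topography study for a small foveate teleost: design-based (fractionator)
estimation of cell densities and totals, shrinkage correction, topographic
mapping with angular fovea localization, and closed-form anatomical acuity.
Because no raw counting data are publicly deposited for this kind of study,
the package pairs the analysis chain with a generative model of the tissue
so that every estimator can be checked against known ground truth.

## Synthetic retina

**Geometry.** The flattened wholemount is modelled as an ellipse (256
boundary segments) with a dorso-ventral/antero-posterior axis ratio of
0.863, an optic-disk hole and a thin falciform gap running naso-ventrally.
The half-axes are solved so the usable area (ellipse minus holes) is
16.09 mm². Coordinates are mm, origin at the bounding-box centre, +x
temporal and +y dorsal for a left eye; right-eye geometry is mirrored about
the y-axis at construction. Flattening cuts are not modelled: the synthetic
outline is already flat, which is the domain the analysis operates in.

**Density fields.** Each cell type has a parametric intensity surface:
`base + gradient·(x, y)` plus Gaussian foveal bumps plus constant plateaus
inside patch polygons, floored at zero. A bump's nominal `peak_value` is
the field value *at* the peak centre (amplitude = peak_value − local trend),
so stated peak densities are reproduced exactly at the fovea. Defaults
(cells/mm²): single cones base 10,000 peaking at 30,800 (σ = 0.25 mm);
twin cones base 22,500 peaking at 104,400; ganglion cells base 31,500
peaking at 81,000 (σ = 0.35 mm, a slightly broader perifoveal annulus
proxy); triple cones confined to a ~0.32 mm² patch between optic disk and
fovea (plateau 16,700, centre value 30,400); rods base 80,000 with
multiplicative Gaussian suppression masks removing them from the foveal and
triple-cone areas. All fields carry a dorso-temporal linear gradient; the
fovea sits at 50° temporal / 30° dorsal under the diameter-equals-180°
convention. The peripheral baselines are chosen so area-weighted means land
near the per-type study means; they are targets of convenience, not
measured peripheral values. One twin-cone record represents a twin pair
and one triple-cone record three members; densities are per-record.

**Point process.** Cells are drawn from an inhomogeneous Poisson process by
thinning: a homogeneous process at an analytic upper bound of the field
over the bounding box, restricted to the usable polygon, thinned with
probability field/bound. The expected count equals the field's integral
over the tissue (verified against midpoint quadrature; the mean count over
200 seeds matches within 1%).

**Mosaics.** Regular cone mosaics are generated as complete unit cells over
the target bounds: the square 2:1 pattern (one single cone per lattice
node, two twins on the half-edge positions), the 4:1 "lucky-clover"
pattern (central single surrounded by four unshared twins), its sheared
variant, and uniform random triple scatter at intensity 1/pitch² (the spec
of a mosaic carries only a pitch, so one triple per unit-cell area is the
natural rate). Emitting whole unit cells makes the twin:single count ratio
exactly 2:1 / 4:1 before clipping for any pitch, seed or jitter; clipping
to a region polygon perturbs the realized ratio only through boundary
cells.

**Shrinkage distortion.** Post-staining shrinkage is modelled region-wise
(default: the four bounding-box quadrants of the usable area, linear scales
0.96–0.99 — "limited" shrinkage): every cell is rescaled about its region's
centroid, so per-region areal ratios equal `linear_scale²` exactly and cell
counts and region membership are conserved.

## Fractionator sampling

A stratum is sampled on a square grid with step `sqrt(area/target_sites)`
and a uniform random origin offset in `[0, step)²` (systematic uniform
random sampling). A counting frame is centred at every node and clipped to
the stratum polygon; partially clipped frames are retained and their
clipped areas enter both the area sampling fraction and the density
denominator, which removes edge bias on irregular outlines. A cell is
counted iff it falls in the half-open frame `(xmin, xmax] × (ymin, ymax]`:
top and right edges (and the top-right corner) include, left and bottom
edges forbid — the Gundersen rule, chosen because frames tiling the plane
then count every cell exactly once (asserted by brute force in the tests).
Wholemounts are two-dimensional, so the thickness sampling fraction is
identically 1 and `total = ΣQ / asf`.

Strata form a strict partition: the foveal circle (0.95 mm²) and the
triple-cone patch are cut out of the general stratum, and retina-wide
totals are sums over strata. Default designs: 200 sites of 50 µm frames
over the general retina (step ≈ 272–284 µm), 60 sites of 25 µm frames over
the fovea (step ≈ 126 µm), 14 sites of 50 µm frames over the triple patch.

**Scheaffer's CE.** Estimate precision uses the survey-sampling total
estimator with finite-population correction over the population of
frame-sized tissue units (`N = n/asf`):
`CE = sqrt((1 − asf)·s²/n) / q̄`, zero for constant counts or a census.
The commercial stereology packages do not print their exact formula; this
is the standard reading, and published per-retina CE values are treated as
calibration context, not as reproduction targets. Under the default
sampling intensity the general-stratum CE is ≈0.02, comfortably below the
0.1 representativeness bound.

**Imputation.** Sites flagged as locally compromised are repaired the way a
counting session would: if only single cones are unreadable, the site's
single count is its twin count times the mean single/twin ratio of the
up-to-8 adjacent grid sites with positive twin counts (mean, not median —
the smallest symmetric local rule), rounded half-up; if twins are
unreadable too, or no valid neighbour exists, the whole site is omitted
from both count sums and sampled area.

## Shrinkage correction

Each region's shrinkage factor is `area_after / area_before` of its
digitised outline. Raw densities measured on stained (shrunken) tissue are
multiplied by the factor of the region containing the frame centre: a
density measured on tissue at fraction `f` of its original area is
inflated by `1/f`, so multiplying by `f < 1` converts it back to
pre-staining scale — the only direction consistent with dimensional
analysis. Edge frames whose centre falls marginally outside every region
(their clipped area still inside one) are assigned to the nearest region
within one frame side. The headline validation is the round trip: shrink a
synthetic map, re-sample it, correct with the measured factors, and recover
the generating field's regional means within Monte-Carlo error.

## Topography

Site densities (`Q/clipped_area`) are interpolated onto a raster (default
25 µm/pixel, the foveal frame side) by piecewise-linear interpolation on
the Delaunay triangulation of site centres — exact at the sites — with
nearest-site fill between the convex hull and the outline, masked to the
usable polygon (NaN outside). The paper-style contour tool being a black
box, this simplest exact-at-sites scheme is used and recorded in the map
metadata. Heavily clipped frames (< 50% of full frame area) are excluded
from the *map* site pool (not from the estimators): a handful of cells over
a sliver denominator otherwise produces spurious density spikes.

The density peak is the masked-raster argmax, ties broken toward smallest
y then x. The fovea's angular position assumes the horizontal and vertical
retinal diameters each subtend 180°: `deg = 90·offset/half_axis` from the
bounding-box centre of the boundary (holes ignored; whether the original
analyses used this centre or visual inspection is unknowable, so the choice
is recorded in output metadata). Temporal sign follows the eye side.

## Optics

`PND = lens_radius × Matthiessen's ratio` (default 2.55, the teleost
average). Nyquist SRP for a hexagonal receptor lattice:
`f_N = (π·PND/360)·sqrt((2/√3)·D)`. The minimal separable angle is defined
as `1/f_N` — the convention forced by the published pairing of 6.7 cpd with
0.15° — not the `1/(2 f_N)` sometimes seen. Resolvable distance uses the
small-angle form `d = size/MSA_rad` (an exact-tangent variant is available
behind a flag; it differs by < 1e-5 relative at sub-degree angles).
Conservative vs maximal densities encode whether a twin cone signals as one
unit or two. Visual-field coverage is arithmetic: per-eye total =
optical field + rotation range (capped at 360°), foveate total = twice the
rotation range. Binocular-overlap figures are not derivable from these
inputs and are not computed. Full precision is carried internally;
decimal half-up rounding (1 decimal cpd, 2 decimal degrees) is applied only
at the reporting layer, matching hand calculation on the printed inputs
(e.g. 0.70 × 2.55 = 1.785 → 1.79).

## Pipeline and reproducibility

`run_pipeline` chains simulate → stratified sampling → estimation →
RGC shrinkage round trip → maps → fovea → acuity. One master seed is split
into stage seeds via `numpy.random.SeedSequence.spawn` in a fixed order, so
reruns are byte-identical; every output file carries the package version,
a hash of the configuration (excluding the output path) and the seed.
External formats are comma-delimited UTF-8 tables (documented column order)
and GeoJSON outlines.

## Problem sizes in the test suite

The statistical guarantees are exercised at the study's sampling intensity:
estimator unbiasedness and CE calibration on a ~1.1×10⁵-cell retina over
200 independent grid origins (mean total within 2% of truth, every CE
< 0.1); shrinkage round-trip on a ~65k-cell map over four regions (4 SD
bands); peak localization on full-density twin-cone fields over 50 seeds
(median error under one foveal grid step). Faster unit tests use uniformly
down-scaled density fields, which preserves the spatial structure while
thinning the point load.

## Limitations

The generator emulates first-order structure (smooth gradients, Gaussian
fovea, regular mosaics, isotropic region-wise shrinkage). It does not model
flattening cuts and their distortions, anisotropic or radial shrinkage,
lateral displacement of foveal ganglion cells, rod/cone interdigitation
constraints, or optical factors (photon catch, aphakic gap, foveal-pit
magnification). Passing tests therefore demonstrate correctness of the
estimators and transforms under the stated generative assumptions, not
robustness to every artefact of real tissue. Published per-retina estimates
cannot be reproduced exactly without the raw per-site counts; the package
instead reproduces the quantities that are closed-form functions of
printed inputs and validates the statistical machinery on simulated ground
truth.
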
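# retstereo

Design-based stereology and anatomical acuity estimation for retinal
wholemounts, with a synthetic-retina simulator for end-to-end validation.

Retinal topography — how photoreceptor and ganglion-cell densities vary
across the retina — predicts where and how well an animal sees. For small
teleosts such as triplefin blennies, the standard workflow is: flatten the
retina, sample it with an optical-fractionator grid of unbiased counting
frames, estimate per-type densities and total populations, correct the
Nissl-stained ganglion-cell stage for tissue shrinkage, interpolate
topographic density maps, locate the fovea, and convert peak foveal
densities into a spatial resolving power. `retstereo` implements every one
of those computational stages as a tested Python library plus CLI, and — in
the absence of public raw counting data — ships a point-process simulator
that generates retinas with *known* density fields, cone mosaics and
shrinkage so the whole chain can be validated against ground truth.

## The estimators

For a stratum of area `A` sampled by `n` counting frames with clipped areas
`a_i` and per-frame counts `Q_i` (unbiased counting-frame rule: top and
right edges include, left and bottom edges forbid):

```
asf  = Σ a_i / A                 (area sampling fraction)
D̂    = Σ Q_i / Σ a_i             (mean density, cells mm⁻²)
N̂    = Σ Q_i / asf               (total population)
CE   = sqrt((1 − asf) · s²_Q / n) / Q̄     (Scheaffer's coefficient of error)
```

Acuity follows from the posterior nodal distance `PND = r_lens × 2.55`
(Matthiessen's ratio for teleosts) and the peak foveal receptor density `D`
on a hexagonal lattice:

```
f_N = (π · PND / 360) · sqrt((2/√3) · D)      [cycles/degree]
MSA = 1 / f_N                                  [degrees]
```

with a conservative density (twin cones as single signalling units,
`D = D_twin + D_single`) and a maximal one (each twin member individually,
`D = 2·D_twin + D_single`).

## Worked example

Closed-form acuity for a triplefin-sized eye (lens radius 0.70 mm, peak
foveal densities 132,000 twin and 28,000 single cones per mm²):

```
$ retstereo srp
PND = 1.79 mm (lens radius 0.7 mm x Matthiessen 2.55)
mode             D (/mm^2)  f_N (cpd)  MSA (deg)     d(1 mm) cm
conservative       160,000        6.7       0.15           38.4
maximal            292,000        9.0       0.11           51.8
```

Reading: treating each twin cone as one unit the foveal mosaic resolves
6.7 cycles per degree (minimal separable angle 0.15°), so a 1 mm object —
a copepod, say — is resolvable at ~38 cm; if both twin members signal
independently the limit rises to 9.0 cpd (0.11°, ~52 cm).

The full simulated analysis (synthetic retina → stratified fractionator
sampling → shrinkage-corrected ganglion cells → topographic maps → fovea →
acuity):

```
$ retstereo run-all --seed 7 -o out/
general stratum: 210 sites, asf 0.0337, CE single_cone=0.021, twin_cone=0.018, ...
fovea: 50.3 deg temporal, 30.1 deg dorsal
srp[conservative]: 6.5 cpd (MSA 0.15 deg)
srp[maximal]: 8.5 cpd (MSA 0.12 deg)
report: out/report.json
```

The general stratum is sampled at an area sampling fraction of ~0.034 with
Scheaffer CEs around 0.02 (well under the 0.1 representativeness bound);
the map peak lands at 50° temporal / 30° dorsal — the simulator's ground
truth fovea position — and the measured peak densities give 6.5/8.5 cpd.
`out/report.json` holds per-stratum densities, totals, CEs, shrinkage
factors and the acuity block; `out/sites_*.csv` are the counting-site
tables and `out/map_*.txt` the raster maps.

Other subcommands: `simulate` (cells + outline to disk), `sample`
(fractionator grid over a cell table), `estimate` (site table → densities,
totals, CE), `map` (site table → contour PNG + text raster), all
composable through delimited-text/GeoJSON interchange formats.

## Layout

- `retstereo.synthetic` — outlines, density fields, Poisson point
  processes, cone mosaics, shrinkage distortion
- `retstereo.fractionator` — sampling designs, counting frames, stratum
  estimates, Scheaffer CE, imputation of compromised sites
- `retstereo.shrinkage` — region shrinkage factors and density correction
- `retstereo.topography` — density rasters, peak finding, angular fovea
  position
- `retstereo.optics` — PND, Nyquist SRP, MSA, resolvable distance,
  visual-field coverage
- `retstereo.pipeline` / `retstereo.cli` / `retstereo.io` — runner,
  command line, formats

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
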
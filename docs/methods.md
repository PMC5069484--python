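# Methods

## Model

The package treats a TIRF recording of a homogeneously distributed
cytosolic fluorophore as a line-of-sight integral of an exponentially
decaying excitation field. With penetration depth `d_p`, a fluorophore
column truncated at height `z` (by the lower surface of a non-fluorescent
organelle) emits the fraction `I_rel(z) = 1 − exp(−z/d_p)` of an
unobstructed column; the gap follows from the exact inverse
`z = −d_p·ln(1 − I_rel)`. Three assumptions underlie everything else:

1. the fluorophore is homogeneous in the cytosol and excluded from the
   organelle (junctional gaps ≳ 10 nm do not sterically exclude GFP-sized
   probes, but very narrow gaps may — distances below ~10–20 nm should be
   read as semi-quantitative);
2. absolute intensity factors (laser power, fluorophore concentration,
   collection efficiency) are unknown but spatially constant across the
   analyzed cell region, so they cancel in the ratio to a nearby
   organelle-free reference;
3. the organelle has finite axial extent `T`, so cytosol *beneath* it
   contributes a residual background `exp(−(z+T)/d_p)`.

### Background correction

Two corrections are provided. The canonical one subtracts a scalar
background fraction `b` before inversion, `z = −d_p·ln(1 − (I−b))`; a
renormalizing variant divides by `(1−b)` for the case where the reference
region shares the background. When the occluder thickness is known (it is,
exactly, for simulated scenes; ~75 nm is a reasonable prior for junctional
ER), the closed-form self-consistent inversion
`z = −d_p·ln((1−I)/(1−exp(−T/d_p)))` removes the depth-dependence of the
background altogether; `label_rois`, `reconstruct_topology` and the
pipeline accept it as `occluder_thickness_nm`.

### Censoring

The inversion diverges as `I_rel → 1`. Pixels at or above a ceiling of
0.95 (distance bound `−d_p·ln(0.05) ≈ 150 nm` at `d_p = 50`) are reported
as censored at that bound, never extrapolated.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `dp_nm` | 50 | nm | penetration depth; overrides geometry when set |
| `background_fraction` | 0.15 | — | scalar residual-background subtraction |
| `occluder_thickness_nm` | None | nm | exact finite-thickness inversion when set |
| `radius_px` | 20 | px | local-threshold window radius |
| `offset_fraction` | 0.10 | — | threshold offset below the local mean |
| `min_area_um2` | 0.07 | μm² | ROI floor (≈0.3 μm-diameter disk, the lateral resolution limit of the method) |
| `circularity_cut` | 0.85 | — | vesicle/junction shape boundary |
| `mobility_cut_px` | 1.0 | px/frame | vesicle/junction mobility boundary |
| `max_link_distance_px` | 5.0 | px | tracking gate (junctions are nearly immobile) |
| `ceiling` | 0.95 | — | censoring threshold |

The classification cutoffs are package choices: the vesicle/junction
dichotomy (round + mobile vs irregular + immobile) is qualitative in
origin, and the defaults were fixed once from the geometry of the
simulated fixtures (discrete disks of the relevant sizes have measured
circularity ≳ 0.9; Brownian vesicles move ≫ 1 px/frame while centroid
jitter of static sheets is ≪ 1 px/frame).

## Segmentation choices

Normalization uses the 95th percentile of in-cell pixels as the reference
level, computed in two passes (detect minima on a provisional
normalization, then recompute the percentile excluding them) so that
junction pixels never contaminate the reference. On shot-noise-limited
images a high percentile of noisy pixels sits ~1.6 noise-SD above the true
mean, which biases distances slightly downward (≈2 nm at SNR 45); an
explicit reference region avoids this when available.

Minima detection marks pixels below (local circular-window mean −
`offset_fraction`), the standard local-threshold analog of particle-
counting plugins; components use 8-connectivity. Because lateral blur
pushes the threshold crossing *outside* the true footprint, each component
is then refined to its half-depth contour (midway between the local
background and the structure's interior level), which crosses a
symmetrically blurred edge at the true boundary — this is what keeps area
errors at the percent level down to the resolution floor. Intensity
statistics are taken on the component eroded by 2 px (falling back to the
full component for small regions) so blur-brightened edge pixels do not
bias the distance.

## Oscillation detection

Per-track inverted-intensity traces are tested for a dominant periodicity
with Fisher's g-statistic (largest periodogram ordinate over total power),
whose null distribution under white noise is exact; traces failing the
test at α = 0.01 report "no oscillation". The significant peak frequency
is refined by parabolic interpolation of the log-spectrum, so recovered
periods are not limited to the discrete FFT grid. Amplitude is the mean
peak-to-trough excursion over detected cycles — for a sinusoid
`A·sin(ωt)` it reports `2A`.

## The simulator, and what passing tests show

The renderer composes: per-pixel forward model (nearest organelle wins
occlusion) → scaling by `brightness_scale` (the single scalar standing in
for all absolute-intensity factors) → Gaussian PSF blur → Poisson shot
noise → Gaussian read noise → camera offset → 16-bit quantization, in
physical acquisition order, all driven by one seed (bit-identical
replays). Defaults emulate a bright cytosolic reporter on a back-thinned
camera: 100 nm pixels, 100 nm PSF sigma, 5000 expected photons per
unobstructed pixel (shot-noise SNR ≈ 70), offset 100, read noise 2
counts. ER sheets default to 75 nm axial thickness (reproducing the ~15 %
residual background at z ≈ 20 nm); vesicles to 150 nm diameter with
Brownian steps of 1.5 px/frame.

What the simulator does *not* emulate — and therefore what passing tests
do not establish about real data: inhomogeneous fluorophore expression,
realistic ER network morphology (only disks/polygons), interference
fringes and uneven illumination, stage drift, bleaching/blinking, and any
dependence of probe diffusion on gap width. Dynamics parameters (growth
rates, oscillation amplitudes/periods) are illustrative, not calibrated to
measured junction kinetics, since no quantitative values exist for them.

## Problem sizes

Validation fixtures were sized for desk-scale runs: 256×256 px scenes
(25.6 μm fields) with up to 20 objects, 8–64 frames for time-resolved
tests, 512×512 for the noise-statistics check. Accuracy at these sizes is
representative because every estimator is local (windows of ~40 px);
larger fields change counts, not errors.

## Known limitations

- Distances assume a single occluding layer per pixel; stacked organelles
  report the nearest surface plus a mis-modeled background.
- The area refinement assumes an approximately symmetric blurred edge;
  strongly asymmetric PSFs would re-introduce bias.
- Two structures closer than the blur scale merge into one ROI.
- Greedy nearest-centroid tracking has no global assignment step; it is
  adequate for nearly immobile junctions and moderately mobile vesicles
  but will swap identities in dense, fast-moving fields.
- Cell-population statistics (junction counts per cell, overlap
  percentages across cells) require real replicate recordings and are out
  of scope; the package computes the per-image quantities they are built
  from.
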
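# fdmap — fluorescence density mapping for TIRF microscopy

`fdmap` turns TIRF recordings of a freely diffusing cytosolic fluorophore
into nanometer-scale maps of the distance between sub-plasmalemmal
organelles and the plasma membrane. The method targets membrane contact
sites — above all ER-PM junctions, the structures that host STIM1-Orai1
coupling and store-operated Ca²⁺ entry — where the inter-membrane gap
(10–50 nm) is far below the axial resolution of ordinary light microscopy.

## The idea

In TIRF, the evanescent excitation decays as `exp(-z/d_p)` with distance
`z` from the coverslip, where the penetration depth

    d_p = λ₀ / (4π √(n₁² sin²θ − n₂²))

is set by the excitation wavelength λ₀, the incidence angle θ and the
refractive indices of glass (n₁) and specimen (n₂). A homogeneous
cytosolic fluorophore filling this field emits, from a layer of thickness
`z`, the fraction

    I_rel(z) = 1 − exp(−z/d_p)

of the signal of an unobstructed column. A non-fluorescent organelle whose
lower surface sits `z` nm above the membrane therefore appears as a local
intensity *minimum* whose depth encodes its distance:

    z = −d_p · ln(1 − I_rel)

At the working point `d_p ≈ 50 nm`, measured junctional intensities of
52 %, 56 % and 61 % of the organelle-free reference correspond to gaps of
~37, ~41 and ~47 nm. Because the field extends beyond the organelle,
cytosol underneath it contributes a residual background
`exp(−(z+T)/d_p)` (~15 % for a 75 nm-thick ER sheet 20 nm above the
membrane); subtracting it before inversion turns the 56 % level into a
26 nm gap — the known STIM1-Orai1 junction spacing.

## What the package provides

- **`fdmap.optics`** — the closed-form model above: penetration depth,
  forward intensity, exact inversions, residual-background corrections,
  censoring at the detection ceiling.
- **`fdmap.simulate`** — a seeded forward renderer: organelle scenes
  (mobile vesicles, static/growing/oscillating ER sheets) → height maps →
  ideal images → PSF blur → Poisson/read noise → 16-bit frames, plus
  sensitized-emission FRET channel triples. Every downstream stage is
  validated against this ground truth.
- **`fdmap.segment`** — normalization to an organelle-free reference,
  local-threshold minima detection (radius 20 px), ROI labeling with
  calibrated areas and distances, vesicle/junction classification,
  coverage and marker-overlap statistics.
- **`fdmap.fret`** — nFRET bleed-through correction
  (`rawFRET − C_D·I_D − C_A·I_A`), coefficient estimation from
  single-fluorophore controls, and the binned FDM-intensity-vs-nFRET
  relation that locates the gap of maximal donor/acceptor coupling.
- **`fdmap.dynamics`** — junction tracking, per-junction inverted-intensity
  time courses, oscillation metrics (Fisher-g tested spectral peak), and
  3D topology reconstruction of the organelle surface under the membrane.
- **`fdmap.stackio` / `fdmap.config` / `fdmap.pipeline` / CLI** — TIFF
  stack I/O, one YAML config for all stages, and the `fdmap` command with
  `simulate`, `map`, `segment`, `fret`, `track`, `report` subcommands.

## Worked example

```python
import fdmap as f
from fdmap.simulate import Disk

# ground truth: three ER-PM junctions at known gaps (22, 37, 45 nm)
config = f.TIRFConfig(dp_override_nm=50.0)
scene = f.Scene(width=256, height=256, seed=7, primitives=[
    f.er_sheet(Disk(60, 70, 11), z_bottom_nm=22.0),
    f.er_sheet(Disk(150, 90, 9), z_bottom_nm=37.0),
    f.er_sheet(Disk(110, 190, 12), z_bottom_nm=45.0),
])
frame = f.render_frame(scene, config)          # noisy 16-bit camera frame

rel = f.normalize_to_reference(frame, offset=scene.camera_offset)
mask = f.detect_minima(rel, radius_px=20, offset_fraction=0.10)
rois = f.label_rois(mask, rel, dp_nm=50.0, occluder_thickness_nm=75.0)
for roi in rois:
    print(f"junction {roi.label}: area {roi.area_um2:.2f} um^2, "
          f"relative intensity {roi.mean_rel_intensity:.2f}, "
          f"gap {roi.mean_distance_nm:.1f} nm")
```

prints

```
junction 1: area 3.73 um^2, relative intensity 0.49, gap 20.9 nm
junction 2: area 2.51 um^2, relative intensity 0.62, gap 35.2 nm
junction 3: area 4.36 um^2, relative intensity 0.67, gap 42.8 nm
```

Each detected minimum is measured as an ROI: its calibrated area, its mean
intensity relative to the organelle-free reference, and the inverted
inter-membrane gap (here using the exact finite-thickness correction for a
75 nm ER sheet). The recovered gaps sit within ~2 nm of the simulated
truth (22/37/45 nm); the small downward bias comes from the percentile
reference picking up shot noise, see `docs/methods.md`.

The same analysis from the shell:

```
fdmap simulate --scene scene.yaml --frames 10 --out run/
fdmap segment --in run/fdm_stack.tif --out run/analysis/
fdmap report --run run/analysis/
```

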
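"""Shared fixtures: seeded synthetic scenes with known ground truth."""

import numpy as np
import pytest

import fdmap as f
from fdmap.simulate import Disk, PolygonFootprint

DP_NM = 50.0


@pytest.fixture(scope="session")
def dp50():
    return f.TIRFConfig(dp_override_nm=DP_NM)


def junction_scene(k, seed, brightness=5000.0):
    """k well-separated disk-shaped ER-sheet junctions (radius 0.9-1.2 um,
    z 20-45 nm, 75 nm thick) on a 25.6 x 25.6 um field with realistic shot
    and read noise.  Returns (scene, truth) where truth rows are
    (cx, cy, radius_px, z_bottom_nm)."""
    rng = np.random.default_rng(seed)
    cells = [(r, c) for r in range(3) for c in range(4)]
    rng.shuffle(cells)
    prims, truth = [], []
    for (r, c) in cells[:k]:
        cx = 38 + c * 60 + rng.uniform(-6, 6)
        cy = 45 + r * 80 + rng.uniform(-6, 6)
        rad = rng.uniform(9, 12)
        z = rng.uniform(20, 45)
        prims.append(f.er_sheet(Disk(cx, cy, rad), z_bottom_nm=z, thickness_nm=75.0))
        truth.append((cx, cy, rad, z))
    scene = f.Scene(width=256, height=256, primitives=prims,
                    brightness_scale=brightness, seed=seed)
    return scene, truth


def classification_scene(seed=3):
    """10 mobile vesicles interleaved with 10 static elongated ER sheets on a
    grid; returns (scene, true_kinds, positions)."""
    prims, kinds = [], []
    positions = [(28 + c * 50, 33 + r * 64) for r in range(4) for c in range(5)]
    for i, (cx, cy) in enumerate(positions):
        if i % 2 == 0:
            prims.append(f.vesicle(cx, cy, radius_px=5, z_bottom_nm=10,
                                   brownian_sd_px=1.5))
            kinds.append("vesicle")
        else:
            rect = ((cx - 12, cy - 3), (cx + 12, cy - 3),
                    (cx + 12, cy + 3), (cx - 12, cy + 3))
            prims.append(f.er_sheet(PolygonFootprint(rect), z_bottom_nm=30))
            kinds.append("junction")
    scene = f.Scene(width=256, height=256, primitives=prims, seed=seed)
    return scene, kinds, positions


def ramp_scene(width=128, z_start=10.0, z_stop=80.0, thickness=4000.0,
               noiseless=True, seed=0):
    """A rectangular sheet with a linear depth ramp along x."""
    rect = ((20, 30), (width - 20, 30), (width - 20, width - 30), (20, width - 30))
    prim = f.er_sheet(PolygonFootprint(rect), z_ramp=("x", z_start, z_stop),
                      thickness_nm=thickness)
    return f.Scene(width=width, height=width, primitives=[prim],
                   shot_noise=not noiseless,
                   read_noise_sd=0.0 if noiseless else 2.0,
                   psf_sigma_nm=0.0 if noiseless else 100.0,
                   brightness_scale=20000.0, seed=seed)


def segment_frames(stack, scene, occluder_thickness_nm=75.0):
    """Normalize + detect + label each frame of a rendered stack."""
    roi_lists = []
    for fr in range(stack.shape[0]):
        rel = f.normalize_to_reference(stack[fr], offset=scene.camera_offset,
                                       pixel_size_nm=scene.pixel_size_nm)
        mask = f.detect_minima(rel)
        roi_lists.append(f.label_rois(mask, rel,
                                      occluder_thickness_nm=occluder_thickness_nm,
                                      frame=fr))
    return roi_lists
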
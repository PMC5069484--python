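"""Forward renderer for synthetic TIRF footprint recordings.

Builds ground-truth scenes of sub-plasmalemmal organelles (mobile spherical
vesicles, static endoplasmic-reticulum sheets), converts them to per-pixel
height maps (distance of the organelle's lower surface from the plasma
membrane plus its axial extent), evaluates the evanescent-field forward model
from :mod:`fdmap.optics`, and applies a camera model: Gaussian lateral blur,
Poisson shot noise, Gaussian read noise, offset, and 16-bit quantization.

Every stochastic element is driven by the scene seed, so renders are
bit-identical across runs.  The simulator is the fixture generator for the
whole analysis pipeline: segmentation, FRET correction, tracking and
topology reconstruction are all validated against its ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import polygon2mask

from . import optics

__all__ = [
    "Disk",
    "PolygonFootprint",
    "OrganellePrimitive",
    "vesicle",
    "er_sheet",
    "Scene",
    "HeightMap",
    "FretChannelSet",
    "height_map",
    "ideal_relative_image",
    "render_frame",
    "render_timeseries",
    "default_fret_efficiency",
    "render_fret_channels",
    "save_scene",
    "load_scene",
]

# Defaults reflect typical geometry of the structures being emulated:
# junctional ER sheets are thin cisternae (~75 nm across both membranes and
# lumen, which also reproduces the ~15 % residual background at z ~ 20 nm),
# sub-plasmalemmal vesicles are 100-200 nm spheres.
DEFAULT_SHEET_THICKNESS_NM = 75.0
DEFAULT_VESICLE_DIAMETER_NM = 150.0


@dataclass(frozen=True)
class Disk:
    """Circular footprint (pixel units, pixel-center convention)."""

    cx: float
    cy: float
    radius_px: float

    def mask(self, shape, dx: float = 0.0, dy: float = 0.0, grow: float = 0.0):
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        r = max(self.radius_px + grow, 0.0)
        return (xx - (self.cx + dx)) ** 2 + (yy - (self.cy + dy)) ** 2 <= r * r

    def bounds(self):
        r = self.radius_px
        return (self.cx - r, self.cy - r, self.cx + r, self.cy + r)


@dataclass(frozen=True)
class PolygonFootprint:
    """Polygonal footprint given as ((x, y), ...) vertices in pixels."""

    vertices: tuple

    def mask(self, shape, dx: float = 0.0, dy: float = 0.0, grow: float = 0.0):
        pts = np.asarray(self.vertices, dtype=float)
        cx, cy = pts.mean(axis=0)
        # Lateral growth scales the outline about its centroid by `grow`
        # pixels of effective radius; mirrors junction extension.
        if grow:
            r_eff = max(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).mean(), 1e-9)
            s = max((r_eff + grow) / r_eff, 0.0)
            pts = np.column_stack([cx + s * (pts[:, 0] - cx), cy + s * (pts[:, 1] - cy)])
        rc = np.column_stack([pts[:, 1] + dy, pts[:, 0] + dx])  # (row, col)
        return polygon2mask(shape, rc)

    def bounds(self):
        pts = np.asarray(self.vertices, dtype=float)
        return (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())


@dataclass(frozen=True)
class OrganellePrimitive:
    """One ground-truth organelle.

    ``kind`` mirrors the two structure classes seen in FDM recordings:
    ``"vesicle"`` (circular footprint, Brownian lateral motion) and
    ``"er_sheet"`` (disk or polygon footprint, immobile, optionally growing
    laterally and oscillating axially).

    ``z_bottom_nm`` is the distance of the lower organelle surface from the
    plasma membrane; ``thickness_nm`` the axial extent.  ``z_ramp`` imposes a
    linear depth gradient ``(axis, z_start, z_stop)`` across the footprint
    bounding box (used for topology-reconstruction truth).  ``z_oscillation``
    is ``(amplitude_nm, period_frames, phase_rad)`` added to ``z_bottom_nm``
    per frame.
    """

    kind: str
    footprint: Disk | PolygonFootprint
    z_bottom_nm: float = 30.0
    thickness_nm: float = DEFAULT_SHEET_THICKNESS_NM
    z_ramp: tuple | None = None
    brownian_sd_px: float = 0.0
    z_oscillation: tuple | None = None
    growth_px_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("vesicle", "er_sheet"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.z_bottom_nm < 0 or self.thickness_nm < 0:
            raise ValueError("z_bottom_nm and thickness_nm must be non-negative")
        if self.kind == "vesicle" and not isinstance(self.footprint, Disk):
            raise ValueError("vesicles must have circular footprints")

    def z_at_frame(self, frame: int) -> float:
        z = self.z_bottom_nm
        if self.z_oscillation is not None:
            amp, period, phase = self.z_oscillation
            z = z + amp * np.sin(2.0 * np.pi * frame / period + phase)
        return max(z, 0.0)


def vesicle(cx, cy, radius_px, z_bottom_nm=10.0,
            thickness_nm=DEFAULT_VESICLE_DIAMETER_NM, brownian_sd_px=1.5):
    """Mobile spherical vesicle primitive (circular footprint)."""
    return OrganellePrimitive(
        kind="vesicle", footprint=Disk(cx, cy, radius_px),
        z_bottom_nm=z_bottom_nm, thickness_nm=thickness_nm,
        brownian_sd_px=brownian_sd_px,
    )


def er_sheet(footprint, z_bottom_nm=30.0, thickness_nm=DEFAULT_SHEET_THICKNESS_NM,
             z_ramp=None, z_oscillation=None, growth_px_per_frame=0.0):
    """Immobile ER-sheet primitive (disk or polygon footprint)."""
    return OrganellePrimitive(
        kind="er_sheet", footprint=footprint, z_bottom_nm=z_bottom_nm,
        thickness_nm=thickness_nm, z_ramp=z_ramp, z_oscillation=z_oscillation,
        growth_px_per_frame=growth_px_per_frame,
    )


@dataclass
class Scene:
    """Ground-truth description of one synthetic recording.

    ``brightness_scale`` is the expected photon count of an unobstructed
    in-cell pixel; it lumps together all absolute-intensity factors of the
    forward model (excitation intensity, fluorophore concentration,
    collection efficiency, d_p) that are unknown in a real experiment and
    cancel in the relative-intensity analysis.
    """

    width: int
    height: int
    pixel_size_nm: float = 100.0
    primitives: list = field(default_factory=list)
    brightness_scale: float = 5000.0
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    psf_sigma_nm: float = 100.0
    shot_noise: bool = True
    cell_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brightness_scale <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("brightness_scale and pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")
        for p in self.primitives:
            x0, y0, x1, y1 = p.footprint.bounds()
            if x0 < 0 or y0 < 0 or x1 > self.width - 1 or y1 > self.height - 1:
                raise ValueError("primitive footprint outside image bounds")

    @property
    def shape(self):
        return (self.height, self.width)

    def mask(self) -> np.ndarray:
        if self.cell_mask is None:
            return np.ones(self.shape, dtype=bool)
        return np.asarray(self.cell_mask, dtype=bool)

    def displacement(self, index: int, frame: int):
        """Cumulative Brownian displacement of primitive ``index`` at ``frame``."""
        prim = self.primitives[index]
        if prim.brownian_sd_px == 0.0 or frame == 0:
            return 0.0, 0.0
        rng = np.random.default_rng([self.seed, 101, index])
        steps = rng.normal(0.0, prim.brownian_sd_px, size=(frame, 2))
        dx, dy = steps.sum(axis=0)
        return float(dx), float(dy)


@dataclass
class HeightMap:
    """Per-pixel ground truth: ``z_bottom_nm`` is +inf where no organelle is
    present; ``thickness_nm`` is 0 there.  Overlaps are resolved by taking
    the organelle nearest the membrane."""

    z_bottom_nm: np.ndarray
    thickness_nm: np.ndarray


def _primitive_z_field(prim: OrganellePrimitive, fmask: np.ndarray, frame: int):
    """Depth of the primitive per footprint pixel (ramp or constant)."""
    z0 = prim.z_at_frame(frame)
    if prim.z_ramp is None:
        return np.full(int(fmask.sum()), z0)
    axis, z_start, z_stop = prim.z_ramp
    rows, cols = np.nonzero(fmask)
    coord = cols if axis == "x" else rows
    lo, hi = coord.min(), coord.max()
    frac = (coord - lo) / max(hi - lo, 1)
    return z_start + (z_stop - z_start) * frac


def height_map(scene: Scene, frame: int = 0) -> HeightMap:
    """Rasterize the scene at ``frame`` into a :class:`HeightMap`."""
    z = np.full(scene.shape, np.inf)
    t = np.zeros(scene.shape)
    for i, prim in enumerate(scene.primitives):
        dx, dy = scene.displacement(i, frame)
        grow = prim.growth_px_per_frame * frame
        fmask = prim.footprint.mask(scene.shape, dx=dx, dy=dy, grow=grow)
        if not fmask.any():
            continue
        zvals = np.clip(_primitive_z_field(prim, fmask, frame), 0.0, None)
        rows, cols = np.nonzero(fmask)
        closer = zvals < z[rows, cols]
        z[rows[closer], cols[closer]] = zvals[closer]
        t[rows[closer], cols[closer]] = prim.thickness_nm
    return HeightMap(z_bottom_nm=z, thickness_nm=t)


def ideal_relative_image(scene: Scene, config: optics.TIRFConfig,
                         frame: int = 0) -> np.ndarray:
    """Noiseless, unblurred relative-intensity image of the scene.

    1.0 at unobstructed in-cell pixels, the occluder forward model over
    organelles, 0 outside the cell footprint.
    """
    dp = config.dp_nm
    hm = height_map(scene, frame)
    rel = np.ones(scene.shape)
    occ = np.isfinite(hm.z_bottom_nm)
    if occ.any():
        rel[occ] = optics.relative_intensity_with_occluder(
            hm.z_bottom_nm[occ], hm.thickness_nm[occ], dp
        )
    rel[~scene.mask()] = 0.0
    return rel


def _camera(photons: np.ndarray, scene: Scene, rng) -> np.ndarray:
    """Blur -> shot noise -> read noise -> offset -> clip/quantize (uint16)."""
    sigma_px = scene.psf_sigma_nm / scene.pixel_size_nm
    if sigma_px > 0:
        photons = ndimage.gaussian_filter(photons, sigma_px)
    if photons.max() + scene.camera_offset > 65535:
        warnings.warn("brightness_scale saturates the 16-bit range", stacklevel=3)
    img = rng.poisson(np.clip(photons, 0, None)).astype(float) if scene.shot_noise \
        else photons.copy()
    if scene.read_noise_sd > 0:
        img += rng.normal(0.0, scene.read_noise_sd, size=img.shape)
    img += scene.camera_offset
    return np.rint(np.clip(img, 0, 65535)).astype(np.uint16)


def render_frame(scene: Scene, config: optics.TIRFConfig, frame: int = 0) -> np.ndarray:
    """Render one camera frame (uint16 counts) of the cytosolic FDM reporter."""
    rel = ideal_relative_image(scene, config, frame)
    photons = rel * scene.brightness_scale
    rng = np.random.default_rng([scene.seed, 7, frame])
    return _camera(photons, scene, rng)


def render_timeseries(scene: Scene, config: optics.TIRFConfig,
                      n_frames: int) -> np.ndarray:
    """Render ``n_frames`` consecutive frames as a (T, H, W) uint16 stack."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return np.stack([render_frame(scene, config, f) for f in range(n_frames)])


def default_fret_efficiency(gap_nm):
    """Default gap -> FRET-efficiency curve: a peak at a 26 nm inter-membrane
    gap with 15 nm width, falling off at both smaller and larger gaps
    (imperfect bridging at very short distances, loss of coupling beyond the
    tether reach)."""
    gap_nm = np.asarray(gap_nm, dtype=float)
    out = np.exp(-((gap_nm - 26.0) ** 2) / (2.0 * 15.0 ** 2))
    return out.item() if out.ndim == 0 else out


@dataclass
class FretChannelSet:
    """Rendered sensitized-emission channel triple plus the noiseless truth."""

    donor: np.ndarray
    acceptor: np.ndarray
    raw_fret: np.ndarray
    true_fret_ideal: np.ndarray


def render_fret_channels(scene: Scene, config: optics.TIRFConfig, bleed,
                         efficiency_curve=None, frame: int = 0,
                         include_donor: bool = True, include_acceptor: bool = True,
                         acceptor_scale: float | None = None,
                         fret_scale: float | None = None) -> FretChannelSet:
    """Render co-registered donor / acceptor / rawFRET frames.

    The donor channel is the cytosolic FDM reporter; the acceptor channel is
    a junction-resident marker (uniform over organelle footprints).  The raw
    FRET channel is built by inverting the sensitized-emission correction:
    ``rawFRET = true_signal + c_donor*donor + c_acceptor*acceptor`` where the
    true signal lives only on organelle pixels, scaled by
    ``efficiency_curve(z_bottom)``.  Setting ``include_donor=False`` (or
    ``include_acceptor=False``) emulates the single-fluorophore control
    recordings used to estimate bleed-through.
    """
    if efficiency_curve is None:
        efficiency_curve = default_fret_efficiency
    if not (0 <= bleed.c_donor < 1 and 0 <= bleed.c_acceptor < 1):
        raise ValueError("bleed-through coefficients must lie in [0, 1)")
    acceptor_scale = scene.brightness_scale if acceptor_scale is None else acceptor_scale
    fret_scale = 0.5 * scene.brightness_scale if fret_scale is None else fret_scale

    cell = scene.mask()
    hm = height_map(scene, frame)
    occ = np.isfinite(hm.z_bottom_nm) & cell

    donor_ideal = np.zeros(scene.shape)
    if include_donor:
        donor_ideal = ideal_relative_image(scene, config, frame) * scene.brightness_scale
    acceptor_ideal = np.zeros(scene.shape)
    if include_acceptor:
        acceptor_ideal[occ] = acceptor_scale
    true_ideal = np.zeros(scene.shape)
    if include_donor and include_acceptor and occ.any():
        true_ideal[occ] = fret_scale * np.asarray(
            efficiency_curve(hm.z_bottom_nm[occ]), dtype=float
        )
    raw_ideal = true_ideal + bleed.c_donor * donor_ideal + bleed.c_acceptor * acceptor_ideal

    channels = []
    for tag, ideal in ((11, donor_ideal), (12, acceptor_ideal), (13, raw_ideal)):
        rng = np.random.default_rng([scene.seed, tag, frame])
        channels.append(_camera(ideal, scene, rng))
    return FretChannelSet(donor=channels[0], acceptor=channels[1],
                          raw_fret=channels[2], true_fret_ideal=true_ideal)


# ---------------------------------------------------------------------------
# Plain-text scene serialization (YAML)

def _footprint_to_dict(fp):
    if isinstance(fp, Disk):
        return {"disk": [float(fp.cx), float(fp.cy), float(fp.radius_px)]}
    return {"polygon": [[float(x), float(y)] for x, y in fp.vertices]}


def _footprint_from_dict(d):
    if "disk" in d:
        cx, cy, r = d["disk"]
        return Disk(cx, cy, r)
    if "polygon" in d:
        return PolygonFootprint(tuple((float(x), float(y)) for x, y in d["polygon"]))
    raise ValueError("footprint needs a 'disk' or 'polygon' entry")


def save_scene(scene: Scene, path) -> None:
    """Write a scene to a plain-text (YAML) file.  Array cell masks are not
    serialized; use rectangular masks or supply the mask at load time."""
    doc = {
        "width": scene.width, "height": scene.height,
        "pixel_size_nm": scene.pixel_size_nm,
        "brightness_scale": scene.brightness_scale,
        "camera_offset": scene.camera_offset,
        "read_noise_sd": scene.read_noise_sd,
        "psf_sigma_nm": scene.psf_sigma_nm,
        "shot_noise": scene.shot_noise,
        "seed": scene.seed,
        "primitives": [],
    }
    for p in scene.primitives:
        entry = {
            "kind": p.kind, **_footprint_to_dict(p.footprint),
            "z_bottom_nm": float(p.z_bottom_nm),
            "thickness_nm": float(p.thickness_nm),
        }
        if p.z_ramp is not None:
            entry["z_ramp"] = [p.z_ramp[0], float(p.z_ramp[1]), float(p.z_ramp[2])]
        if p.brownian_sd_px:
            entry["brownian_sd_px"] = float(p.brownian_sd_px)
        if p.z_oscillation is not None:
            entry["z_oscillation"] = [float(v) for v in p.z_oscillation]
        if p.growth_px_per_frame:
            entry["growth_px_per_frame"] = float(p.growth_px_per_frame)
        doc["primitives"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_SCENE_KEYS = {"width", "height", "pixel_size_nm", "brightness_scale",
               "camera_offset", "read_noise_sd", "psf_sigma_nm", "shot_noise",
               "seed", "primitives"}
_PRIM_KEYS = {"kind", "disk", "polygon", "z_bottom_nm", "thickness_nm", "z_ramp",
              "brownian_sd_px", "z_oscillation", "growth_px_per_frame"}


def load_scene(path, cell_mask: np.ndarray | None = None) -> Scene:
    """Load a scene from a plain-text (YAML) file written by :func:`save_scene`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    unknown = set(doc) - _SCENE_KEYS
    if unknown:
        raise ValueError(f"unknown scene keys: {sorted(unknown)}")
    prims = []
    for entry in doc.get("primitives", []):
        unknown = set(entry) - _PRIM_KEYS
        if unknown:
            raise ValueError(f"unknown primitive keys: {sorted(unknown)}")
        z_ramp = entry.get("z_ramp")
        if z_ramp is not None:
            z_ramp = (z_ramp[0], float(z_ramp[1]), float(z_ramp[2]))
        z_osc = entry.get("z_oscillation")
        if z_osc is not None:
            z_osc = tuple(float(v) for v in z_osc)
        prims.append(OrganellePrimitive(
            kind=entry["kind"], footprint=_footprint_from_dict(entry),
            z_bottom_nm=float(entry.get("z_bottom_nm", 30.0)),
            thickness_nm=float(entry.get("thickness_nm", DEFAULT_SHEET_THICKNESS_NM)),
            z_ramp=z_ramp,
            brownian_sd_px=float(entry.get("brownian_sd_px", 0.0)),
            z_oscillation=z_osc,
            growth_px_per_frame=float(entry.get("growth_px_per_frame", 0.0)),
        ))
    kwargs = {k: doc[k] for k in doc if k not in ("primitives",)}
    return Scene(primitives=prims, cell_mask=cell_mask, **kwargs)
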
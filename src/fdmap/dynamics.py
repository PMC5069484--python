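"""Time-resolved junction analysis and 3D topology reconstruction.

Junctions are linked across frames by greedy nearest-centroid matching
(junctional ER is essentially immobile, so linking is unambiguous at
moderate frame rates).  Per-track time courses of inverted mean intensity
(1 - relative intensity, larger = organelle closer/denser) expose the
vertical oscillations of the inter-membrane gap; a spectral estimator
extracts their dominant period and peak-to-trough amplitude.  Finally, the
per-pixel inversion of the relative-intensity image yields a height map of
the organelle surface under the membrane -- a 3D topology of the contact
landscape -- with unstable pixels (relative intensity at the detection
ceiling) censored at the ceiling bound instead of extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from . import optics
from .segment import JunctionROI, RelativeIntensityImage

__all__ = [
    "JunctionTrack",
    "TopologyMap",
    "OscillationMetrics",
    "track_junctions",
    "junction_timecourse",
    "oscillation_metrics",
    "reconstruct_topology",
]


@dataclass
class JunctionTrack:
    """A junction (or vesicle) followed across frames: at most one ROI per
    frame, frames strictly increasing."""

    track_id: int
    frames: list = field(default_factory=list)
    rois: list = field(default_factory=list)

    def append(self, frame: int, roi: JunctionROI) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("track frames must be strictly increasing")
        self.frames.append(frame)
        self.rois.append(roi)
        roi.track_id = self.track_id

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mean_displacement_px(self) -> float | None:
        """Mean frame-to-frame centroid displacement; None for single-ROI
        tracks (mobility unknown)."""
        if len(self.rois) < 2:
            return None
        c = np.array([r.centroid for r in self.rois])
        steps = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
        return float(steps.mean())

    def timecourse(self) -> np.ndarray:
        """Inverted mean intensity per frame (1 - mean relative intensity)."""
        return np.array([1.0 - r.mean_rel_intensity for r in self.rois])

    def distance_course(self) -> np.ndarray:
        return np.array([r.mean_distance_nm for r in self.rois])

    def area_course(self) -> np.ndarray:
        return np.array([r.area_um2 for r in self.rois])


def track_junctions(roi_lists, max_link_distance_px: float = 5.0) -> list[JunctionTrack]:
    """Link per-frame ROI lists into tracks by greedy nearest-centroid matching.

    Candidate links between consecutive frames are sorted by centroid
    distance (ties broken by smaller area difference) and accepted greedily;
    links longer than ``max_link_distance_px`` are rejected and start new
    tracks.  Every ROI ends up in exactly one track.
    """
    tracks: list[JunctionTrack] = []
    open_tracks: list[JunctionTrack] = []  # tracks whose last ROI is in frame f-1
    for f, rois in enumerate(roi_lists):
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.rois[-1]
            for ri, roi in enumerate(rois):
                d = float(np.hypot(roi.centroid[0] - last.centroid[0],
                                   roi.centroid[1] - last.centroid[1]))
                if d <= max_link_distance_px:
                    candidates.append((d, abs(roi.area_um2 - last.area_um2), ti, ri))
        candidates.sort()
        used_t, used_r = set(), set()
        links = {}
        for d, _, ti, ri in candidates:
            if ti in used_t or ri in used_r:
                continue
            used_t.add(ti)
            used_r.add(ri)
            links[ri] = ti
        next_open = []
        for ri, roi in enumerate(rois):
            if ri in links:
                tr = open_tracks[links[ri]]
            else:
                tr = JunctionTrack(track_id=len(tracks))
                tracks.append(tr)
            tr.append(f, roi)
            next_open.append(tr)
        open_tracks = next_open
    return tracks


def junction_timecourse(rel_seq, track: JunctionTrack) -> np.ndarray:
    """Inverted mean in-ROI intensity per track frame, measured on the images.

    ``rel_seq`` is a sequence of :class:`RelativeIntensityImage` (or a 3D
    array of relative values) indexed by frame.  Frames absent from the
    track simply do not appear -- gaps are not interpolated.
    """
    out = np.empty(track.n_frames)
    for i, (f, roi) in enumerate(zip(track.frames, track.rois)):
        img = rel_seq[f]
        values = img.values if isinstance(img, RelativeIntensityImage) else np.asarray(img)
        out[i] = 1.0 - float(values[roi.coords[:, 0], roi.coords[:, 1]].mean())
    return out


@dataclass(frozen=True)
class OscillationMetrics:
    """Peak-to-trough amplitude, dominant period and cycle count of a trace."""

    amplitude: float
    period_s: float
    n_cycles: int


def oscillation_metrics(timecourse, frame_interval_s: float = 1.0,
                        alpha: float = 0.01) -> OscillationMetrics | None:
    """Detect and quantify a dominant oscillation in a short trace.

    The mean-subtracted trace is Fourier-transformed and the dominant
    frequency bin is tested for significance with Fisher's g-test (the
    fraction of total periodogram power in the largest bin, whose null
    distribution under white noise is known exactly).  Traces whose peak is
    not distinguishable from a flat/noisy one at level ``alpha`` return
    ``None``.  The period is refined by parabolic interpolation of the
    log-spectrum around the peak, so it is not limited to the discrete
    frequency grid.  Amplitude is the mean peak-to-trough excursion over
    detected cycles.
    """
    tc = np.asarray(timecourse, dtype=float)
    n = tc.size
    if n < 8:
        raise ValueError("oscillation analysis needs at least 8 frames")
    x = tc - tc.mean()
    if np.allclose(x, 0.0):
        return None
    power = np.abs(np.fft.rfft(x)) ** 2
    power = power[1:]  # drop DC
    k = int(np.argmax(power))
    # Fisher's g-test: P(g > g_obs) ~ m * (1 - g_obs)^(m-1) for m bins.
    g = power[k] / power.sum()
    m = power.size
    p_value = min(1.0, m * (1.0 - g) ** (m - 1))
    if p_value > alpha:
        return None

    # Parabolic interpolation on the log-spectrum for sub-bin frequency.
    kk = k + 1  # index into the rfft grid
    freq = kk / (n * frame_interval_s)
    if 1 <= k < power.size - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = np.log(power[k - 1]), np.log(power[k]), np.log(power[k + 1])
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = 0.5 * (la - lc) / denom
            freq = (kk + float(np.clip(delta, -0.5, 0.5))) / (n * frame_interval_s)
    period_s = 1.0 / freq

    period_frames = period_s / frame_interval_s
    dist = max(int(round(0.6 * period_frames)), 1)
    peaks, _ = find_peaks(x, distance=dist)
    troughs, _ = find_peaks(-x, distance=dist)
    if peaks.size and troughs.size:
        amplitude = float(x[peaks].mean() - x[troughs].mean())
        n_cycles = int(min(peaks.size, troughs.size))
    else:
        amplitude = float(x.max() - x.min())
        n_cycles = int(n * frame_interval_s / period_s)
    return OscillationMetrics(amplitude=amplitude, period_s=float(period_s),
                              n_cycles=n_cycles)


@dataclass
class TopologyMap:
    """Per-pixel organelle-membrane distance (nm).

    ``z_nm`` is NaN outside the cell footprint; censored pixels (relative
    intensity at or above the detection ceiling -- no resolvable structure)
    carry the ceiling bound, not a point estimate.  Smaller z = closer to
    the plasma membrane.
    """

    z_nm: np.ndarray
    censored: np.ndarray
    ceiling_nm: float


def reconstruct_topology(rel: RelativeIntensityImage, dp_nm: float = 50.0,
                         background: float = 0.0, ceiling: float = optics.DETECTION_CEILING,
                         occluder_thickness_nm: float | None = None) -> TopologyMap:
    """Invert a relative-intensity image into a sub-membrane height map.

    Each in-cell pixel's background-corrected intensity is inverted to a
    distance; ``background`` may be a scalar or a per-pixel array.  When
    ``occluder_thickness_nm`` is given the exact finite-occluder inversion
    is used instead of subtraction.  Pixels whose corrected intensity
    reaches ``ceiling`` are censored at ``-dp*ln(1-ceiling)``; corrected
    intensities below zero (over-correction by noise) clamp to distance 0.
    """
    values, mask = rel.values, rel.cell_mask
    if occluder_thickness_nm is not None:
        scale = -np.expm1(-occluder_thickness_nm / dp_nm)
        if scale <= 0:
            raise ValueError("occluder thickness must be positive")
        corrected = 1.0 - (1.0 - values) / scale
    else:
        corrected = values - np.asarray(background, dtype=float)
    corrected = np.clip(corrected, 0.0, None)
    censored = mask & (corrected >= ceiling)
    ceiling_nm = optics.detection_ceiling_distance(dp_nm, ceiling)
    z = np.full(values.shape, np.nan)
    ok = mask & ~censored
    z[ok] = -dp_nm * np.log1p(-corrected[ok])
    z[censored] = ceiling_nm
    return TopologyMap(z_nm=z, censored=censored, ceiling_nm=float(ceiling_nm))
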
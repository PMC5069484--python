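"""Sensitized-emission FRET correction and the FDM-FRET relation.

Raw sensitized-emission FRET images contain spectral bleed-through from both
the donor and the acceptor channel.  The net signal is

    nFRET = rawFRET - c_donor * I_donor - c_acceptor * I_acceptor

with coefficients determined from single-fluorophore control recordings.
Combining the corrected FRET image with the FDM relative-intensity image of
the same cell yields the FRET-versus-distance relation: binning nFRET by
FDM intensity locates the inter-membrane gap at which the donor/acceptor
pair couples most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import optics
from .segment import RelativeIntensityImage

__all__ = [
    "BleedThrough",
    "nfret",
    "bleedthrough_coefficient",
    "estimate_bleedthrough",
    "FdmFretRelation",
    "fdm_fret_relation",
]


@dataclass(frozen=True)
class BleedThrough:
    """Spectral crosstalk coefficients into the FRET channel."""

    c_donor: float
    c_acceptor: float

    def __post_init__(self) -> None:
        if not (0 <= self.c_donor < 1 and 0 <= self.c_acceptor < 1):
            raise ValueError("bleed-through coefficients must lie in [0, 1)")


def nfret(raw_fret, donor, acceptor, bleed: BleedThrough) -> np.ndarray:
    """Pixelwise net FRET: rawFRET - c_donor*donor - c_acceptor*acceptor.

    Inputs must be co-registered, offset-subtracted images of equal shape.
    Negative pixels are retained (clipping them would bias region means).
    """
    raw_fret = np.asarray(raw_fret, dtype=float)
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if not (raw_fret.shape == donor.shape == acceptor.shape):
        raise ValueError("channel images must have identical shapes")
    return raw_fret - bleed.c_donor * donor - bleed.c_acceptor * acceptor


def bleedthrough_coefficient(pairs, floor: float = 10.0,
                             min_pixels: int = 100) -> float:
    """Crosstalk coefficient of one fluorophore from control recordings.

    ``pairs`` is a list of ``(expression_image, fret_image)`` tuples from
    cells expressing only that fluorophore (offset-subtracted counts).  The
    coefficient is the slope of a least-squares fit *through the origin* of
    FRET-channel versus expression-channel pixel intensities, using pixels
    whose expression intensity exceeds ``floor``: crosstalk is proportional
    by construction, so no intercept is fitted.
    """
    xs, ys = [], []
    for expr, fr in pairs:
        expr = np.asarray(expr, dtype=float).ravel()
        fr = np.asarray(fr, dtype=float).ravel()
        sel = expr > floor
        xs.append(expr[sel])
        ys.append(fr[sel])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if x.size < min_pixels:
        raise ValueError(
            f"unreliable bleed-through estimate: only {x.size} pixels above floor"
        )
    return float(np.dot(x, y) / np.dot(x, x))


def estimate_bleedthrough(donor_pairs, acceptor_pairs, floor: float = 10.0,
                          min_pixels: int = 100) -> BleedThrough:
    """Estimate both coefficients from donor-only and acceptor-only controls."""
    return BleedThrough(
        c_donor=bleedthrough_coefficient(donor_pairs, floor, min_pixels),
        c_acceptor=bleedthrough_coefficient(acceptor_pairs, floor, min_pixels),
    )


@dataclass
class FdmFretRelation:
    """Binned nFRET-versus-FDM-intensity curve.

    ``table`` columns: bin_center, mean_nfret, sem, n_pixels, distance_nm.
    ``peak_fdm_intensity`` / ``peak_distance_nm`` locate the occupied bin
    with maximal mean nFRET.
    """

    table: pd.DataFrame
    peak_fdm_intensity: float
    peak_distance_nm: float


def fdm_fret_relation(rel: RelativeIntensityImage, nfret_img, mask=None,
                      n_bins: int = 20, dp_nm: float = 50.0,
                      background: float = 0.0) -> FdmFretRelation:
    """Bin nFRET pixel values by FDM relative intensity.

    Pixels inside ``mask`` (default: the cell mask) are grouped into
    ``n_bins`` equal-width bins over FDM intensity [0, 1]; per-bin mean and
    standard error of nFRET are reported.  Empty bins carry NaN, not zero.
    Each bin center is also converted to a background-corrected distance so
    the curve can be read on the nanometer axis.
    """
    nfret_img = np.asarray(nfret_img, dtype=float)
    if nfret_img.shape != rel.shape:
        raise ValueError("nFRET image shape does not match the FDM image")
    sel = rel.cell_mask if mask is None else (np.asarray(mask, bool) & rel.cell_mask)
    i = rel.values[sel].ravel()
    f = nfret_img[sel].ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(i, edges) - 1, 0, n_bins - 1)
    inside = (i >= 0) & (i <= 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        v = f[inside & (idx == b)]
        count[b] = v.size
        if v.size:
            mean[b] = v.mean()
            sem[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    dist = np.full(n_bins, np.nan)
    ok = np.clip(centers - background, 0.0, None) < 1.0
    dist[ok] = -dp_nm * np.log1p(-np.clip(centers[ok] - background, 0.0, None))
    table = pd.DataFrame({
        "bin_center": centers, "mean_nfret": mean, "sem": sem,
        "n_pixels": count, "distance_nm": dist,
    })
    occupied = count > 0
    if not occupied.any():
        raise ValueError("no pixels fell into the FDM intensity range [0, 1]")
    peak_bin = int(np.nanargmax(np.where(occupied, mean, -np.inf)))
    return FdmFretRelation(
        table=table,
        peak_fdm_intensity=float(centers[peak_bin]),
        peak_distance_nm=float(dist[peak_bin]),
    )
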
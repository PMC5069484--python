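"""Closed-form evanescent-field model for TIRF distance estimation.

In objective-type TIRF the excitation light is totally reflected at the
glass/specimen interface and an evanescent field decays exponentially into
the sample.  A homogeneously distributed cytosolic fluorophore then emits a
signal that depends only on how much of the excited layer is filled with
fluorophore: a non-fluorescent organelle whose lower surface sits ``z``
nanometers above the plasma membrane displaces fluorophore and reduces the
local intensity to a fraction

    I_rel(z) = 1 - exp(-z / d_p)

of the intensity at an organelle-free reference position, where ``d_p`` is
the penetration depth of the evanescent wave.  Inverting this relation maps
a measured relative intensity to an organelle-membrane distance:

    z = -d_p * ln(1 - I_rel)

Because the field extends beyond the organelle, cytosol *underneath* a
structure of finite axial extent still contributes a residual background
``exp(-(z + T)/d_p)`` which, if uncorrected, biases distances upward.  This
module provides the forward model, its exact inverses (with and without
background correction), and the penetration-depth geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DETECTION_CEILING",
    "SubCriticalAngleError",
    "TIRFConfig",
    "penetration_depth",
    "excitation_at_depth",
    "relative_layer_intensity",
    "distance_from_relative_intensity",
    "background_corrected_distance",
    "residual_background_fraction",
    "occluded_fraction",
    "relative_intensity_with_occluder",
    "distance_from_intensity_with_occluder",
    "detection_ceiling_distance",
]

#: Relative intensities at or above this value are treated as "no resolvable
#: structure": the inversion -d_p*ln(1-I) diverges as I -> 1, so estimates are
#: censored at the corresponding ceiling distance instead of extrapolated.
DETECTION_CEILING = 0.95


class SubCriticalAngleError(ValueError):
    """Raised when n1*sin(theta) <= n2 and no evanescent field exists."""


@dataclass(frozen=True)
class TIRFConfig:
    """Optical geometry of a TIRF setup.

    Either the full geometry (``lambda0_nm``, ``theta_deg``, ``n1``, ``n2``)
    or a direct penetration depth ``dp_override_nm`` must be supplied.  When
    both are present the override wins: microscope calibrations usually state
    d_p directly while the exact incidence angle is unknown.

    Parameters
    ----------
    lambda0_nm : float, optional
        Vacuum wavelength of the excitation laser (nm).
    theta_deg : float, optional
        Incidence angle to the interface normal (degrees).
    n1, n2 : float, optional
        Refractive indices of the glass and the specimen; total internal
        reflection requires ``n1*sin(theta) > n2``.
    dp_override_nm : float, optional
        Penetration depth (nm) used directly, bypassing the geometry.
    """

    lambda0_nm: float | None = None
    theta_deg: float | None = None
    n1: float | None = None
    n2: float | None = None
    dp_override_nm: float | None = None

    def __post_init__(self) -> None:
        if self.dp_override_nm is not None:
            if not (math.isfinite(self.dp_override_nm) and self.dp_override_nm > 0):
                raise ValueError("dp_override_nm must be positive and finite")
            return
        geom = (self.lambda0_nm, self.theta_deg, self.n1, self.n2)
        if any(v is None for v in geom):
            raise ValueError(
                "TIRFConfig needs either dp_override_nm or the full geometry "
                "(lambda0_nm, theta_deg, n1, n2)"
            )
        if self.lambda0_nm <= 0:
            raise ValueError("lambda0_nm must be positive")
        if not (self.n1 > self.n2 > 0):
            raise ValueError("refractive indices must satisfy n1 > n2 > 0")
        if self.n1 * math.sin(math.radians(self.theta_deg)) <= self.n2:
            raise SubCriticalAngleError(
                "sub-critical angle: n1*sin(theta) <= n2, no evanescent field"
            )

    @property
    def dp_nm(self) -> float:
        """Resolved penetration depth: the override if given, else computed."""
        if self.dp_override_nm is not None:
            return self.dp_override_nm
        return penetration_depth(self)


def penetration_depth(config: TIRFConfig) -> float:
    """Penetration depth d_p = lambda0 / (4*pi*sqrt(n1^2 sin^2(theta) - n2^2)).

    ``d_p`` is the depth at which the evanescent excitation has decayed to
    1/e of its value at the interface.  It diverges as theta approaches the
    critical angle from above and shrinks toward grazing incidence.
    """
    geom = (config.lambda0_nm, config.theta_deg, config.n1, config.n2)
    if any(v is None for v in geom):
        raise ValueError("penetration_depth requires the full optical geometry")
    s = config.n1 * math.sin(math.radians(config.theta_deg))
    disc = s * s - config.n2 * config.n2
    if disc <= 0:
        raise SubCriticalAngleError(
            "sub-critical angle: n1*sin(theta) <= n2, no evanescent field"
        )
    return config.lambda0_nm / (4.0 * math.pi * math.sqrt(disc))


def _check_dp(dp: float) -> None:
    if not (np.isfinite(dp) and dp > 0):
        raise ValueError("penetration depth dp must be positive and finite")


def excitation_at_depth(z, dp: float):
    """Relative excitation intensity exp(-z/dp) at depth ``z`` nm.

    Normalized to the intensity at the interface (z = 0).
    """
    _check_dp(dp)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be non-negative")
    out = np.exp(-z / dp)
    return out.item() if out.ndim == 0 else out


def relative_layer_intensity(z, dp: float):
    """Fluorescence of a fluorophore layer of thickness ``z``, relative to an
    unbounded layer: I_rel(z) = 1 - exp(-z/dp).

    This is the integral of the exponential excitation profile from the
    interface up to ``z``, normalized by the integral over the full field.
    """
    _check_dp(dp)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("layer thickness z must be non-negative")
    out = -np.expm1(-z / dp)
    return out.item() if out.ndim == 0 else out


def distance_from_relative_intensity(i_rel, dp: float):
    """Invert the layer-intensity relation: z = -dp * ln(1 - i_rel).

    Exact inverse of :func:`relative_layer_intensity`.  ``i_rel`` must lie in
    [0, 1); values >= 1 are beyond the detection ceiling (the distance is
    unbounded) and values < 0 indicate a broken normalization.
    """
    _check_dp(dp)
    i_rel = np.asarray(i_rel, dtype=float)
    if np.any(i_rel < 0):
        raise ValueError("invalid normalization: relative intensity < 0")
    if np.any(i_rel >= 1):
        raise ValueError("beyond detection ceiling: relative intensity >= 1")
    out = -dp * np.log1p(-i_rel)
    return out.item() if out.ndim == 0 else out


def background_corrected_distance(i_rel, background, dp: float, mode: str = "subtract"):
    """Distance after correcting the measured intensity for residual background.

    The canonical correction subtracts the background fraction before
    inverting: ``z = -dp * ln(1 - (i_rel - background))``.  With
    ``mode="renormalize"`` the corrected intensity is instead
    ``(i_rel - background) / (1 - background)``, appropriate when the
    reference region itself carries the same background.

    With ``background=0`` both modes reduce to
    :func:`distance_from_relative_intensity`.
    """
    _check_dp(dp)
    i_rel = np.asarray(i_rel, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background < 0) or np.any(background >= 1):
        raise ValueError("background fraction must lie in [0, 1)")
    corrected = i_rel - background
    if np.any(corrected < 0):
        raise ValueError("over-correction: relative intensity below background")
    if mode == "renormalize":
        corrected = corrected / (1.0 - background)
    elif mode != "subtract":
        raise ValueError(f"unknown correction mode {mode!r}")
    return distance_from_relative_intensity(corrected, dp)


def residual_background_fraction(z_bottom, thickness, dp: float):
    """Fraction of the unobstructed signal coming from cytosol *below* an
    occluding organelle: exp(-(z_bottom + thickness)/dp).

    ``z_bottom`` is the distance of the organelle's lower surface from the
    membrane and ``thickness`` its axial extent.  With ``thickness=0`` this is
    simply the field remaining beyond ``z_bottom`` and the conservation
    identity ``relative_layer_intensity(z) + residual = 1`` holds.
    """
    _check_dp(dp)
    z_bottom = np.asarray(z_bottom, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(z_bottom < 0) or np.any(thickness < 0):
        raise ValueError("z_bottom and thickness must be non-negative")
    out = np.exp(-(z_bottom + thickness) / dp)
    return out.item() if out.ndim == 0 else out


def occluded_fraction(z_bottom, thickness, dp: float):
    """Fraction of the unobstructed signal blocked by the organelle body:
    exp(-z/dp) - exp(-(z+T)/dp).  Completes the conservation identity
    layer + occluded + residual = 1."""
    _check_dp(dp)
    z_bottom = np.asarray(z_bottom, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(z_bottom < 0) or np.any(thickness < 0):
        raise ValueError("z_bottom and thickness must be non-negative")
    out = np.exp(-z_bottom / dp) - np.exp(-(z_bottom + thickness) / dp)
    return out.item() if out.ndim == 0 else out


def relative_intensity_with_occluder(z_bottom, thickness, dp: float):
    """Forward model of a pixel over an occluder of finite axial extent.

    Layer above the organelle plus residual background below it:
    ``1 - exp(-z/dp) * (1 - exp(-T/dp))``.  As ``T -> inf`` this reduces to
    :func:`relative_layer_intensity`.
    """
    layer = relative_layer_intensity(z_bottom, dp)
    resid = residual_background_fraction(z_bottom, thickness, dp)
    return layer + resid


def distance_from_intensity_with_occluder(i_rel, thickness, dp: float):
    """Exact inverse of :func:`relative_intensity_with_occluder` at known
    occluder thickness: z = -dp * ln((1 - i_rel) / (1 - exp(-T/dp))).

    This is the self-consistent residual-background correction: instead of
    subtracting a fixed fraction, the known axial extent of the organelle
    fixes the background at every depth.
    """
    _check_dp(dp)
    i_rel = np.asarray(i_rel, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(thickness < 0):
        raise ValueError("thickness must be non-negative")
    scale = -np.expm1(-thickness / dp)  # 1 - exp(-T/dp)
    if np.any(scale <= 0):
        raise ValueError("zero-thickness occluder produces no intensity deficit")
    ratio = (1.0 - i_rel) / scale
    if np.any(ratio <= 0):
        raise ValueError("beyond detection ceiling: relative intensity >= model max")
    if np.any(ratio > 1 + 1e-12):
        raise ValueError("invalid normalization: intensity below the model minimum")
    out = -dp * np.log(np.minimum(ratio, 1.0))
    return out.item() if out.ndim == 0 else out


def detection_ceiling_distance(dp: float, ceiling: float = DETECTION_CEILING) -> float:
    """Largest reportable distance: -dp * ln(1 - ceiling).

    Pixels whose relative intensity reaches ``ceiling`` are censored at this
    bound rather than inverted (the inversion is numerically unstable near 1).
    """
    _check_dp(dp)
    if not 0 < ceiling < 1:
        raise ValueError("ceiling must lie in (0, 1)")
    return -dp * math.log1p(-ceiling)
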
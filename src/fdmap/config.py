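"""Plain-text analysis configuration shared by all pipeline stages.

One YAML file drives every subcommand; unknown keys are rejected so typos
fail loudly, and serialize(parse(text)) is idempotent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .optics import TIRFConfig

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All tunable parameters of the FDM pipeline, with documented defaults.

    Optics: either ``dp_nm`` directly (the usual case -- calibrated setups
    state the penetration depth) or the full geometry
    (``lambda0_nm``/``theta_deg``/``n1``/``n2``), in which case ``dp_nm``
    should be left None.
    """

    # optics
    lambda0_nm: float | None = None
    theta_deg: float | None = None
    n1: float | None = None
    n2: float | None = None
    dp_nm: float | None = 50.0
    # calibration / correction
    pixel_size_nm: float = 100.0
    camera_offset: float = 100.0
    background_fraction: float = 0.15
    occluder_thickness_nm: float | None = None
    # segmentation
    radius_px: int = 20
    offset_fraction: float = 0.10
    min_area_um2: float = 0.07
    circularity_cut: float = 0.85
    mobility_cut_px: float = 1.0
    # fret
    c_donor: float = 0.0
    c_acceptor: float = 0.0
    n_bins: int = 20
    # dynamics
    max_link_distance_px: float = 5.0
    frame_interval_s: float = 1.0
    ceiling: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not 0 < self.ceiling < 1:
            raise ValueError("ceiling must lie in (0, 1)")
        if self.min_area_um2 < 0 or self.offset_fraction <= 0:
            raise ValueError("min_area_um2 must be >= 0 and offset_fraction > 0")
        if not (0 <= self.c_donor < 1 and 0 <= self.c_acceptor < 1):
            raise ValueError("bleed-through coefficients must lie in [0, 1)")
        if self.dp_nm is not None and self.dp_nm <= 0:
            raise ValueError("dp_nm must be positive")

    def tirf_config(self) -> TIRFConfig:
        return TIRFConfig(lambda0_nm=self.lambda0_nm, theta_deg=self.theta_deg,
                          n1=self.n1, n2=self.n2, dp_override_nm=self.dp_nm)

    @property
    def resolved_dp_nm(self) -> float:
        return self.tirf_config().dp_nm

    @classmethod
    def from_yaml(cls, text_or_path) -> "AnalysisConfig":
        """Parse a config from YAML text or a file path; unknown keys are
        rejected with the offending names."""
        text = str(text_or_path)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                text = fh.read()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
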
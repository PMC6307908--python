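"""Analysis parameters and their defaults.

The intensity and size thresholds default to the values used in the original
Volocity workflow this package reimplements: a graft object must exceed 250
intensity units and 100 µm³; a vessel object must exceed 100 units and
100 µm³. The association geometry defaults to a 10-µm-radius scoring disc
with the control disc 25 µm away, and a macrophage counts as a tip cell
after ≥ 40 min of tip contact. All are configurable because the original
detector scale and the inclusivity conventions are instrument-specific.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and geometry parameters for the whole pipeline.

    Attributes
    ----------
    graft_min_intensity : float
        Minimum intensity (detector units) for a graft voxel. Inclusive.
    graft_min_volume : float
        Minimum connected-object volume in µm³ for the graft channel. Inclusive.
    vessel_min_intensity, vessel_min_volume : float
        Same thresholds for the vessel channel.
    angiogenic_radius : float
        Radius in µm of the scoring disc centred on the vessel tip.
    control_offset : float
        Distance in µm between angiogenic and control disc centres
        (``control_offset_mode='edge'`` measures edge-to-edge instead).
    tipcell_min_duration : float
        Minimum tip-contact duration in minutes for tip-cell classification.
    contact_radius : float or None
        Macrophage–tip distance in µm that counts as contact; ``None`` means
        "same as angiogenic_radius".
    connectivity : int
        3D voxel connectivity for component labelling: 6, 18 or 26.
    aoi_mode : str
        'bounding_box' (axis-aligned box around graft objects) or 'mask'.
    frame_interval : float
        Time-lapse frame spacing in minutes.
    alpha_gate : float
        Significance level for the normality and variance gates in the
        statistical decision tree.
    """

    graft_min_intensity: float = 250.0
    graft_min_volume: float = 100.0
    vessel_min_intensity: float = 100.0
    vessel_min_volume: float = 100.0
    angiogenic_radius: float = 10.0
    control_offset: float = 25.0
    control_offset_mode: str = "centre"  # or "edge"
    tipcell_min_duration: float = 40.0
    contact_radius: float | None = None
    connectivity: int = 26
    aoi_mode: str = "bounding_box"
    frame_interval: float = 10.0
    alpha_gate: float = 0.05
    macrophage_min_intensity: float = 100.0
    macrophage_min_volume: float = 50.0
    macrophage_norm_volume: float = field(default=1e5)  # counts per this many µm³

    def __post_init__(self) -> None:
        positive = (
            ("graft_min_intensity", self.graft_min_intensity),
            ("graft_min_volume", self.graft_min_volume),
            ("vessel_min_intensity", self.vessel_min_intensity),
            ("vessel_min_volume", self.vessel_min_volume),
            ("angiogenic_radius", self.angiogenic_radius),
            ("control_offset", self.control_offset),
            ("tipcell_min_duration", self.tipcell_min_duration),
            ("frame_interval", self.frame_interval),
            ("macrophage_norm_volume", self.macrophage_norm_volume),
        )
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity!r}")
        if self.aoi_mode not in ("bounding_box", "mask"):
            raise ValueError(f"aoi_mode must be 'bounding_box' or 'mask', got {self.aoi_mode!r}")
        if self.control_offset_mode not in ("centre", "edge"):
            raise ValueError("control_offset_mode must be 'centre' or 'edge'")
        if self.contact_radius is not None and not self.contact_radius > 0:
            raise ValueError("contact_radius must be strictly positive when given")
        if not 0 < self.alpha_gate < 1:
            raise ValueError("alpha_gate must lie in (0, 1)")

    @property
    def effective_contact_radius(self) -> float:
        return self.angiogenic_radius if self.contact_radius is None else self.contact_radius

    def fingerprint(self) -> str:
        """Short stable hash of the configuration, embedded in all outputs."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
        return cls(**known)
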
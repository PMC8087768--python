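"""Pipeline configuration: filter specs, event detection, model constants.

Every literature-derived constant the pipeline depends on (segment inertial
proportions, moment-arm polynomials, PCSA partition, tendon material
constants) lives here so it can be overridden from a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml

from .exceptions import ValidationError
from .inverse_dynamics import MomentArmModel, PcsaPartition, SegmentInertia, SegmentParams
from .signal_processing import FilterSpec
from .tendon_mechanics import TendonConstants


@dataclass
class PipelineConfig:
    """All tunable parameters of the trial -> TendonOutcome pipeline."""

    # smoothing: 4th-order zero-lag Butterworth, 6 Hz (kinematics), 100 Hz (force)
    kinematic_filter: FilterSpec = field(default_factory=lambda: FilterSpec(order=4, cutoff=6.0))
    force_filter: FilterSpec = field(default_factory=lambda: FilterSpec(order=4, cutoff=100.0))
    filtering_enabled: bool = True  # disable for noise-free oracle runs
    filter_cop: bool = True  # smooth COP with the force filter

    # stance detection
    stance_threshold: float = 20.0  # N
    stance_min_duration: float = 0.050  # s

    # models
    inertia: SegmentInertia = field(default_factory=SegmentInertia)
    moment_arms: MomentArmModel = field(default_factory=MomentArmModel)
    pcsa: PcsaPartition = field(default_factory=PcsaPartition)
    tendon: TendonConstants = field(default_factory=TendonConstants)

    # Eq-level switches
    stress_raw_impulse: bool = False  # literal impulse/CSA (Pa*s) instead of Pa
    # numerator integrand of the external-arm ratio: the instantaneous AT
    # moment arm ("at_arm", as printed) or the COP-to-ankle lever ("cop")
    external_arm_integrand: str = "at_arm"

    def __post_init__(self) -> None:
        if self.external_arm_integrand not in ("at_arm", "cop"):
            raise ValidationError(
                f"external_arm_integrand must be 'at_arm' or 'cop', got {self.external_arm_integrand!r}"
            )
        if self.stance_threshold <= 0:
            raise ValidationError("stance threshold must be positive")

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        kwargs: Dict[str, Any] = dict(d)
        for key, typ in (
            ("kinematic_filter", FilterSpec),
            ("force_filter", FilterSpec),
            ("pcsa", PcsaPartition),
            ("tendon", TendonConstants),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if isinstance(kwargs.get("inertia"), dict):
            kwargs["inertia"] = SegmentInertia(
                **{seg: SegmentParams(**p) if isinstance(p, dict) else p
                   for seg, p in kwargs["inertia"].items()}
            )
        if isinstance(kwargs.get("moment_arms"), dict):
            ma = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in kwargs["moment_arms"].items()}
            kwargs["moment_arms"] = MomentArmModel(**ma)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
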
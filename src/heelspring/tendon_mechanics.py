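"""Specific net work and Achilles-tendon stress, strain and elastic energy.

Specific net work (SNW) summarises a joint's stance-phase energy pattern as
|W+ + W-| / (|W+| + |W-|): 0 is a perfect spring (all absorbed energy
returned), 1 a pure motor or brake.  Tendon loading is summarised by the
plantarflexor force impulse over stance; stress divides the time-averaged
force by tendon cross-sectional area, strain follows from a Hookean modulus
(819 MPa, mean human AT), and stored energy is the Hookean spring energy
0.5 F dL discounted by a tendon resilience of 0.93.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Tuple

from .exceptions import UndefinedResultError, ValidationError

__all__ = [
    "TendonConstants",
    "TendonOutcome",
    "specific_net_work",
    "tendon_stress",
    "tendon_strain_and_dl",
    "strain_energy",
    "assemble_outcome",
]


@dataclass(frozen=True)
class TendonConstants:
    """Material constants of the Achilles tendon."""

    elastic_modulus: float = 819e6  # Pa, mean human AT
    resilience: float = 0.93  # fraction of stored energy returned

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ValidationError(f"elastic modulus must be positive, got {self.elastic_modulus}")
        if not 0.0 < self.resilience <= 1.0:
            raise ValidationError(f"resilience must be in (0, 1], got {self.resilience}")


# Field order is the on-disk column order of result tables.
@dataclass
class TendonOutcome:
    """Per-step derived scalars for one support phase."""

    subject_id: str
    gait: str
    step_index: int
    froude: float
    snw_hip: float
    snw_knee: float
    snw_ankle: float
    force_impulse: float  # N*s, plantarflexor force over stance
    r_ankle_ext: float  # m, impulse-averaged external moment arm of the GRF
    stress_mean: float  # Pa
    stress_peak: float  # Pa
    strain: float  # dimensionless
    delta_l: float  # m
    energy: float  # J
    energy_per_kg: float  # J/kg
    stress_mean_per_kg: float  # Pa/kg

    def validate(self) -> "TendonOutcome":
        for j in ("snw_hip", "snw_knee", "snw_ankle"):
            v = getattr(self, j)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValidationError(f"{j} = {v} outside [0, 1]")
        if self.strain < 0:
            raise ValidationError(f"strain = {self.strain} must be >= 0")
        if self.energy < 0:
            raise ValidationError(f"energy = {self.energy} must be >= 0")
        return self

    def as_dict(self) -> Dict[str, object]:
        return asdict(self)


def specific_net_work(work_pos: float, work_neg: float) -> float:
    """SNW = |W+ + W-| / (|W+| + |W-|), in [0, 1].

    Raises :class:`UndefinedResultError` when both work terms are zero;
    callers flag such steps and exclude them from statistics.
    """
    if work_pos < 0:
        raise ValidationError(f"work_pos must be >= 0, got {work_pos}")
    if work_neg > 0:
        raise ValidationError(f"work_neg must be <= 0, got {work_neg}")
    total = abs(work_pos) + abs(work_neg)
    if total == 0.0:
        raise UndefinedResultError("SNW undefined: zero positive and negative work")
    return abs(work_pos + work_neg) / total


def tendon_stress(
    force_impulse: float,
    stance_duration: float,
    peak_force: float,
    csa: float,
    raw_impulse: bool = False,
) -> Tuple[float, float]:
    """Mean and peak tendon stress (Pa).

    Default: the force impulse is divided by the stance duration (a
    time-averaged plantarflexor force) before dividing by CSA, so the mean
    stress is in Pa.  With ``raw_impulse=True`` the impulse itself is
    divided by CSA (units Pa*s), the literal impulse-over-area form.
    Peak stress is the peak instantaneous force over CSA.
    """
    if csa <= 0:
        raise ValidationError(f"tendon CSA must be positive, got {csa}")
    if stance_duration <= 0:
        raise ValidationError(f"stance duration must be positive, got {stance_duration}")
    if raw_impulse:
        stress_mean = force_impulse / csa
    else:
        stress_mean = (force_impulse / stance_duration) / csa
    stress_peak = peak_force / csa
    return stress_mean, stress_peak


def tendon_strain_and_dl(
    stress: float, constants: TendonConstants, resting_length: float
) -> Tuple[float, float]:
    """Hookean strain (stress / modulus) and tendon length change (strain * L0)."""
    if resting_length <= 0:
        raise ValidationError(f"resting length must be positive, got {resting_length}")
    strain = stress / constants.elastic_modulus
    return strain, strain * resting_length


def strain_energy(force: float, delta_l: float, constants: TendonConstants) -> float:
    """Recovered elastic energy W = 0.5 F dL scaled by tendon resilience."""
    if force < 0 or delta_l < 0:
        raise ValidationError("strain_energy requires non-negative force and length change")
    return 0.5 * force * delta_l * constants.resilience


def assemble_outcome(
    *,
    subject_id: str,
    gait: str,
    step_index: int,
    froude: float,
    work_pos: Dict[str, float],
    work_neg: Dict[str, float],
    force_impulse: float,
    peak_force: float,
    stance_duration: float,
    r_ankle_ext: float,
    body_mass: float,
    tendon_csa: float,
    tendon_length: float,
    constants: TendonConstants,
    raw_impulse: bool = False,
) -> TendonOutcome:
    """Populate a :class:`TendonOutcome` from upstream per-step quantities.

    Mass-specific fields are the plain fields divided by body mass.  The
    tendon chain (stress -> strain -> delta L -> energy) is driven by the
    time-averaged plantarflexor force by default; negative mean stresses
    (net dorsiflexor impulse, not seen on realistic steps) are clipped to
    zero before the strain/energy chain so the Hookean model stays in its
    tensile regime.
    """
    for name, val in (("body_mass", body_mass), ("tendon_csa", tendon_csa),
                      ("tendon_length", tendon_length)):
        if val is None or val <= 0:
            raise ValidationError(f"missing or non-positive upstream value: {name}")
    snw = {j: specific_net_work(work_pos[j], work_neg[j]) for j in ("hip", "knee", "ankle")}
    stress_mean, stress_peak = tendon_stress(
        force_impulse, stance_duration, peak_force, tendon_csa, raw_impulse=raw_impulse
    )
    tensile = max(stress_mean, 0.0)
    strain, delta_l = tendon_strain_and_dl(tensile, constants, tendon_length)
    mean_force = max(force_impulse / stance_duration, 0.0)
    energy = strain_energy(mean_force, delta_l, constants)
    return TendonOutcome(
        subject_id=subject_id,
        gait=gait,
        step_index=step_index,
        froude=froude,
        snw_hip=snw["hip"],
        snw_knee=snw["knee"],
        snw_ankle=snw["ankle"],
        force_impulse=force_impulse,
        r_ankle_ext=r_ankle_ext,
        stress_mean=stress_mean,
        stress_peak=stress_peak,
        strain=strain,
        delta_l=delta_l,
        energy=energy,
        energy_per_kg=energy / body_mass,
        stress_mean_per_kg=stress_mean / body_mass,
    ).validate()
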
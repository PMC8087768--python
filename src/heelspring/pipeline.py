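"""Trial -> per-step TendonOutcome orchestration.

Processing order per trial: smooth kinematic and force channels (zero-lag
Butterworth, 6 Hz / 100 Hz), decimate force to the kinematic rate, detect
support phases, then per stance run the inverse-dynamics recursion, the
muscle-force system, the external-arm ratio, the work decomposition and the
tendon chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .exceptions import ValidationError
from .inverse_dynamics import (
    JOINTS,
    JointKinetics,
    StanceStep,
    angular_velocities,
    external_moment_arm_ankle,
    froude_number,
    joint_angles,
    joint_power_work,
    muscle_forces,
    net_joint_moments,
)
from .io_formats import SubjectMorphometrics, TrialRecording
from .signal_processing import (
    detect_stance,
    downsample_force,
    trapz_integral,
    zero_lag_butterworth,
)
from .tendon_mechanics import TendonOutcome, assemble_outcome


@dataclass
class ProcessedStep:
    """One support phase's full kinetics plus the derived outcome row."""

    outcome: TendonOutcome
    kinetics: JointKinetics
    step: StanceStep


def _filtered_channels(
    trial: TrialRecording, config: PipelineConfig
) -> Tuple[Dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed markers plus force channels decimated to the kinematic rate."""
    kr, fr = trial.kinematic_rate, trial.force_rate
    if config.filtering_enabled:
        markers = {
            name: np.column_stack([
                zero_lag_butterworth(arr[:, 0], kr, config.kinematic_filter),
                zero_lag_butterworth(arr[:, 1], kr, config.kinematic_filter),
            ])
            for name, arr in trial.markers.items()
        }
        fz = zero_lag_butterworth(trial.fz, fr, config.force_filter)
        fx = zero_lag_butterworth(trial.fx, fr, config.force_filter)
        cop = (zero_lag_butterworth(trial.cop_x, fr, config.force_filter)
               if config.filter_cop else trial.cop_x)
    else:
        markers = {name: arr.astype(float) for name, arr in trial.markers.items()}
        fz, fx, cop = trial.fz, trial.fx, trial.cop_x
    # anti-aliasing already handled (or deliberately skipped) above
    fz = downsample_force(fz, fr, kr, antialias=None)
    fx = downsample_force(fx, fr, kr, antialias=None)
    cop = downsample_force(cop, fr, kr, antialias=None)
    n = trial.time_kinematic.size
    return markers, fz[:n], fx[:n], cop[:n]


def process_trial(
    trial: TrialRecording,
    subject: SubjectMorphometrics,
    config: Optional[PipelineConfig] = None,
    keep_kinetics: bool = False,
) -> List[ProcessedStep] | List[TendonOutcome]:
    """Process one trial into per-support-phase outcomes.

    Returns a list of :class:`TendonOutcome` (one per detected stance), or
    :class:`ProcessedStep` records when ``keep_kinetics`` is true.
    """
    if trial.subject_id != subject.subject_id:
        raise ValidationError(
            f"trial subject {trial.subject_id!r} does not match morphometrics "
            f"{subject.subject_id!r}"
        )
    config = config or PipelineConfig()
    kr = trial.kinematic_rate
    markers, fz_full, fx_full, cop_full = _filtered_channels(trial, config)
    intervals = detect_stance(fz_full, config.stance_threshold, kr, config.stance_min_duration)
    arms = config.moment_arms.for_subject(subject.at_moment_arm, subject.hip_height)

    # differentiate and invert over the whole record, then window per stance:
    # one-sided stencils then only ever touch the record ends, not stance edges
    whole = StanceStep(
        subject_id=trial.subject_id, gait_label=trial.gait_label, step_index=-1,
        rate=kr, markers=markers, fz=fz_full, fx=fx_full, cop_x=cop_full,
    )
    moments_full = net_joint_moments(whole, config.inertia, subject.body_mass)
    angles_full = joint_angles(markers)
    omega_full = angular_velocities(angles_full, kr)
    forces_full, r_series_full = muscle_forces(moments_full, angles_full, arms, config.pcsa)

    results: List[ProcessedStep] = []
    for step_index, win in enumerate(intervals):
        sl = win.slice()
        step = StanceStep(
            subject_id=trial.subject_id,
            gait_label=trial.gait_label,
            step_index=step_index,
            rate=kr,
            markers={k: v[sl] for k, v in markers.items()},
            fz=fz_full[sl], fx=fx_full[sl], cop_x=cop_full[sl],
        )
        moments = {j: m[sl] for j, m in moments_full.items()}
        angles = {j: a[sl] for j, a in angles_full.items()}
        omega = {j: w[sl] for j, w in omega_full.items()}
        forces = {j: f[sl] for j, f in forces_full.items()}
        r_series = {j: r[sl] for j, r in r_series_full.items()}

        power: Dict[str, np.ndarray] = {}
        wpos: Dict[str, float] = {}
        wneg: Dict[str, float] = {}
        impulse: Dict[str, float] = {}
        for j in JOINTS:
            power[j], wpos[j], wneg[j] = joint_power_work(moments[j], omega[j], kr)
            impulse[j] = trapz_integral(forces[j], kr)
        grf_mag = np.hypot(step.fx, step.fz)
        grf_impulse = trapz_integral(grf_mag, kr)
        if config.external_arm_integrand == "at_arm":
            integrand_arm = r_series["ankle"]
        else:
            integrand_arm = step.cop_x - step.markers["ankle"][:, 0]
        r_ext = external_moment_arm_ankle(grf_mag, integrand_arm, forces["ankle"], kr)

        hip_x = step.markers["hip"][:, 0]
        speed = abs(hip_x[-1] - hip_x[0]) / step.duration
        froude = froude_number(max(speed, 1e-9), subject.hip_height)

        outcome = assemble_outcome(
            subject_id=subject.subject_id,
            gait=trial.gait_label,
            step_index=step_index,
            froude=froude,
            work_pos=wpos,
            work_neg=wneg,
            force_impulse=impulse["ankle"],
            peak_force=float(np.max(forces["ankle"])),
            stance_duration=step.duration,
            r_ankle_ext=r_ext,
            body_mass=subject.body_mass,
            tendon_csa=subject.tendon_csa,
            tendon_length=subject.tendon_length,
            constants=config.tendon,
            raw_impulse=config.stress_raw_impulse,
        )
        kinetics = JointKinetics(
            rate=kr, moments=moments, forces=forces, angles=angles,
            angular_velocity=omega, power=power, work_pos=wpos, work_neg=wneg,
            force_impulse=impulse, grf_impulse=grf_impulse,
            r_ankle_series=r_series["ankle"], r_ankle_external=r_ext,
        )
        results.append(ProcessedStep(outcome=outcome, kinetics=kinetics, step=step))
    if keep_kinetics:
        return results
    return [r.outcome for r in results]


def process_cohort(
    trials: Sequence[TrialRecording],
    subjects: Sequence[SubjectMorphometrics],
    config: Optional[PipelineConfig] = None,
) -> List[TendonOutcome]:
    """Process many trials; step indices count per subject and gait."""
    by_id: Mapping[str, SubjectMorphometrics] = {s.subject_id: s for s in subjects}
    counters: Dict[Tuple[str, str], int] = {}
    out: List[TendonOutcome] = []
    for trial in trials:
        if trial.subject_id not in by_id:
            raise ValidationError(f"no morphometrics for subject {trial.subject_id!r}")
        for outcome in process_trial(trial, by_id[trial.subject_id], config):
            key = (trial.subject_id, trial.gait_label)
            outcome.step_index = counters.get(key, 0)
            counters[key] = outcome.step_index + 1
            out.append(outcome)
    return out
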
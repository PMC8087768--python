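"""Synthetic cohorts and gait trials with forward-constructed ground truth.

The generator emulates the study conditions of a motion-capture / force-plate
gait experiment: subjects walk, fast-walk, jog, run and sprint over force
plates; each trial yields one support phase.  Morphometrics are drawn from
truncated normals matching the cohort summary statistics (body mass
64.15 +- 9.84 kg, AT moment arm 4.27 +- 0.48 cm correlated with mass at
r ~ 0.6, tendon CSA 0.61 +- 0.15 cm^2), vertical GRF is double-peaked for
walking gaits and single-peaked (2.2-2.8 x body weight) for running gaits,
and progression speed is drawn so Froude numbers land on the per-gait means.

Every trial carries a :class:`GroundTruth` computed *forward* from the
constructed kinematics and forces with the same free-body equations the
inverse-dynamics stage inverts (a shared-equation oracle, written as an
independent per-frame code path).

Effect injection
----------------
With injection enabled (the default) the tendon-load mechanism under study
is present naturally: the plantarflexor force is M/r, so subjects with
shorter AT moment arms carry proportionally larger tendon loads, and the
ankle's stance energy pattern is made more motor-like for longer moment
arms at running/sprinting gaits.  With injection disabled (a null cohort)
the per-subject GRF is scaled by (moment arm / cohort mean arm) so the
tendon force loses its 1/r dependence, and the kinematic link is removed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import PipelineConfig
from .exceptions import ValidationError
from .inverse_dynamics import G, SegmentInertia, SegmentParams
from .io_formats import GAITS, SubjectMorphometrics, TrialRecording
from .signal_processing import StanceInterval, finite_diff_accel, trapz_integral
from .tendon_mechanics import TendonConstants, tendon_strain_and_dl, strain_energy

__all__ = [
    "GaitParams", "GAIT_TABLE", "CohortSpec", "EffectInjection", "GroundTruth",
    "generate_subject", "generate_stance_grf", "generate_trial",
    "generate_cohort", "generate_static_trial",
]

# Cohort summary statistics the subject generator reproduces
MASS_MEAN, MASS_SD = 64.15, 9.84  # kg
ARM_MEAN, ARM_SD = 0.0427, 0.0048  # m
CSA_MEAN, CSA_SD = 0.61e-4, 0.15e-4  # m^2
MASS_ARM_R = 0.6  # target mass / moment-arm correlation
# latent conditional correlation; range truncation of the moment arm
# attenuates the realized cohort correlation down to the target
_ARM_GIVEN_MASS_RHO = 0.70
P_FEMALE = 17.0 / 24.0


@dataclass(frozen=True)
class GaitParams:
    """Per-gait generator parameters (the emulated study conditions)."""

    froude_mean: float
    froude_sd: float
    stance_duration: float  # s
    n_lobes: int  # vertical GRF lobes (2 = walking, 1 = running)
    peak_bw: float  # vertical GRF peak, multiples of body weight
    fx_bw: float  # fore-aft amplitude, multiples of body weight
    cop_start: float  # initial COP position, fraction of foot length from heel
    shank_angle_td: float  # rad from vertical at touchdown (negative = tilted back)
    shank_excursion: float  # rad, base stance excursion (rescaled to match speed)
    knee_flexion_base: float  # rad
    knee_flexion_amp: float  # rad, mid-stance flexion bump
    ankle_angle_td: float  # rad, included ankle angle at touchdown
    ankle_excursion: float  # rad, dorsi/plantarflexion amplitude scale
    snw_target: float  # cohort-mean ankle SNW the asymmetry aims at
    snw_logit_offset: float  # logit-scale calibration of realized vs target SNW


GAIT_TABLE: Dict[str, GaitParams] = {
    #                 Froude        T     lobes peak  fx    cop  phi_td  dphi  k0    kA    th_td  A     snw
    "walk": GaitParams(0.130, 0.041, 0.65, 2, 1.10, 0.15, 0.05, -0.34, 0.60, 0.04, 0.12, 1.48, 0.40, 0.450, -0.66),
    "fast_walk": GaitParams(0.245, 0.054, 0.55, 2, 1.20, 0.18, 0.05, -0.35, 0.65, 0.04, 0.15, 1.48, 0.45, 0.367, -0.85),
    "jog": GaitParams(0.362, 0.086, 0.30, 1, 2.25, 0.22, 0.15, -0.30, 0.55, 0.06, 0.25, 1.47, 0.50, 0.231, -0.32),
    "run": GaitParams(0.662, 0.179, 0.25, 1, 2.45, 0.28, 0.25, -0.30, 0.55, 0.06, 0.30, 1.45, 0.52, 0.447, -0.35),
    "sprint": GaitParams(1.086, 0.283, 0.18, 1, 2.70, 0.35, 0.40, -0.28, 0.50, 0.08, 0.35, 1.42, 0.55, 0.755, -0.61),
}


@dataclass(frozen=True)
class EffectInjection:
    """Strength of the moment-arm -> tendon-behaviour link in the generator.

    Two coupled channels represent the posited mechanism at running and
    sprinting gaits: a kinematic channel (longer moment arms -> more
    motor-like ankle energy patterns, i.e. higher ankle SNW) and a posture /
    loading channel (shorter moment arms -> more forefoot-biased foot strike,
    shifting the COP forward and raising the external lever, hence the
    tendon load F = M/r on top of its intrinsic 1/r dependence).
    """

    snw_slope_per_sd: float = 0.15  # ankle SNW shift per SD of AT moment arm
    cop_slope_per_sd: float = 0.10  # COP start shift (fraction of foot length) per SD
    gaits: Tuple[str, ...] = ("run", "sprint")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    n_subjects: int = 24
    steps_per_gait: int = 3
    gaits: Tuple[str, ...] = GAITS
    seed: int = 0
    at_moment_arm_range: Tuple[float, float] = (0.0312, 0.0501)  # m
    mass_range: Tuple[float, float] = (40.0, 95.0)  # kg
    effect_injection: Optional[EffectInjection] = field(default_factory=EffectInjection)
    marker_noise_sd: float = 1e-3  # m
    force_noise_sd: float = 2.0  # N
    kinematic_rate: float = 500.0  # Hz
    force_rate: float = 1000.0  # Hz
    subject_snw_sd: float = 0.12  # between-subject ankle SNW spread
    step_snw_sd: float = 0.07  # step-to-step ankle SNW spread
    pad: float = 0.15  # s of swing padding either side of stance

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("cohort needs at least 2 subjects")
        for name in ("at_moment_arm_range", "mass_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must be ordered low <= high")
        for g in self.gaits:
            if g not in GAIT_TABLE:
                raise ValidationError(f"unsupported gait label {g!r}")


@dataclass
class GroundTruth:
    """Forward-computed truth for one trial, independent of the inverse pipeline."""

    moments: Dict[str, np.ndarray]  # N*m per joint, all kinematic frames
    ankle_force: np.ndarray  # N, plantarflexor force at all kinematic frames
    angles: Dict[str, np.ndarray]  # prescribed included joint angles, rad
    stance_start: int  # kinematic frame indices of the constructed stance
    stance_end: int
    speed: float  # m/s
    froude: float
    stored_energy: float  # J, tendon elastic energy over the stance
    snw_target: float  # the ankle SNW the asymmetry parameter aimed at


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived child stream: reproducible independent of call order."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Draw from N(mean, sd) truncated to [lo, hi] by rejection."""
    if lo == hi:
        return lo
    if sd <= 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_subject(spec: CohortSpec, index: int) -> SubjectMorphometrics:
    """Draw one subject's morphometrics from the cohort distributions.

    The AT moment arm is drawn conditionally on body mass so the cohort
    correlation lands near the target r = 0.6; tendon CSA is independent of
    body mass; hip height, foot length and resting tendon length follow mild
    allometric relations with added individual scatter.
    """
    if index >= spec.n_subjects:
        raise ValidationError(f"subject index {index} >= n_subjects {spec.n_subjects}")
    rng = _child_rng(spec.seed, 1, index)
    m_lo, m_hi = spec.mass_range
    mass = _trunc_normal(rng, MASS_MEAN, MASS_SD, m_lo, m_hi)
    z_mass = (mass - MASS_MEAN) / MASS_SD
    a_lo, a_hi = spec.at_moment_arm_range
    arm = _trunc_normal(
        rng,
        ARM_MEAN + _ARM_GIVEN_MASS_RHO * ARM_SD * z_mass,
        ARM_SD * math.sqrt(1.0 - _ARM_GIVEN_MASS_RHO**2),
        a_lo, a_hi,
    )
    csa = _trunc_normal(rng, CSA_MEAN, CSA_SD, 0.25e-4, 1.2e-4)
    hip_height = _trunc_normal(rng, 0.62 + 0.0042 * mass, 0.025, 0.70, 1.05)
    foot_length = _trunc_normal(rng, 0.175 + 1.0 * arm + 0.0004 * mass, 0.008, 0.20, 0.31)
    # resting AT length is drawn independently of stature: its (weak) stature
    # link is omitted so tendon-chain outcomes carry no hidden moment-arm channel
    tendon_length = _trunc_normal(rng, 0.20, 0.015, 0.15, 0.26)
    sex = "F" if rng.random() < P_FEMALE else "M"
    return SubjectMorphometrics(
        subject_id=f"S{index:02d}",
        sex=sex,
        body_mass=mass,
        hip_height=hip_height,
        foot_length=foot_length,
        at_moment_arm=arm,
        tendon_csa=csa,
        tendon_length=tendon_length,
    )


def _raised_cosine(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """One raised-cosine lobe on [center - width/2, center + width/2]."""
    phase = (u - center) / width
    lobe = 0.5 * (1.0 + np.cos(2.0 * np.pi * phase))
    return np.where(np.abs(phase) <= 0.5, lobe, 0.0)


def generate_stance_grf(
    gait: str,
    mass: float,
    duration: float,
    rate: float,
    rng: np.random.Generator,
    foot_length: float = 0.25,
    cop_start: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stance phase of GRF sampled at ``rate``: ``(fz, fx, cop_rel)``.

    ``fz`` is non-negative, zero at both endpoints, double-peaked
    (~1.1 x body weight per peak) for walking gaits and single-peaked
    (2.2-2.8 x body weight) for running gaits.  ``fx`` is braking then
    propulsive with near-zero net impulse.  ``cop_rel`` travels monotonically
    heel -> toe, in metres from the heel.
    """
    if gait not in GAIT_TABLE:
        raise ValidationError(f"unsupported gait label {gait!r}")
    if not 0.08 <= duration <= 1.2:
        raise ValidationError(f"stance duration {duration} s outside [0.08, 1.2] s")
    if rate < 200:
        raise ValidationError(f"force rate {rate} Hz too low (need >= 200 Hz)")
    par = GAIT_TABLE[gait]
    n = int(round(duration * rate)) + 1
    u = np.linspace(0.0, 1.0, n)
    bw = mass * G
    jitter = float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.92, 1.10))
    if par.n_lobes == 2:
        fz = par.peak_bw * bw * jitter * (
            _raised_cosine(u, 0.27, 0.54) + _raised_cosine(u, 0.73, 0.54)
        )
    else:
        fz = par.peak_bw * bw * jitter * _raised_cosine(u, 0.5, 1.0)
    fx = -par.fx_bw * bw * jitter * np.sin(2.0 * np.pi * u) * np.sin(np.pi * u)
    s0 = par.cop_start if cop_start is None else float(np.clip(cop_start, 0.02, 0.60))
    cop_rel = (s0 + (0.95 - s0) * u) * foot_length
    return fz, fx, cop_rel


# -- stance kinematics -------------------------------------------------------

def _progress(u: np.ndarray) -> np.ndarray:
    """Smooth monotone stance-progress warp on the (extended) stance clock."""
    return u - 0.12 * np.sin(2.0 * np.pi * u)


def _moment_proxy(par: GaitParams, s0: float, u: np.ndarray) -> np.ndarray:
    """Idealized ankle-moment waveform over the stance clock: the vertical
    GRF shape times the COP-to-ankle lever implied by the COP progression
    (the ankle sits ~0.16 foot lengths ahead of the heel print)."""
    if par.n_lobes == 2:
        shape = _raised_cosine(u, 0.27, 0.54) + _raised_cosine(u, 0.73, 0.54)
    else:
        shape = _raised_cosine(u, 0.5, 1.0)
    lever = s0 + (0.95 - s0) * u - 0.16
    return shape * lever


def _snw_of_asymmetry(d: float, par: GaitParams, s0: float) -> float:
    """Ankle SNW of the idealized stance: moment proxy times angular
    velocity proportional to (d - sin(2 pi u))."""
    u = np.linspace(0.0, 1.0, 801)
    p = _moment_proxy(par, s0, u) * (d - np.sin(2.0 * np.pi * u))
    num = abs(np.trapezoid(p, u))
    den = np.trapezoid(np.abs(p), u)
    return num / den if den > 0 else 1.0


def _asymmetry_for_snw(target: float, par: GaitParams, s0: float) -> float:
    """Invert the idealized SNW(d) map on its increasing branch.

    SNW(d) is V-shaped in d: it vanishes where the net work integral
    crosses zero (d0, solved in closed form because the integral is linear
    in d) and rises to 1 on either side.  Motor-like targets are realized
    on the plantarflexion-dominant branch d >= d0.
    """
    target = float(np.clip(target, 1e-3, 0.999))
    u = np.linspace(0.0, 1.0, 801)
    m = _moment_proxy(par, s0, u)
    d0 = float(np.trapezoid(m * np.sin(2.0 * np.pi * u), u) / np.trapezoid(m, u))
    hi = d0 + 1.5
    if _snw_of_asymmetry(hi, par, s0) <= target:
        return hi
    return float(brentq(lambda d: _snw_of_asymmetry(d, par, s0) - target,
                        d0, hi, xtol=1e-6))


def _stance_segment_angles(
    par: GaitParams,
    u: np.ndarray,
    shank_len: float,
    thigh_len: float,
    advance: float,
    asymmetry: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absolute shank/thigh angles (rad from vertical, + = top end forward)
    and the included ankle angle, over the extended stance clock ``u``.

    The base shank excursion is rescaled (monotone 1-D solve) so the hip
    travels exactly ``advance`` metres over the stance proper (u in [0, 1]).
    """
    w = _progress(u)

    def hip_travel(k: float) -> float:
        def hip_x(uu: float) -> float:
            ww = uu - 0.12 * math.sin(2.0 * math.pi * uu)
            phi_s = par.shank_angle_td + k * par.shank_excursion * ww
            kappa = par.knee_flexion_base + par.knee_flexion_amp * math.sin(math.pi * uu)
            phi_t = phi_s + kappa
            return shank_len * math.sin(phi_s) + thigh_len * math.sin(phi_t)

        return hip_x(1.0) - hip_x(0.0)

    # travel is monotone in k while the toe-off shank angle stays below pi/2;
    # bracket there and clamp unreachable (extreme-draw) speeds to the limit
    k_max = (math.pi / 2.0 - par.shank_angle_td) / par.shank_excursion
    if hip_travel(k_max) <= advance:
        k = k_max
    else:
        k = brentq(lambda kk: hip_travel(kk) - advance, 0.02, k_max, xtol=1e-12)
    phi_s = par.shank_angle_td + k * par.shank_excursion * w
    kappa = par.knee_flexion_base + par.knee_flexion_amp * np.sin(np.pi * np.clip(u, 0.0, 1.0))
    phi_t = phi_s + kappa
    theta_ankle = par.ankle_angle_td + par.ankle_excursion * (
        asymmetry * u + (np.cos(2.0 * np.pi * u) - 1.0) / (2.0 * np.pi)
    )
    return phi_s, phi_t, theta_ankle


def _build_markers(
    subject: SubjectMorphometrics,
    phi_s: np.ndarray,
    phi_t: np.ndarray,
    theta_ankle: np.ndarray,
) -> Dict[str, np.ndarray]:
    """Marker positions from an anchored ankle and the segment angles."""
    shank_len = 0.47 * subject.hip_height
    thigh_len = 0.53 * subject.hip_height
    lf = subject.foot_length
    n = phi_s.size
    psi_f = np.pi / 2.0 - phi_s - theta_ankle  # absolute foot axis angle
    # smooth heel-rise: the ankle lifts as the foot pitches toe-down so the
    # metatarsal head stays near the floor through late stance
    lift = 0.72 * lf * 0.5 * (-psi_f + np.sqrt(psi_f**2 + 0.01))
    ankle = np.column_stack([np.zeros(n), 0.08 + lift])
    knee = ankle + shank_len * np.column_stack([np.sin(phi_s), np.cos(phi_s)])
    hip = knee + thigh_len * np.column_stack([np.sin(phi_t), np.cos(phi_t)])
    mthead = ankle + 0.72 * lf * np.column_stack([np.cos(psi_f), np.sin(psi_f)])
    heel_dir = psi_f + np.pi + 1.0
    heel = ankle + 0.30 * lf * np.column_stack([np.cos(heel_dir), np.sin(heel_dir)])
    return {"hip": hip, "knee": knee, "ankle": ankle, "mthead": mthead, "heel": heel}


def _prescribed_angles(phi_s: np.ndarray, phi_t: np.ndarray,
                       theta_ankle: np.ndarray) -> Dict[str, np.ndarray]:
    """Included joint angles implied by the absolute segment angles."""
    return {
        "hip": np.abs(phi_t),
        "knee": np.pi - np.abs(phi_t - phi_s),
        "ankle": theta_ankle.copy(),
    }


# -- forward ground truth ----------------------------------------------------

_SEG_CHAIN = (
    ("foot", "ankle", -1.0),
    ("shank", "knee", 1.0),
    ("thigh", "hip", -1.0),
)
_SEG_POINTS = {"foot": ("ankle", "mthead"), "shank": ("knee", "ankle"), "thigh": ("hip", "knee")}


def _forward_moments(
    markers: Dict[str, np.ndarray],
    fz: np.ndarray,
    fx: np.ndarray,
    cop_x: np.ndarray,
    rate: float,
    inertia: SegmentInertia,
    body_mass: float,
) -> Dict[str, np.ndarray]:
    """Forward free-body construction of the net joint moments.

    Frame-by-frame Newton-Euler balance of each segment, distal to proximal,
    written independently of the vectorized inverse pipeline but from the
    same equations (the shared-equation oracle channel).
    """
    n = fz.size
    pre: Dict[str, dict] = {}
    for seg, (prox, dist) in _SEG_POINTS.items():
        par = inertia.params(seg)
        p, d = markers[prox], markers[dist]
        com = p + par.com_fraction * (d - p)
        length = float(np.median(np.hypot(*(d - p).T)))
        theta = np.unwrap(np.arctan2(d[:, 1] - p[:, 1], d[:, 0] - p[:, 0]))
        pre[seg] = {
            "mass": par.mass_fraction * body_mass,
            "moi": par.mass_fraction * body_mass * (par.gyration_fraction * length) ** 2,
            "com": com,
            "acom_x": finite_diff_accel(com[:, 0], rate),
            "acom_y": finite_diff_accel(com[:, 1], rate),
            "alpha": finite_diff_accel(theta, rate),
            "joint_point": markers[prox],
        }
    out = {joint: np.zeros(n) for _, joint, _ in _SEG_CHAIN}
    for i in range(n):
        fbx, fby = fx[i], fz[i]  # force on the current segment from below
        pbx, pby = cop_x[i], 0.0  # its point of application
        mb = 0.0  # moment from below
        for seg, joint, sign in _SEG_CHAIN:
            s = pre[seg]
            m, moi = s["mass"], s["moi"]
            cx, cy = s["com"][i]
            jx, jy = s["joint_point"][i]
            # Newton: joint force from the segment above
            fjx = m * s["acom_x"][i] - fbx
            fjy = m * s["acom_y"][i] + m * G - fby
            # Euler about the COM, expanded
            mj = (
                moi * s["alpha"][i]
                - ((jx - cx) * fjy - (jy - cy) * fjx)
                - ((pbx - cx) * fby - (pby - cy) * fbx)
                - mb
            )
            out[joint][i] = sign * mj
            fbx, fby = -fjx, -fjy
            pbx, pby = jx, jy
            mb = -mj
    return out


# -- trials ------------------------------------------------------------------

def _subject_index(subject_id: str) -> int:
    m = re.search(r"(\d+)$", subject_id)
    return int(m.group(1)) if m else 0


def generate_trial(
    subject: SubjectMorphometrics,
    gait: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    step_index: int = 0,
    config: Optional[PipelineConfig] = None,
) -> Tuple[TrialRecording, GroundTruth]:
    """Generate one trial (one support phase with swing padding) plus truth.

    The stance is constructed bottom-up: the ankle is anchored while the
    shank and thigh rotate over it with a monotone progression warp whose
    amplitude is solved so the hip marker travels at the Froude-drawn speed.
    The included ankle angle dorsiflexes then plantarflexes with an
    asymmetry parameter calibrated to a per-step ankle-SNW target; with
    effect injection that target shifts with the subject's AT moment arm at
    the injected gaits.
    """
    if gait not in GAIT_TABLE:
        raise ValidationError(f"unsupported gait label {gait!r}")
    par = GAIT_TABLE[gait]
    cfg = config or PipelineConfig()
    idx = _subject_index(subject.subject_id)

    froude = _trunc_normal(rng, par.froude_mean, par.froude_sd,
                           max(par.froude_mean - 2.0 * par.froude_sd, 0.02),
                           par.froude_mean + 2.0 * par.froude_sd)
    speed = math.sqrt(froude * G * subject.hip_height)
    duration = float(np.clip(par.stance_duration * (1.0 + 0.08 * rng.standard_normal()),
                             0.09, 1.1))

    # per-step ankle SNW target: base + subject offset + injected arm link +
    # step noise, composed on the logit scale so targets stay inside (0, 1)
    # without piling up at a clip boundary (which would destroy the injected
    # correlation at gaits with a high base value)
    z_arm = (subject.at_moment_arm - ARM_MEAN) / ARM_SD
    subj_offset = _child_rng(spec.seed, 7, idx).normal(0.0, spec.subject_snw_sd)
    inj = spec.effect_injection
    slope = inj.snw_slope_per_sd if (inj is not None and gait in inj.gaits) else 0.0
    shift = subj_offset + slope * z_arm + spec.step_snw_sd * rng.standard_normal()
    snw_target = float(expit(logit(par.snw_target) + par.snw_logit_offset + 4.0 * shift))
    cop_start = par.cop_start
    if inj is not None and gait in inj.gaits:
        cop_start = float(np.clip(par.cop_start - inj.cop_slope_per_sd * z_arm, 0.02, 0.60))
    asym = _asymmetry_for_snw(snw_target, par, cop_start)

    # time base: pads are whole kinematic frames so force frames stay aligned
    dt_k = 1.0 / spec.kinematic_rate
    pad_frames = int(round(spec.pad / dt_k))
    stance_frames = int(round(duration / dt_k))
    duration = stance_frames * dt_k
    n_k = 2 * pad_frames + stance_frames + 1
    t_k = np.arange(n_k) * dt_k
    t_touchdown = pad_frames * dt_k
    u_k = (t_k - t_touchdown) / duration

    shank_len = 0.47 * subject.hip_height
    thigh_len = 0.53 * subject.hip_height
    phi_s, phi_t, theta_ankle = _stance_segment_angles(
        par, u_k, shank_len, thigh_len, speed * duration, asym
    )
    markers = _build_markers(subject, phi_s, phi_t, theta_ankle)
    # realized progression speed (extreme draws are clamped by the geometry)
    speed = abs(markers["hip"][min(len(u_k) - 1, int(np.searchsorted(u_k, 1.0))), 0]
                - markers["hip"][int(np.searchsorted(u_k, 0.0)), 0]) / duration
    froude = speed**2 / (G * subject.hip_height)

    # forces at the force rate, embedded in swing-padded records
    ratio = int(round(spec.force_rate / spec.kinematic_rate))
    n_f = (n_k - 1) * ratio + 1
    t_f = np.arange(n_f) / spec.force_rate
    u_f = (t_f - t_touchdown) / duration
    in_stance_f = (u_f >= -1e-9) & (u_f <= 1.0 + 1e-9)
    fz_st, fx_st, cop_rel = generate_stance_grf(
        gait, subject.body_mass, duration, spec.force_rate, rng, subject.foot_length,
        cop_start=cop_start,
    )
    fz = np.zeros(n_f)
    fx = np.zeros(n_f)
    fz[in_stance_f] = fz_st[: int(in_stance_f.sum())]
    fx[in_stance_f] = fx_st[: int(in_stance_f.sum())]
    if inj is None:
        # null construction: tendon force made independent of the moment arm
        scale = subject.at_moment_arm / ARM_MEAN
        fz *= scale
        fx *= scale
    heel_ground_x = -0.04  # heel print relative to the anchored ankle
    cop_x = np.full(n_f, heel_ground_x + 0.5 * subject.foot_length)
    cop_x[in_stance_f] = heel_ground_x + cop_rel[: int(in_stance_f.sum())]

    # ground truth from the noise-free construction
    fz_k, fx_k, cop_k = fz[::ratio], fx[::ratio], cop_x[::ratio]
    truth_moments = _forward_moments(
        markers, fz_k, fx_k, cop_k, spec.kinematic_rate, cfg.inertia, subject.body_mass
    )
    angles = _prescribed_angles(phi_s, phi_t, theta_ankle)
    arms = cfg.moment_arms.for_subject(subject.at_moment_arm, subject.hip_height)
    r_ankle = arms.evaluate("ankle", angles["ankle"])
    ankle_force = truth_moments["ankle"] / r_ankle

    s0 = int(np.searchsorted(u_k, -1e-9))
    s1 = int(np.searchsorted(u_k, 1.0 + 1e-9, side="right"))
    win = StanceInterval(s0, s1, 1.0)
    impulse = trapz_integral(ankle_force, spec.kinematic_rate, win)
    mean_force = max(impulse / win.duration(spec.kinematic_rate), 0.0)
    stress = mean_force / subject.tendon_csa
    constants: TendonConstants = cfg.tendon
    _, dl = tendon_strain_and_dl(max(stress, 0.0), constants, subject.tendon_length)
    energy = strain_energy(mean_force, dl, constants)

    truth = GroundTruth(
        moments=truth_moments,
        ankle_force=ankle_force,
        angles=angles,
        stance_start=s0,
        stance_end=s1,
        speed=speed,
        froude=froude,
        stored_energy=energy,
        snw_target=snw_target,
    )

    noisy_markers = {k: v.copy() for k, v in markers.items()}
    if spec.marker_noise_sd > 0:
        for v in noisy_markers.values():
            v += rng.normal(0.0, spec.marker_noise_sd, size=v.shape)
    fz_n, fx_n = fz.copy(), fx.copy()
    if spec.force_noise_sd > 0:
        fz_n += rng.normal(0.0, spec.force_noise_sd, size=n_f)
        fx_n += rng.normal(0.0, spec.force_noise_sd, size=n_f)

    trial = TrialRecording(
        subject_id=subject.subject_id,
        gait_label=gait,
        kinematic_rate=spec.kinematic_rate,
        force_rate=spec.force_rate,
        time_kinematic=t_k,
        markers=noisy_markers,
        time_force=t_f,
        fz=fz_n,
        fx=fx_n,
        cop_x=cop_x.copy(),
    )
    return trial, truth


def generate_cohort(
    spec: CohortSpec,
    config: Optional[PipelineConfig] = None,
) -> Tuple[List[TrialRecording], List[GroundTruth], List[SubjectMorphometrics]]:
    """Generate the full cohort: one trial per subject x gait x step.

    Randomness is counter-derived from the master seed per subject / gait /
    step, so regeneration is bit-identical and independent of order.
    """
    subjects = [generate_subject(spec, i) for i in range(spec.n_subjects)]
    trials: List[TrialRecording] = []
    truths: List[GroundTruth] = []
    for i, subject in enumerate(subjects):
        for gi, gait in enumerate(spec.gaits):
            for step in range(spec.steps_per_gait):
                rng = _child_rng(spec.seed, 2, i, gi, step)
                trial, truth = generate_trial(subject, gait, spec, rng,
                                              step_index=step, config=config)
                trials.append(trial)
                truths.append(truth)
    return trials, truths, subjects


def generate_static_trial(
    subject: SubjectMorphometrics,
    duration: float = 0.5,
    cop_offset: float = 0.05,
    kinematic_rate: float = 500.0,
    force_rate: float = 1000.0,
    inertia: Optional[SegmentInertia] = None,
) -> Tuple[TrialRecording, GroundTruth]:
    """A stationary standing "trial": constant posture, GRF = m g at a fixed COP.

    In the weightless-linkage limit (vanishing segment mass fractions, the
    default here) static equilibrium gives the exact identity
    M_ankle = fz * (COP_x - ankle_x) at every frame, which isolates the GRF
    pathway of the free-body recursion.
    """
    inertia = inertia or massless_inertia()
    n_k = int(round(duration * kinematic_rate)) + 1
    t_k = np.arange(n_k) / kinematic_rate
    phi_s = np.full(n_k, 0.0)
    phi_t = np.full(n_k, 0.05)  # slight hip flexion avoids a degenerate knee
    theta = np.full(n_k, np.pi / 2.0)
    markers = _build_markers(subject, phi_s, phi_t, theta)
    ratio = int(round(force_rate / kinematic_rate))
    n_f = (n_k - 1) * ratio + 1
    t_f = np.arange(n_f) / force_rate
    fz = np.full(n_f, subject.body_mass * G)
    fx = np.zeros(n_f)
    cop_x = np.full(n_f, cop_offset)  # ankle anchored at x = 0
    moments = _forward_moments(markers, fz[::ratio], fx[::ratio], cop_x[::ratio],
                               kinematic_rate, inertia, subject.body_mass)
    angles = _prescribed_angles(phi_s, phi_t, theta)
    trial = TrialRecording(
        subject_id=subject.subject_id, gait_label="walk",
        kinematic_rate=kinematic_rate, force_rate=force_rate,
        time_kinematic=t_k, markers=markers, time_force=t_f,
        fz=fz, fx=fx, cop_x=cop_x,
    )
    truth = GroundTruth(
        moments=moments, ankle_force=np.zeros(n_k), angles=angles,
        stance_start=0, stance_end=n_k, speed=0.0, froude=0.0,
        stored_energy=0.0, snw_target=0.0,
    )
    return trial, truth


def massless_inertia(mass_fraction: float = 1e-12) -> SegmentInertia:
    """Near-massless segment table: the weightless-linkage statics limit."""
    p = SegmentParams(mass_fraction, 0.5, 0.3)
    return SegmentInertia(foot=p, shank=p, thigh=p)
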
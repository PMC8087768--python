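"""Planar (sagittal) link-segment inverse dynamics of the lower limb.

Computes joint angles from markers, net joint moments by the distal-to-
proximal free-body recursion (foot -> shank -> thigh), extensor muscle
forces from the net moments with bi-articular flexor corrections, the
impulse-averaged external moment arm of the GRF at the ankle, joint power
and its positive/negative work decomposition, and Froude numbers.

Conventions
-----------
* 2D sagittal plane: x fore-aft (+ = travel direction), y vertical (+ = up);
  scalar moments are the z-component (counter-clockwise positive) remapped so
  that *extensor* (plantarflexor at the ankle) net moments are positive.
* Angles are radians internally.  Joint angles are included angles between
  adjacent segment vectors: a straight knee is pi (180 deg), the neutral
  ankle (shank perpendicular to foot) is pi/2 (90 deg).  The hip angle is
  the included angle between the downward vertical and the hip->knee vector
  (0 = thigh vertical), standing in for a trunk segment that carries no
  marker.
* Mediolateral forces are ignored; g = 9.81 m/s^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np

from .exceptions import UndefinedResultError, ValidationError
from .signal_processing import (
    StanceInterval,
    finite_diff_accel,
    finite_diff_velocity,
    trapz_integral,
)

log = logging.getLogger(__name__)

G = 9.81  # m/s^2

JOINTS = ("hip", "knee", "ankle")
SEGMENTS = ("foot", "shank", "thigh")

# segment -> (proximal marker, distal marker)
SEGMENT_MARKERS: Mapping[str, Tuple[str, str]] = {
    "foot": ("ankle", "mthead"),
    "shank": ("knee", "ankle"),
    "thigh": ("hip", "knee"),
}

# Reported net moments are "extensor positive".  The raw recursion yields the
# counter-clockwise moment exerted on the distal segment by the proximal one;
# plantarflexion (ankle) and hip extension rotate their segment clockwise for
# travel in +x, so those two flip sign.
_REPORT_SIGN = {"ankle": -1.0, "knee": 1.0, "hip": -1.0}


@dataclass(frozen=True)
class SegmentParams:
    """One segment's inertial parameters as fractions of body mass / length."""

    mass_fraction: float
    com_fraction: float  # COM position from the proximal end, fraction of length
    gyration_fraction: float  # radius of gyration about the COM, fraction of length

    def __post_init__(self) -> None:
        for name in ("mass_fraction", "com_fraction", "gyration_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"segment {name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class SegmentInertia:
    """Winter-style anthropometric proportions for foot, shank and thigh."""

    foot: SegmentParams = field(default_factory=lambda: SegmentParams(0.0145, 0.50, 0.475))
    shank: SegmentParams = field(default_factory=lambda: SegmentParams(0.0465, 0.433, 0.302))
    thigh: SegmentParams = field(default_factory=lambda: SegmentParams(0.100, 0.433, 0.323))

    def __post_init__(self) -> None:
        total = self.foot.mass_fraction + self.shank.mass_fraction + self.thigh.mass_fraction
        if total >= 1.0:
            raise ValidationError(f"segment mass fractions must sum to < 1, got {total}")

    def params(self, segment: str) -> SegmentParams:
        return getattr(self, segment)


@dataclass(frozen=True)
class PcsaPartition:
    """Bi-articular force fractions by physiological cross-sectional area.

    ``gastroc`` is the gastrocnemius share of total plantarflexor force,
    ``hamstrings`` the hamstring share of hip-extensor force, and
    ``rectus_femoris`` the RF share of knee-extensor force.
    """

    gastroc: float = 0.35
    hamstrings: float = 0.40
    rectus_femoris: float = 0.25

    def __post_init__(self) -> None:
        for name in ("gastroc", "hamstrings", "rectus_femoris"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"PCSA fraction {name} must be in [0, 1), got {v}")


# Default extensor moment-arm polynomials, metres, as functions of the joint
# angle (rad) about a per-joint reference angle.  Values follow published
# cadaver/imaging regressions for the ankle plantarflexors and the hip/knee
# extensors; they are deliberately exposed in config because the exact
# regression choice is a swappable literature dependence, scaled linearly to
# each subject (measured AT moment arm at the ankle, hip height elsewhere).
_ANKLE_REF = np.pi / 2  # neutral ankle
_KNEE_REF = 2.35  # ~135 deg
_HIP_REF = 0.0


@dataclass(frozen=True)
class MomentArmModel:
    """Per-joint extensor moment arms r(angle) as polynomials, subject-scaled."""

    ankle_coeffs: Tuple[float, ...] = (0.0427, 0.008, -0.010)
    knee_coeffs: Tuple[float, ...] = (0.040, 0.008, -0.006)
    hip_coeffs: Tuple[float, ...] = (0.060, 0.015)
    gastroc_knee_coeffs: Tuple[float, ...] = (0.020,)
    hamstrings_knee_coeffs: Tuple[float, ...] = (0.025,)
    rectus_femoris_hip_coeffs: Tuple[float, ...] = (0.035,)
    ankle_scale: float = 1.0
    knee_scale: float = 1.0
    hip_scale: float = 1.0

    _COEFF_ATTR = {
        "ankle": ("ankle_coeffs", _ANKLE_REF, "ankle_scale"),
        "knee": ("knee_coeffs", _KNEE_REF, "knee_scale"),
        "hip": ("hip_coeffs", _HIP_REF, "hip_scale"),
        "gastroc_knee": ("gastroc_knee_coeffs", _KNEE_REF, "knee_scale"),
        "hamstrings_knee": ("hamstrings_knee_coeffs", _KNEE_REF, "knee_scale"),
        "rectus_femoris_hip": ("rectus_femoris_hip_coeffs", _HIP_REF, "hip_scale"),
    }

    def evaluate(self, name: str, angle: np.ndarray) -> np.ndarray:
        """Moment arm (m) at ``angle`` (rad) for joint or bi-articular path ``name``."""
        attr, ref, scale_attr = self._COEFF_ATTR[name]
        coeffs = getattr(self, attr)
        scale = getattr(self, scale_attr)
        d = np.asarray(angle, dtype=float) - ref
        r = np.zeros_like(d)
        for k, c in enumerate(coeffs):
            r = r + c * d**k
        return scale * r

    def for_subject(self, at_moment_arm: float, hip_height: float,
                    reference_hip_height: float = 0.88) -> "MomentArmModel":
        """Scale the model to one subject.

        The ankle polynomial is anchored so that at the neutral angle it
        equals the subject's measured (static) AT moment arm; hip and knee
        arms scale linearly with hip height.
        """
        if at_moment_arm <= 0 or hip_height <= 0:
            raise ValidationError("subject scaling requires positive moment arm and hip height")
        return replace(
            self,
            ankle_scale=at_moment_arm / self.ankle_coeffs[0],
            knee_scale=hip_height / reference_hip_height,
            hip_scale=hip_height / reference_hip_height,
        )


@dataclass
class StanceStep:
    """One support phase: synchronized kinematics and kinetics at one rate."""

    subject_id: str
    gait_label: str
    step_index: int
    rate: float  # Hz
    markers: Dict[str, np.ndarray]  # name -> (N, 2) positions, m
    fz: np.ndarray  # vertical GRF, N
    fx: np.ndarray  # fore-aft GRF, N
    cop_x: np.ndarray  # centre of pressure, m

    @property
    def n_frames(self) -> int:
        return int(self.fz.size)

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate

    def window(self) -> StanceInterval:
        return StanceInterval(0, self.n_frames, threshold=1.0)


@dataclass
class JointKinetics:
    """Per-joint stance time series and integral summaries."""

    rate: float
    moments: Dict[str, np.ndarray]  # N*m, extensor positive
    forces: Dict[str, np.ndarray]  # N, extensor muscle-group force
    angles: Dict[str, np.ndarray]  # rad
    angular_velocity: Dict[str, np.ndarray]  # rad/s
    power: Dict[str, np.ndarray]  # W
    work_pos: Dict[str, float]  # J
    work_neg: Dict[str, float]  # J
    force_impulse: Dict[str, float]  # N*s
    grf_impulse: float  # N*s, resultant GRF magnitude integral J
    r_ankle_series: np.ndarray  # instantaneous AT moment arm, m
    r_ankle_external: float  # impulse-averaged external arm R_Ankle, m


def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """z-component of the 2D cross product r x f."""
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


def joint_angles(markers: Mapping[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Included joint angles (rad) from marker positions.

    knee: angle between knee->hip and knee->ankle (straight leg = pi);
    ankle: angle between ankle->knee and ankle->mthead (neutral = pi/2);
    hip: angle between the downward vertical and hip->knee (thigh vertical = 0).
    """
    required = ("hip", "knee", "ankle", "mthead")
    for name in required:
        if name not in markers:
            raise ValidationError(f"missing marker {name!r}")

    def _vec(a: str, b: str) -> np.ndarray:
        v = np.asarray(markers[b], float) - np.asarray(markers[a], float)
        norms = np.hypot(v[:, 0], v[:, 1])
        bad = np.nonzero(norms < 1e-12)[0]
        if bad.size:
            raise ValidationError(
                f"degenerate zero-length segment {a}->{b} at frame {int(bad[0])}"
            )
        return v / norms[:, None]

    def _included(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.arccos(np.clip(np.sum(u * v, axis=1), -1.0, 1.0))

    thigh_down = _vec("hip", "knee")
    shank_up = _vec("knee", "hip")
    shank_down = _vec("knee", "ankle")
    foot_fwd = _vec("ankle", "mthead")
    ankle_up = _vec("ankle", "knee")

    vertical_down = np.zeros_like(thigh_down)
    vertical_down[:, 1] = -1.0

    return {
        "hip": _included(vertical_down, thigh_down),
        "knee": _included(shank_up, shank_down),
        "ankle": _included(ankle_up, foot_fwd),
    }


def segment_kinematics(
    markers: Mapping[str, np.ndarray],
    rate: float,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-segment COM path/acceleration and orientation angle/angular accel.

    COM fractions are not applied here; the caller positions the COM from the
    proximal marker using SegmentInertia.  This helper returns the raw
    endpoint series, unwrapped orientation angles, and their second
    derivatives by the same finite-difference stencils the rest of the
    pipeline uses.
    """
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for seg, (prox, dist) in SEGMENT_MARKERS.items():
        p = np.asarray(markers[prox], float)
        d = np.asarray(markers[dist], float)
        v = d - p
        length = np.hypot(v[:, 0], v[:, 1])
        theta = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
        out[seg] = {
            "prox": p,
            "dist": d,
            "length": length,
            "theta": theta,
            "alpha": finite_diff_accel(theta, rate),
        }
    return out


def net_joint_moments(
    step: StanceStep,
    inertia: SegmentInertia,
    body_mass: float,
    cop_warning_margin: float = 0.05,
) -> Dict[str, np.ndarray]:
    """Net joint moments (N*m, extensor positive) by free-body recursion.

    The recursion runs distal to proximal: the foot free body carries the
    GRF at the COP, the foot weight and the foot inertial terms and yields
    the ankle moment; the shank and thigh follow with the reaction of the
    joint below.  Mediolateral forces are ignored (planar model).
    """
    markers = step.markers
    n = step.n_frames
    segs = segment_kinematics(markers, step.rate)

    # COP sanity: warn (never fail) when the COP strays far outside the foot
    foot_x = np.stack([markers["heel"][:, 0], markers["mthead"][:, 0]]) if "heel" in markers else \
        np.stack([markers["ankle"][:, 0], markers["mthead"][:, 0]])
    lo, hi = foot_x.min(axis=0), foot_x.max(axis=0)
    outside = np.maximum(lo - step.cop_x, step.cop_x - hi)
    if np.any(outside > cop_warning_margin):
        frame = int(np.argmax(outside > cop_warning_margin))
        log.warning(
            "COP outside foot-marker span by more than %.0f cm at frame %d",
            cop_warning_margin * 100.0, frame,
        )

    grf = np.column_stack([step.fx, step.fz])  # (N, 2)
    cop = np.column_stack([step.cop_x, np.zeros(n)])
    g_vec = np.array([0.0, -G])

    moments: Dict[str, np.ndarray] = {}
    # force/moment exerted on the current segment by the segment below it
    # (for the foot: the ground)
    f_below = grf
    m_below = np.zeros(n)
    p_below = cop  # point of application of f_below

    joint_of_segment = {"foot": "ankle", "shank": "knee", "thigh": "hip"}
    for seg in ("foot", "shank", "thigh"):
        par = inertia.params(seg)
        sk = segs[seg]
        m_seg = par.mass_fraction * body_mass
        length = float(np.median(sk["length"]))
        com = sk["prox"] + par.com_fraction * (sk["dist"] - sk["prox"])
        a_com = np.column_stack(
            [finite_diff_accel(com[:, 0], step.rate), finite_diff_accel(com[:, 1], step.rate)]
        )
        inertia_moi = m_seg * (par.gyration_fraction * length) ** 2
        joint = joint_of_segment[seg]
        p_joint = sk["prox"] if seg != "foot" else np.asarray(markers["ankle"], float)

        # joint force on this segment from above (Newton)
        f_joint = m_seg * a_com - m_seg * g_vec[None, :] - f_below
        # joint moment on this segment from above (Euler, about the COM)
        m_joint = (
            inertia_moi * sk["alpha"]
            - _cross2(p_joint - com, f_joint)
            - _cross2(p_below - com, f_below)
            - m_below
        )
        moments[joint] = _REPORT_SIGN[joint] * m_joint
        # reaction on the segment above
        f_below = -f_joint
        m_below = -m_joint
        p_below = p_joint
    return moments


def muscle_forces(
    moments: Mapping[str, np.ndarray],
    angles: Mapping[str, np.ndarray],
    arms: MomentArmModel,
    pcsa: PcsaPartition,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Extensor muscle-group forces from net moments with bi-articular terms.

    The ankle is mono-articular in the model: F_ankle = M_ankle / r_ankle.
    The gastrocnemius fraction of the plantarflexor force flexes the knee,
    the hamstring fraction of the hip-extensor force flexes the knee, and
    the rectus femoris fraction of the knee-extensor force flexes the hip:

        M_knee = F_knee r_knee - F_G r_G,knee - F_H r_H,knee
        M_hip  = F_hip  r_hip  - F_RF r_RF,hip

    With F_G = c_G F_ankle, F_H = c_H F_hip and F_RF = c_RF F_knee this is a
    linear 2x2 system in (F_knee, F_hip) per frame, solved in closed form.

    Returns ``(forces, r_series)`` where ``r_series`` holds the evaluated
    moment arms per joint (the ankle entry is the instantaneous AT arm).
    """
    r: Dict[str, np.ndarray] = {}
    for joint in JOINTS:
        rj = arms.evaluate(joint, np.asarray(angles[joint], float))
        bad = np.nonzero(rj <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"non-positive extensor moment arm at joint {joint!r}, frame {int(bad[0])}"
            )
        r[joint] = rj

    m_a = np.asarray(moments["ankle"], float)
    m_k = np.asarray(moments["knee"], float)
    m_h = np.asarray(moments["hip"], float)

    f_ankle = m_a / r["ankle"]
    f_g = pcsa.gastroc * f_ankle
    r_gk = arms.evaluate("gastroc_knee", angles["knee"])
    r_hk = arms.evaluate("hamstrings_knee", angles["knee"])
    r_rfh = arms.evaluate("rectus_femoris_hip", angles["hip"])

    # [ r_knee              , -c_H r_H,knee ] [F_knee]   [M_knee + F_G r_G,knee]
    # [ -c_RF r_RF,hip      ,  r_hip        ] [F_hip ] = [M_hip                ]
    det = r["knee"] * r["hip"] - pcsa.hamstrings * r_hk * pcsa.rectus_femoris * r_rfh
    if np.any(np.abs(det) < 1e-12):
        raise ValidationError("singular bi-articular moment-arm system")
    b1 = m_k + f_g * r_gk
    f_knee = (b1 * r["hip"] + pcsa.hamstrings * r_hk * m_h) / det
    f_hip = (m_h * r["knee"] + pcsa.rectus_femoris * r_rfh * b1) / det

    return {"ankle": f_ankle, "knee": f_knee, "hip": f_hip}, r


def external_moment_arm_ankle(
    grf_magnitude: np.ndarray,
    r_ankle: np.ndarray,
    f_ankle: np.ndarray,
    rate: float,
    window: StanceInterval | None = None,
) -> float:
    """Impulse-averaged external moment arm of the GRF at the ankle.

    R_Ankle = integral(GRF * r_ankle dt) / integral(F_ankle dt) over stance,
    where GRF is the resultant ground-reaction-force magnitude, r_ankle the
    instantaneous AT moment arm and F_ankle the plantarflexor muscle force.
    """
    num = trapz_integral(np.asarray(grf_magnitude, float) * np.asarray(r_ankle, float), rate, window)
    den = trapz_integral(np.asarray(f_ankle, float), rate, window)
    if abs(den) < 1e-12:
        raise UndefinedResultError("zero ankle force impulse: external moment arm undefined")
    return num / den


def joint_power_work(
    moment: np.ndarray,
    angular_velocity: np.ndarray,
    rate: float,
    window: StanceInterval | None = None,
) -> Tuple[np.ndarray, float, float]:
    """Joint power M*omega and its positive / negative work decomposition.

    Work_pos integrates the positive part of power, Work_neg the negative
    part, so Work_pos + Work_neg equals the integral of power exactly
    (trapezoid rule is linear).
    """
    power = np.asarray(moment, float) * np.asarray(angular_velocity, float)
    wpos = trapz_integral(np.maximum(power, 0.0), rate, window)
    wneg = trapz_integral(np.minimum(power, 0.0), rate, window)
    return power, wpos, wneg


def froude_number(speed: float, hip_height: float) -> float:
    """Dimensionless Froude number v^2 / (g * hip height)."""
    if speed <= 0 or hip_height <= 0:
        raise ValidationError(
            f"froude_number requires positive inputs, got speed={speed}, hip_height={hip_height}"
        )
    return speed**2 / (G * hip_height)


def angular_velocities(angles: Mapping[str, np.ndarray], rate: float) -> Dict[str, np.ndarray]:
    """Joint angular velocities by first-order central differences."""
    return {j: finite_diff_velocity(np.asarray(a, float), rate) for j, a in angles.items()}
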
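"""Delimited-text trial formats, subject configuration, and result tables.

On-disk dialect: tab-delimited UTF-8 with "." decimals and a single header
line.  Units on disk are SI (m, N, kg, s); morphometrics may declare cm /
cm^2 and are converted on read.  The time column is authoritative for the
sampling rate and must be uniform to 1e-9 s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError
from .tendon_mechanics import TendonOutcome

GAITS = ("walk", "fast_walk", "jog", "run", "sprint")
REQUIRED_MARKERS = ("hip", "knee", "ankle", "mthead", "heel")
FORCE_COLUMNS = ("time", "fz", "fx", "cop_x")

RESULT_COLUMNS = (
    "subject_id", "gait", "step_index", "froude", "snw_hip", "snw_knee",
    "snw_ankle", "force_impulse", "r_ankle_ext", "stress_mean", "stress_peak",
    "strain", "delta_l", "energy", "energy_per_kg", "stress_mean_per_kg",
)

_CSA_SANITY_BOUND = 5e-4  # m^2; anything larger is not a human Achilles tendon


@dataclass(frozen=True)
class SubjectMorphometrics:
    """Per-subject measured scalars, SI units."""

    subject_id: str
    sex: str  # "M" or "F"
    body_mass: float  # kg
    hip_height: float  # m
    foot_length: float  # m
    at_moment_arm: float  # m, static AT moment arm
    tendon_csa: float  # m^2
    tendon_length: float  # m, resting length

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"subject {self.subject_id}: sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("body_mass", "hip_height", "foot_length", "at_moment_arm",
                     "tendon_csa", "tendon_length"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"subject {self.subject_id}: {name} must be strictly positive, got {v}")
        if self.at_moment_arm >= self.foot_length:
            raise ValidationError(
                f"subject {self.subject_id}: at_moment_arm ({self.at_moment_arm} m) must be "
                f"smaller than foot_length ({self.foot_length} m)"
            )
        if self.tendon_csa >= _CSA_SANITY_BOUND:
            raise ValidationError(
                f"subject {self.subject_id}: tendon_csa {self.tendon_csa} m^2 exceeds the "
                f"sanity bound {_CSA_SANITY_BOUND} m^2"
            )


@dataclass
class TrialRecording:
    """Synchronized marker and force-plate series for one pass at one gait."""

    subject_id: str
    gait_label: str
    kinematic_rate: float  # Hz
    force_rate: float  # Hz
    time_kinematic: np.ndarray  # (Nk,)
    markers: Dict[str, np.ndarray]  # name -> (Nk, 2) positions, m
    time_force: np.ndarray  # (Nf,)
    fz: np.ndarray  # vertical GRF, N
    fx: np.ndarray  # fore-aft GRF, N
    cop_x: np.ndarray  # centre-of-pressure x, m

    def __post_init__(self) -> None:
        if self.gait_label not in GAITS:
            raise ValidationError(f"unknown gait label {self.gait_label!r}; expected one of {GAITS}")
        ratio = self.force_rate / self.kinematic_rate
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValidationError(
                f"force rate {self.force_rate} Hz must be an integer multiple of the "
                f"kinematic rate {self.kinematic_rate} Hz"
            )
        for name in REQUIRED_MARKERS:
            if name not in self.markers:
                raise ValidationError(f"missing required marker {name!r}")
        nk = self.time_kinematic.size
        for name, arr in self.markers.items():
            if arr.shape != (nk, 2):
                raise ValidationError(f"marker {name!r} has shape {arr.shape}, expected ({nk}, 2)")
        nf = self.time_force.size
        for name in ("fz", "fx", "cop_x"):
            if getattr(self, name).size != nf:
                raise ValidationError(f"force column {name!r} length mismatch")
        dur_k = (nk - 1) / self.kinematic_rate
        dur_f = (nf - 1) / self.force_rate
        if abs(dur_k - dur_f) > 1.0 / self.force_rate + 1e-9:
            raise ValidationError(
                f"marker and force durations differ by more than one force frame "
                f"({dur_k:.6f} s vs {dur_f:.6f} s)"
            )


def _check_uniform_time(t: np.ndarray, path: str) -> float:
    """Validate a monotone, uniform time column; return the sampling rate."""
    if t.size < 2:
        raise FormatError(f"{path}: time column needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        idx = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise FormatError(f"{path}: time column not monotone increasing at row {idx}")
    step = float(dt[0])
    bad = np.nonzero(np.abs(dt - step) > 1e-9)[0]
    if bad.size:
        raise FormatError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 1} "
            f"(step {dt[bad[0]]:.9g} s, expected {step:.9g} s)"
        )
    return 1.0 / step


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse tab-delimited table: {exc}") from exc


def read_trial(marker_path: str | Path, force_path: str | Path,
               meta: Mapping[str, str]) -> TrialRecording:
    """Read one trial from a marker file and a force file.

    ``meta`` must carry ``subject_id`` and ``gait_label``.  Marker files have
    columns ``time, <name>_x, <name>_y, ...``; force files ``time, fz, fx,
    cop_x``.  Missing columns and non-uniform sampling raise
    :class:`FormatError` naming the offender.
    """
    mdf = _read_table(marker_path)
    if "time" not in mdf.columns:
        raise FormatError(f"{marker_path}: missing required column 'time'")
    names = sorted({re.sub(r"_(x|y)$", "", c) for c in mdf.columns if c != "time"})
    for name in REQUIRED_MARKERS:
        for axis in ("x", "y"):
            col = f"{name}_{axis}"
            if col not in mdf.columns:
                raise FormatError(f"{marker_path}: missing required column '{col}'")
    markers = {}
    for name in names:
        if f"{name}_x" in mdf.columns and f"{name}_y" in mdf.columns:
            markers[name] = np.column_stack(
                [mdf[f"{name}_x"].to_numpy(float), mdf[f"{name}_y"].to_numpy(float)]
            )
    t_k = mdf["time"].to_numpy(float)
    kin_rate = _check_uniform_time(t_k, str(marker_path))

    fdf = _read_table(force_path)
    for col in FORCE_COLUMNS:
        if col not in fdf.columns:
            raise FormatError(f"{force_path}: missing required column '{col}'")
    t_f = fdf["time"].to_numpy(float)
    force_rate = _check_uniform_time(t_f, str(force_path))

    return TrialRecording(
        subject_id=str(meta["subject_id"]),
        gait_label=str(meta["gait_label"]),
        kinematic_rate=kin_rate,
        force_rate=force_rate,
        time_kinematic=t_k,
        markers=markers,
        time_force=t_f,
        fz=fdf["fz"].to_numpy(float),
        fx=fdf["fx"].to_numpy(float),
        cop_x=fdf["cop_x"].to_numpy(float),
    )


def write_trial(trial: TrialRecording, marker_path: str | Path,
                force_path: str | Path) -> None:
    """Write a trial in the same dialect :func:`read_trial` consumes."""
    cols: Dict[str, np.ndarray] = {"time": trial.time_kinematic}
    for name in sorted(trial.markers):
        cols[f"{name}_x"] = trial.markers[name][:, 0]
        cols[f"{name}_y"] = trial.markers[name][:, 1]
    pd.DataFrame(cols).to_csv(marker_path, sep="\t", index=False, float_format="%.12g")
    pd.DataFrame({
        "time": trial.time_force, "fz": trial.fz, "fx": trial.fx, "cop_x": trial.cop_x,
    }).to_csv(force_path, sep="\t", index=False, float_format="%.12g")


# -- subject configuration ---------------------------------------------------

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}
_AREA_UNITS = {"m^2": 1.0, "m2": 1.0, "cm^2": 1e-4, "cm2": 1e-4}
_FIELD_KIND = {
    "body_mass": "mass", "hip_height": "length", "foot_length": "length",
    "at_moment_arm": "length", "tendon_csa": "area", "tendon_length": "length",
}


def _convert(subject_id: str, field_name: str, raw: object) -> float:
    """Convert a config value to SI.  Bare numbers are taken as SI; a declared
    unit (``"4.27 cm"`` or ``{value: 4.27, unit: cm}``) is converted."""
    kind = _FIELD_KIND[field_name]
    if isinstance(raw, (int, float)):
        return float(raw)
    if isinstance(raw, Mapping):
        value, unit = raw.get("value"), raw.get("unit")
    elif isinstance(raw, str):
        parts = raw.split()
        if len(parts) != 2:
            raise ValidationError(f"subject {subject_id}: cannot parse {field_name} value {raw!r}")
        value, unit = parts
    else:
        raise ValidationError(f"subject {subject_id}: cannot parse {field_name} value {raw!r}")
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"subject {subject_id}: non-numeric {field_name} value {raw!r}") from exc
    units = {"length": _LENGTH_UNITS, "area": _AREA_UNITS, "mass": {"kg": 1.0}}[kind]
    if unit not in units:
        raise ValidationError(
            f"subject {subject_id}: unit {unit!r} not allowed for {field_name} (allowed: {sorted(units)})"
        )
    return value * units[unit]


def read_subject_config(path: str | Path) -> List[SubjectMorphometrics]:
    """Read per-subject morphometrics from a YAML document.

    Layout: a top-level ``subjects`` list, one mapping per subject.  Values
    are SI unless a unit is declared (cm and cm^2 accepted for lengths and
    areas).  Invariant violations raise :class:`ValidationError` naming the
    subject and field.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping) or "subjects" not in doc:
        raise FormatError(f"{path}: expected a mapping with a 'subjects' list")
    out = []
    for block in doc["subjects"]:
        sid = str(block.get("subject_id", "<missing id>"))
        kwargs = {"subject_id": sid, "sex": str(block.get("sex", ""))}
        for field_name in _FIELD_KIND:
            if field_name not in block:
                raise ValidationError(f"subject {sid}: missing field {field_name}")
            kwargs[field_name] = _convert(sid, field_name, block[field_name])
        out.append(SubjectMorphometrics(**kwargs))
    return out


def write_subject_config(subjects: Sequence[SubjectMorphometrics], path: str | Path) -> None:
    doc = {"subjects": [asdict(s) for s in subjects]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# -- result tables -----------------------------------------------------------

def outcomes_to_frame(outcomes: Sequence[TendonOutcome]) -> pd.DataFrame:
    df = pd.DataFrame([o.as_dict() for o in outcomes])
    return df[list(RESULT_COLUMNS)]


def write_results(outcomes: Sequence[TendonOutcome], path: str | Path) -> None:
    """Write a per-step result table, one row per support phase.

    Columns are fixed (see ``RESULT_COLUMNS``); floats are written with 12
    significant digits so the table round-trips to 1e-10 relative.
    """
    if not outcomes:
        raise ValidationError("cannot write an empty result table")
    outcomes_to_frame(outcomes).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing result columns {sorted(missing)}")
    return df


def results_to_outcomes(df: pd.DataFrame) -> List[TendonOutcome]:
    return [
        TendonOutcome(**{
            **row, "subject_id": str(row["subject_id"]), "gait": str(row["gait"]),
            "step_index": int(row["step_index"]),
        })
        for row in df[list(RESULT_COLUMNS)].to_dict("records")
    ]
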
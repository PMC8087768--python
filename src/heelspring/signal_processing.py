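"""Filtering, resampling, differentiation, stance detection, integration.

All series are uniformly sampled 1-D arrays.  Conventions follow standard
gait-lab practice: zero-lag (forward-backward) Butterworth low-pass
smoothing of kinematic and force channels, second-order finite differences
for accelerations, and a vertical-force threshold rule for support-phase
(stance) detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import signal as _sig

from .exceptions import ValidationError

__all__ = [
    "FilterSpec",
    "StanceInterval",
    "zero_lag_butterworth",
    "downsample_force",
    "finite_diff_accel",
    "detect_stance",
    "trapz_integral",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter description.

    ``order`` is the *effective* (reported) order of the zero-lag filter.
    By the common gait-lab convention a "fourth-order zero-lag" filter is a
    second-order pass run forward and backward, which doubles the magnitude
    response order.  Set ``order_is_per_pass=True`` to apply ``order`` in
    each direction instead.
    """

    order: int = 4
    cutoff: float = 6.0  # Hz
    kind: str = "lowpass"
    zero_lag: bool = True
    order_is_per_pass: bool = False

    def __post_init__(self) -> None:
        if self.order <= 0 or self.order % 2 != 0:
            raise ValidationError(f"filter order must be a positive even integer, got {self.order}")
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")
        if self.kind != "lowpass":
            raise ValidationError(f"only lowpass filters are supported, got {self.kind!r}")

    def design_order(self) -> int:
        """Per-pass order handed to the filter design routine."""
        if self.order_is_per_pass or not self.zero_lag:
            return self.order
        return self.order // 2


@dataclass(frozen=True)
class StanceInterval:
    """Half-open frame window ``[start_frame, end_frame)`` of one support phase."""

    start_frame: int
    end_frame: int
    threshold: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValidationError(
                f"stance interval must satisfy end > start, got [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration(self, rate: float) -> float:
        """Stance duration in seconds at sampling ``rate`` (trapezoid support)."""
        return (self.n_frames - 1) / rate

    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame)


def zero_lag_butterworth(x: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply a zero-lag Butterworth low-pass filter to a uniform series.

    The forward-backward application (``scipy.signal.filtfilt``) cancels
    phase distortion, so a symmetric pulse keeps its peak frame and the DC
    gain is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    min_len = 3 * spec.order
    if x.size < min_len:
        raise ValidationError(
            f"series too short for filtering: length {x.size} < minimum {min_len} (3x filter order)"
        )
    nyquist = rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValidationError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz")
    b, a = _sig.butter(spec.design_order(), spec.cutoff / nyquist, btype="low")
    if spec.zero_lag:
        return _sig.filtfilt(b, a, x)
    return _sig.lfilter(b, a, x)


def downsample_force(
    force: np.ndarray,
    source_rate: float,
    target_rate: float,
    antialias: FilterSpec | None = None,
) -> np.ndarray:
    """Decimate a force-rate series down to the kinematic rate.

    The force record is smoothed with ``antialias`` (typically the 100 Hz
    force filter) and then every ``source_rate/target_rate``-th sample is
    kept, starting at sample 0 so the output stays phase-aligned with the
    kinematic frames.  Pass ``antialias=None`` to decimate raw samples.
    """
    force = np.asarray(force, dtype=float)
    ratio = source_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValidationError(
            f"source rate {source_rate} Hz must be an integer multiple of target {target_rate} Hz"
        )
    step = int(round(ratio))
    if antialias is not None:
        force = zero_lag_butterworth(force, source_rate, antialias)
    return force[::step]


def finite_diff_accel(x: np.ndarray, rate: float) -> np.ndarray:
    """Second derivative of a position series by second-order finite differences.

    Interior frames use the central stencil ``(x[i+1] - 2 x[i] + x[i-1]) * rate**2``;
    the endpoints use one-sided second-order stencils.  The result is exact for
    any quadratic trajectory.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need at least 3 samples to differentiate, got {x.size}")
    a = np.empty_like(x)
    r2 = rate * rate
    a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * r2
    if x.size >= 4:
        # one-sided stencils, second-order accurate
        a[0] = (2.0 * x[0] - 5.0 * x[1] + 4.0 * x[2] - x[3]) * r2
        a[-1] = (2.0 * x[-1] - 5.0 * x[-2] + 4.0 * x[-3] - x[-4]) * r2
    else:
        a[0] = a[1]
        a[-1] = a[-2]
    return a


def finite_diff_velocity(x: np.ndarray, rate: float) -> np.ndarray:
    """First derivative by central differences (one-sided at endpoints)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need at least 3 samples to differentiate, got {x.size}")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (rate / 2.0)
    v[0] = (-3.0 * x[0] + 4.0 * x[1] - x[2]) * (rate / 2.0)
    v[-1] = (3.0 * x[-1] - 4.0 * x[-2] + x[-3]) * (rate / 2.0)
    return v


def detect_stance(
    fz: np.ndarray,
    threshold: float,
    rate: float = 500.0,
    min_duration: float = 0.050,
) -> List[StanceInterval]:
    """Find support phases as maximal runs of vertical GRF above threshold.

    Runs shorter than ``min_duration`` (default 50 ms) are discarded as
    contact artefacts.  Returns disjoint, sorted intervals; an empty list is
    a valid result.
    """
    fz = np.asarray(fz, dtype=float)
    if not np.all(np.isfinite(fz)):
        raise ValidationError("fz contains non-finite values")
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    above = fz >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(fz.size)
    min_frames = int(np.ceil(min_duration * rate))
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_frames:
            out.append(StanceInterval(int(s), int(e), threshold))
    return out


def trapz_integral(y: np.ndarray, rate: float, window: StanceInterval | None = None) -> float:
    """Composite trapezoid integral of a series over a stance window."""
    y = np.asarray(y, dtype=float)
    if window is not None:
        if window.start_frame < 0 or window.end_frame > y.size:
            raise ValidationError(
                f"window [{window.start_frame}, {window.end_frame}) out of bounds for series of length {y.size}"
            )
        y = y[window.slice()]
    return float(np.trapezoid(y, dx=1.0 / rate))
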
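"""Optokinetic-reflex (OKR) quantification.

The OKR is a gaze-stabilising reflex: a moving grating drives slow
tracking eye movements interrupted by fast resetting saccades.  This
module quantifies it from either raw video frames (moment-based eye
segmentation) or eye-angle traces: slow-phase segmentation, per-direction
gain (ratio of slow-phase eye velocity to grating velocity), total eye
range, and strong/weak-eye assignment.

Angle convention: 0 deg = body axis, positive counter-clockwise in the
top view (rostral up).  With that convention the left eye moves nasally
(toward the nose) when its angle decreases, the right eye when its angle
increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "EyeTrace",
    "OKRResult",
    "NASAL_SIGN",
    "eye_orientation",
    "segment_slow_phases",
    "compute_gain",
    "eye_range_and_dominance",
    "analyse_trace",
]

#: Sign of d(angle)/dt corresponding to nasal movement, per eye.
NASAL_SIGN = {"left": -1.0, "right": 1.0}


@dataclass
class EyeTrace:
    """Uniformly sampled eye-angle traces plus the stimulus schedule.

    Attributes
    ----------
    t : array, s
    angle_left, angle_right : array, deg
    stimulus_velocity : array, deg/s (signed, piecewise constant)
    reversal_times : array, s — times at which the grating reverses
    sample_rate : float, Hz
    truth : dict
        Optional generator ground truth (clean angles, slow-phase masks,
        true gains); empty for measured data.
    """

    t: np.ndarray
    angle_left: np.ndarray
    angle_right: np.ndarray
    stimulus_velocity: np.ndarray
    reversal_times: np.ndarray
    sample_rate: float
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("angle_left", "angle_right", "stimulus_velocity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match t")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")

    def angle(self, eye: str) -> np.ndarray:
        return {"left": self.angle_left, "right": self.angle_right}[eye]


@dataclass
class OKRResult:
    """Per-session OKR summary (gains are dimensionless, ranges in deg)."""

    gain_nasal: dict[str, float]
    gain_temporal: dict[str, float]
    eye_range: dict[str, float]
    strong_eye: Literal["left", "right"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "gain_nasal": self.gain_nasal,
            "gain_temporal": self.gain_temporal,
            "eye_range": self.eye_range,
            "strong_eye": self.strong_eye,
        }


class TrackingError(RuntimeError):
    """Eye segmentation failed (fewer than two objects in the frame)."""


def eye_orientation(frame: np.ndarray, min_area: int = 1) -> dict[str, dict[str, Any]]:
    """Orientation and centroid of the two eyes in a thresholded frame.

    The two largest connected components are taken to be the eyes.  For
    each, the orientation of the major axis is computed from the central
    second moments, theta = 1/2 * atan2(2*mu11, mu20 - mu02), reported in
    degrees in (-90, 90] with the image y-axis pointing up (row index
    increasing downward is negated).  Eyes are labelled left/right by
    centroid column.

    Returns a dict {"left": {...}, "right": {...}} with keys ``angle_deg``,
    ``centroid`` (row, col) and ``undefined`` (True when the component is
    rotationally symmetric and orientation is meaningless).

    Raises
    ------
    TrackingError
        If fewer than two connected components are present.
    """
    binary = np.asarray(frame) > 0
    labels, n = ndimage.label(binary)
    if n < 2:
        raise TrackingError(f"expected >= 2 connected components, found {n}")
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1][:2] + 1
    eyes = []
    for lab in order:
        rr, cc = np.nonzero(labels == lab)
        r0, c0 = rr.mean(), cc.mean()
        # y up: negate row offsets so reported angles are CCW-positive
        y = -(rr - r0)
        x = cc - c0
        mu20 = np.mean(x * x)
        mu02 = np.mean(y * y)
        mu11 = np.mean(x * y)
        scale = mu20 + mu02
        undefined = bool(
            abs(mu20 - mu02) < 1e-6 * scale and abs(mu11) < 1e-6 * scale
        )
        theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
        if theta <= -90.0:
            theta += 180.0
        elif theta > 90.0:
            theta -= 180.0
        eyes.append({
            "angle_deg": float(theta),
            "centroid": (float(r0), float(c0)),
            "undefined": undefined,
        })
    eyes.sort(key=lambda e: e["centroid"][1])
    return {"left": eyes[0], "right": eyes[1]}


def _smoothed_velocity(angle: np.ndarray, sample_rate: float, smooth: int = 5) -> np.ndarray:
    """Central-difference velocity (deg/s) after moving-average smoothing.

    Edge-replicated padding keeps the estimate exactly invariant to a
    constant angle offset (zero padding would fake edge saccades).
    """
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        half = smooth // 2
        padded = np.pad(angle, half, mode="edge")
        angle = np.convolve(padded, kernel, mode="valid")[: len(angle)]
    return np.gradient(angle, 1.0 / sample_rate)


def segment_slow_phases(
    trace: EyeTrace,
    eye: str,
    velocity_threshold: float | None = None,
    guard_s: float = 0.05,
    min_duration_s: float = 0.1,
    smooth: int = 5,
) -> list[tuple[int, int]]:
    """Slow-phase intervals of one eye, as [start, stop) sample index pairs.

    Samples whose smoothed absolute eye velocity exceeds
    ``velocity_threshold`` (default: 3x the peak stimulus speed) are
    marked fast phase and excluded together with a symmetric guard window
    of ``guard_s`` seconds.  The remaining runs are split at stimulus
    reversals and runs shorter than ``min_duration_s`` are dropped.
    """
    angle = trace.angle(eye)
    if velocity_threshold is None:
        velocity_threshold = 3.0 * float(np.max(np.abs(trace.stimulus_velocity)))
    vel = _smoothed_velocity(angle, trace.sample_rate, smooth=smooth)
    fast = np.abs(vel) > velocity_threshold
    guard = int(round(guard_s * trace.sample_rate))
    if guard > 0 and fast.any():
        fast = ndimage.binary_dilation(fast, iterations=guard)
    slow = ~fast

    # never span a reversal: cut the slow mask at each reversal sample
    cut = np.zeros(len(slow), dtype=bool)
    for rt in trace.reversal_times:
        idx = int(round(rt * trace.sample_rate))
        if 0 < idx < len(cut):
            cut[idx] = True

    intervals: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(slow):
        if ok and (start is None or cut[i]):
            if start is not None and cut[i]:
                intervals.append((start, i))
            start = i
        elif not ok and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(slow)))

    min_len = max(2, int(round(min_duration_s * trace.sample_rate)))
    intervals = [(a, b) for a, b in intervals if b - a >= min_len]
    if not intervals:
        warnings.warn("no slow phases detected", stacklevel=2)
    return intervals


def compute_gain(
    trace: EyeTrace,
    slow_phases: list[tuple[int, int]],
    eye: str,
    direction: Literal["nasal", "temporal"],
) -> float:
    """Slow-phase gain of one eye in one direction.

    For each slow-phase interval the eye velocity is estimated as the
    least-squares slope of angle against time (robust to sample-level
    angle noise), and the interval is classified nasal or temporal from
    the slope's sign relative to the eye's nasal direction.  The gain is
    the duration-weighted mean of |slope| / |grating velocity| over
    qualifying intervals.  Returns NaN (with a warning) when no interval
    qualifies.
    """
    if direction not in ("nasal", "temporal"):
        raise ValueError(f"unknown direction: {direction}")
    angle = trace.angle(eye)
    nasal_sign = NASAL_SIGN[eye]
    num = 0.0
    den = 0.0
    for a, b in slow_phases:
        seg_t = trace.t[a:b]
        seg_angle = angle[a:b]
        stim_v = float(np.median(trace.stimulus_velocity[a:b]))
        if stim_v == 0.0:
            continue
        slope = float(np.polyfit(seg_t, seg_angle, 1)[0])
        # a (numerically) stationary eye has no direction: it contributes
        # its ~zero gain to both, rather than yielding a spurious NaN
        stationary = abs(slope) <= 1e-9 * abs(stim_v)
        is_nasal = slope * nasal_sign > 0
        if not stationary and (direction == "nasal") != is_nasal:
            continue
        w = seg_t[-1] - seg_t[0]
        num += w * abs(slope) / abs(stim_v)
        den += w
    if den == 0.0:
        warnings.warn(f"no {direction} slow phase for {eye} eye", stacklevel=2)
        return float("nan")
    return num / den


def eye_range_and_dominance(trace: EyeTrace) -> tuple[dict[str, float], str]:
    """Total excursion (max - min, deg) per eye and the strong eye.

    The strong eye is the one with the greater range; ties go to the left
    eye with a logged note.
    """
    ranges = {
        eye: float(np.max(trace.angle(eye)) - np.min(trace.angle(eye)))
        for eye in ("left", "right")
    }
    if ranges["left"] == ranges["right"]:
        warnings.warn("eye ranges tied; strong eye set to left", stacklevel=2)
        strong = "left"
    else:
        strong = max(ranges, key=ranges.__getitem__)
    return ranges, strong


def analyse_trace(trace: EyeTrace, velocity_threshold: float | None = None) -> OKRResult:
    """Full per-session OKR analysis: gains, ranges, dominance."""
    gain_nasal: dict[str, float] = {}
    gain_temporal: dict[str, float] = {}
    for eye in ("left", "right"):
        phases = segment_slow_phases(trace, eye, velocity_threshold=velocity_threshold)
        gain_nasal[eye] = compute_gain(trace, phases, eye, "nasal")
        gain_temporal[eye] = compute_gain(trace, phases, eye, "temporal")
    ranges, strong = eye_range_and_dominance(trace)
    return OKRResult(
        gain_nasal=gain_nasal,
        gain_temporal=gain_temporal,
        eye_range=ranges,
        strong_eye=strong,
    )
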
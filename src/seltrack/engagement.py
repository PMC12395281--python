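"""Attentional-engagement metrics: gaze velocity (GV) and repeated-word hit rate (HR).

GV indexes attentional effort inversely: suppressed oculomotor activity
(low GV) marks an effortfully focused listener.  Gaze samples arrive as
screen-normalized coordinates at 60 Hz with a blink mask; GV is the
trial-average absolute angular velocity in deg/s, computed with exact
arctangent geometry from the physical screen size and viewing distance.

HR is the fraction of the three repeated words in a trial detected by a
button press within a response window, so HR takes values {0, 1/3, 2/3, 1}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class GazeRecord:
    """Screen-normalized gaze track with blink mask."""

    xy: np.ndarray  # (n, 2) in [0, 1]^2
    t: np.ndarray  # seconds, strictly increasing
    blink_mask: np.ndarray  # True where the sample is a blink (invalid)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.t) != len(self.xy) or len(self.blink_mask) != len(self.xy):
            raise ValueError("xy, t and blink_mask must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen dimensions and viewing distance in meters.

    Default is a 24-inch 16:9 panel viewed from 0.6 m.
    """

    width_m: float = 0.53
    height_m: float = 0.30
    viewing_distance_m: float = 0.6

    def __post_init__(self) -> None:
        if min(self.width_m, self.height_m, self.viewing_distance_m) <= 0:
            raise ValueError("screen dimensions and distance must be positive")


@dataclass(frozen=True)
class EngagementMetrics:
    gv_deg_per_s: float  # NaN when no valid gaze
    hr: float

    def __post_init__(self) -> None:
        if not math.isnan(self.gv_deg_per_s) and self.gv_deg_per_s < 0:
            raise ValueError("gaze velocity must be non-negative")
        if not any(math.isclose(self.hr, v) for v in (0.0, 1 / 3, 2 / 3, 1.0)):
            raise ValueError("hit rate must be one of {0, 1/3, 2/3, 1}")


def _screen_to_eye_vectors(xy: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """3-D gaze vectors from the eye to on-screen points.

    The eye is assumed aligned with the screen center at the viewing
    distance; normalized coordinates are restored to meters.
    """
    v = np.empty((len(xy), 3))
    v[:, 0] = (xy[:, 0] - 0.5) * geometry.width_m
    v[:, 1] = (xy[:, 1] - 0.5) * geometry.height_m
    v[:, 2] = geometry.viewing_distance_m
    return v


def gaze_velocity(record: GazeRecord, geometry: ScreenGeometry = ScreenGeometry()) -> float:
    """Trial-average absolute gaze angular velocity in deg/s.

    Per-sample angular displacement is the exact angle between successive
    eye-to-screen vectors (arctangent geometry, no small-angle
    approximation), divided by the sample interval; the absolute values are
    averaged over pairs of consecutive non-blink samples.  Returns NaN when
    no valid pair exists.
    """
    valid = ~record.blink_mask
    if valid.sum() < 2:
        return float("nan")
    v = _screen_to_eye_vectors(record.xy, geometry)
    pair_ok = valid[:-1] & valid[1:]
    if not np.any(pair_ok):
        return float("nan")
    a, b = v[:-1][pair_ok], v[1:][pair_ok]
    cross = np.linalg.norm(np.cross(a, b), axis=1)
    dot = np.einsum("ij,ij->i", a, b)
    angle = np.degrees(np.arctan2(cross, dot))
    dt = np.diff(record.t)[pair_ok]
    return float(np.mean(angle / dt))


def hit_rate(
    word_onsets: np.ndarray,
    press_times: np.ndarray,
    window_s: tuple[float, float] = (0.2, 2.0),
) -> float:
    """Repeated-word hit rate: fraction of onsets with a matched press.

    A press matches an onset when it falls in ``(onset + min_lag,
    onset + max_lag]``.  Onsets are processed in temporal order and each
    press can be consumed by at most one onset (earliest-match), so a press
    inside two overlapping windows credits the earlier word.  Unmatched
    presses (false alarms) are ignored, not penalized.
    """
    lo, hi = window_s
    if lo < 0 or hi <= lo:
        raise ValueError("response window must satisfy 0 <= min_lag < max_lag")
    onsets = np.sort(np.asarray(word_onsets, dtype=float))
    if len(onsets) != 3:
        warnings.warn(f"expected 3 repeated-word onsets, got {len(onsets)}", stacklevel=2)
    if len(onsets) == 0:
        return 0.0
    presses = np.sort(np.asarray(press_times, dtype=float))
    used = np.zeros(len(presses), dtype=bool)
    hits = 0
    for onset in onsets:
        in_window = (~used) & (presses > onset + lo) & (presses <= onset + hi)
        idx = np.flatnonzero(in_window)
        if len(idx):
            used[idx[0]] = True
            hits += 1
    return hits / len(onsets)
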
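"""Orientation correction, 1 s windowing, transition buffering, level datasets.

The phone's resting orientation on the pelvis differs between people; a
shortest-arc (quaternion) rotation built from the quietest second of a
standing calibration maps the measured gravity direction onto the canonical
upright +y axis.  Windows are non-overlapping 1 s segments labelled by
majority vote; a +/-2 s buffer around every state change relabels windows as
transitions.  Seven class-granularity "levels" map window labels onto the
class sets used for feature selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .synthetic import G, SensorRecording, TRANSITION_PREFIX, BASE_ACTIVITIES

UPRIGHT = np.array([0.0, 1.0, 0.0])

LEVELS = (1, 2, 3, 4, 5, 6, 7)

#: level -> {window label: class}; labels absent from a level's map are
#: excluded from that level.  Transition labels are handled separately.
_LEVEL_MAPS = {
    1: {
        "walk": "mobile",
        "stairs_up": "mobile",
        "stairs_down": "mobile",
        "ramp_up": "mobile",
        "ramp_down": "mobile",
        "sit": "immobile",
        "stand": "immobile",
        "lie": "immobile",
        "small_move_sit": "immobile",
        "small_move_stand": "immobile",
        "small_move_lie": "immobile",
    },
    2: {"sit": "sit", "stand": "stand"},
    3: {
        "sit": "sit",
        "small_move_sit": "sit",
        "stand": "stand",
        "small_move_stand": "stand",
        "lie": "lie",
        "small_move_lie": "lie",
    },
    4: {
        "walk": "large_movements",
        "ramp_up": "large_movements",
        "ramp_down": "large_movements",
        "stairs_up": "stairs",
        "stairs_down": "stairs",
    },
    5: {
        "walk": "large_movements",
        "stairs_up": "stairs_up",
        "stairs_down": "stairs_down",
        "ramp_up": "ramp_up",
        "ramp_down": "ramp_down",
    },
    6: {
        "small_move_sit": "yes",
        "small_move_stand": "yes",
        "small_move_lie": "yes",
        "sit": "no",
        "stand": "no",
        "lie": "no",
    },
}


@dataclass(frozen=True)
class RotationCorrection:
    """Orthonormal rotation aligning measured gravity with upright +y."""

    R: np.ndarray
    source_window: tuple

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("R must be a proper rotation (det = +1)")
        object.__setattr__(self, "R", R)

    @classmethod
    def identity(cls) -> "RotationCorrection":
        return cls(np.eye(3), (0.0, 1.0))


def _shortest_arc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any axis orthogonal to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    angle = math.atan2(s, c)
    return Rotation.from_rotvec(angle * axis / s).as_matrix()


def estimate_orientation_correction(
    calibration: SensorRecording, stride: float = 0.1
) -> RotationCorrection:
    """Rotation correction from a standing-still calibration sample.

    Scans contiguous 1 s windows of the raw acceleration at ``stride``
    spacing and picks the window minimising the summed per-axis standard
    deviation (earliest on ties).  The returned shortest-arc rotation takes
    the mean measured gravity direction of that window onto +y, so
    ``R @ mean(gravity) ~ (0, 9.81, 0)``.  The quietest-second search runs
    on the raw accelerometer channel (the channel a calibration procedure
    records); the rotation itself is built from the fused gravity estimate,
    which is what the correction must cancel.
    """
    t = calibration.t
    span = t[-1] - t[0]
    if span < 1.0:
        raise ValueError("calibration must cover at least 1 s")
    raw = calibration.accel_raw
    best = None
    start = t[0]
    while start + 1.0 <= t[0] + span + 1e-9:
        m = (t >= start) & (t < start + 1.0)
        if m.sum() >= 2:
            score = float(raw[m].std(axis=0, ddof=0).sum())
            if best is None or score < best[0] - 1e-15:
                best = (score, float(start), m)
        start += stride
    score, w_start, m = best
    mean_g = calibration.gravity[m].mean(axis=0)
    norm = float(np.linalg.norm(mean_g))
    if norm < 1.0:
        raise ValueError(
            f"invalid calibration: mean acceleration norm {norm:.3f} m/s^2 < 1"
        )
    R = _shortest_arc(mean_g / norm, UPRIGHT)
    return RotationCorrection(R, (w_start, w_start + 1.0))


def apply_rotation(stream: np.ndarray, correction: RotationCorrection) -> np.ndarray:
    """Rotate an (n, 3) vector series sample-by-sample (norm preserving)."""
    stream = np.asarray(stream, dtype=float)
    return stream @ correction.R.T


@dataclass
class Window:
    """One second of sensor data with a derived label."""

    participant_id: str
    index: int
    t_start: float
    t: np.ndarray
    accel_raw: np.ndarray
    gravity: np.ndarray
    accel_linear: np.ndarray
    gyro: np.ndarray
    label: str
    duration: float = 1.0

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def is_transition(self) -> bool:
        return self.label.startswith(TRANSITION_PREFIX)


def _majority_label(labels: np.ndarray) -> str:
    """Most frequent label; ties broken by earliest occurrence in the window."""
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    top = counts.max()
    tied = first[counts == top]
    return str(labels[tied.min()])


def segment_windows(recording: SensorRecording) -> list:
    """Cut a recording into consecutive non-overlapping 1 s windows.

    Windows cover half-open intervals [t0 + i, t0 + i + 1).  The window
    count is floor(span + nominal dt): a recording sampled over k whole
    seconds yields k windows; any trailing partial second is discarded.
    """
    t = recording.t
    if len(t) < 2:
        return []
    t0 = float(t[0])
    dt_nom = float(np.median(np.diff(t)))
    n_windows = int(np.floor((t[-1] - t0) + dt_nom))
    windows = []
    for i in range(n_windows):
        lo, hi = t0 + i, t0 + i + 1.0
        m = (t >= lo) & (t < hi)
        if m.sum() < 2:
            continue
        windows.append(
            Window(
                participant_id=recording.participant_id,
                index=i,
                t_start=lo,
                t=t[m],
                accel_raw=recording.accel_raw[m],
                gravity=recording.gravity[m],
                accel_linear=recording.accel_linear[m],
                gyro=recording.gyro[m],
                label=_majority_label(recording.label[m]),
            )
        )
    return windows


def state_changes(annotations: pd.DataFrame) -> list:
    """State-change intervals from an annotation table.

    Annotations are (label, start_s, end_s) runs.  Transition-labelled runs
    are treated as the gap between their neighbouring stable states; a direct
    boundary between two differing stable states is a zero-length change.
    Returns (change_start, change_end, from_label, to_label) tuples.
    """
    stable = annotations[
        ~annotations["label"].astype(str).str.startswith(TRANSITION_PREFIX)
    ].reset_index(drop=True)
    changes = []
    for i in range(len(stable) - 1):
        a, b = stable.iloc[i], stable.iloc[i + 1]
        if a["label"] == b["label"]:
            continue
        changes.append(
            (float(a["end_s"]), float(b["start_s"]), str(a["label"]), str(b["label"]))
        )
    return changes


def apply_transition_buffer(
    windows: list, annotations: pd.DataFrame, buffer_s: float = 2.0
) -> list:
    """Relabel every window within +/- ``buffer_s`` of a state change.

    A window is relabelled ``trans_<from>_to_<to>`` if its [t_start,
    t_start + 1) interval intersects [change_start - buffer, change_end +
    buffer]; overlapping buffered regions are all applied (earliest change
    wins where regions overlap).  Relabelled windows are the level-7
    occurrences and are excluded from levels 1-6.
    """
    changes = state_changes(annotations)
    out = []
    for w in windows:
        label = w.label
        for c_start, c_end, frm, to in changes:
            if w.t_start < c_end + buffer_s and w.t_start + w.duration > c_start - buffer_s:
                label = f"{TRANSITION_PREFIX}{frm}_to_{to}"
                break
        if label != w.label:
            w = Window(
                w.participant_id, w.index, w.t_start, w.t, w.accel_raw,
                w.gravity, w.accel_linear, w.gyro, label, w.duration,
            )
        out.append(w)
    return out


@dataclass
class LevelDataset:
    """Occurrence matrix restricted to one level's class set."""

    level: int
    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    window_index: np.ndarray

    @property
    def n_occurrences(self) -> int:
        return len(self.y)

    @property
    def classes(self):
        return sorted(set(self.y))


def map_label_to_level(label: str, level: int):
    """Class of a window label at a level, or None if excluded there."""
    if level not in LEVELS:
        raise ValueError(f"level must be in 1..7, got {level}")
    if label.startswith(TRANSITION_PREFIX):
        return label if level == 7 else None
    if label not in BASE_ACTIVITIES:
        raise ValueError(f"unknown window label: {label!r}")
    if level == 7:
        return None
    return _LEVEL_MAPS[level].get(label)


def build_level_dataset(windows: list, features: pd.DataFrame, level: int) -> LevelDataset:
    """Assemble one level's (X, y, groups) from windows and their features.

    ``features`` must be row-aligned with ``windows``.  Rows whose label maps
    to no class at this level are dropped.
    """
    if len(windows) != len(features):
        raise ValueError("features must be row-aligned with windows")
    keep, classes = [], []
    for i, w in enumerate(windows):
        cls = map_label_to_level(w.label, level)
        if cls is not None:
            keep.append(i)
            classes.append(cls)
    X = features.iloc[keep].reset_index(drop=True)
    return LevelDataset(
        level=level,
        X=X,
        y=np.asarray(classes, dtype=object),
        groups=np.asarray([windows[i].participant_id for i in keep], dtype=object),
        window_index=np.asarray([windows[i].index for i in keep]),
    )
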
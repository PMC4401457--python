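"""The 76 time-domain signal features computed per 1 s window.

Feature families: ranges, means, standard deviations, skewness/kurtosis,
covariance-matrix elements of the gravity / linear / rotated-linear
acceleration channels; window-integrated velocities; Euclidean norms;
harmonic means; cumulative sums; interquartile ranges; gyroscope means;
zero/mean cross rates; and simple moving averages over a span of W
consecutive windows (the moving-average features couple neighbouring
windows through a WindowContext).

Conventions (fixed and documented):
- standard deviations, variances and covariances use ddof=1 (sample form,
  matching ``np.cov``); skewness and kurtosis use the population (biased)
  moment estimators, kurtosis non-excess (Gaussian -> 3);
- "rotated" linear acceleration is the orientation-corrected channel
  (R @ linear acceleration), whose y axis is vertical by construction;
- velocities integrate linear acceleration by the trapezoid rule with zero
  initial velocity per window (no drift carry-over);
- the heading direction is the unit vector of the window-mean horizontal
  (x, z) rotated linear acceleration; when its norm is < 1e-6 the
  heading-dependent features are 0 by convention;
- cross rates count sign-sequence changes of the vertical (y) linear
  acceleration per second; the mean cross rate counts crossings of the
  window mean.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .preprocessing import RotationCorrection, Window, apply_rotation

N_FEATURES = 76
_AXES = ("x", "y", "z")
_COV_ELEMENTS = ("xx", "xy", "xz", "yy", "yz", "zz")
_COV_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def _registry() -> list:
    reg = {}

    def add(i, name, channel, family, **params):
        reg[i] = {
            "index": i,
            "name": name,
            "channel": channel,
            "family": family,
            "params": params,
        }

    add(1, "sum of range of linear acceleration", "linear", "range")
    add(2, "sum of standard deviation of linear acceleration", "linear", "dispersion")
    add(3, "simple moving average of sum of range of linear acceleration",
        "linear", "moving_average", of=1)
    add(4, "difference to y (y gravity - z gravity - x gravity)", "gravity", "mean")
    for k, ax in enumerate(_AXES):
        add(5 + k, f"range of gravity vector ({ax})", "gravity", "range", axis=ax)
    for k, ax in enumerate(_AXES):
        add(8 + k, f"mean of gravity vector ({ax})", "gravity", "mean", axis=ax)
    for k, ax in enumerate(_AXES):
        add(11 + k, f"range of linear acceleration ({ax})", "linear", "range", axis=ax)
    for k, ax in enumerate(_AXES):
        add(14 + k, f"mean of linear acceleration ({ax})", "linear", "mean", axis=ax)
    for k, ax in enumerate(_AXES):
        add(17 + k, f"kurtosis of gravity vector ({ax})", "gravity", "shape", axis=ax)
    add(20, "sum of kurtosis of gravity vector", "gravity", "shape")
    add(21, "sum of standard deviation of linear acceleration", "linear", "dispersion")
    add(22, "sum of variances of gravity (summed diagonal of covariance matrix)",
        "gravity", "dispersion")
    add(23, "simple moving average of sum of variances", "gravity",
        "moving_average", of=22)
    add(24, "maximum slope of simple moving average of sum of variances",
        "gravity", "moving_average", of=23)
    for k, el in enumerate(_COV_ELEMENTS):
        add(25 + k, f"covariance matrix element ({el}) of gravity vector",
            "gravity", "covariance", element=el)
    for k, el in enumerate(_COV_ELEMENTS):
        add(31 + k, f"covariance matrix element ({el}) of linear acceleration",
            "linear", "covariance", element=el)
    for k, el in enumerate(_COV_ELEMENTS):
        add(37 + k, f"covariance matrix element ({el}) of rotated linear acceleration",
            "rotated_linear", "covariance", element=el)
    add(43, "velocity from integral of rotated linear acceleration (excluding y)",
        "rotated_linear", "velocity")
    add(44, "velocity for y-axis", "rotated_linear", "velocity", axis="y")
    add(45, "mean Euclidean norm of linear acceleration", "linear", "norm")
    add(46, "mean Euclidean norm of rotated linear acceleration",
        "rotated_linear", "norm")
    add(47, "mean Euclidean norm of raw acceleration", "raw", "norm")
    for k, ax in enumerate(_AXES):
        add(48 + k, f"skewness of rotated linear acceleration ({ax})",
            "rotated_linear", "shape", axis=ax)
    for k, ax in enumerate(_AXES):
        add(51 + k, f"moving average of skewness of rotated linear acceleration ({ax})",
            "rotated_linear", "moving_average", of=48 + k)
    add(54, "sum of moving average of skewness (x, y)", "rotated_linear",
        "moving_average")
    add(55, "range of rotated linear acceleration (x)", "rotated_linear",
        "range", axis="x")
    add(56, "moving average of distance from rotated linear acceleration",
        "rotated_linear", "moving_average")
    for k, ax in enumerate(_AXES):
        add(57 + k, f"mean absolute linear acceleration ({ax})", "linear",
            "mean", axis=ax)
    for k, ax in enumerate(_AXES):
        add(60 + k, f"harmonic mean linear acceleration ({ax})", "linear",
            "mean", axis=ax)
    for k, ax in enumerate(_AXES):
        add(63 + k, f"cumulative sum linear acceleration ({ax})", "linear",
            "sum", axis=ax)
    add(66, "correlation between acceleration along gravity and heading",
        "rotated_linear", "correlation")
    add(67, "average velocity in gravity direction", "rotated_linear", "velocity")
    add(68, "average velocity in heading direction", "rotated_linear", "velocity")
    for k, ax in enumerate(_AXES):
        add(69 + k, f"gyroscope mean ({ax})", "gyro", "mean", axis=ax)
    for k, ax in enumerate(_AXES):
        add(72 + k, f"interquartile range linear acceleration ({ax})", "linear",
            "dispersion", axis=ax)
    add(75, "zero cross rate", "linear", "cross_rate", axis="y")
    add(76, "mean cross rate", "linear", "cross_rate", axis="y")
    return [reg[i] for i in range(1, N_FEATURES + 1)]


FEATURE_REGISTRY = _registry()
FEATURE_NAMES = {f["index"]: f["name"] for f in FEATURE_REGISTRY}


def registry_frame() -> pd.DataFrame:
    """The feature registry as a DataFrame (index, name, channel, family)."""
    return pd.DataFrame(
        [
            {k: (v if k != "params" else str(v)) for k, v in f.items()}
            for f in FEATURE_REGISTRY
        ]
    )


def export_registry_json(path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(FEATURE_REGISTRY, fh, indent=1)


def harmonic_mean(series) -> float:
    """Harmonic mean of absolute values: n / sum(1/|s|).

    Returns 0 when any element is zero (the harmonic mean collapses); this
    convention keeps the feature finite on quiescent windows.
    """
    s = np.abs(np.asarray(series, dtype=float))
    if s.size == 0:
        raise ValueError("series must be non-empty")
    if np.any(s == 0):
        return 0.0
    return float(s.size / np.sum(1.0 / s))


def max_slope_sma(sma_history) -> float:
    """Maximum successive difference of a moving-average history.

    With fewer than two points (cold start) the slope is 0.
    """
    h = np.asarray(sma_history, dtype=float)
    if h.size < 2:
        return 0.0
    return float(np.max(np.diff(h)))


def _cross_rate(series: np.ndarray, duration: float) -> float:
    """Sign-sequence changes per second (zeros count as crossing points)."""
    s = np.sign(np.asarray(series, dtype=float))
    return float(np.count_nonzero(np.diff(s) != 0) / duration)


def _heading_unit(rot: np.ndarray):
    """Unit heading vector (x, z components) or None if undefined."""
    m = rot[:, [0, 2]].mean(axis=0)
    n = float(np.linalg.norm(m))
    if n < 1e-6:
        return None
    return m / n


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def grav_heading_correlation(window: Window, correction: RotationCorrection) -> float:
    """Pearson correlation between vertical and heading-direction acceleration.

    Vertical is the y component of the rotated linear acceleration; heading
    is the dominant horizontal direction of the window.  0 by convention when
    the heading is undefined or either component has zero variance.
    """
    rot = apply_rotation(window.accel_linear, correction)
    return _grav_heading_correlation_rot(rot)


def _grav_heading_correlation_rot(rot: np.ndarray) -> float:
    h = _heading_unit(rot)
    if h is None:
        return 0.0
    head = rot[:, 0] * h[0] + rot[:, 2] * h[1]
    return _pearson(rot[:, 1], head)


@dataclass
class WindowContext:
    """Rolling per-recording state feeding the moving-average features.

    Holds the last W values of the quantities that are smoothed across
    windows: feature 1 (sum of linear-acceleration ranges), feature 22
    (summed gravity variances) plus its smoothed history, the three rotated
    skewnesses, and the mean within-window distance from the rotated mean.
    Averages over fewer than W windows at the start of a recording.
    """

    span: int = 3
    f1: deque = field(default_factory=deque)
    f22: deque = field(default_factory=deque)
    sma22_history: list = field(default_factory=list)
    skew: deque = field(default_factory=deque)
    dist: deque = field(default_factory=deque)

    def push(self, f1, f22, skew, dist):
        for q, v in ((self.f1, f1), (self.f22, f22), (self.skew, skew), (self.dist, dist)):
            q.append(v)
            while len(q) > self.span:
                q.popleft()
        self.sma22_history.append(float(np.mean(self.f22)))
        while len(self.sma22_history) > self.span:
            self.sma22_history.pop(0)


def compute_feature_vector(
    window: Window,
    context: WindowContext,
    correction: RotationCorrection,
) -> np.ndarray:
    """The 76-feature vector for one window, updating ``context`` in place.

    ``context`` must be fed windows in recording order; pass a fresh
    WindowContext at the start of each recording.  Returns a length-76 array
    (feature i at position i-1).
    """
    if window.n_samples < 2:
        raise ValueError("degenerate window: fewer than 2 samples")
    t = window.t
    lin = np.asarray(window.accel_linear, dtype=float)
    grav = np.asarray(window.gravity, dtype=float)
    raw = np.asarray(window.accel_raw, dtype=float)
    gyro = np.asarray(window.gyro, dtype=float)
    rot = apply_rotation(lin, correction)
    dur = float(window.duration)

    f = np.zeros(N_FEATURES + 1)  # 1-based

    rng_lin = lin.max(axis=0) - lin.min(axis=0)
    f[1] = rng_lin.sum()
    f[2] = f[21] = lin.std(axis=0, ddof=1).sum()
    gmean = grav.mean(axis=0)
    f[4] = gmean[1] - gmean[2] - gmean[0]
    f[5:8] = grav.max(axis=0) - grav.min(axis=0)
    f[8:11] = gmean
    f[11:14] = rng_lin
    f[14:17] = lin.mean(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant channels
        kur = _kurtosis(grav, axis=0, fisher=False, bias=True)
        skew = _skew(rot, axis=0, bias=True)
    kur = np.where(np.isnan(kur), 3.0, kur)  # constant axis: Gaussian baseline
    f[17:20] = kur
    f[20] = kur.sum()

    cov_g = np.cov(grav.T, ddof=1)
    cov_l = np.cov(lin.T, ddof=1)
    cov_r = np.cov(rot.T, ddof=1)
    f[22] = np.trace(cov_g)
    for k, (i, j) in enumerate(_COV_IDX):
        f[25 + k] = cov_g[i, j]
        f[31 + k] = cov_l[i, j]
        f[37 + k] = cov_r[i, j]

    vel = cumulative_trapezoid(rot, t, axis=0, initial=0.0)
    f[43] = float(np.hypot(vel[-1, 0], vel[-1, 2]))
    f[44] = float(vel[-1, 1])
    f[45] = float(np.linalg.norm(lin, axis=1).mean())
    f[46] = float(np.linalg.norm(rot, axis=1).mean())
    f[47] = float(np.linalg.norm(raw, axis=1).mean())

    skew = np.where(np.isnan(skew), 0.0, skew)
    f[48:51] = skew
    dist = float(np.linalg.norm(rot - rot.mean(axis=0), axis=1).mean())

    # moving-average features need the updated context (current included)
    context.push(f[1], f[22], skew, dist)
    f[3] = float(np.mean(context.f1))
    f[23] = context.sma22_history[-1]
    f[24] = max_slope_sma(context.sma22_history)
    ma_skew = np.mean(np.asarray(context.skew, dtype=float), axis=0)
    f[51:54] = ma_skew
    f[54] = ma_skew[0] + ma_skew[1]
    f[55] = float(rot[:, 0].max() - rot[:, 0].min())
    f[56] = float(np.mean(context.dist))

    f[57:60] = np.abs(lin).mean(axis=0)
    for k in range(3):
        f[60 + k] = harmonic_mean(lin[:, k])
    f[63:66] = lin.sum(axis=0)

    h = _heading_unit(rot)
    f[66] = _grav_heading_correlation_rot(rot)
    f[67] = float(vel[:, 1].mean())
    if h is None:
        f[68] = 0.0
    else:
        vel_head = vel[:, 0] * h[0] + vel[:, 2] * h[1]
        f[68] = float(vel_head.mean())

    f[69:72] = gyro.mean(axis=0)
    q75, q25 = np.percentile(lin, [75, 25], axis=0)
    f[72:75] = q75 - q25
    f[75] = _cross_rate(lin[:, 1], dur)
    f[76] = _cross_rate(lin[:, 1] - lin[:, 1].mean(), dur)

    return f[1:]


def feature_matrix(
    windows: list,
    correction: RotationCorrection,
    span: int = 3,
) -> pd.DataFrame:
    """Feature matrix (one row per window, columns f1..f76).

    Windows must be in recording order for one participant: the
    moving-average features read up to ``span`` preceding windows.
    """
    context = WindowContext(span=span)
    rows = [compute_feature_vector(w, context, correction) for w in windows]
    cols = [f"f{i}" for i in range(1, N_FEATURES + 1)]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(np.vstack(rows), columns=cols)
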
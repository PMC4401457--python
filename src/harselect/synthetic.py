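"""Synthetic labelled IMU recordings for waist-worn smartphone activity data.

Emulates the signal structure a waist-worn phone produces during daily-living
activities: a gravity vector whose device-frame direction tracks pelvis tilt
(sit / stand / lie differ by tilt), quasi-periodic linear acceleration during
gait with a per-step left/right amplitude asymmetry, skewed vertical
acceleration on stairs (sign flips between ascent and descent), gyroscope
micro-rotation bursts during small movements, and smooth 1-2 s transition
segments between activities.  Sampling is ~50 Hz with jittered spacing.

Axis convention (device frame): x and y lie in the phone's face plane, z
points outward (forward when worn on the front of the pelvis).  Upright
stance reads gravity ~ (0, 9.81, 0): y is the vertical axis.

The generator is deterministic given a seed; raw acceleration is constructed
as gravity + linear acceleration so the decomposition identity holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

G = 9.81  # m/s^2

BASE_ACTIVITIES = (
    "sit",
    "stand",
    "lie",
    "walk",
    "stairs_up",
    "stairs_down",
    "ramp_up",
    "ramp_down",
    "small_move_sit",
    "small_move_stand",
    "small_move_lie",
)

#: activities with locomotion-style periodic linear acceleration
_GAIT_ACTIVITIES = {"walk", "stairs_up", "stairs_down", "ramp_up", "ramp_down"}
#: activities with small-movement bursts on top of a static posture
_SMALL_MOVE = {"small_move_sit", "small_move_stand", "small_move_lie"}

TRANSITION_PREFIX = "trans_"

#: default pelvis tilt (degrees about the device x axis) per activity.
#: Positive tilt rotates gravity from +y toward +z, so the mean z-gravity
#: separates sit from stand by design.
DEFAULT_TILTS = {
    "stand": 0.0,
    "sit": 30.0,
    "lie": 85.0,
    "walk": 5.0,
    "stairs_up": 14.0,
    "stairs_down": -8.0,
    "ramp_up": 9.0,
    "ramp_down": -4.0,
    "small_move_sit": 30.0,
    "small_move_stand": 0.0,
    "small_move_lie": 85.0,
}


@dataclass(frozen=True)
class PopulationProfile:
    """Gait and posture parameters of a simulated population.

    Parameters
    ----------
    profile_id : str
        One of ``able_bodied``, ``elderly``, ``stroke``.
    step_frequency : float
        Steps per second during walking (Hz).
    step_accel_amplitude : float
        Peak vertical linear acceleration per step (m/s^2).
    gait_asymmetry : float
        Left/right amplitude-ratio deviation in [0, 1]; alternate steps have
        amplitude scaled by (1 +/- gait_asymmetry).  Zero for symmetric gait.
    pelvis_tilt_by_activity : dict
        Activity -> tilt angle (deg) of the device frame about its x axis.
    stair_vertical_skew : float
        Strength of the asymmetric vertical-acceleration component on stairs;
        applied with positive sign for ascent, negative for descent.
    small_move_rotation_rate : float
        Peak gyroscope rate (deg/s) of micro-rotations during small moves.
    sensor_noise_sd : float
        Gaussian noise SD on linear acceleration (m/s^2).
    sample_rate_mean, sample_rate_sd : float
        Nominal sampling rate and its standard deviation (Hz).
    """

    profile_id: str
    step_frequency: float = 1.9
    step_accel_amplitude: float = 2.5
    gait_asymmetry: float = 0.0
    pelvis_tilt_by_activity: dict = field(default_factory=lambda: dict(DEFAULT_TILTS))
    stair_vertical_skew: float = 0.6
    small_move_rotation_rate: float = 25.0
    sensor_noise_sd: float = 0.15
    sample_rate_mean: float = 50.0
    sample_rate_sd: float = 3.84

    def __post_init__(self):
        if self.sample_rate_mean <= 0:
            raise ValueError("sample_rate_mean must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")
        if not 0.0 <= self.gait_asymmetry <= 1.0:
            raise ValueError("gait_asymmetry must lie in [0, 1]")


def able_bodied_profile(**overrides) -> PopulationProfile:
    return replace(PopulationProfile("able_bodied"), **overrides)


def elderly_profile(**overrides) -> PopulationProfile:
    """Slower cadence, reduced step amplitude, slight asymmetry."""
    base = PopulationProfile(
        "elderly",
        step_frequency=1.5,
        step_accel_amplitude=1.5,
        gait_asymmetry=0.05,
        small_move_rotation_rate=18.0,
    )
    return replace(base, **overrides)


def stroke_profile(**overrides) -> PopulationProfile:
    """Hemiparetic gait: marked step asymmetry, reduced cadence."""
    base = PopulationProfile(
        "stroke",
        step_frequency=1.3,
        step_accel_amplitude=1.8,
        gait_asymmetry=0.4,
        stair_vertical_skew=0.8,
        sensor_noise_sd=0.2,
    )
    return replace(base, **overrides)


DEFAULT_PROFILES = {
    "able_bodied": able_bodied_profile,
    "elderly": elderly_profile,
    "stroke": stroke_profile,
}


@dataclass(frozen=True)
class ActivityScript:
    """Ordered sequence of (activity_label, duration_s) segments."""

    segments: tuple

    def __init__(self, segments):
        segments = tuple((str(lbl), float(dur)) for lbl, dur in segments)
        if not segments:
            raise ValueError("script must contain at least one segment")
        for lbl, dur in segments:
            if lbl not in BASE_ACTIVITIES:
                raise ValueError(f"unknown activity label: {lbl!r}")
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")
        object.__setattr__(self, "segments", segments)

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def boundaries(self):
        """Absolute (start, end, label) of each segment."""
        out, t = [], 0.0
        for lbl, dur in self.segments:
            out.append((t, t + dur, lbl))
            t += dur
        return out

    @classmethod
    def from_csv(cls, path) -> "ActivityScript":
        df = pd.read_csv(path)
        return cls(list(zip(df["label"], df["duration"])))


@dataclass
class SensorRecording:
    """Time-aligned multi-channel IMU stream with per-sample labels.

    All channels are (n, 3) float arrays in SI units; ``accel_raw`` equals
    ``gravity + accel_linear`` per sample by construction.
    """

    participant_id: str
    t: np.ndarray
    accel_raw: np.ndarray
    gravity: np.ndarray
    accel_linear: np.ndarray
    gyro: np.ndarray
    label: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel_raw[:, 0],
                "ay": self.accel_raw[:, 1],
                "az": self.accel_raw[:, 2],
                "gx": self.gravity[:, 0],
                "gy": self.gravity[:, 1],
                "gz": self.gravity[:, 2],
                "lx": self.accel_linear[:, 0],
                "ly": self.accel_linear[:, 1],
                "lz": self.accel_linear[:, 2],
                "wx": self.gyro[:, 0],
                "wy": self.gyro[:, 1],
                "wz": self.gyro[:, 2],
                "label": self.label,
            }
        )

    def annotations(self) -> pd.DataFrame:
        """Contiguous label runs as (label, start_s, end_s) rows.

        A run's end is the start of the next run (the final run ends at the
        last timestamp), so runs partition the recorded span.
        """
        lbl = np.asarray(self.label, dtype=object)
        change = np.flatnonzero(lbl[1:] != lbl[:-1]) + 1
        starts = np.concatenate(([0], change))
        rows = []
        for i, s in enumerate(starts):
            end_t = self.t[starts[i + 1]] if i + 1 < len(starts) else self.t[-1]
            rows.append((lbl[s], float(self.t[s]), float(end_t)))
        return pd.DataFrame(rows, columns=["label", "start_s", "end_s"])


def _tilt_rotation(angle_deg: float, axis: str = "x") -> Rotation:
    return Rotation.from_euler(axis, angle_deg, degrees=True)


def _gravity_from_tilt(tilt_deg: np.ndarray) -> np.ndarray:
    """Device-frame gravity for a pelvis tilt about the device x axis.

    The device is rotated by ``tilt`` relative to upright, so the world
    gravity (0, G, 0) reads as its inverse rotation in the device frame.
    """
    rad = np.deg2rad(np.asarray(tilt_deg, dtype=float))
    g = np.zeros((rad.size, 3))
    g[:, 1] = G * np.cos(rad)
    g[:, 2] = G * np.sin(rad)
    return g


def _jittered_timestamps(duration: float, profile: PopulationProfile, rng) -> np.ndarray:
    """Strictly increasing timestamps with ~1/rate mean spacing and jitter.

    The reported rate SD is mapped to a spacing SD by the delta method
    (sd_dt = sd_rate / rate^2); spacings are truncated below at 20% of the
    nominal spacing so timestamps stay strictly increasing.
    """
    dt_nom = 1.0 / profile.sample_rate_mean
    n = int(np.ceil(duration / dt_nom)) + 2
    sd_dt = profile.sample_rate_sd / profile.sample_rate_mean**2
    dt = dt_nom + rng.normal(0.0, sd_dt, size=n)
    dt = np.clip(dt, 0.2 * dt_nom, None)
    t = np.concatenate(([0.0], np.cumsum(dt)))
    return t[t < duration]


def _step_parity(local_t, freq):
    """+1 on even steps, -1 on odd steps (left/right alternation)."""
    return np.where((np.floor(local_t * freq).astype(int) % 2) == 0, 1.0, -1.0)


def _activity_linear_accel(activity, local_t, profile, rng):
    """Noise-free linear-acceleration template (n, 3) for one segment."""
    n = local_t.size
    a = np.zeros((n, 3))
    if activity in _GAIT_ACTIVITIES:
        if activity == "walk":
            freq, amp, skew = profile.step_frequency, profile.step_accel_amplitude, 0.0
        elif activity.startswith("stairs"):
            freq = 0.8 * profile.step_frequency
            amp = 1.15 * profile.step_accel_amplitude
            skew = profile.stair_vertical_skew
            if activity.endswith("down"):
                skew = -skew
        else:  # ramps: walking-like, mild skew
            freq = 0.95 * profile.step_frequency
            amp = profile.step_accel_amplitude
            skew = 0.2 * profile.stair_vertical_skew
            if activity.endswith("down"):
                skew = -skew
        phase = 2 * np.pi * freq * local_t
        s = np.sin(phase)
        env = 1.0 + profile.gait_asymmetry * _step_parity(local_t, freq)
        a[:, 1] = amp * env * s + skew * amp * s**2
        a[:, 2] = 0.4 * amp * np.sin(phase + np.pi / 3)
        a[:, 0] = 0.25 * amp * env * np.sin(np.pi * freq * local_t)
    elif activity in _SMALL_MOVE:
        # low-amplitude quasi-periodic fidgeting on all axes
        a[:, 0] = 0.25 * np.sin(2 * np.pi * 1.1 * local_t)
        a[:, 1] = 0.30 * np.sin(2 * np.pi * 0.9 * local_t + 0.7)
        a[:, 2] = 0.25 * np.sin(2 * np.pi * 1.3 * local_t + 1.9)
    return a


def _activity_gyro(activity, local_t, profile):
    """Noise-free gyroscope template (n, 3), rad/s."""
    n = local_t.size
    w = np.zeros((n, 3))
    if activity in _GAIT_ACTIVITIES:
        freq = profile.step_frequency * (0.8 if activity.startswith("stairs") else 1.0)
        # pelvis yaw/roll oscillation at stride frequency
        w[:, 1] = 0.5 * np.sin(np.pi * freq * local_t)
        w[:, 2] = 0.3 * np.sin(np.pi * freq * local_t + 0.9)
    elif activity in _SMALL_MOVE:
        rate = np.deg2rad(profile.small_move_rotation_rate)
        w[:, 0] = rate * np.sin(2 * np.pi * 0.8 * local_t)
        w[:, 1] = 0.6 * rate * np.sin(2 * np.pi * 0.6 * local_t + 1.1)
    return w


def _activity_tilt(activity, local_t, profile):
    """Per-sample pelvis tilt (deg): static tilt plus gait wobble."""
    base = profile.pelvis_tilt_by_activity.get(activity, DEFAULT_TILTS[activity])
    tilt = np.full(local_t.size, float(base))
    if activity in _GAIT_ACTIVITIES:
        freq = profile.step_frequency
        tilt = tilt + 2.0 * np.sin(2 * np.pi * freq * local_t)
    elif activity in _SMALL_MOVE:
        tilt = tilt + 1.5 * np.sin(2 * np.pi * 0.8 * local_t)
    return tilt


def generate_recording(
    script: ActivityScript,
    profile: PopulationProfile,
    seed: int,
    participant_id: str = "sim",
    transition_duration: float = 1.5,
) -> SensorRecording:
    """Generate one labelled recording for an activity script.

    Transitions: around each segment boundary a ``transition_duration``
    interval (centred on the boundary) is rendered as a smooth cosine
    interpolation of the pelvis tilt with an added movement burst, and
    labelled ``trans_<from>_to_<to>``.

    Deterministic given ``seed``.
    """
    if not isinstance(script, ActivityScript):
        script = ActivityScript(script)
    rng = np.random.default_rng(seed)
    t = _jittered_timestamps(script.total_duration, profile, rng)
    n = t.size
    segs = script.boundaries()

    tilt = np.zeros(n)
    lin = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    label = np.empty(n, dtype=object)

    for start, end, activity in segs:
        m = (t >= start) & (t < end)
        local = t[m] - start
        tilt[m] = _activity_tilt(activity, local, profile)
        lin[m] = _activity_linear_accel(activity, local, profile, rng)
        gyro[m] = _activity_gyro(activity, local, profile)
        label[m] = activity
    # samples exactly at the final boundary (none normally, t < duration)
    label[label == None] = segs[-1][2]  # noqa: E711

    # transition overlays centred on interior boundaries
    half = transition_duration / 2.0
    for i in range(len(segs) - 1):
        b = segs[i][1]
        a_lbl, b_lbl = segs[i][2], segs[i + 1][2]
        m = (t >= b - half) & (t < b + half)
        if not m.any():
            continue
        u = (t[m] - (b - half)) / transition_duration  # in [0, 1)
        blend = 0.5 - 0.5 * np.cos(np.pi * u)  # cosine ease
        tilt_a = profile.pelvis_tilt_by_activity.get(a_lbl, DEFAULT_TILTS[a_lbl])
        tilt_b = profile.pelvis_tilt_by_activity.get(b_lbl, DEFAULT_TILTS[b_lbl])
        tilt[m] = tilt_a + (tilt_b - tilt_a) * blend
        burst = np.sin(np.pi * u)
        lin[m] = 0.0
        lin[m, 1] = 1.2 * burst * np.sin(2 * np.pi * 2.0 * u)
        lin[m, 2] = 0.8 * burst * np.sin(2 * np.pi * 1.5 * u + 0.5)
        # gyro consistent with the tilt sweep about x (deg -> rad)
        gyro[m] = 0.0
        gyro[m, 0] = np.deg2rad(
            (tilt_b - tilt_a) * 0.5 * np.pi * np.sin(np.pi * u) / transition_duration
        )
        label[m] = f"{TRANSITION_PREFIX}{a_lbl}_to_{b_lbl}"

    if profile.sensor_noise_sd > 0:
        lin = lin + rng.normal(0.0, profile.sensor_noise_sd, size=lin.shape)
        gyro = gyro + rng.normal(0.0, 0.2 * profile.sensor_noise_sd, size=gyro.shape)
        tilt = tilt + rng.normal(0.0, 0.2, size=n)  # orientation wobble (deg)

    gravity = _gravity_from_tilt(tilt)
    raw = gravity + lin
    return SensorRecording(participant_id, t, raw, gravity, lin, gyro, label)


def generate_calibration_sample(
    profile: PopulationProfile,
    tilt_perturbation: float,
    seed: int,
    duration: float = 10.0,
    axis: str = "z",
    participant_id: str = "cal",
    quiet_window: tuple = (4.0, 5.0),
) -> SensorRecording:
    """10 s standing-still sample with the device rotated off upright.

    The device orientation is rotated from canonical upright by
    ``tilt_perturbation`` degrees about ``axis``; a contiguous 1 s region
    (``quiet_window``) carries near-zero noise, as the quietest second a
    calibration procedure should find.
    """
    rng = np.random.default_rng(seed)
    t = _jittered_timestamps(duration, profile, rng)
    n = t.size
    rot = _tilt_rotation(tilt_perturbation, axis)
    g_dev = rot.inv().apply([0.0, G, 0.0])
    gravity = np.tile(g_dev, (n, 1))
    scale = np.full(n, profile.sensor_noise_sd)
    quiet = (t >= quiet_window[0]) & (t < quiet_window[1])
    scale[quiet] *= 0.02
    lin = rng.normal(0.0, 1.0, size=(n, 3)) * scale[:, None]
    gyro = rng.normal(0.0, 1.0, size=(n, 3)) * (0.2 * scale)[:, None]
    raw = gravity + lin
    label = np.full(n, "stand", dtype=object)
    return SensorRecording(participant_id, t, raw, gravity, lin, gyro, label)


@dataclass
class SimulatedParticipant:
    """One simulated subject: main recording plus standing calibration."""

    participant_id: str
    profile: PopulationProfile
    recording: SensorRecording
    calibration: SensorRecording


def generate_cohort(n_per_profile: dict, script, seed: int) -> list:
    """Generate a cohort: one recording + calibration per participant.

    ``n_per_profile`` maps a profile name (or a PopulationProfile) to a
    participant count.  Per-participant seeds are spawned deterministically
    from the master seed; each participant gets a random calibration tilt in
    [-25, 25] degrees so orientation correction is exercised.
    """
    master = np.random.default_rng(seed)
    cohort = []
    for key in n_per_profile:
        count = n_per_profile[key]
        if count < 0:
            raise ValueError("participant counts must be non-negative")
        if isinstance(key, PopulationProfile):
            profile = key
        else:
            profile = DEFAULT_PROFILES[key]()
        for i in range(count):
            pid = f"{profile.profile_id}_{i:02d}"
            sub = int(master.integers(0, 2**31 - 1))
            tilt = float(np.random.default_rng(sub).uniform(-25, 25))
            rec = generate_recording(script, profile, seed=sub, participant_id=pid)
            cal = generate_calibration_sample(
                profile, tilt_perturbation=tilt, seed=sub + 1, participant_id=pid
            )
            cohort.append(SimulatedParticipant(pid, profile, rec, cal))
    ids = [p.participant_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids are not unique")
    return cohort


def planted_feature_matrix(
    n_samples: int = 300,
    n_features: int = 20,
    n_informative: int = 4,
    effect: float = 2.0,
    seed: int = 0,
):
    """Feature matrix with a known set of class-informative columns.

    Two balanced classes; each informative column is shifted by ``effect``
    standard deviations between classes with independent unit noise, so the
    informative columns carry independent class signal (their mutual
    dependence is induced by the class only).  Returns ``(X, y, informative)``
    with ``informative`` the sorted column indices carrying signal.

    This is the planted-signal ground for selector parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n_samples - n_samples // 2, n_samples // 2])
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, size=(n_samples, n_features))
    informative = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    shift = effect * (y - 0.5)  # +/- effect/2 per class
    for j in informative:
        X[:, j] += shift
    return X, y, informative
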
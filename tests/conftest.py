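import numpy as np
import pytest

import harselect as hs

COHORT_SEED = 7

#: continuous daily-living circuit exercised by every participant:
#: postures, gait, stairs, ramps, small movements, and many transitions.
CIRCUIT = [
    ("stand", 12), ("sit", 12), ("stand", 8), ("walk", 20),
    ("stairs_up", 10), ("stairs_down", 10), ("walk", 10),
    ("ramp_up", 10), ("ramp_down", 10), ("lie", 12),
    ("small_move_lie", 8), ("sit", 10), ("small_move_sit", 10),
    ("stand", 8), ("small_move_stand", 10), ("walk", 12),
    ("stairs_up", 8), ("stairs_down", 8), ("sit", 10),
]


@pytest.fixture(scope="session")
def circuit_script():
    return hs.ActivityScript(CIRCUIT)


@pytest.fixture(scope="session")
def cohort(circuit_script):
    """Nine simulated participants, three per population profile."""
    return hs.generate_cohort(
        {"able_bodied": 3, "elderly": 3, "stroke": 3}, circuit_script,
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def study(cohort):
    return hs.FeatureSelectionStudy.from_recordings(cohort)


@pytest.fixture(scope="session")
def study_results(study):
    """Full fixed-subset fit: selection + LOOCV + sign tests, all levels."""
    return study.fit(seed=COHORT_SEED)


@pytest.fixture()
def quiet_profile():
    return hs.synthetic.able_bodied_profile(sensor_noise_sd=0.0, sample_rate_sd=0.0)


@pytest.fixture()
def default_profile():
    return hs.synthetic.able_bodied_profile()


def make_window(t, lin, grav=None, gyro=None, label="stand", pid="p0", index=0):
    """Assemble a Window directly from channel arrays (test helper)."""
    t = np.asarray(t, dtype=float)
    lin = np.asarray(lin, dtype=float)
    n = len(t)
    if grav is None:
        grav = np.tile([0.0, 9.81, 0.0], (n, 1))
    if gyro is None:
        gyro = np.zeros((n, 3))
    return hs.Window(
        participant_id=pid, index=index, t_start=float(t[0]), t=t,
        accel_raw=np.asarray(grav) + lin, gravity=np.asarray(grav, dtype=float),
        accel_linear=lin, gyro=np.asarray(gyro, dtype=float), label=label,
    )
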
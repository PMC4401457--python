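"""Orientation correction, windowing, transition buffering, level mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import harselect as hs
from harselect.preprocessing import (
    LEVELS,
    RotationCorrection,
    map_label_to_level,
    state_changes,
)
from harselect.synthetic import G, generate_calibration_sample, generate_recording

from conftest import make_window


# -- orientation correction -------------------------------------------------


def test_upright_noiseless_calibration_gives_identity(quiet_profile):
    cal = generate_calibration_sample(quiet_profile, 0.0, seed=0)
    corr = hs.estimate_orientation_correction(cal)
    assert np.allclose(corr.R, np.eye(3), atol=1e-9)


def test_tilted_calibration_recovers_upright_closed_form(quiet_profile):
    """30 degrees about z: R must equal the inverse axis-angle rotation and
    map the measured gravity back onto (0, 9.81, 0)."""
    cal = generate_calibration_sample(quiet_profile, 30.0, seed=0, axis="z")
    corr = hs.estimate_orientation_correction(cal)
    assert np.allclose(corr.R @ cal.gravity.mean(axis=0), [0, G, 0], atol=1e-6)
    expected = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
    assert np.allclose(corr.R, expected, atol=1e-9)


def test_quietest_second_is_selected(default_profile):
    cal = generate_calibration_sample(default_profile, 10.0, seed=4,
                                      quiet_window=(6.0, 7.0))
    corr = hs.estimate_orientation_correction(cal)
    assert corr.source_window[0] == pytest.approx(6.0, abs=0.15)


def test_equal_variance_windows_tie_break_earliest(quiet_profile):
    # zero noise everywhere: every window scores 0, earliest must win
    cal = generate_calibration_sample(quiet_profile, 5.0, seed=0)
    corr = hs.estimate_orientation_correction(cal)
    assert corr.source_window[0] == pytest.approx(cal.t[0], abs=1e-9)


def test_calibration_errors():
    prof = hs.synthetic.able_bodied_profile()
    short = generate_calibration_sample(prof, 0.0, seed=0, duration=0.5)
    with pytest.raises(ValueError):
        hs.estimate_orientation_correction(short)
    freefall = generate_calibration_sample(prof, 0.0, seed=0)
    freefall.gravity[:] = 0.0
    freefall.accel_raw[:] = freefall.accel_linear
    with pytest.raises(ValueError, match="calibration"):
        hs.estimate_orientation_correction(freefall)


def test_rotation_correction_validates_matrix():
    with pytest.raises(ValueError):
        RotationCorrection(np.ones((3, 3)), (0, 1))
    with pytest.raises(ValueError):  # reflection: orthonormal but det = -1
        RotationCorrection(np.diag([1.0, 1.0, -1.0]), (0, 1))


def test_apply_rotation_identity_isometry_and_quarter_turn():
    rng = np.random.default_rng(0)
    series = rng.normal(size=(100, 3))
    ident = RotationCorrection.identity()
    assert np.array_equal(hs.apply_rotation(series, ident), series)
    quarter = RotationCorrection(
        Rotation.from_euler("z", 90, degrees=True).as_matrix(), (0, 1))
    out = hs.apply_rotation(series, quarter)
    assert np.allclose(np.linalg.norm(out, axis=1),
                       np.linalg.norm(series, axis=1), atol=1e-9)
    one = hs.apply_rotation(np.array([[1.0, 0.0, 0.0]]), quarter)
    assert np.allclose(one, [[0.0, 1.0, 0.0]], atol=1e-12)


# -- windowing ---------------------------------------------------------------


def _recording_of(duration, profile, seed=0):
    return generate_recording(hs.ActivityScript([("walk", duration)]),
                              profile, seed=seed)


def test_window_counts_drop_trailing_partial_second(quiet_profile):
    assert len(hs.segment_windows(_recording_of(10.0, quiet_profile))) == 10
    assert len(hs.segment_windows(_recording_of(10.7, quiet_profile))) == 10


def test_windows_are_consecutive_half_open_intervals(default_profile):
    rec = _recording_of(12.0, default_profile, seed=9)
    windows = hs.segment_windows(rec)
    for w in windows:
        lo, hi = w.t_start, w.t_start + 1.0
        member = (rec.t >= lo) & (rec.t < hi)
        assert np.array_equal(w.t, rec.t[member])
    starts = [w.t_start for w in windows]
    assert np.allclose(np.diff(starts), 1.0)
    # jittered 50 Hz: per-window sample counts vary around 50
    counts = [w.n_samples for w in windows]
    assert min(counts) >= 40 and max(counts) <= 60 and len(set(counts)) > 1


def test_majority_label_with_earliest_tie_break():
    t = np.arange(10) * 0.1
    lin = np.zeros((10, 3))
    w = make_window(t, lin)
    labels = np.array(["sit"] * 5 + ["stand"] * 5, dtype=object)
    from harselect.preprocessing import _majority_label

    assert _majority_label(labels) == "sit"           # tie -> earliest
    labels[0] = "stand"                                # stand now majority
    assert _majority_label(labels) == "stand"


# -- transition buffering ----------------------------------------------------


def _uniform_windows(labels):
    out = []
    for i, lbl in enumerate(labels):
        t = i + np.arange(10) * 0.1
        out.append(make_window(t, np.zeros((10, 3)), label=lbl, index=i))
    return out


def test_no_state_changes_leaves_windows_unchanged():
    windows = _uniform_windows(["sit"] * 6)
    ann = pd.DataFrame({"label": ["sit"], "start_s": [0.0], "end_s": [6.0]})
    out = hs.apply_transition_buffer(windows, ann)
    assert [w.label for w in out] == ["sit"] * 6


def test_single_change_buffers_two_seconds_each_side():
    """Change at t=10: windows intersecting [8, 12] become transitions."""
    windows = _uniform_windows(["sit"] * 10 + ["stand"] * 10)
    ann = pd.DataFrame({"label": ["sit", "stand"],
                        "start_s": [0.0, 10.0], "end_s": [10.0, 20.0]})
    out = hs.apply_transition_buffer(windows, ann)
    labels = [w.label for w in out]
    for i in range(20):
        if 8 <= i <= 11:  # windows [8,9) .. [11,12) intersect [8, 12]
            assert labels[i] == "trans_sit_to_stand", i
        else:
            assert labels[i] == ("sit" if i < 10 else "stand"), i


def test_close_changes_absorb_intervening_state():
    """Two changes 3 s apart: the buffered regions overlap and the short
    middle state is fully relabelled (interval-union behaviour)."""
    windows = _uniform_windows(["sit"] * 10 + ["stand"] * 3 + ["lie"] * 10)
    ann = pd.DataFrame({"label": ["sit", "stand", "lie"],
                        "start_s": [0.0, 10.0, 13.0],
                        "end_s": [10.0, 13.0, 23.0]})
    out = hs.apply_transition_buffer(windows, ann)
    labels = [w.label for w in out]
    assert all(l.startswith("trans_") for l in labels[8:15])
    assert not any(l == "stand" for l in labels)
    assert labels[0] == "sit" and labels[-1] == "lie"


def test_state_changes_span_generator_transition_runs(cohort):
    rec = cohort[0].recording
    changes = state_changes(rec.annotations())
    assert changes, "circuit must contain state changes"
    for start, end, frm, to in changes:
        assert end >= start and frm != to


# -- level datasets ----------------------------------------------------------


@pytest.mark.parametrize(
    "label, expectations",
    [
        ("stairs_up", {1: "mobile", 2: None, 4: "stairs", 5: "stairs_up",
                       6: None, 7: None}),
        ("small_move_stand", {1: "immobile", 2: None, 3: "stand", 6: "yes"}),
        ("ramp_down", {1: "mobile", 4: "large_movements", 5: "ramp_down"}),
        ("sit", {1: "immobile", 2: "sit", 3: "sit", 6: "no", 7: None}),
        ("trans_sit_to_stand", {1: None, 6: None, 7: "trans_sit_to_stand"}),
    ],
)
def test_level_class_mapping(label, expectations):
    for level, expected in expectations.items():
        assert map_label_to_level(label, level) == expected


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        map_label_to_level("jumping", 1)
    with pytest.raises(ValueError):
        map_label_to_level("sit", 9)


def test_build_level_dataset_empty_windows():
    empty = hs.build_level_dataset([], pd.DataFrame(), level=3)
    assert empty.n_occurrences == 0


def test_level_membership_invariants(study):
    """L2 occurrences are a subset of L3; transitions appear only at L7;
    every non-transition window lands in L1."""
    datasets = {lvl: study.level_dataset(lvl) for lvl in LEVELS}
    key = lambda ds: set(zip(ds.groups.tolist(), ds.window_index.tolist()))
    k = {lvl: key(datasets[lvl]) for lvl in LEVELS}
    assert k[2] <= k[3]
    for lvl in range(1, 7):
        assert all(not c.startswith("trans_") for c in datasets[lvl].classes)
        assert not (k[lvl] & k[7])
    n_windows = len(study.data)
    n_trans = int(study.data["label"].str.startswith("trans_").sum())
    assert len(k[1]) + n_trans == n_windows          # window conservation
    assert len(k[7]) == n_trans
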
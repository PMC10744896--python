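import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_recording
from neckpose import features as feat
from neckpose import quality_control as qc
from neckpose.features import FEATURE_SCHEMA, feature_schema
from neckpose.pose_io import ANGLES, KEYPOINTS, VALUE_COLUMNS

CLINICAL = {"gender": "female", "age": 30, "height_cm": 165.0, "weight_kg": 60.0,
            "bmi": 22.04}


# ---------------------------------------------------------------- schema

def test_schema_has_exactly_381_unique_names():
    names = feature_schema()
    assert len(names) == 381
    assert len(set(names)) == 381


def test_schema_family_counts_per_window():
    """15 original + 15 offset + 25 status + 20 normalized + 19 variation = 94."""
    names = feature_schema()
    for w in range(4):
        suffix = f"_{w}"
        in_w = [n for n in names if n.endswith(suffix)]
        raw = [n for n in in_w if n.startswith("RAW_") and "_AVG_" in n]
        offset = [n for n in in_w if n.startswith("OFFSET_") and "_AVG_" in n
                  and "Mneck" not in n]
        mneck = [n for n in in_w if "Mneck" in n]
        sd = [n for n in in_w if n.endswith(f"_SD_{w}")]
        diffs = [n for n in in_w if "Shoulder_Diff" in n]
        status = [n for n in in_w
                  if n not in raw + offset + mneck + sd + diffs]
        assert (len(raw), len(offset), len(status), len(mneck),
                len(sd) + len(diffs)) == (15, 15, 25, 20, 19)
        assert len(in_w) == 94


def test_schema_contains_published_style_names():
    """Spot-check the naming convention on names the field would recognize."""
    for name in [
        "RAW_yaw_AVG_1", "RAW_Rshoulder_x_AVG_1", "OFFSET_Lshoulder_y_AVG_2",
        "RAW_nose_x_AVG_3", "Rshoulder_y_SD_0", "OFFSET_Rshoulder_y_Mneck_1",
        "Lshoulder_y_Mneck_2", "Yaw_Severe_Right_1", "Shoulder_Normal_0",
        "Shrug_3", "ABS_Offset_Shoulder_Diff_2", "bmi",
    ]:
        assert name in FEATURE_SCHEMA, name


# ---------------------------------------------------------------- baseline

def test_baseline_is_mean_of_first_ten_seconds():
    rec = make_recording(n=30, values={"yaw": np.concatenate(
        [np.arange(10, dtype=float), np.zeros(20)])})
    base = feat.compute_baseline(rec)
    assert base["yaw"] == pytest.approx(4.5)


def test_baseline_skips_qc_removed_frames():
    """Dropping frame 3 leaves the mean over the 9 remaining baseline frames."""
    yaw = np.concatenate([np.arange(10, dtype=float), np.zeros(20)])
    rec = make_recording(n=30, values={"yaw": yaw})
    rec.frames.loc[3, "neck_y"] = np.nan
    kept, _ = qc.apply_qc(rec)
    base = feat.compute_baseline(kept)
    assert base["yaw"] == pytest.approx((45 - 3) / 9)


def test_baseline_requires_five_valid_frames():
    rec = make_recording(n=30)
    rec = rec.with_frames(rec.frames.drop(index=[0, 1, 2, 3, 4, 5]))
    with pytest.raises(ValueError, match="baseline"):
        feat.compute_baseline(rec)


# ---------------------------------------------------------------- means

def test_original_features_average_the_window():
    yaw = np.zeros(30)
    yaw[10:20] = [-10, 10] * 5
    rec = make_recording(n=30, values={"yaw": yaw})
    vals = feat.original_pose_features(rec, 2)
    assert vals["RAW_yaw_AVG_2"] == pytest.approx(0.0)
    const = feat.original_pose_features(rec, 3)
    assert const["RAW_nose_x_AVG_3"] == pytest.approx(0.50)


def test_offset_equals_window_mean_minus_baseline():
    """Per-frame subtraction then averaging equals mean-minus-baseline."""
    yaw = np.concatenate([np.full(10, 2.0), np.full(10, 5.0), np.full(10, 5.0)])
    rec = make_recording(n=30, values={"yaw": yaw})
    base = feat.compute_baseline(rec)
    off = feat.offset_pose_features(rec, base, 2)
    assert off["OFFSET_yaw_AVG_2"] == pytest.approx(5.0 - 2.0)
    raw = feat.original_pose_features(rec, 2)["RAW_yaw_AVG_2"]
    assert off["OFFSET_yaw_AVG_2"] == pytest.approx(raw - base["yaw"])


def test_window_identical_to_baseline_has_zero_offsets():
    rec = make_recording(n=30)
    base = feat.compute_baseline(rec)
    off = feat.offset_pose_features(rec, base, 1)
    assert all(v == pytest.approx(0.0) for v in off.values())


# ---------------------------------------------------------------- Mneck

def test_mneck_is_neck_relative():
    rec = make_recording(n=30)
    base = feat.compute_baseline(rec)
    vals = feat.normalized_position_features(rec, base, 0)
    # nose sits at neck + (0.00, -0.15) in the bland test pose
    assert vals["nose_x_Mneck_0"] == pytest.approx(0.0)
    assert vals["nose_y_Mneck_0"] == pytest.approx(-0.15)


def test_mneck_raw_is_translation_invariant():
    rec = make_recording(n=30)
    shifted = make_recording(n=30)
    for kp in KEYPOINTS:
        shifted.frames[f"{kp}_x"] += 0.1
        shifted.frames[f"{kp}_y"] += 0.05
    b1 = feat.compute_baseline(rec)
    b2 = feat.compute_baseline(shifted)
    v1 = feat.normalized_position_features(rec, b1, 0)
    v2 = feat.normalized_position_features(shifted, b2, 0)
    for k in v1:
        assert v1[k] == pytest.approx(v2[k], abs=1e-12)


# ---------------------------------------------------------------- status

def brute_force_intervals(values, mu, sd):
    """Independent frame-by-frame interval counter."""
    counts = dict.fromkeys(feat.HEAD_STATUS_NAMES, 0)
    for v in values:
        z = (v - mu) / sd
        if abs(z) <= 1:
            k = "Normal"
        elif z < -3:
            k = "Severe_Right"
        elif z < -2:
            k = "Moderate_Right"
        elif z < -1:
            k = "Mild_Right"
        elif z > 3:
            k = "Severe_Left"
        elif z > 2:
            k = "Moderate_Left"
        else:
            k = "Mild_Left"
        counts[k] += 1
    return {k: c / len(values) for k, c in counts.items()}


def test_status_matches_brute_force_counter_with_planted_tail():
    """100 gaming frames with 10 planted far below mu - 3 SD give Severe_Right = 0.10."""
    rng = np.random.default_rng(0)
    n = 300
    yaw = np.zeros(n)
    window = rng.normal(0.0, 2.0, 100)
    window[:10] = -50.0  # far right outliers
    yaw[100:200] = window
    rec = make_recording(n=n, values={"yaw": yaw})
    base = feat.compute_baseline(rec)
    out = feat.head_pose_status(rec, base, 2)
    sd = np.std(window, ddof=1)
    oracle = brute_force_intervals(window, base["yaw"], sd)
    for s, p in oracle.items():
        assert out[f"Yaw_{s}_2"] == pytest.approx(p)
    assert out["Yaw_Severe_Right_2"] == pytest.approx(0.10)


def test_status_boundary_frames_go_to_the_nearer_normal_side():
    """An angle exactly at mu + 1 SD counts as Normal, at mu + 2 SD as Mild."""
    # window values chosen so mu=0 and sd is known exactly
    vals = np.array([-2.0, -1.0, 1.0, 2.0] * 5)
    sd = np.std(vals, ddof=1)
    rec = make_recording(n=30, values={"yaw": np.concatenate([np.zeros(10), vals])})
    base = feat.compute_baseline(rec)
    out = feat.head_pose_status(rec, base, 2)  # gaming = frames 10..19
    window = vals[:10]
    z = window / sd
    n_normal = np.sum(np.abs(z) <= 1)
    assert out["Yaw_Normal_2"] == pytest.approx(n_normal / 10)


def test_zero_sd_window_is_all_normal():
    rec = make_recording(n=30, values={"yaw": np.full(30, 7.0)})
    rec.frames.loc[:9, "yaw"] = 0.0
    base = feat.compute_baseline(rec)
    out = feat.head_pose_status(rec, base, 3)
    assert out["Yaw_Normal_3"] == 1.0
    assert sum(out[f"Yaw_{s}_3"] for s in feat.HEAD_STATUS_NAMES) == pytest.approx(1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-60, 60), min_size=12, max_size=60),
       st.integers(0, 2 ** 31 - 1))
def test_status_proportions_always_partition(angles, seed):
    """The seven head-pose proportions of every angle and window sum to one."""
    rng = np.random.default_rng(seed)
    n = 30
    yaw = rng.choice(np.asarray(angles, dtype=float), size=n)
    rec = make_recording(n=n, values={"yaw": yaw})
    base = feat.compute_baseline(rec)
    for w in range(4):
        out = feat.head_pose_status(rec, base, w)
        for angle in ANGLES:
            total = sum(out[f"{angle.capitalize()}_{s}_{w}"]
                        for s in feat.HEAD_STATUS_NAMES)
            assert total == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- shoulders

def test_shoulder_imbalance_brute_force_planted_rate():
    """Frames planted beyond +2 SD of the gap land in Imbalance_Left."""
    rng = np.random.default_rng(1)
    n = 300
    lsh = 0.60 + np.zeros(n)
    window = rng.normal(0.0, 0.005, 100)
    window[:5] = 0.08  # strongly left-low frames
    lsh[100:200] += window
    rec = make_recording(n=n, values={"lshoulder_y": lsh})
    base = feat.compute_baseline(rec)
    out = feat.shoulder_imbalance_status(rec, base, 2)
    d = lsh[100:200] - 0.60
    sd = np.std(d, ddof=1)
    n_left = np.sum(d >= 2 * sd)
    assert out["Shoulder_Imbalance_Left_2"] == pytest.approx(n_left / 100)
    assert out["Shoulder_Imbalance_Left_2"] == pytest.approx(0.05)
    total = sum(out[f"{s}_2"] for s in feat.SHOULDER_STATUS_NAMES)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_level_shoulders_are_all_normal():
    rec = make_recording(n=30, values={"rshoulder_y": np.full(30, 0.60)})
    base = feat.compute_baseline(rec)
    out = feat.shoulder_imbalance_status(rec, base, 1)
    assert out["Shoulder_Normal_1"] == 1.0


def test_shrug_requires_both_shoulders_raised():
    """Raising one shoulder beyond threshold never counts as a shrug."""
    n = 60
    lsh = np.full(n, 0.60)
    rsh = np.full(n, 0.60)
    rng = np.random.default_rng(2)
    lsh[20:40] += rng.normal(0, 0.002, 20)
    rsh[20:40] += rng.normal(0, 0.002, 20)
    lsh[25:28] = 0.50  # left shoulder alone strongly raised (smaller y)
    rec = make_recording(n=n, values={"lshoulder_y": lsh, "rshoulder_y": rsh})
    base = feat.compute_baseline(rec)
    out = feat.shrug_proportion(rec, base, 2)
    dl = lsh[20:40] - base["lshoulder_y"]
    dr = rsh[20:40] - base["rshoulder_y"]
    expected = np.mean((dl < -np.std(dl, ddof=1)) & (dr < -np.std(dr, ddof=1)))
    assert out["Shrug_2"] == pytest.approx(expected)
    # and the one-sided raise is excluded by construction
    only_left = (dl < -np.std(dl, ddof=1)) & ~(dr < -np.std(dr, ddof=1))
    assert only_left.any()


def test_shrug_counts_planted_simultaneous_raises():
    n = 60
    lsh = np.full(n, 0.60)
    rsh = np.full(n, 0.60)
    rng = np.random.default_rng(3)
    lsh[20:40] += rng.normal(0, 0.002, 20)
    rsh[20:40] += rng.normal(0, 0.002, 20)
    lsh[30:34] = 0.55
    rsh[30:34] = 0.55  # 4 of 20 frames with both raised
    rec = make_recording(n=n, values={"lshoulder_y": lsh, "rshoulder_y": rsh})
    base = feat.compute_baseline(rec)
    out = feat.shrug_proportion(rec, base, 2)
    assert out["Shrug_2"] == pytest.approx(4 / 20)


def test_motionless_shoulders_never_shrug():
    rec = make_recording(n=30)
    base = feat.compute_baseline(rec)
    assert feat.shrug_proportion(rec, base, 0)["Shrug_0"] == 0.0


# ---------------------------------------------------------------- variation

def test_constant_recording_has_zero_sds_and_constant_gap():
    rec = make_recording(n=30)
    base = feat.compute_baseline(rec)
    out = feat.variation_features(rec, base, 0)
    for c in VALUE_COLUMNS:
        assert out[f"{feat._display(c)}_SD_0"] == pytest.approx(0.0, abs=1e-12)
    assert out["Shoulder_Diff_0"] == pytest.approx(0.0)  # level test pose


def test_shoulder_diff_family_hand_example():
    """Three-frame window with gaps 0.01, -0.01, 0.03."""
    n = 9  # windows of 3 frames each
    rsh = np.full(n, 0.59)
    lsh = np.full(n, 0.59)
    lsh[:6] = 0.60  # baseline/early gap 0.01
    lsh[6:] = 0.59 + np.array([0.01, -0.01, 0.03])
    rec = make_recording(n=n, values={"lshoulder_y": lsh, "rshoulder_y": rsh})
    base = feat.compute_baseline(rec)  # all 9 frames (< 10 s)
    out = feat.variation_features(rec, base, 3)
    assert out["Shoulder_Diff_3"] == pytest.approx(0.01)
    assert out["ABS_Shoulder_Diff_3"] == pytest.approx(0.05 / 3)
    base_gap = np.mean(lsh - rsh)
    assert out["Offset_Shoulder_Diff_3"] == pytest.approx(0.01 - base_gap)


def test_abs_diff_dominates_signed_diff():
    rng = np.random.default_rng(4)
    rec = make_recording(n=30, values={
        "lshoulder_y": 0.60 + rng.normal(0, 0.01, 30),
        "rshoulder_y": 0.60 + rng.normal(0, 0.01, 30)})
    base = feat.compute_baseline(rec)
    for w in range(4):
        out = feat.variation_features(rec, base, w)
        assert out[f"ABS_Shoulder_Diff_{w}"] >= abs(out[f"Shoulder_Diff_{w}"])
        assert (out[f"ABS_Offset_Shoulder_Diff_{w}"]
                >= abs(out[f"Offset_Shoulder_Diff_{w}"]))


def test_scaling_y_scales_the_shoulder_diff_family():
    rng = np.random.default_rng(5)
    lsh = np.clip(0.60 + rng.normal(0, 0.01, 30), 0, 1)
    rec1 = make_recording(n=30, values={"lshoulder_y": lsh})
    c = 0.5
    rec2 = make_recording(n=30, values={"lshoulder_y": lsh * c})
    for kp in KEYPOINTS:
        rec2.frames[f"{kp}_y"] = rec1.frames[f"{kp}_y"] * c
    b1, b2 = feat.compute_baseline(rec1), feat.compute_baseline(rec2)
    v1 = feat.variation_features(rec1, b1, 0)
    v2 = feat.variation_features(rec2, b2, 0)
    for name in ["Shoulder_Diff_0", "Offset_Shoulder_Diff_0",
                 "ABS_Shoulder_Diff_0", "ABS_Offset_Shoulder_Diff_0"]:
        assert v2[name] == pytest.approx(c * v1[name], abs=1e-12)


# ---------------------------------------------------------------- assembly

def test_assembled_vector_matches_schema(fixture_cohort):
    matrix = fixture_cohort["matrix"]
    assert matrix.shape[1] == 381
    assert list(matrix.columns) == FEATURE_SCHEMA
    assert not matrix.isna().any().any()


def test_empty_window_is_hard_error_naming_the_window():
    rec = make_recording(n=30)
    rec = rec.with_frames(rec.frames[rec.frames.index < 20])  # watching empty
    with pytest.raises(ValueError, match="watching"):
        feat.assemble_feature_vector(rec, CLINICAL)


def test_whole_window_means_are_count_weighted_task_means():
    rng = np.random.default_rng(6)
    yaw = rng.normal(0, 5, 30)
    rec = make_recording(n=30, values={"yaw": yaw})
    rec.frames.loc[12, "neck_x"] = np.nan
    kept, _ = qc.apply_qc(rec)
    vec = feat.assemble_feature_vector(kept, CLINICAL)
    parts = [kept.window(w) for w in (1, 2, 3)]
    weighted = sum(len(p) * p["yaw"].mean() for p in parts) / sum(len(p) for p in parts)
    assert vec["RAW_yaw_AVG_0"] == pytest.approx(weighted)


def test_translation_invariance_of_calibrated_features():
    """A rigid shift of all coordinates leaves every baseline-relative,
    neck-relative, status, shrug and variation feature unchanged."""
    rng = np.random.default_rng(7)
    values = {}
    for kp in KEYPOINTS:
        values[f"{kp}_y"] = np.clip(0.5 + rng.normal(0, 0.01, 30), 0, 1)
        values[f"{kp}_x"] = np.clip(0.5 + rng.normal(0, 0.01, 30), 0, 1)
    values["yaw"] = rng.normal(0, 3, 30)
    rec1 = make_recording(n=30, values=values)
    rec2 = make_recording(n=30, values=values)
    for kp in KEYPOINTS:
        rec2.frames[f"{kp}_x"] += 0.1
        rec2.frames[f"{kp}_y"] += 0.2
    v1 = feat.assemble_feature_vector(rec1, CLINICAL)
    v2 = feat.assemble_feature_vector(rec2, CLINICAL)
    invariant = [n for n in FEATURE_SCHEMA
                 if n.startswith("OFFSET_") or "Mneck" in n or "_SD_" in n
                 or "Shoulder" in n or "Shrug" in n
                 or any(n.startswith(a.capitalize() + "_") for a in ANGLES)]
    assert len(invariant) > 200
    for name in invariant:
        assert v1[name] == pytest.approx(v2[name], abs=1e-9), name
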
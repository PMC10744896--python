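"""Personal-baseline calibration and the 381-feature posture schema.

Each subject is summarized by 94 pose features per window over four windows
(whole recording, typing, gaming, video watching) plus five clinical
covariates.  The per-window families:

* 15 original features — window mean of each raw pose value (``RAW_*_AVG``);
* 15 offset features — the same means after subtracting the subject's
  personal baseline, the mean posture of the first 10 s of upright sitting
  (``OFFSET_*_AVG``);
* 20 normalized position features — eye/nose/shoulder coordinates re-origined
  at the neck, in raw and offset variants (``*_Mneck``);
* 25 status features — occupancy proportions of SD-defined intervals around
  the baseline mean: seven intervals per head angle (21), three shoulder
  imbalance intervals on the left-minus-right shoulder height (3), and the
  shrug proportion (1);
* 19 variation features — window SD of each raw value (15) plus the four
  shoulder-height-difference aggregates (``Shoulder_Diff`` family).

Conventions baked in here and pinned by tests: the status mean mu comes from
the *baseline*, the status SD from the *task window*; interval boundaries
(angle exactly at mu +/- k*SD) go to the interval nearer Normal; a window
with zero SD puts every frame in Normal; image y grows downward, so a raised
shoulder means a *negative* baseline-relative y offset.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .pose_io import (
    ANGLES,
    DISPLAY_NAMES,
    KEYPOINTS,
    VALUE_COLUMNS,
    WINDOW_NAMES,
    SubjectRecording,
)
from .quality_control import MIN_BASELINE_FRAMES

#: keypoints that get neck-relative (Mneck) coordinates — all but the neck itself
MNECK_POINTS = ("leye", "reye", "nose", "lshoulder", "rshoulder")

#: seven head-pose interval names, negative (Right) side first
HEAD_STATUS_NAMES = (
    "Normal",
    "Mild_Right",
    "Moderate_Right",
    "Severe_Right",
    "Mild_Left",
    "Moderate_Left",
    "Severe_Left",
)

SHOULDER_STATUS_NAMES = ("Shoulder_Normal", "Shoulder_Imbalance_Right", "Shoulder_Imbalance_Left")

CLINICAL_FEATURES = ("gender", "age", "height_cm", "weight_kg", "bmi")

_WINDOWS = (0, 1, 2, 3)


def _display(col: str) -> str:
    """Feature-name form of a raw column: lshoulder_y -> Lshoulder_y."""
    if col in ANGLES:
        return col
    kp, ax = col.rsplit("_", 1)
    return f"{DISPLAY_NAMES[kp]}_{ax}"


def _window_family_names(w: int) -> list[str]:
    names: list[str] = []
    names += [f"RAW_{_display(c)}_AVG_{w}" for c in VALUE_COLUMNS]
    names += [f"OFFSET_{_display(c)}_AVG_{w}" for c in VALUE_COLUMNS]
    for angle in ANGLES:
        names += [f"{angle.capitalize()}_{s}_{w}" for s in HEAD_STATUS_NAMES]
    names += [f"{s}_{w}" for s in SHOULDER_STATUS_NAMES]
    names += [f"Shrug_{w}"]
    for p in MNECK_POINTS:
        for ax in ("x", "y"):
            names += [f"{DISPLAY_NAMES[p]}_{ax}_Mneck_{w}"]
    for p in MNECK_POINTS:
        for ax in ("x", "y"):
            names += [f"OFFSET_{DISPLAY_NAMES[p]}_{ax}_Mneck_{w}"]
    names += [f"{_display(c)}_SD_{w}" for c in VALUE_COLUMNS]
    names += [
        f"Shoulder_Diff_{w}",
        f"Offset_Shoulder_Diff_{w}",
        f"ABS_Shoulder_Diff_{w}",
        f"ABS_Offset_Shoulder_Diff_{w}",
    ]
    return names


def feature_schema() -> list[str]:
    """Canonical ordered list of all 381 feature names.

    Window-major: the 94 features of window 0 (whole), then windows 1-3, then
    the five clinical covariates.
    """
    names: list[str] = []
    for w in _WINDOWS:
        names += _window_family_names(w)
    names += list(CLINICAL_FEATURES)
    return names


FEATURE_SCHEMA = feature_schema()


def compute_baseline(recording: SubjectRecording) -> pd.Series:
    """Mean of each of the 15 raw pose values over valid baseline-window frames.

    The baseline window is the first 10 s of upright, camera-corrected
    sitting; it calibrates out body size and camera placement.  Requires at
    least five valid frames there (QC may have removed some).
    """
    base = recording.baseline_frames()
    if len(base) < MIN_BASELINE_FRAMES:
        raise ValueError(
            f"subject {recording.subject_id}: {len(base)} valid baseline frames "
            f"(need >= {MIN_BASELINE_FRAMES})"
        )
    mu = base[VALUE_COLUMNS].mean()
    if not np.isfinite(mu.to_numpy()).all():
        raise ValueError(
            f"subject {recording.subject_id}: non-finite baseline (missing values "
            "survived QC?)"
        )
    return mu


def _sd(x: pd.Series | np.ndarray) -> float:
    """Sample SD (ddof=1); 0 for degenerate windows of < 2 frames."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1))


def original_pose_features(recording: SubjectRecording, w: int) -> dict[str, float]:
    win = recording.window(w)
    means = win[VALUE_COLUMNS].mean()
    return {f"RAW_{_display(c)}_AVG_{w}": float(means[c]) for c in VALUE_COLUMNS}


def offset_pose_features(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    win = recording.window(w)
    # per-frame subtraction then mean; equal to mean-minus-baseline by linearity
    means = (win[VALUE_COLUMNS] - baseline[VALUE_COLUMNS]).mean()
    return {f"OFFSET_{_display(c)}_AVG_{w}": float(means[c]) for c in VALUE_COLUMNS}


def normalized_position_features(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    """Neck-relative coordinates of eyes, nose and shoulders, raw and offset."""
    win = recording.window(w)
    out: dict[str, float] = {}
    for p in MNECK_POINTS:
        for ax in ("x", "y"):
            rel = win[f"{p}_{ax}"] - win[f"neck_{ax}"]
            out[f"{DISPLAY_NAMES[p]}_{ax}_Mneck_{w}"] = float(rel.mean())
    for p in MNECK_POINTS:
        for ax in ("x", "y"):
            rel = (win[f"{p}_{ax}"] - baseline[f"{p}_{ax}"]) - (
                win[f"neck_{ax}"] - baseline[f"neck_{ax}"]
            )
            out[f"OFFSET_{DISPLAY_NAMES[p]}_{ax}_Mneck_{w}"] = float(rel.mean())
    return out


def _interval_proportions(values: np.ndarray, mu: float, sd: float) -> dict[str, float]:
    """Fractions of frames in the seven SD intervals around mu.

    Boundary values land on the side nearer Normal; sd == 0 collapses
    everything into Normal.
    """
    n = values.size
    if n == 0:
        raise ValueError("empty window")
    if sd <= 0 or not np.isfinite(sd):
        props = dict.fromkeys(HEAD_STATUS_NAMES, 0.0)
        props["Normal"] = 1.0
        return props
    z = (values - mu) / sd
    counts = {
        "Normal": np.count_nonzero(np.abs(z) <= 1),
        "Mild_Right": np.count_nonzero((z < -1) & (z >= -2)),
        "Moderate_Right": np.count_nonzero((z < -2) & (z >= -3)),
        "Severe_Right": np.count_nonzero(z < -3),
        "Mild_Left": np.count_nonzero((z > 1) & (z <= 2)),
        "Moderate_Left": np.count_nonzero((z > 2) & (z <= 3)),
        "Severe_Left": np.count_nonzero(z > 3),
    }
    return {k: v / n for k, v in counts.items()}


def head_pose_status(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    """Seven interval-occupancy proportions per head angle (21 features).

    mu is the subject's baseline mean of the angle; the interval half-width is
    the angle's SD within this window, so the intervals adapt to how much the
    subject moved during the task.
    """
    win = recording.window(w)
    out: dict[str, float] = {}
    for angle in ANGLES:
        vals = win[angle].to_numpy(dtype=float)
        props = _interval_proportions(vals, float(baseline[angle]), _sd(vals))
        for s in HEAD_STATUS_NAMES:
            out[f"{angle.capitalize()}_{s}_{w}"] = props[s]
    return out


def shoulder_imbalance_status(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    """Three-interval occupancy of the left-minus-right shoulder height.

    d = Lshoulder_y - Rshoulder_y per frame; mu_d from the baseline window,
    cutoffs at mu_d +/- 2 * window-SD of d.  The side labels follow the
    head-pose convention: the negative side of d is labeled Right.
    """
    win = recording.window(w)
    d = (win["lshoulder_y"] - win["rshoulder_y"]).to_numpy(dtype=float)
    mu_d = float(baseline["lshoulder_y"] - baseline["rshoulder_y"])
    sd_d = _sd(d)
    n = d.size
    if n == 0:
        raise ValueError("empty window")
    if sd_d <= 0:
        return {
            f"Shoulder_Normal_{w}": 1.0,
            f"Shoulder_Imbalance_Right_{w}": 0.0,
            f"Shoulder_Imbalance_Left_{w}": 0.0,
        }
    dev = d - mu_d
    right = np.count_nonzero(dev <= -2 * sd_d)
    left = np.count_nonzero(dev >= 2 * sd_d)
    return {
        f"Shoulder_Normal_{w}": (n - right - left) / n,
        f"Shoulder_Imbalance_Right_{w}": right / n,
        f"Shoulder_Imbalance_Left_{w}": left / n,
    }


def shrug_proportion(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    """Fraction of frames with both shoulders raised beyond one SD.

    Raised means the baseline-relative y offset is below minus one window-SD
    of that shoulder's offset series (y grows downward).  Both shoulders must
    cross simultaneously — one-sided raises are not shrugs.
    """
    win = recording.window(w)
    dl = (win["lshoulder_y"] - baseline["lshoulder_y"]).to_numpy(dtype=float)
    dr = (win["rshoulder_y"] - baseline["rshoulder_y"]).to_numpy(dtype=float)
    sd_l, sd_r = _sd(dl), _sd(dr)
    if sd_l <= 0 or sd_r <= 0:
        return {f"Shrug_{w}": 0.0}
    shrug = (dl < -sd_l) & (dr < -sd_r)
    return {f"Shrug_{w}": float(np.count_nonzero(shrug) / dl.size)}


def variation_features(
    recording: SubjectRecording, baseline: pd.Series, w: int
) -> dict[str, float]:
    """Window SDs of the 15 raw values plus the shoulder-difference family.

    The four aggregates are per-frame expressions averaged over the window's
    kept frames: signed and absolute versions of the left-minus-right shoulder
    height, with and without baseline calibration.
    """
    win = recording.window(w)
    out = {f"{_display(c)}_SD_{w}": _sd(win[c]) for c in VALUE_COLUMNS}
    gap = (win["lshoulder_y"] - win["rshoulder_y"]).to_numpy(dtype=float)
    base_gap = float(baseline["lshoulder_y"] - baseline["rshoulder_y"])
    off = gap - base_gap
    out[f"Shoulder_Diff_{w}"] = float(gap.mean())
    out[f"Offset_Shoulder_Diff_{w}"] = float(off.mean())
    out[f"ABS_Shoulder_Diff_{w}"] = float(np.abs(gap).mean())
    out[f"ABS_Offset_Shoulder_Diff_{w}"] = float(np.abs(off).mean())
    return out


def _encode_clinical(clinical: Mapping[str, object]) -> dict[str, float]:
    gender = clinical["gender"]
    if isinstance(gender, str):
        gender = {"female": 1.0, "male": 0.0}[gender.lower()]
    return {
        "gender": float(gender),
        "age": float(clinical["age"]),
        "height_cm": float(clinical["height_cm"]),
        "weight_kg": float(clinical["weight_kg"]),
        "bmi": float(clinical["bmi"]),
    }


def assemble_feature_vector(
    recording: SubjectRecording, clinical: Mapping[str, object]
) -> pd.Series:
    """All 381 features for one QC'd subject, in canonical schema order."""
    if recording.frames[VALUE_COLUMNS].isna().any().any():
        raise ValueError(
            f"subject {recording.subject_id}: recording contains missing pose "
            "values; run quality control first"
        )
    for w in (1, 2, 3):
        if len(recording.window(w)) == 0:
            raise ValueError(
                f"subject {recording.subject_id}: window {w} "
                f"({WINDOW_NAMES[w]}) is empty after QC"
            )
    baseline = compute_baseline(recording)
    values: dict[str, float] = {}
    for w in _WINDOWS:
        values.update(original_pose_features(recording, w))
        values.update(offset_pose_features(recording, baseline, w))
        values.update(head_pose_status(recording, baseline, w))
        values.update(shoulder_imbalance_status(recording, baseline, w))
        values.update(shrug_proportion(recording, baseline, w))
        values.update(normalized_position_features(recording, baseline, w))
        values.update(variation_features(recording, baseline, w))
    values.update(_encode_clinical(clinical))
    vec = pd.Series(values, name=recording.subject_id)
    return vec.reindex(FEATURE_SCHEMA)


def build_feature_matrix(
    recordings: list[SubjectRecording], clinical: pd.DataFrame
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per subject, 381 columns."""
    rows = []
    for rec in recordings:
        if rec.subject_id not in clinical.index:
            raise KeyError(f"no clinical record for subject {rec.subject_id}")
        rows.append(assemble_feature_vector(rec, clinical.loc[rec.subject_id]))
    matrix = pd.DataFrame(rows)
    matrix.index.name = "subject_id"
    return matrix
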
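"""Synthetic case/control pose cohorts with known planted effects.

The generator emulates the study design the pipeline assumes: each subject
yields 1800 pose frames at 1 Hz (three 600-frame tasks: typing, gaming,
video watching), preceded by a 10 s upright calibration window, plus a
clinical record.  Cases differ from controls in a small set of planted
posture effects whose directions mirror what the analysis is meant to
recover:

* the head turns away from center (negative yaw) during typing, with an
  extra tail of severe right-turn frames;
* the right-shoulder height jitters more (larger Rshoulder_y SD over the
  whole recording; defaults 0.019 case vs 0.014 control);
* the left shoulder sits lower relative to the baseline during tasks
  (shoulder-height asymmetry).

Frame noise is Gaussian around per-task means with AR(1) autocorrelation
(default rho = 0.8) to mimic slow postural drift — i.i.d. frames would
understate within-window SDs relative to real sitting behavior.  A fraction
of frames is corrupted (all pose values missing, as for unanalyzably blurred
frames) and a further fraction carries one implausibly low keypoint
confidence, so the QC stage has realistic work to do.

Clinical covariates are drawn per group from demographic marginals typical
of a neck-pain clinic cohort (cases older, shorter, more often female); with
``clinical_group_effect=False`` both groups share pooled marginals so the
only signal is postural.

Everything derives from a single integer seed; the same seed reproduces the
cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .pose_io import (
    ANGLES,
    CONF_COLUMNS,
    KEYPOINTS,
    VALUE_COLUMNS,
    SubjectRecording,
    default_window_bounds,
)

#: neutral sitting posture in image-normalized coordinates (top-left origin;
#: the subject faces the camera, so their right shoulder is on the image left)
NEUTRAL_POSE = {
    "leye_x": 0.56, "leye_y": 0.30,
    "reye_x": 0.44, "reye_y": 0.30,
    "nose_x": 0.50, "nose_y": 0.36,
    "neck_x": 0.50, "neck_y": 0.52,
    "lshoulder_x": 0.68, "lshoulder_y": 0.62,
    "rshoulder_x": 0.32, "rshoulder_y": 0.62,
}

#: per-frame marginal SD of each coordinate during tasks (normalized units)
COORD_SD = 0.008

#: per-frame marginal SD of head angles during tasks (degrees)
ANGLE_SD = {"yaw": 2.5, "pitch": 2.0, "roll": 1.5}

#: mild task-specific posture offsets shared by both groups
TASK_OFFSETS = {
    1: {"pitch": 4.0},             # typing: looking down at the keyboard
    2: {"yaw": 1.5, "pitch": 2.0},  # gaming: mouse hand biases the head
    3: {"pitch": -1.0},            # watching: gaze level with the screen
}

#: clinical marginals per group: (female proportion, age, height, weight, NDI)
CLINICAL_MARGINALS = {
    "control": {
        "p_female": 0.476,
        "age": (31.5, 6.90),
        "height_cm": (168.2, 6.75),
        "weight_kg": (73.5, 19.68),
        "ndi": None,
    },
    "case": {
        "p_female": 0.765,
        "age": (35.8, 16.48),
        "height_cm": (160.9, 6.84),
        "weight_kg": (62.5, 12.17),
        "ndi": (3.2, 1.9),
    },
}


@dataclass
class EffectConfig:
    """Cohort size, noise model and planted case effects."""

    n_cases: int = 27
    n_controls: int = 33
    frames_per_subject: int = 1800
    #: case head-yaw mean shift during typing, degrees (negative = rightward)
    yaw_mean_shift: float = 5.0
    #: extra fraction of case typing frames planted far right of baseline
    severe_right_yaw_excess: float = 0.05
    #: marginal per-frame SD of the right-shoulder y-coordinate, by group
    rshoulder_y_sd_case: float = 0.019
    rshoulder_y_sd_control: float = 0.014
    #: case left-shoulder drop (y increase) during tasks, normalized units
    shoulder_imbalance_shift: float = 0.01
    #: fraction of frames with all pose values missing
    corrupt_frame_rate: float = 0.09
    #: fraction of frames with one implausibly low keypoint confidence
    low_conf_rate: float = 0.01
    #: AR(1) autocorrelation of frame noise
    ar_rho: float = 0.8
    #: draw clinical covariates from per-group (True) or pooled (False) marginals
    clinical_group_effect: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("corrupt_frame_rate", "low_conf_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rshoulder_y_sd_case", "rshoulder_y_sd_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.ar_rho < 1.0:
            raise ValueError(f"ar_rho must lie in (-1, 1), got {self.ar_rho}")
        if self.frames_per_subject % 3 != 0 or self.frames_per_subject < 30:
            raise ValueError(
                "frames_per_subject must be >= 30 and divisible by 3 "
                f"(got {self.frames_per_subject})"
            )
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")

    @classmethod
    def null(cls, **overrides) -> "EffectConfig":
        """A zero-effect configuration: groups are exchangeable."""
        kw = dict(
            yaw_mean_shift=0.0,
            severe_right_yaw_excess=0.0,
            rshoulder_y_sd_case=0.014,
            rshoulder_y_sd_control=0.014,
            shoulder_imbalance_shift=0.0,
            clinical_group_effect=False,
        )
        kw.update(overrides)
        return cls(**kw)

    def planted_features(self) -> list[str]:
        """Feature names the planted effects genuinely move (ground truth).

        Effects planted on typing frames propagate to the whole-recording
        window (suffix 0), and a task-mean shift moves raw means, offset
        means and the occupancy of the affected SD intervals alike, so each
        effect maps to a family of features, not a single name.
        """
        out: list[str] = []
        if self.yaw_mean_shift:
            for w in (0, 1):
                out += [f"RAW_yaw_AVG_{w}", f"OFFSET_yaw_AVG_{w}",
                        f"Yaw_Normal_{w}", f"Yaw_Mild_Right_{w}",
                        f"Yaw_Moderate_Right_{w}"]
            out.append("yaw_SD_0")  # task-mean contrast inflates whole-window SD
        if self.severe_right_yaw_excess or self.yaw_mean_shift:
            out += ["Yaw_Severe_Right_0", "Yaw_Severe_Right_1", "yaw_SD_1"]
        if self.rshoulder_y_sd_case != self.rshoulder_y_sd_control:
            out += [f"Rshoulder_y_SD_{w}" for w in range(4)]
            out += [f"ABS_Offset_Shoulder_Diff_{w}" for w in range(4)]
        if self.shoulder_imbalance_shift:
            for w in range(4):
                out += [f"OFFSET_Lshoulder_y_AVG_{w}",
                        f"Lshoulder_y_Mneck_{w}",
                        f"OFFSET_Lshoulder_y_Mneck_{w}",
                        f"Shoulder_Diff_{w}", f"Offset_Shoulder_Diff_{w}",
                        f"Shoulder_Imbalance_Left_{w}"]
        if self.clinical_group_effect:
            out += ["height_cm", "weight_kg", "gender", "age"]
        return out


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Zero-mean AR(1) series with marginal SD ``sd``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -rho], innov)


def _simulate_subject(
    rng: np.random.Generator, subject_id: str, label: str, cfg: EffectConfig
) -> SubjectRecording:
    n = cfg.frames_per_subject
    task_len = n // 3
    bounds = default_window_bounds(n)
    is_case = label == "case"

    # subject-level resting posture: neutral plus idiosyncratic offsets
    upright: dict[str, float] = {}
    for a in ANGLES:
        upright[a] = rng.normal(0.0, 2.0)
    for c, v in NEUTRAL_POSE.items():
        upright[c] = v + rng.normal(0.0, 0.015)

    cols: dict[str, np.ndarray] = {}
    for col in VALUE_COLUMNS:
        if col in ANGLES:
            sd = ANGLE_SD[col]
        elif col == "rshoulder_y":
            sd = cfg.rshoulder_y_sd_case if is_case else cfg.rshoulder_y_sd_control
        else:
            sd = COORD_SD
        series = np.empty(n)
        for w, (lo, hi) in bounds.items():
            mean = upright[col] + TASK_OFFSETS.get(w, {}).get(col, 0.0)
            if is_case:
                if col == "yaw" and w == 1:
                    mean -= cfg.yaw_mean_shift
                if col == "lshoulder_y":
                    mean += cfg.shoulder_imbalance_shift
            seg = mean + _ar1(rng, hi - lo, sd, cfg.ar_rho)
            # the first 10 s are camera-corrected upright sitting: tight noise
            if w == 1:
                seg[: min(10, len(seg))] = upright[col] + rng.normal(
                    0.0, sd * 0.15, min(10, len(seg))
                )
            series[lo:hi] = seg
        cols[col] = series

    # extra far-right yaw excursions for cases during typing
    if is_case and cfg.severe_right_yaw_excess > 0:
        lo, hi = bounds[1]
        eligible = np.arange(lo + 10, hi)
        k = rng.binomial(len(eligible), cfg.severe_right_yaw_excess)
        idx = rng.choice(eligible, size=k, replace=False)
        cols["yaw"][idx] = upright["yaw"] - 12.0 - np.abs(rng.normal(0.0, 2.0, k))

    for col in VALUE_COLUMNS:
        if col in ANGLES:
            cols[col] = np.clip(cols[col], -180.0, 180.0)
        else:
            cols[col] = np.clip(cols[col], 0.0, 1.0)

    # confidences: uniform bands per keypoint -> the Tukey fence sits below
    # the band and only planted low-confidence frames fall under it
    for kp in KEYPOINTS:
        center = rng.uniform(0.75, 0.88)
        cols[f"{kp}_conf"] = rng.uniform(center - 0.08, center + 0.08, n)

    corrupt = rng.random(n) < cfg.corrupt_frame_rate
    # keep the baseline window usable: at most 5 of the first 10 frames corrupt
    while corrupt[:10].sum() > 5:
        corrupt[:10] = rng.random(10) < cfg.corrupt_frame_rate
    for col in VALUE_COLUMNS:
        cols[col][corrupt] = np.nan

    low_conf = (rng.random(n) < cfg.low_conf_rate) & ~corrupt
    for i in np.flatnonzero(low_conf):
        kp = KEYPOINTS[rng.integers(len(KEYPOINTS))]
        cols[f"{kp}_conf"][i] = rng.uniform(0.05, 0.30)

    frames = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    frames = frames[VALUE_COLUMNS + CONF_COLUMNS]
    return SubjectRecording(
        subject_id=subject_id, label=label, frames=frames, window_bounds=bounds
    )


def _simulate_clinical(
    rng: np.random.Generator, subject_id: str, label: str, cfg: EffectConfig
) -> dict:
    if cfg.clinical_group_effect:
        marg = CLINICAL_MARGINALS[label]
    else:  # pooled marginals: label carries no clinical information
        c, k = CLINICAL_MARGINALS["control"], CLINICAL_MARGINALS["case"]
        marg = {
            "p_female": (c["p_female"] + k["p_female"]) / 2,
            "age": tuple((np.array(c["age"]) + np.array(k["age"])) / 2),
            "height_cm": tuple((np.array(c["height_cm"]) + np.array(k["height_cm"])) / 2),
            "weight_kg": tuple((np.array(c["weight_kg"]) + np.array(k["weight_kg"])) / 2),
            "ndi": None,
        }
    gender = "female" if rng.random() < marg["p_female"] else "male"
    age = max(18.0, rng.normal(*marg["age"]))
    height = rng.normal(*marg["height_cm"])
    weight = max(35.0, rng.normal(*marg["weight_kg"]))
    row = {
        "subject_id": subject_id,
        "label": label,
        "gender": gender,
        "age": round(age, 1),
        "height_cm": round(height, 1),
        "weight_kg": round(weight, 1),
    }
    row["bmi"] = round(row["weight_kg"] / (row["height_cm"] / 100.0) ** 2, 2)
    ndi = marg["ndi"] if cfg.clinical_group_effect else None
    row["ndi"] = round(max(0.0, rng.normal(*ndi)), 1) if (ndi and label == "case") else np.nan
    return row


def generate_cohort(
    config: EffectConfig, seed: int | None = None
) -> tuple[list[SubjectRecording], pd.DataFrame, dict]:
    """Simulate a full cohort.

    Returns ``(recordings, clinical, manifest)``.  ``clinical`` is indexed by
    subject id; ``manifest`` records the configuration actually used and the
    feature names targeted by planted effects (ground truth for recovery
    tests).  ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    n_total = config.n_cases + config.n_controls
    children = root.spawn(n_total)
    labels = ["case"] * config.n_cases + ["control"] * config.n_controls

    recordings: list[SubjectRecording] = []
    clinical_rows: list[dict] = []
    for i, (label, ss) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(ss)
        sid = f"S{i:03d}"
        recordings.append(_simulate_subject(rng, sid, label, config))
        clinical_rows.append(_simulate_clinical(rng, sid, label, config))

    clinical = pd.DataFrame(clinical_rows).set_index("subject_id")
    manifest = {
        "seed": seed,
        "config": asdict(config),
        "planted_features": config.planted_features(),
        "n_subjects": n_total,
    }
    return recordings, clinical, manifest


def worked_fixture() -> tuple[list[SubjectRecording], pd.DataFrame]:
    """Two deterministic 30-frame subjects with hand-computable features.

    Windows are 10 frames each (typing, gaming, watching); the baseline
    window coincides with the typing window.  All confidences are 0.8, so the
    confidence filter removes nothing.  Hand-checkable facts, frozen by the
    test suite:

    subject F1 (control)
      * frame 5 has a missing neck_y -> removed by QC; baseline = mean of the
        9 remaining typing-window frames
      * yaw: 0 over frames 0-9, alternating +1/-1 over 10-19, constant 2 over
        20-29 (zero-SD window -> all Normal)
      * nose sits at neck + (0.05, -0.10) in every frame
      * shoulder gap Lshoulder_y - Rshoulder_y = 0.01 in every frame

    subject F2 (case)
      * no missing frames; yaw constant 0
      * watching-window shoulder gap cycles 0.01, -0.01, 0.03, so
        Shoulder_Diff_3 = 0.01 and ABS_Shoulder_Diff_3 = 0.016
    """
    n = 30
    base = {
        "pitch": 5.0, "roll": -3.0,
        "leye_x": 0.45, "leye_y": 0.30,
        "reye_x": 0.60, "reye_y": 0.30,
        "nose_x": 0.55, "nose_y": 0.40,
        "neck_x": 0.50, "neck_y": 0.50,
        "lshoulder_x": 0.65, "lshoulder_y": 0.60,
        "rshoulder_x": 0.35, "rshoulder_y": 0.59,
    }

    def frame_table(yaw: np.ndarray, lsh_y: np.ndarray, rsh_y: np.ndarray) -> pd.DataFrame:
        cols = {c: np.full(n, v) for c, v in base.items()}
        cols["yaw"] = yaw
        cols["lshoulder_y"] = lsh_y
        cols["rshoulder_y"] = rsh_y
        for kp in KEYPOINTS:
            cols[f"{kp}_conf"] = np.full(n, 0.8)
        df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
        return df[VALUE_COLUMNS + CONF_COLUMNS]

    yaw1 = np.concatenate(
        [np.zeros(10), np.tile([1.0, -1.0], 5), np.full(10, 2.0)]
    )
    f1 = frame_table(yaw1, np.full(n, 0.60), np.full(n, 0.59))
    f1.loc[5, "neck_y"] = np.nan  # the planted unanalyzable frame

    gaps = np.concatenate([np.full(20, 0.01), np.tile([0.01, -0.01, 0.03], 4)[:10]])
    f2 = frame_table(np.zeros(n), 0.59 + gaps, np.full(n, 0.59))

    bounds = default_window_bounds(n)
    recs = [
        SubjectRecording("F1", "control", f1, bounds),
        SubjectRecording("F2", "case", f2, bounds),
    ]
    clinical = pd.DataFrame(
        [
            {"subject_id": "F1", "label": "control", "gender": "male",
             "age": 30.0, "height_cm": 170.0, "weight_kg": 70.0},
            {"subject_id": "F2", "label": "case", "gender": "female",
             "age": 40.0, "height_cm": 160.0, "weight_kg": 60.0},
        ]
    ).set_index("subject_id")
    clinical["bmi"] = (clinical["weight_kg"] / (clinical["height_cm"] / 100) ** 2).round(2)
    return recs, clinical
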
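"""Tabular interchange for pose time series, clinical tables and feature matrices.

A recording is a flat frame table: one row per second of video, fifteen pose
values (three head angles in degrees plus x/y image-normalized coordinates of
six upper-body keypoints) and one confidence score per keypoint.  Coordinates
use the image convention with the origin at the top-left corner, so *y grows
downward* — a raised shoulder has a smaller y.  Missing estimates stay missing
(NaN); nothing in this module imputes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: keypoints emitted by the upstream 2D pose estimator, in canonical order
KEYPOINTS: tuple[str, ...] = ("leye", "reye", "nose", "neck", "lshoulder", "rshoulder")

#: head-pose angles from the head-orientation estimator, degrees
ANGLES: tuple[str, ...] = ("yaw", "pitch", "roll")

#: the 15 per-frame pose values
VALUE_COLUMNS: list[str] = list(ANGLES) + [
    f"{kp}_{ax}" for kp in KEYPOINTS for ax in ("x", "y")
]

#: per-keypoint confidence scores (in [0, 1])
CONF_COLUMNS: list[str] = [f"{kp}_conf" for kp in KEYPOINTS]

#: full pose-CSV column contract
POSE_COLUMNS: list[str] = ["frame"] + VALUE_COLUMNS + CONF_COLUMNS

#: display capitalization used in feature names (shoulders/eyes sided, rest lower)
DISPLAY_NAMES: dict[str, str] = {
    "leye": "Leye",
    "reye": "Reye",
    "nose": "nose",
    "neck": "neck",
    "lshoulder": "Lshoulder",
    "rshoulder": "Rshoulder",
}

#: task windows by suffix index: 0 = whole recording, 1..3 = the three tasks
WINDOW_NAMES: dict[int, str] = {0: "whole", 1: "typing", 2: "gaming", 3: "watching"}

CLINICAL_COLUMNS = ["subject_id", "label", "gender", "age", "height_cm", "weight_kg", "bmi"]

#: seconds of upright sitting used for the personal baseline
BASELINE_SECONDS = 10


@dataclass
class SubjectRecording:
    """One subject's ordered pose frames plus task-window bookkeeping.

    ``frames`` is indexed by frame number (1 Hz, so index == seconds).
    ``window_bounds`` maps window id (1..3) to half-open ``[lo, hi)`` frame
    ranges; window 0 is always the whole recording.
    """

    subject_id: str
    label: str  # "case" or "control"
    frames: pd.DataFrame
    window_bounds: dict[int, tuple[int, int]]
    baseline_window: tuple[int, int] = (0, BASELINE_SECONDS)

    def __post_init__(self) -> None:
        if not self.frames.index.is_monotonic_increasing:
            self.frames = self.frames.sort_index()
        if self.frames.index.has_duplicates:
            raise ValueError(
                f"subject {self.subject_id}: duplicate frame indices in recording"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def window(self, w: int) -> pd.DataFrame:
        """Frames belonging to window ``w`` (0 = all kept frames)."""
        if w == 0:
            return self.frames
        lo, hi = self.window_bounds[w]
        return self.frames[(self.frames.index >= lo) & (self.frames.index < hi)]

    def baseline_frames(self) -> pd.DataFrame:
        lo, hi = self.baseline_window
        return self.frames[(self.frames.index >= lo) & (self.frames.index < hi)]

    def with_frames(self, frames: pd.DataFrame) -> "SubjectRecording":
        return replace(self, frames=frames)


def default_window_bounds(n_frames: int) -> dict[int, tuple[int, int]]:
    """Partition ``[0, n_frames)`` into three equal task windows.

    The standard protocol is 1800 frames = 3 tasks x 600 s; shorter recordings
    (fixtures) split the same way, with any remainder going to the last task.
    """
    t = n_frames // 3
    return {1: (0, t), 2: (t, 2 * t), 3: (2 * t, n_frames)}


def _validate_ranges(df: pd.DataFrame, path: str) -> None:
    checks = [(list(ANGLES), -180.0, 180.0, "head angle")]
    coord_cols = [c for c in VALUE_COLUMNS if c not in ANGLES]
    checks.append((coord_cols, 0.0, 1.0, "normalized coordinate"))
    checks.append((CONF_COLUMNS, 0.0, 1.0, "confidence"))
    for cols, lo, hi, what in checks:
        present = [c for c in cols if c in df.columns]
        if not present:
            continue
        block = df[present]
        bad = (block < lo) | (block > hi)
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            row = int(bad[col].idxmax())
            raise ValueError(
                f"{path}: {what} out of range in column '{col}' at frame {row} "
                f"(value {df.loc[row, col]!r}, expected [{lo}, {hi}])"
            )


def read_pose_table(
    path: str | Path,
    subject_id: str | None = None,
    label: str = "control",
    pixel_dims: tuple[float, float] | None = None,
) -> SubjectRecording:
    """Read a per-frame pose CSV into a :class:`SubjectRecording`.

    Parameters
    ----------
    path
        Delimited text file with a ``frame`` column plus any of the documented
        pose/confidence columns.  Unknown columns are ignored with a warning;
        empty cells become NaN and are never imputed.
    pixel_dims
        ``(width, height)`` if coordinates are in pixels; they are divided
        down to image-normalized [0, 1] units before validation.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if "frame" not in raw.columns:
        raise ValueError(f"{path}: pose table has no 'frame' column")
    unknown = [c for c in raw.columns if c not in POSE_COLUMNS]
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown columns {unknown}", stacklevel=2)
        raw = raw.drop(columns=unknown)

    df = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        malformed = numeric.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if malformed.any():
            row = int(malformed.idxmax())
            raise ValueError(
                f"{path}: malformed value {raw.loc[row, col]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        df[col] = numeric.astype(float)

    if df["frame"].isna().any():
        row = int(df["frame"].isna().idxmax())
        raise ValueError(f"{path}: missing frame index at data row {row + 1}")
    df["frame"] = df["frame"].astype(int)
    df = df.set_index("frame").sort_index()
    if df.index.has_duplicates:
        dup = int(df.index[df.index.duplicated()][0])
        raise ValueError(f"{path}: duplicate frame index {dup}")

    # columns the contract names but the file omits stay all-missing
    for col in VALUE_COLUMNS + CONF_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[VALUE_COLUMNS + CONF_COLUMNS]

    if pixel_dims is not None:
        w, h = pixel_dims
        for kp in KEYPOINTS:
            df[f"{kp}_x"] = df[f"{kp}_x"] / w
            df[f"{kp}_y"] = df[f"{kp}_y"] / h
    _validate_ranges(df, str(path))

    n = int(df.index.max()) + 1
    return SubjectRecording(
        subject_id=subject_id or path.stem,
        label=label,
        frames=df,
        window_bounds=default_window_bounds(n),
    )


def write_pose_table(recording: SubjectRecording, path: str | Path) -> None:
    out = recording.frames.reset_index().rename(columns={"index": "frame"})
    out.to_csv(path, index=False, float_format="%.6g")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-subject clinical CSV, recomputing BMI when absent.

    Returns a frame indexed by ``subject_id`` with columns label, gender,
    age, height_cm, weight_kg, bmi.  A stored BMI farther than 0.5 kg/m^2
    from weight/height^2 is rejected as inconsistent.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c != "bmi"]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    bad_label = ~df["label"].isin(["case", "control"])
    if bad_label.any():
        raise ValueError(
            f"{path}: label must be case/control, got {df.loc[bad_label, 'label'].iloc[0]!r}"
        )
    computed = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    if "bmi" not in df.columns:
        df["bmi"] = computed
    else:
        df["bmi"] = df["bmi"].fillna(computed)
        off = (df["bmi"] - computed).abs() > 0.5
        if off.any():
            sid = df.loc[off, "subject_id"].iloc[0]
            raise ValueError(
                f"{path}: stored BMI inconsistent with height/weight for subject {sid}"
            )
    return df.set_index("subject_id")


def write_feature_matrix(
    vectors: Sequence[pd.Series] | pd.DataFrame, path: str | Path
) -> None:
    """Write subject feature vectors as CSV, one row per subject.

    All vectors must share the same (canonically ordered) feature schema;
    a mismatch is a hard error rather than a silent reindex.
    """
    if isinstance(vectors, pd.DataFrame):
        matrix = vectors
    else:
        vectors = list(vectors)
        if vectors:
            ref = list(vectors[0].index)
            for v in vectors[1:]:
                if list(v.index) != ref:
                    raise ValueError(
                        f"inconsistent feature schema between subjects "
                        f"{vectors[0].name!r} and {v.name!r}"
                    )
            matrix = pd.DataFrame([v for v in vectors])
        else:
            from .features import feature_schema

            matrix = pd.DataFrame(columns=feature_schema())
    matrix.index.name = "subject_id"
    matrix.to_csv(path, float_format="%.10g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id").astype(float)
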
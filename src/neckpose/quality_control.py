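"""Frame-level quality control for pose recordings.

Two rules, applied in order and per subject:

1. frames missing any of the 15 estimated pose values are dropped (blurred or
   otherwise unanalyzable frames surface as missing estimates downstream of
   the pose networks);
2. frames whose confidence for *any* keypoint falls strictly below that
   keypoint's Tukey lower fence, Q1 - 1.5*IQR, computed over the subject's own
   recording, are dropped.

Quartiles use linear interpolation between order statistics (numpy default).
Thresholds are strictly per subject: no other subject's frames ever influence
a removal decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pose_io import CONF_COLUMNS, KEYPOINTS, VALUE_COLUMNS, SubjectRecording

#: minimum valid frames required inside the baseline window after QC
MIN_BASELINE_FRAMES = 5


@dataclass
class QCThresholds:
    """Per-keypoint confidence cutoffs for one subject."""

    q1: dict[str, float]
    iqr: dict[str, float]

    def cutoff(self, keypoint: str) -> float:
        return self.q1[keypoint] - 1.5 * self.iqr[keypoint]

    @property
    def cutoffs(self) -> dict[str, float]:
        return {kp: self.cutoff(kp) for kp in self.q1}


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int = 0
    n_removed_low_confidence: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_low_confidence

    @property
    def removal_rate(self) -> float:
        return (self.n_removed_missing + self.n_removed_low_confidence) / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_low_confidence": self.n_removed_low_confidence,
            "n_kept": self.n_kept,
            "removal_rate": self.removal_rate,
        }


def drop_incomplete_frames(
    recording: SubjectRecording,
) -> tuple[SubjectRecording, QCReport]:
    """Remove frames missing any of the 15 pose values.

    A missing *confidence* alone does not remove a frame — the rule applies to
    the estimated values, not their scores.
    """
    complete = recording.frames[VALUE_COLUMNS].notna().all(axis=1)
    kept = recording.frames[complete]
    if kept.empty:
        raise ValueError(
            f"subject {recording.subject_id}: every frame is missing pose values"
        )
    report = QCReport(
        n_input=recording.n_frames,
        n_removed_missing=int((~complete).sum()),
    )
    return recording.with_frames(kept), report


def compute_confidence_thresholds(recording: SubjectRecording) -> QCThresholds:
    """Per-keypoint Q1/IQR of confidence over the subject's whole recording."""
    q1: dict[str, float] = {}
    iqr: dict[str, float] = {}
    for kp in KEYPOINTS:
        conf = recording.frames[f"{kp}_conf"].dropna().to_numpy()
        if conf.size < 4:
            raise ValueError(
                f"subject {recording.subject_id}: only {conf.size} confidence "
                f"values for keypoint '{kp}' (need >= 4 for quartiles)"
            )
        lo, hi = np.percentile(conf, [25.0, 75.0])
        q1[kp] = float(lo)
        iqr[kp] = float(hi - lo)
    return QCThresholds(q1=q1, iqr=iqr)


def confidence_filter(
    recording: SubjectRecording, thresholds: QCThresholds
) -> tuple[SubjectRecording, QCReport]:
    """Drop frames with any keypoint confidence strictly below its cutoff.

    Missing confidences never trigger removal here (they carry no evidence of
    a bad estimate; the value-completeness rule already ran).
    """
    below = pd.Series(False, index=recording.frames.index)
    for kp in KEYPOINTS:
        cut = thresholds.cutoff(kp)
        conf = recording.frames[f"{kp}_conf"]
        below |= conf.notna() & (conf < cut)
    kept = recording.frames[~below]
    if kept.empty:
        raise ValueError(
            f"subject {recording.subject_id}: confidence filter removed all frames"
        )
    report = QCReport(
        n_input=recording.n_frames,
        n_removed_low_confidence=int(below.sum()),
    )
    return recording.with_frames(kept), report


def apply_qc(recording: SubjectRecording) -> tuple[SubjectRecording, QCReport]:
    """Full QC pass: completeness rule, then per-keypoint confidence fences.

    Runs before baseline computation so the personal baseline sees only valid
    frames; errors out if fewer than :data:`MIN_BASELINE_FRAMES` valid frames
    remain inside the baseline window.
    """
    step1, rep1 = drop_incomplete_frames(recording)
    thresholds = compute_confidence_thresholds(step1)
    step2, rep2 = confidence_filter(step1, thresholds)
    report = QCReport(
        n_input=recording.n_frames,
        n_removed_missing=rep1.n_removed_missing,
        n_removed_low_confidence=rep2.n_removed_low_confidence,
    )
    n_base = len(step2.baseline_frames())
    if n_base < MIN_BASELINE_FRAMES:
        raise ValueError(
            f"subject {recording.subject_id}: only {n_base} valid frames in the "
            f"baseline window after QC (need >= {MIN_BASELINE_FRAMES})"
        )
    return step2, report
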
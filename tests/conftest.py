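import numpy as np
import pandas as pd
import pytest

from neckpose import features as feat
from neckpose import quality_control as qc
from neckpose import synthetic
from neckpose.pose_io import (
    CONF_COLUMNS,
    KEYPOINTS,
    VALUE_COLUMNS,
    SubjectRecording,
    default_window_bounds,
)


def make_recording(
    values: dict[str, np.ndarray] | None = None,
    n: int = 30,
    conf: float = 0.8,
    subject_id: str = "T",
    label: str = "control",
) -> SubjectRecording:
    """Build a recording from per-column overrides over a bland constant pose."""
    base = {
        "yaw": 0.0, "pitch": 0.0, "roll": 0.0,
        "leye_x": 0.45, "leye_y": 0.30, "reye_x": 0.60, "reye_y": 0.30,
        "nose_x": 0.50, "nose_y": 0.35, "neck_x": 0.50, "neck_y": 0.50,
        "lshoulder_x": 0.65, "lshoulder_y": 0.60,
        "rshoulder_x": 0.35, "rshoulder_y": 0.60,
    }
    cols = {c: np.full(n, v, dtype=float) for c, v in base.items()}
    for kp in KEYPOINTS:
        cols[f"{kp}_conf"] = np.full(n, conf, dtype=float)
    if values:
        for c, v in values.items():
            cols[c] = np.asarray(v, dtype=float)
    frames = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    frames = frames[VALUE_COLUMNS + CONF_COLUMNS]
    return SubjectRecording(subject_id, label, frames, default_window_bounds(n))


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic two-subject worked fixture, QC'd, with its features."""
    recs, clinical = synthetic.worked_fixture()
    kept = [qc.apply_qc(r)[0] for r in recs]
    matrix = feat.build_feature_matrix(kept, clinical)
    return {"raw": recs, "kept": kept, "clinical": clinical, "matrix": matrix}


@pytest.fixture(scope="session")
def default_cohort():
    """A default planted-effect cohort (n=60, 1800 frames) with its feature matrix."""
    cfg = synthetic.EffectConfig()
    recs, clinical, manifest = synthetic.generate_cohort(cfg, seed=11)
    kept = [qc.apply_qc(r)[0] for r in recs]
    matrix = feat.build_feature_matrix(kept, clinical)
    y = clinical.loc[matrix.index, "label"].to_numpy()
    return {"matrix": matrix, "y": y, "clinical": clinical, "manifest": manifest,
            "config": cfg}


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for modeling smoke tests (short recordings)."""
    cfg = synthetic.EffectConfig(n_cases=10, n_controls=10, frames_per_subject=300)
    recs, clinical, manifest = synthetic.generate_cohort(cfg, seed=5)
    kept = [qc.apply_qc(r)[0] for r in recs]
    matrix = feat.build_feature_matrix(kept, clinical)
    y = clinical.loc[matrix.index, "label"].to_numpy()
    return {"matrix": matrix, "y": y, "clinical": clinical, "manifest": manifest}
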
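"""Seven-level EEG-vigilance stage taxonomy and per-second stage sequences.

Each one-second eyes-closed resting EEG segment is assigned one of seven
ordinal vigilance stages, spanning active wakefulness (0), relaxed
wakefulness with alpha dominance (A1 occipital, A2 intermediate, A3
anteriorized), drowsiness (B1 low-voltage, B2/3 delta-theta dominant), and
sleep onset (C, spindles/K-complexes).  Stages map bijectively onto the
numeric scale 7 (highest arousal) .. 1 (lowest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Stage labels ordered from highest to lowest arousal.
STAGE_LABELS: tuple[str, ...] = ("0", "A1", "A2", "A3", "B1", "B2/3", "C")

#: label -> numeric value (7 = active wakefulness .. 1 = sleep onset)
STAGE_TO_NUMERIC: dict[str, int] = {lab: 7 - i for i, lab in enumerate(STAGE_LABELS)}

#: numeric value -> label
NUMERIC_TO_STAGE: dict[int, str] = {v: k for k, v in STAGE_TO_NUMERIC.items()}

#: ROI names used for band current densities.
ROIS: tuple[str, ...] = ("occipital", "parietal", "temporal", "frontal")


def stage_to_numeric(labels) -> np.ndarray:
    """Vectorized label -> numeric (7..1) conversion."""
    arr = np.asarray(labels, dtype=object)
    try:
        return np.array([STAGE_TO_NUMERIC[l] for l in arr.ravel()]).reshape(arr.shape)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown stage label {exc.args[0]!r}") from None


def numeric_to_stage(values) -> np.ndarray:
    """Vectorized numeric (7..1) -> label conversion."""
    arr = np.asarray(values)
    if not np.isin(arr, list(NUMERIC_TO_STAGE)).all():
        raise ValueError("numeric stage values must lie in 1..7")
    return np.array([NUMERIC_TO_STAGE[int(v)] for v in arr.ravel()], dtype=object).reshape(arr.shape)


@dataclass
class StageSequence:
    """Per-second vigilance stages of one recording.

    Parameters
    ----------
    numeric
        Integer stage values in 1..7, one per one-second segment.  Values at
        artifact positions are retained but ignored by all metrics.
    artifact
        Boolean mask marking artifact-contaminated segments (missing data).
    subject_id
        Optional identifier carried through to tabular output.
    """

    numeric: np.ndarray
    artifact: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.numeric = np.asarray(self.numeric, dtype=int)
        if self.numeric.ndim != 1:
            raise ValueError("stage sequence must be one-dimensional")
        if self.artifact is None:
            self.artifact = np.zeros(self.numeric.shape, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.shape != self.numeric.shape:
            raise ValueError("artifact mask length must match sequence length")
        clean = self.numeric[~self.artifact]
        if clean.size and ((clean < 1) | (clean > 7)).any():
            raise ValueError("numeric stage values must lie in 1..7")

    @classmethod
    def from_labels(cls, labels, artifact=None, subject_id=None) -> "StageSequence":
        numeric = stage_to_numeric(labels)
        return cls(numeric=numeric, artifact=artifact, subject_id=subject_id)

    @property
    def labels(self) -> np.ndarray:
        return numeric_to_stage(np.clip(self.numeric, 1, 7))

    @property
    def n_segments(self) -> int:
        return int(self.numeric.size)

    @property
    def clean_numeric(self) -> np.ndarray:
        """Numeric stages with artifact segments removed."""
        return self.numeric[~self.artifact]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: subject_id, second_index, stage_label, numeric_value, artifact_flag."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id if self.subject_id is not None else "",
                "second_index": np.arange(self.n_segments),
                "stage_label": self.labels,
                "numeric_value": self.numeric,
                "artifact_flag": self.artifact.astype(int),
            }
        )
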
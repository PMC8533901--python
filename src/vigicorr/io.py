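"""Delimited-text readers and writers for pipeline tables.

All tables are TSV with a header row.  Stage tables are long format
(subject_id, second_index, stage_label, numeric_value, artifact_flag);
feature tables carry one row per one-second segment with the eight ROI band
current-density columns and the three flags; phenotype and summary tables
are one row per subject.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .stages import StageSequence
from .staging import FEATURE_COLS


def write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stage_sequences(sequences: list[StageSequence], path) -> None:
    write_table(pd.concat([s.to_frame() for s in sequences], ignore_index=True), path)


def read_stage_sequences(path) -> list[StageSequence]:
    frame = read_table(path)
    required = {"subject_id", "second_index", "numeric_value", "artifact_flag"}
    if not required.issubset(frame.columns):
        raise ValueError(f"stage table must have columns {sorted(required)}")
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("second_index")
        out.append(
            StageSequence(
                numeric=grp["numeric_value"].to_numpy(dtype=int),
                artifact=grp["artifact_flag"].to_numpy(dtype=bool),
                subject_id=str(sid),
            )
        )
    return out


def read_features(path) -> pd.DataFrame:
    frame = read_table(path)
    missing = [c for c in FEATURE_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return frame


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
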
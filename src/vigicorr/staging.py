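"""Rule-based classification of 1-s EEG segments into vigilance stages.

The classifier consumes per-segment band current densities (alpha and
delta+theta) for four regions of interest (occipital, parietal, temporal,
frontal) plus EOG slow-eye-movement and graph-element (sleep spindle /
K-complex) flags, and assigns one of the seven vigilance stages.  The rule
cascade follows the published A-stage criteria: an A stage requires the
alpha current density of some ROI to exceed an individually adapted absolute
threshold and to dominate that ROI's delta+theta density by a configurable
factor; the topography of the dominant alpha (occipital vs anteriorized)
separates A1 from A2/A3.  Graph elements force sleep onset (C); diffuse
delta+theta dominance marks B2/3; slow eye movements or recent sub-wake
context mark B1; everything else is active wakefulness (0).

The individual A-stage threshold procedure used by the reference tool is not
public; this module uses a documented, configurable approximation (a fixed
fraction of the mean occipital alpha over the top quantile of artifact-free
segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import ROIS, STAGE_TO_NUMERIC, StageSequence

ALPHA_COLS = [f"alpha_{r}" for r in ROIS]
DT_COLS = [f"deltatheta_{r}" for r in ROIS]
FLAG_COLS = ["sem_flag", "graph_flag", "artifact_flag"]
FEATURE_COLS = ALPHA_COLS + DT_COLS + FLAG_COLS

#: minimum number of artifact-free segments required to adapt the threshold
MIN_CLEAN_SEGMENTS = 60


class QCError(ValueError):
    """Raised when a recording fails a quality-control precondition."""


@dataclass(frozen=True)
class StagingConfig:
    """Tunable constants of the staging rule cascade.

    a_ratio
        Factor by which ROI alpha must exceed the same ROI's delta+theta
        density for an A-stage candidate (default 2.0).
    threshold_quantile
        Upper quantile of occipital alpha used to adapt the individual
        A-stage threshold (default 0.10, i.e. the top decile).
    threshold_scale
        The threshold is ``threshold_scale`` times the mean occipital alpha
        over that top quantile (default 0.25).
    dt_dominance_factor
        Mean delta+theta must exceed mean alpha by this factor for B2/3.
    b1_context_window
        Seconds of preceding history searched for sub-wake stages when
        separating B1 from stage 0.
    """

    a_ratio: float = 2.0
    threshold_quantile: float = 0.10
    threshold_scale: float = 0.25
    dt_dominance_factor: float = 2.0
    b1_context_window: int = 60

    def __post_init__(self) -> None:
        for name in ("a_ratio", "threshold_quantile", "threshold_scale", "dt_dominance_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_quantile > 1:
            raise ValueError("threshold_quantile must lie in (0, 1]")
        if self.b1_context_window < 1:
            raise ValueError("b1_context_window must be at least 1 s")


def _validate_features(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    dens = table[ALPHA_COLS + DT_COLS].to_numpy(dtype=float)
    if not np.isfinite(dens).all() or (dens < 0).any():
        raise ValueError("band current densities must be finite and non-negative")


def compute_adaptive_threshold(table: pd.DataFrame, config: StagingConfig | None = None) -> float:
    """Individually adapted absolute alpha threshold for A-stages.

    Defined as ``threshold_scale`` x the mean occipital alpha current density
    over the top ``threshold_quantile`` of artifact-free segments.  Invariant
    to segment order and homogeneous under rescaling of all densities.

    Raises
    ------
    QCError
        If fewer than 60 artifact-free segments are available.
    """
    config = config or StagingConfig()
    _validate_features(table)
    clean = table.loc[table["artifact_flag"].astype(bool) == False, "alpha_occipital"]  # noqa: E712
    if len(clean) < MIN_CLEAN_SEGMENTS:
        raise QCError(
            f"adaptive threshold needs >= {MIN_CLEAN_SEGMENTS} artifact-free segments, "
            f"got {len(clean)}"
        )
    occ = np.sort(clean.to_numpy(dtype=float))[::-1]
    k = max(1, int(np.ceil(config.threshold_quantile * occ.size)))
    threshold = config.threshold_scale * float(occ[:k].mean())
    if threshold <= 0:
        raise QCError("adaptive threshold is non-positive (flat zero alpha)")
    return threshold


def classify_segment(
    features: pd.Series | dict,
    threshold: float,
    context: list[int] | np.ndarray = (),
    config: StagingConfig | None = None,
) -> int | None:
    """Classify one artifact-free segment; returns the numeric stage (7..1).

    ``context`` holds the numeric stages of the immediately preceding
    segments (most recent last); only the last ``b1_context_window`` entries
    are consulted.  Artifact segments are missing data and return ``None``.

    Rule cascade, first match wins:

    1. graph element present -> C
    2. A-candidate: max ROI alpha >= threshold and that ROI's alpha >=
       ``a_ratio`` x same-ROI delta+theta; then A1 if occipital alpha is
       strictly the greatest, A3 if frontal alpha >= occipital, else A2
    3. mean delta+theta >= ``dt_dominance_factor`` x mean alpha -> B2/3
    4. slow eye movements, or any sub-wake stage (A/B/C) in the recent
       context -> B1; otherwise stage 0
    """
    config = config or StagingConfig()
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    f = features
    if bool(f["artifact_flag"]):
        return None
    if bool(f["graph_flag"]):
        return STAGE_TO_NUMERIC["C"]

    alpha = np.array([float(f[c]) for c in ALPHA_COLS])
    dt = np.array([float(f[c]) for c in DT_COLS])
    i_max = int(np.argmax(alpha))
    if alpha[i_max] >= threshold and alpha[i_max] >= config.a_ratio * dt[i_max]:
        occ, fro = alpha[0], alpha[3]
        if occ > max(alpha[1], alpha[2], fro):
            return STAGE_TO_NUMERIC["A1"]
        if fro >= occ:
            return STAGE_TO_NUMERIC["A3"]
        return STAGE_TO_NUMERIC["A2"]

    if dt.mean() >= config.dt_dominance_factor * alpha.mean():
        return STAGE_TO_NUMERIC["B2/3"]

    recent = np.asarray(context)[-config.b1_context_window:]
    subwake = recent.size and (recent <= STAGE_TO_NUMERIC["A1"]).any()
    if bool(f["sem_flag"]) or subwake:
        return STAGE_TO_NUMERIC["B1"]
    return STAGE_TO_NUMERIC["0"]


def stage_recording(
    table: pd.DataFrame,
    config: StagingConfig | None = None,
    subject_id: str | None = None,
) -> StageSequence:
    """Classify every segment of one recording, left to right.

    The B1-vs-0 context rule is causal: it sees only previously assigned
    stages.  Artifact segments yield missing stages (kept in the sequence,
    flagged, excluded from all downstream metrics).
    """
    config = config or StagingConfig()
    if len(table) == 0:
        raise ValueError("empty feature table")
    _validate_features(table)
    threshold = compute_adaptive_threshold(table, config)

    n = len(table)
    numeric = np.full(n, STAGE_TO_NUMERIC["0"], dtype=int)
    artifact = table["artifact_flag"].to_numpy(dtype=bool)
    context: list[int] = []
    rows = table.to_dict("records")
    for i, row in enumerate(rows):
        stage = classify_segment(row, threshold, context, config)
        if stage is None:
            continue
        numeric[i] = stage
        context.append(stage)
    return StageSequence(numeric=numeric, artifact=artifact, subject_id=subject_id)


@dataclass(frozen=True)
class QCResult:
    fraction_artifact: float
    passed: bool


def qc_artifact_filter(seq: StageSequence, max_fraction: float = 0.15) -> QCResult:
    """Recording-level artifact rule: exclude if >= 15% of segments are artifacts.

    The bound is inclusive: a recording with exactly 15% artifact segments
    fails.
    """
    if seq.n_segments == 0:
        raise ValueError("empty stage sequence")
    frac = float(seq.artifact.mean())
    return QCResult(fraction_artifact=frac, passed=frac < max_fraction)
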
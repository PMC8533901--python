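"""Recording-level vigilance summaries: mean vigilance, stability score, slope index.

A 20-minute per-second stage sequence is reduced to three outcome variables:

* **mean vigilance** — arithmetic mean of the numeric stages (7..1) over
  artifact-free segments; the habitual arousal level.
* **stability score** — a 14-level ordinal index of how stably high arousal
  is maintained, driven by the depth and earliness of the decline (14 = only
  active/relaxed wakefulness throughout, 1 = early and substantial sleep
  onset).  The exact published rubric is not in the open literature; the
  rubric used here is a documented reconstruction shipped as a data file
  (``data/stability_rubric.csv``) and replaceable via
  :func:`load_stability_rubric`.
* **slope index** — ordinary least-squares slope of per-minute mean
  vigilance against time, in numeric stages per 10 minutes (negative =
  declining arousal).

Artifact segments are missing data: excluded from every numerator and
denominator, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stages import STAGE_TO_NUMERIC, StageSequence
from .staging import QCError

SECONDS_PER_MINUTE = 60
#: a per-minute block must contain at least this many artifact-free seconds
MIN_SECONDS_PER_BLOCK = 30

_STAGE_CLASS_NUMERIC = {
    "C": (1,),
    "B2/3": (2,),
    "B1": (3,),
    "A2A3": (4, 5),
}


@dataclass(frozen=True)
class VigilanceSummary:
    mean_vigilance: float
    stability_score: int
    slope_index: float

    def as_dict(self) -> dict:
        return {
            "mean_vigilance": self.mean_vigilance,
            "stability_score": self.stability_score,
            "slope_index": self.slope_index,
        }


def mean_vigilance(seq: StageSequence) -> float:
    """Mean numeric stage over artifact-free segments (range 1..7)."""
    clean = seq.clean_numeric
    if clean.size == 0:
        raise QCError("no artifact-free segments")
    return float(clean.mean())


def _minute_means(seq: StageSequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute mean vigilance and block midpoint times (minutes).

    Only blocks with >= 30 artifact-free seconds contribute.
    """
    n = seq.n_segments
    n_blocks = n // SECONDS_PER_MINUTE
    if n % SECONDS_PER_MINUTE:
        n_blocks += 1
    times, means = [], []
    for b in range(n_blocks):
        lo, hi = b * SECONDS_PER_MINUTE, min((b + 1) * SECONDS_PER_MINUTE, n)
        vals = seq.numeric[lo:hi][~seq.artifact[lo:hi]]
        if vals.size >= MIN_SECONDS_PER_BLOCK:
            times.append((lo + hi) / 2 / SECONDS_PER_MINUTE)
            means.append(vals.mean())
    return np.asarray(times, dtype=float), np.asarray(means, dtype=float)


def slope_index(seq: StageSequence) -> float:
    """OLS slope of per-minute mean vigilance vs time, per 10 minutes."""
    t, y = _minute_means(seq)
    if t.size < 2:
        raise QCError("slope index needs >= 2 usable one-minute blocks")
    tc = t - t.mean()
    slope_per_minute = float((tc @ (y - y.mean())) / (tc @ tc))
    return 10.0 * slope_per_minute


def load_stability_rubric(path=None) -> pd.DataFrame:
    """Load the 14-row first-match stability rubric (default: packaged file)."""
    if path is None:
        with resources.files("vigicorr.data").joinpath("stability_rubric.csv").open() as fh:
            rubric = pd.read_csv(fh)
    else:
        rubric = pd.read_csv(path)
    required = {"score", "stage_class", "min_prop", "strict", "first_within_minute"}
    if not required.issubset(rubric.columns):
        raise ValueError(f"rubric must have columns {sorted(required)}")
    return rubric


def stability_score(seq: StageSequence, rubric: pd.DataFrame | None = None) -> int:
    """14-level ordinal stability of arousal regulation.

    Rows of the rubric are evaluated in order (least stable first); the first
    matching row assigns the score.  A row matches when the proportion of
    artifact-free segments in its stage class reaches ``min_prop`` (strictly
    exceeds it when ``strict``) and, if ``first_within_minute`` is set, the
    first occurrence of that class falls within that many minutes from
    recording onset.  The terminal row (class ``any``) always matches.
    """
    if rubric is None:
        rubric = load_stability_rubric()
    clean_mask = ~seq.artifact
    clean = seq.numeric[clean_mask]
    if clean.size == 0:
        raise QCError("no artifact-free segments")
    seconds = np.arange(seq.n_segments)[clean_mask]

    for row in rubric.itertuples(index=False):
        if row.stage_class == "any":
            return int(row.score)
        members = np.isin(clean, _STAGE_CLASS_NUMERIC[row.stage_class])
        prop = members.mean()
        ok = prop > row.min_prop if row.strict else prop >= row.min_prop
        if not ok:
            continue
        if not pd.isna(row.first_within_minute):
            first_minute = seconds[members][0] / SECONDS_PER_MINUTE
            if first_minute > float(row.first_within_minute):
                continue
        return int(row.score)
    raise ValueError("rubric has no terminal row")  # pragma: no cover


def moving_average_course(seq: StageSequence, window: int = 61) -> np.ndarray:
    """Centered simple moving average of numeric stages over clean segments.

    For each second the mean is taken over the artifact-free segments inside
    ``t +/- (window-1)/2``, truncated at the recording edges; positions whose
    window holds no clean segment yield NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    n = seq.n_segments
    vals = np.where(seq.artifact, 0.0, seq.numeric.astype(float))
    cnts = (~seq.artifact).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0.0], np.cumsum(cnts)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    num = csum[hi] - csum[lo]
    den = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def summarize(seq: StageSequence, rubric: pd.DataFrame | None = None) -> VigilanceSummary:
    """All three outcome variables of one recording."""
    return VigilanceSummary(
        mean_vigilance=mean_vigilance(seq),
        stability_score=stability_score(seq, rubric),
        slope_index=slope_index(seq),
    )


def summarize_cohort(sequences: list[StageSequence], rubric: pd.DataFrame | None = None,
                     max_artifact_fraction: float = 0.15) -> pd.DataFrame:
    """Summary table over a cohort with a per-recording QC flag."""
    from .staging import qc_artifact_filter

    if rubric is None:
        rubric = load_stability_rubric()
    rows = []
    for seq in sequences:
        qc = qc_artifact_filter(seq, max_artifact_fraction)
        rec = {"subject_id": seq.subject_id, "qc_pass": qc.passed}
        if qc.passed:
            rec.update(summarize(seq, rubric).as_dict())
        else:
            rec.update({"mean_vigilance": np.nan, "stability_score": np.nan,
                        "slope_index": np.nan})
        rows.append(rec)
    cols = ["subject_id", "mean_vigilance", "stability_score", "slope_index", "qc_pass"]
    return pd.DataFrame(rows)[cols]
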
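"""Figure generation: group time-courses, slope boxplots, qq-envelope plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .metrics import moving_average_course
from .permutation import QQData
from .stages import StageSequence


def plot_timecourse(
    sequences: list[StageSequence],
    group_labels,
    window: int = 61,
    ax=None,
    title: str | None = None,
):
    """Per-group mean 61-s moving-average vigilance courses with +/- SE bands.

    ``group_labels`` assigns each sequence to a group (e.g. the low/high
    halves of a median split).
    """
    group_labels = np.asarray(group_labels, dtype=object)
    if len(group_labels) != len(sequences):
        raise ValueError("one group label per sequence required")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for group in pd_unique(group_labels):
        members = [s for s, g in zip(sequences, group_labels) if g == group]
        if not members:
            raise ValueError(f"empty group {group!r}")
        courses = np.vstack([moving_average_course(s, window) for s in members])
        mean = np.nanmean(courses, axis=0)
        se = np.nanstd(courses, axis=0, ddof=1) / np.sqrt(len(members))
        t = np.arange(mean.size) / 60.0
        ax.plot(t, mean, label=f"{group} (n={len(members)})")
        ax.fill_between(t, mean - se, mean + se, alpha=0.3)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("vigilance stage (7..1)")
    ax.set_ylim(1, 7)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def pd_unique(values):
    """Order-preserving unique (low/high groups keep their first-seen order)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def plot_slope_boxplots(summaries, phenotypes, traits, ax=None):
    """Slope-index boxplots stratified by low/high median-split per trait."""
    from .association import median_split_groups

    merged = phenotypes.merge(summaries, on="subject_id")
    if "qc_pass" in merged.columns:
        merged = merged[merged["qc_pass"].astype(bool)]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(traits) + 1, 4))
    data, labels = [], []
    for trait in traits:
        groups = median_split_groups(merged[trait].to_numpy())
        for g in ("low", "high"):
            data.append(merged.loc[groups == g, "slope_index"].to_numpy())
            labels.append(f"{trait[:5]}\n{g}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("slope index (stages / 10 min)")
    return ax


def plot_qq(qq: QQData, ax=None, title: str | None = None):
    """Observed vs expected -log10 p with the 5th-95th percentile null band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x = qq.mean_log10
    ax.fill_between(x, qq.lower_log10, qq.upper_log10, color="0.85",
                    label="5th-95th percentile (null)")
    ax.plot(x, x, color="k", lw=1, label="mean expected")
    ax.plot(x, qq.observed_log10, "o", ms=5, color="tab:blue", label="observed")
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def save(fig_or_ax, path) -> None:
    fig = fig_or_ax.figure if hasattr(fig_or_ax, "figure") else fig_or_ax
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
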
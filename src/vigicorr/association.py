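"""Spearman association testing between trait scores and vigilance metrics.

Implements rank correlations with mean-rank tie handling, the t-based
two-sided p-value, covariate-adjusted (partial) rank correlations via
residualization, and Benjamini–Hochberg step-up FDR adjustment.  The
association matrix couples a phenotype table (five trait dimensions or
thirty facets as T-scores) with the three vigilance summary metrics,
adjusting within the full family of tests (15 or 90).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DIMENSIONS = ["neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness"]
METRICS = ["mean_vigilance", "stability_score", "slope_index"]


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mean-ranked data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value from the t approximation on n-2 degrees of freedom.

    ``t = rho * sqrt((n-2) / (1-rho^2))``.  At |rho| = 1 the limit p = 0 is
    returned.  Standard at the cohort sizes this package targets (hundreds);
    for very small n an exact permutation p is available via
    :func:`spearman_exact_pvalue`.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if abs(rho) == 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_exact_pvalue(x, y) -> float:
    """Exact/permutation two-sided p (delegates to scipy; small n only)."""
    res = stats.spearmanr(x, y, alternative="two-sided")
    return float(res.pvalue)


def partial_spearman(x, y, covariates) -> tuple[float, float]:
    """Covariate-adjusted Spearman correlation.

    Both variables and every covariate column are rank-transformed; the
    ranked x and y are residualized on the ranked covariates (with
    intercept) by least squares and the Pearson correlation of the
    residuals is returned with a t-based p on ``n - 2 - k`` degrees of
    freedom.  With an empty covariate set this reduces exactly to
    :func:`spearman` + :func:`spearman_pvalue`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.size == 0:
        rho = spearman(x, y)
        return rho, spearman_pvalue(rho, x.size)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if n != x.size:
        raise ValueError("covariate rows must match observations")
    if k >= n - 3:
        raise ValueError("too many covariates for the sample size")
    Zr = np.apply_along_axis(stats.rankdata, 0, Z)
    design = np.column_stack([np.ones(n), Zr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient (collinear columns)")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((res_x @ res_x) * (res_y @ res_y))
    if denom == 0:
        return 0.0, 1.0
    rho = float((res_x @ res_y) / denom)
    df = n - 2 - k
    if abs(rho) >= 1:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return rho, float(2 * stats.t.sf(abs(t), df=df))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved.

    ``p_adj_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def median_split_groups(scores) -> np.ndarray:
    """Split scores into 'low'/'high' halves of the ascending order.

    The lower ``floor(n/2)`` order statistics form the low group; ties at
    the cut are resolved by stable sort order, so median-tied values fall
    into the low group first.  With all values equal everything is 'low'.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    labels = np.empty(s.size, dtype=object)
    order = np.argsort(s, kind="mergesort")
    n_low = s.size - s.size // 2  # odd n: low gets the extra member
    labels[order[:n_low]] = "low"
    labels[order[n_low:]] = "high"
    if np.ptp(s) == 0:
        import warnings

        warnings.warn("all scores equal; every subject assigned to the low group")
        labels[:] = "low"
    return labels


def association_matrix(
    phenotypes: pd.DataFrame,
    summaries: pd.DataFrame,
    trait_columns: list[str] | None = None,
    metric_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
    compute_bf: bool = True,
    kappa: float = 1 / 3,
) -> pd.DataFrame:
    """All trait x metric Spearman associations with BH-FDR and Bayes factors.

    Subjects are matched on ``subject_id``; recordings failing QC
    (``qc_pass`` False) are dropped.  FDR adjustment is performed within the
    full set of tests produced by this call (e.g. 5x3 = 15 dimension tests
    or 30x3 = 90 facet tests).
    """
    from .bayes import correlation_bf10

    trait_columns = trait_columns or DIMENSIONS
    metric_columns = metric_columns or METRICS
    for frame, name in ((phenotypes, "phenotypes"), (summaries, "summaries")):
        if frame["subject_id"].duplicated().any():
            dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids in {name}: {dupes[:5]}")
    merged = phenotypes.merge(summaries, on="subject_id", how="inner", validate="1:1")
    unmatched = set(phenotypes["subject_id"]) ^ set(summaries["subject_id"])
    if unmatched:
        raise ValueError(f"unmatched subject ids: {sorted(unmatched)[:10]}")
    if "qc_pass" in merged.columns:
        merged = merged[merged["qc_pass"].astype(bool)]
    n = len(merged)

    Z = merged[covariate_columns].to_numpy(dtype=float) if covariate_columns else None
    records = []
    for trait in trait_columns:
        for metric in metric_columns:
            x = merged[trait].to_numpy(dtype=float)
            y = merged[metric].to_numpy(dtype=float)
            if Z is None:
                rho = spearman(x, y)
                p = spearman_pvalue(rho, n)
            else:
                rho, p = partial_spearman(x, y, Z)
            records.append({"trait": trait, "metric": metric, "rho": rho, "n": n, "p": p})
    out = pd.DataFrame(records)
    out["p_fdr"] = bh_adjust(out["p"].to_numpy())
    if compute_bf:
        out["bf10"] = [correlation_bf10(r, n, kappa) for r in out["rho"]]
    out.attrs["n_nominal"] = int((out["p"] < 0.05).sum())
    out.attrs["n_fdr_significant"] = int((out["p_fdr"] < 0.05).sum())
    return out
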
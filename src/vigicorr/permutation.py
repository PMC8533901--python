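"""Structured permutation null for families of cross-domain rank correlations.

To judge whether a family of m observed p-values (trait x vigilance-metric
tests) collectively departs from chance, subject rows of the vigilance block
are shuffled as a unit: correlations *within* the trait block and *within*
the vigilance block are preserved exactly, while every cross-domain
correlation is destroyed.  Repeating this B times yields B exchangeable sets
of m null p-values from which qq-plot envelopes (per-rank mean and 5th/95th
percentiles on the -log10 scale) and exceedance summaries (fraction of sets
with >= k p-values below alpha; fraction with a minimum below p0) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import spearman_pvalue


def block_permute(Y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one shared row permutation to a whole variable block.

    Columns travel together, so the block's internal correlation matrix is
    bit-identical before and after; only its alignment with any other block
    is randomized.
    """
    Y = np.asarray(Y)
    perm = rng.permutation(Y.shape[0])
    return Y[perm]


def _rank_standardize(M: np.ndarray) -> np.ndarray:
    """Column-wise mean ranks, centered and scaled to unit norm."""
    R = np.apply_along_axis(stats.rankdata, 0, np.asarray(M, dtype=float))
    R -= R.mean(axis=0)
    norms = np.linalg.norm(R, axis=0)
    if (norms == 0).any():
        raise ValueError("constant column: rank correlation undefined")
    return R / norms


@dataclass
class PermutationNull:
    """B sorted sets of m null p-values plus the RNG seed that produced them."""

    p_sets: np.ndarray  # shape (B, m), each row sorted ascending
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.p_sets.shape[0]

    @property
    def n_tests(self) -> int:
        return self.p_sets.shape[1]


def permutation_pvalue_sets(
    X: np.ndarray,
    Y: np.ndarray,
    B: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> PermutationNull:
    """B permutation sets of all cross-domain Spearman p-values.

    X (n x p traits) and Y (n x q metrics) must be row-aligned by subject.
    Each permutation shuffles the rows of Y as a block and computes all
    p*q Spearman p-values (t approximation, matching the observed analysis).
    Rows of the result are sorted ascending.
    """
    if B < 100:
        raise ValueError("need at least B = 100 permutation sets")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have matching rows (subjects)")
    n = X.shape[0]
    Xs = _rank_standardize(X)
    Ys = _rank_standardize(Y)
    m = Xs.shape[1] * Ys.shape[1]
    p_sets = np.empty((B, m))
    for b in range(B):
        perm = rng.permutation(n)
        rho = Xs.T @ Ys[perm]  # p x q cross-correlations of ranks
        rho = np.clip(rho.ravel(), -1 + 1e-15, 1 - 1e-15)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p_sets[b] = np.sort(2 * stats.t.sf(np.abs(t), df=n - 2))
    return PermutationNull(p_sets=p_sets, seed=seed)


@dataclass
class QQData:
    """Per-rank envelope of the permutation null, on the -log10 p scale.

    Ranks run from the largest p-value to the smallest, matching a qq-plot
    drawn left to right.
    """

    mean_log10: np.ndarray
    lower_log10: np.ndarray  # 5th percentile
    upper_log10: np.ndarray  # 95th percentile
    observed_log10: np.ndarray
    exceeds_upper: np.ndarray  # bool per rank


def qq_envelope(null: PermutationNull, observed_p: np.ndarray,
                percentiles: tuple[float, float] = (5.0, 95.0)) -> QQData:
    """Observed -log10 p-values against the permutation envelope, per rank."""
    observed_p = np.asarray(observed_p, dtype=float)
    if observed_p.size != null.n_tests:
        raise ValueError("observed p-value count must equal tests per permutation set")
    # sort sets descending in p (ascending in -log10 p): rank 0 = largest p
    neglog_null = -np.log10(null.p_sets[:, ::-1])
    mean = neglog_null.mean(axis=0)
    lower = np.percentile(neglog_null, percentiles[0], axis=0)
    upper = np.percentile(neglog_null, percentiles[1], axis=0)
    observed = -np.log10(np.sort(observed_p)[::-1])
    return QQData(
        mean_log10=mean,
        lower_log10=lower,
        upper_log10=upper,
        observed_log10=observed,
        exceeds_upper=observed > upper,
    )


def exceedance_summaries(
    null: PermutationNull,
    alpha: float = 0.05,
    k: int = 1,
    p0: float | None = None,
) -> dict:
    """Chance frequencies of multiplicity patterns under the null.

    Returns the fraction of permutation sets containing at least ``k``
    p-values below ``alpha``, and (if ``p0`` given) the fraction whose
    smallest p-value falls below ``p0``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    counts = (null.p_sets < alpha).sum(axis=1)
    out = {"frac_at_least_k_below_alpha": float((counts >= k).mean()),
           "alpha": alpha, "k": k}
    if p0 is not None:
        if not 0 < p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        out["frac_min_below_p0"] = float((null.p_sets[:, 0] < p0).mean())
        out["p0"] = p0
    return out
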
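"""Reference association results from a published resting-state cohort analysis.

A large population cohort study (N = 468) correlated the five NEO
personality dimensions and thirty facets (sex- and age-normalized T-scores)
with three EEG-vigilance summary variables.  The printed dimension-level
association table and the nominally significant facet rows are shipped here
as package data: they serve as worked-example inputs and as internal
consistency fixtures (recomputing p from rho and n, FDR counts, Bayes
factors) without requiring the access-restricted raw data.
"""

from __future__ import annotations

import pandas as pd

#: sample size of the reference cohort
REFERENCE_N = 468

_DIMENSION_ROWS = [
    # trait, metric, rho, p, p_fdr, bf10
    ("neuroticism", "mean_vigilance", -0.063, 0.170, 0.365, 0.27),
    ("neuroticism", "stability_score", -0.030, 0.515, 0.766, 0.13),
    ("neuroticism", "slope_index", -0.002, 0.972, 0.972, 0.11),
    ("extraversion", "mean_vigilance", -0.104, 0.025, 0.082, 1.29),
    ("extraversion", "stability_score", -0.096, 0.038, 0.095, 0.91),
    ("extraversion", "slope_index", -0.137, 0.003, 0.023, 8.35),
    ("openness", "mean_vigilance", -0.102, 0.027, 0.082, 1.20),
    ("openness", "stability_score", -0.121, 0.009, 0.044, 3.23),
    ("openness", "slope_index", -0.173, 2e-4, 0.002, 121.33),
    ("agreeableness", "mean_vigilance", -0.027, 0.561, 0.766, 0.13),
    ("agreeableness", "stability_score", -0.012, 0.791, 0.913, 0.11),
    ("agreeableness", "slope_index", -0.032, 0.496, 0.766, 0.14),
    ("conscientiousness", "mean_vigilance", -0.023, 0.624, 0.780, 0.12),
    ("conscientiousness", "stability_score", -0.005, 0.913, 0.972, 0.11),
    ("conscientiousness", "slope_index", -0.039, 0.399, 0.748, 0.15),
]

_FACET_ROWS = [
    ("impulsiveness", "mean_vigilance", -0.150, 0.001, 19.88),
    ("warmth", "slope_index", -0.119, 0.010, 2.90),
    ("assertiveness", "slope_index", -0.109, 0.018, 1.73),
    ("activity", "slope_index", -0.114, 0.014, 2.14),
    ("positive_emotions", "slope_index", -0.116, 0.012, 2.43),
    ("fantasy", "slope_index", -0.094, 0.041, 0.85),
    ("aesthetics", "slope_index", -0.137, 0.003, 8.60),
    ("feelings", "slope_index", -0.137, 0.003, 8.27),
    ("actions", "slope_index", -0.109, 0.018, 1.68),
    ("ideas", "slope_index", -0.128, 0.006, 4.76),
    ("tender_mindedness", "slope_index", -0.145, 0.002, 14.40),
    ("achievement_striving", "slope_index", -0.135, 0.003, 7.65),
]


def dimension_associations() -> pd.DataFrame:
    """The 15 dimension x metric reference associations (rho, p, FDR, BF10)."""
    return pd.DataFrame(
        _DIMENSION_ROWS, columns=["trait", "metric", "rho", "p", "p_fdr", "bf10"]
    )


def facet_highlights() -> pd.DataFrame:
    """The nominally significant facet-level reference associations."""
    return pd.DataFrame(_FACET_ROWS, columns=["trait", "metric", "rho", "p", "bf10"])
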
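"""End-to-end orchestration: simulate -> stage -> summarize -> associate -> qq -> power.

The pipeline runs on a synthetic cohort (or on user-supplied tables), writes
all intermediate TSVs, a JSON result bundle, optional figures, and a run
manifest tying every product to the seed and configuration hash.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import DIMENSIONS, METRICS, association_matrix, median_split_groups
from .metrics import summarize_cohort
from .permutation import exceedance_summaries, permutation_pvalue_sets, qq_envelope
from .power import bonferroni_alpha, correlation_power, detectable_r
from .synthetic import FACET_COLUMNS, CohortConfig, MarkovParams, simulate_cohort

log = logging.getLogger("vigicorr")

COVARIATES = ["sex", "age", "daytime"]


def load_config(path) -> CohortConfig:
    """Build a cohort configuration from a YAML mapping (missing keys -> defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    markov = MarkovParams(**raw.pop("markov", {}))
    return CohortConfig(markov=markov, **raw)


def _qq_block(X, Y, observed_p, B, rng):
    null = permutation_pvalue_sets(X, Y, B=B, rng=rng)
    qq = qq_envelope(null, observed_p)
    exc = exceedance_summaries(null, alpha=0.05, k=int((observed_p < 0.05).sum()),
                               p0=float(np.min(observed_p)))
    return null, qq, exc


def run_pipeline(
    config: CohortConfig | None = None,
    out_dir: str | Path = "results",
    B: int = 10_000,
    with_figures: bool = True,
    with_features: bool = False,
    facets: bool = True,
) -> dict:
    """Execute the full analysis on a simulated cohort and write all products.

    Returns the result bundle (also written to ``out_dir/results.json``).
    """
    t0 = time.time()
    config = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)  # analysis stream, distinct from cohort

    log.info("simulate: n_subjects=%d n_segments=%d seed=%d",
             config.n_subjects, config.n_segments, config.seed)
    cohort = simulate_cohort(config, with_features=with_features)
    io.write_table(cohort.phenotypes, out / "phenotypes.tsv")
    io.write_stage_sequences(cohort.sequences, out / "stages.tsv")
    if with_features:
        io.write_table(cohort.feature_frame(), out / "features.tsv")

    summaries = summarize_cohort(cohort.sequences)
    n_fail = int((~summaries["qc_pass"]).sum())
    log.info("summarize: %d subjects, %d excluded by artifact QC", len(summaries), n_fail)
    io.write_table(summaries, out / "summaries.tsv")

    results: dict = {"manifest": cohort.manifest}
    scopes = {"dimensions": DIMENSIONS}
    if facets:
        scopes["facets"] = FACET_COLUMNS
    merged = cohort.phenotypes.merge(summaries, on="subject_id")
    merged = merged[merged["qc_pass"].astype(bool)]

    for scope, traits in scopes.items():
        assoc = association_matrix(cohort.phenotypes, summaries, trait_columns=traits)
        io.write_table(assoc, out / f"associations_{scope}.tsv")
        assoc_adj = association_matrix(cohort.phenotypes, summaries, trait_columns=traits,
                                       covariate_columns=COVARIATES, compute_bf=False)
        io.write_table(assoc_adj, out / f"associations_{scope}_adjusted.tsv")
        log.info("associate[%s]: %d tests, %d nominal, %d FDR-significant",
                 scope, len(assoc), assoc.attrs["n_nominal"], assoc.attrs["n_fdr_significant"])

        X = merged[traits].to_numpy(dtype=float)
        Y = merged[METRICS].to_numpy(dtype=float)
        null, qq, exc = _qq_block(X, Y, assoc["p"].to_numpy(), B, rng)
        results[scope] = {
            "n_tests": len(assoc),
            "n_nominal": assoc.attrs["n_nominal"],
            "n_fdr_significant": assoc.attrs["n_fdr_significant"],
            "strongest": assoc.loc[assoc["p"].idxmin(),
                                   ["trait", "metric", "rho", "p", "p_fdr", "bf10"]].to_dict(),
            "exceedance": exc,
            "n_ranks_above_envelope": int(qq.exceeds_upper.sum()),
        }
        if with_figures:
            from . import plots

            ax = plots.plot_qq(qq, title=f"{scope} ({len(assoc)} tests, B={null.n_sets})")
            plots.save(ax, out / f"qq_{scope}.svg")

    n = len(merged)
    results["power"] = {
        "n": n,
        "detectable_r": {p: detectable_r(p, n, 0.05) for p in (0.2, 0.5, 0.8)},
        "detectable_r_bonferroni": {
            p: detectable_r(p, n, bonferroni_alpha(0.05, 15)) for p in (0.2, 0.5, 0.8)
        },
        "power_at_r_0.2": correlation_power(0.2, n, 0.05),
    }

    if with_figures:
        from . import plots

        for trait in ("extraversion", "openness"):
            groups = median_split_groups(merged[trait].to_numpy())
            seqs = [s for s in cohort.sequences if s.subject_id in set(merged["subject_id"])]
            ax = plots.plot_timecourse(seqs, groups, title=trait)
            plots.save(ax, out / f"timecourse_{trait}.svg")
        ax = plots.plot_slope_boxplots(summaries, cohort.phenotypes, DIMENSIONS)
        plots.save(ax, out / "slope_boxplots.svg")

    results["manifest"]["runtime_s"] = round(time.time() - t0, 2)
    results["manifest"]["markov"] = asdict(config.markov)
    io.write_manifest(results, out / "results.json")
    log.info("pipeline complete in %.1f s -> %s", time.time() - t0, out)
    return results
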
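"""Synthetic resting-state cohorts with trait-linked arousal decline.

The generator emulates the statistical structure that the association
pipeline assumes, so that every downstream stage (staging, summary metrics,
correlation testing, permutation nulls) can be exercised end to end without
access-restricted cohort data:

* five correlated personality dimensions plus thirty facets on the T-score
  scale (mean 50, SD 10), six facets loading on each parent dimension;
* a latent *arousal propensity* ``g`` per subject, constructed so that its
  population correlation with each trait equals a configurable effect
  vector, with additive age and daytime-of-assessment effects;
* a 20-minute per-second vigilance stage course realized by a sticky
  single-step Markov chain over the numeric stages 7..1 that mean-reverts
  toward a subject-specific target level declining linearly in time — the
  decline rate is an affine function of the subject's decline propensity
  ``d = -g``;
* optional stage-conditional feature channels (ROI band current densities
  plus EOG/graph-element flags) built from per-stage templates that satisfy
  the staging rule cascade exactly at zero noise.

All stochastic operations take an explicit :class:`numpy.random.Generator`;
cohort products carry a manifest recording the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stages import STAGE_LABELS, STAGE_TO_NUMERIC, ROIS, StageSequence
from .association import DIMENSIONS

#: NEO-style facet names, six per dimension.
FACETS: dict[str, list[str]] = {
    "neuroticism": ["anxiety", "angry_hostility", "depression",
                    "self_consciousness", "impulsiveness", "vulnerability"],
    "extraversion": ["warmth", "gregariousness", "assertiveness",
                     "activity", "excitement_seeking", "positive_emotions"],
    "openness": ["fantasy", "aesthetics", "feelings", "actions", "ideas", "values"],
    "agreeableness": ["trust", "straightforwardness", "altruism",
                      "compliance", "modesty", "tender_mindedness"],
    "conscientiousness": ["competence", "order", "dutifulness",
                          "achievement_striving", "self_discipline", "deliberation"],
}
FACET_COLUMNS = [f for facets in FACETS.values() for f in facets]

DAYTIME_SLOTS = (8.5, 11.0, 13.5)  # morning / late morning / early afternoon, hours

AGE_RANGE = (40.0, 79.0)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def spearman_to_pearson(rho_s):
    """Greiner's relation: latent Pearson correlation of a bivariate normal
    pair whose population Spearman correlation is ``rho_s``.

    Configured correlations (trait matrix, effect vector, covariate effects)
    are interpreted on the Spearman scale — the scale on which the analysis
    reports them — and mapped through this relation before being imposed on
    the latent normal variables, so that *sample Spearman* correlations
    recover the configured values.  The mapping is elementwise and preserves
    positive semi-definiteness of correlation matrices.
    """
    return 2 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6)


def default_trait_corr() -> np.ndarray:
    """Default dimension correlation matrix: identity except rho(E, O) = 0.477."""
    corr = np.eye(5)
    i, j = DIMENSIONS.index("extraversion"), DIMENSIONS.index("openness")
    corr[i, j] = corr[j, i] = 0.477
    return corr


def default_effect_vector() -> np.ndarray:
    """Default trait -> arousal-propensity correlations (N, E, O, A, C)."""
    return np.array([-0.002, -0.137, -0.173, -0.032, -0.039])


def default_feature_templates() -> dict:
    """Per-stage ROI density templates satisfying the staging rules at zero noise.

    ROI order is (occipital, parietal, temporal, frontal).
    """
    return {
        "0":    {"alpha": (3.0, 3.0, 2.5, 2.5), "deltatheta": (2.0, 2.0, 2.0, 2.0),
                 "sem": False, "graph": False},
        "A1":   {"alpha": (20.0, 10.0, 8.0, 8.0), "deltatheta": (4.0, 4.0, 4.0, 4.0),
                 "sem": False, "graph": False},
        "A2":   {"alpha": (12.0, 22.0, 6.0, 6.0), "deltatheta": (4.0, 4.0, 4.0, 4.0),
                 "sem": False, "graph": False},
        "A3":   {"alpha": (6.0, 6.0, 6.0, 18.0), "deltatheta": (4.0, 4.0, 4.0, 4.0),
                 "sem": False, "graph": False},
        "B1":   {"alpha": (3.0, 3.0, 3.0, 3.0), "deltatheta": (4.0, 4.0, 4.0, 4.0),
                 "sem": True, "graph": False},
        "B2/3": {"alpha": (2.0, 2.0, 2.0, 2.0), "deltatheta": (10.0, 10.0, 10.0, 10.0),
                 "sem": False, "graph": False},
        "C":    {"alpha": (2.0, 2.0, 2.0, 2.0), "deltatheta": (12.0, 12.0, 12.0, 12.0),
                 "sem": False, "graph": True},
    }


@dataclass(frozen=True)
class MarkovParams:
    """Dynamics of the per-second stage chain.

    The chain makes single-step moves over the numeric stages 7..1 with
    stickiness (probability of not moving at all each second).  Given a move
    opportunity, the chain steps toward its subject-specific target level,
    which declines linearly with elapsed minutes at a subject-specific rate:
    down (with certainty) when strictly above target, up (with probability
    ``recovery``) when strictly below, and not at all when on target.

    stickiness
        P(no move opportunity) per second.
    recovery
        P(up-step | move opportunity, below target): how readily arousal
        recovers toward its target after a transient dip.
    drift_mean, drift_sd
        Population mean and between-subject SD of the decline rate, in
        numeric stages per minute.  A subject with decline propensity
        ``d`` (standard normal across the cohort) declines at
        ``drift_mean + drift_sd * d``; negative rates (arousal maintenance)
        are possible and capped by the stage ceiling.
    start_level
        Target level at recording onset (subjects start in active/relaxed
        wakefulness after a brief activating task).
    """

    stickiness: float = 0.70
    recovery: float = 0.5
    drift_mean: float = 0.152
    drift_sd: float = 0.092
    start_level: float = 6.7

    def __post_init__(self) -> None:
        for name in ("stickiness", "recovery"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.start_level <= 7:
            raise ConfigurationError("start_level must lie in [1, 7]")


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort."""

    n_subjects: int = 468
    seed: int = 0
    trait_corr: np.ndarray = field(default_factory=default_trait_corr)
    facet_loading: float = 0.7
    effect_vector: np.ndarray = field(default_factory=default_effect_vector)
    age_effect: float = 0.168
    daytime_effect: float = -0.155
    n_segments: int = 1200
    markov: MarkovParams = field(default_factory=MarkovParams)
    feature_templates: dict = field(default_factory=default_feature_templates)
    feature_noise_sd: float = 0.2  # multiplicative noise, fraction of template value
    artifact_rate: float = 0.02  # mean per-second artifact probability

    def __post_init__(self) -> None:
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        self.effect_vector = np.asarray(self.effect_vector, dtype=float)
        if self.trait_corr.shape != (5, 5):
            raise ConfigurationError("trait_corr must be 5x5")
        if not np.allclose(self.trait_corr, self.trait_corr.T):
            raise ConfigurationError(f"trait_corr is not symmetric:\n{self.trait_corr}")
        if not np.allclose(np.diag(self.trait_corr), 1.0):
            raise ConfigurationError("trait_corr must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.trait_corr)
        if eigvals.min() < -1e-10:
            raise ConfigurationError(
                f"trait_corr is not positive semi-definite (min eigenvalue "
                f"{eigvals.min():.3g}):\n{self.trait_corr}"
            )
        if self.effect_vector.shape != (5,):
            raise ConfigurationError("effect_vector must have 5 entries")
        for name in ("age_effect", "daytime_effect"):
            if abs(getattr(self, name)) >= 1:
                raise ConfigurationError(f"|{name}| must be < 1")
        if (np.abs(self.effect_vector) >= 1).any():
            raise ConfigurationError("each trait effect must satisfy |effect| < 1")
        if not 0 < self.facet_loading <= 1:
            raise ConfigurationError("facet_loading must lie in (0, 1]")
        if self.n_segments < 60:
            raise ConfigurationError("n_segments must be at least 60 (one minute)")
        if not 0 <= self.artifact_rate < 1:
            raise ConfigurationError("artifact_rate must lie in [0, 1)")
        # explained variance of the latent propensity must stay below 1
        corr_latent = spearman_to_pearson(self.trait_corr)
        np.fill_diagonal(corr_latent, 1.0)
        effects_latent = spearman_to_pearson(self.effect_vector)
        w = np.linalg.solve(corr_latent, effects_latent)
        explained = (float(effects_latent @ w)
                     + float(spearman_to_pearson(self.age_effect)) ** 2
                     + float(spearman_to_pearson(self.daytime_effect)) ** 2)
        if explained >= 1:
            raise ConfigurationError(
                f"effect vector and covariate effects imply multiple correlation "
                f">= 1 (explained variance {explained:.3f})"
            )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["trait_corr"] = self.trait_corr.tolist()
        payload["effect_vector"] = self.effect_vector.tolist()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def simulate_traits(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Phenotype table: correlated dimension and facet T-scores plus covariates.

    Dimensions are multivariate normal on the latent scale (correlation
    ``trait_corr``), affinely mapped to T-scores (mean 50, SD 10) without
    rounding.  Each facet is ``loading * parent + sqrt(1-loading^2) * noise``
    on the latent scale, likewise mapped to the T-scale.
    """
    n = config.n_subjects
    corr_latent = spearman_to_pearson(config.trait_corr)
    np.fill_diagonal(corr_latent, 1.0)
    L = np.linalg.cholesky(corr_latent + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ L.T

    table = {"subject_id": [f"S{i:04d}" for i in range(n)]}
    for j, dim in enumerate(DIMENSIONS):
        table[dim] = 50 + 10 * z[:, j]
    lam = config.facet_loading
    resid = np.sqrt(1 - lam**2)
    for j, dim in enumerate(DIMENSIONS):
        for facet in FACETS[dim]:
            table[facet] = 50 + 10 * (lam * z[:, j] + resid * rng.standard_normal(n))
    table["sex"] = rng.integers(0, 2, size=n)
    table["age"] = rng.uniform(*AGE_RANGE, size=n)
    table["daytime"] = rng.choice(DAYTIME_SLOTS, size=n)
    return pd.DataFrame(table)


def _latent_arousal(config: CohortConfig, phenotypes: pd.DataFrame,
                    rng: np.random.Generator) -> np.ndarray:
    """Standard-normal arousal propensity with the configured correlations.

    corr(trait_k, g) = effect_vector[k], corr(age, g) = age_effect,
    corr(daytime, g) = daytime_effect (all on the Spearman scale, imposed on
    the latent scale via Greiner's relation); the remainder is independent
    noise.
    """
    z = (phenotypes[DIMENSIONS].to_numpy() - 50) / 10
    corr_latent = spearman_to_pearson(config.trait_corr)
    np.fill_diagonal(corr_latent, 1.0)
    effects_latent = spearman_to_pearson(config.effect_vector)
    w = np.linalg.solve(corr_latent, effects_latent)

    age = phenotypes["age"].to_numpy()
    age_sd = (AGE_RANGE[1] - AGE_RANGE[0]) / np.sqrt(12)
    age_s = (age - np.mean(AGE_RANGE)) / age_sd
    day = phenotypes["daytime"].to_numpy()
    slots = np.asarray(DAYTIME_SLOTS)
    day_s = (day - slots.mean()) / slots.std()

    age_eff = float(spearman_to_pearson(config.age_effect))
    day_eff = float(spearman_to_pearson(config.daytime_effect))
    explained = float(effects_latent @ w) + age_eff**2 + day_eff**2
    eps = rng.standard_normal(len(phenotypes))
    return (z @ w + age_eff * age_s + day_eff * day_s
            + np.sqrt(1 - explained) * eps)


def _simulate_stage_matrix(decline: np.ndarray, config: CohortConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Vectorized stage chains, one row per subject.

    ``decline`` holds the standardized decline propensities d_i; the
    per-minute decline rate is ``drift_mean + drift_sd * d_i``.
    """
    mk = config.markov
    n = decline.size
    T = config.n_segments
    drift = mk.drift_mean + mk.drift_sd * np.asarray(decline, dtype=float)

    # start in wakefulness: stochastic rounding of the onset target level
    base = int(np.floor(mk.start_level))
    frac = mk.start_level - base
    s = base + (rng.random(n) < frac).astype(int)
    s = np.clip(s, 1, 7)

    move_prob = 1 - mk.stickiness

    out = np.empty((n, T), dtype=np.int8)
    minutes = np.arange(T) / 60.0
    for t in range(T):
        out[:, t] = s
        # target never exceeds its onset level: without stimulation, arousal
        # does not rise above where the activating pre-task left it
        mu = np.clip(mk.start_level - drift * minutes[t], 1.0, mk.start_level)
        delta = s - mu
        move = rng.random(n) < move_prob
        down = move & (delta > 0)
        up = move & (delta < 0) & (rng.random(n) < mk.recovery)
        s = np.clip(s + up.astype(int) - down.astype(int), 1, 7)
    return out


def simulate_vigilance_course(decline_propensity: float, config: CohortConfig,
                              rng: np.random.Generator) -> StageSequence:
    """One subject's per-second stage sequence (no artifacts)."""
    numeric = _simulate_stage_matrix(np.array([decline_propensity]), config, rng)[0]
    return StageSequence(numeric=numeric.astype(int))


def simulate_features_from_stages(seq: StageSequence, config: CohortConfig,
                                  rng: np.random.Generator) -> pd.DataFrame:
    """Stage-conditional ROI band densities and flags for one recording.

    Each segment draws its densities from the template of its true stage
    with multiplicative Gaussian noise (SD = ``feature_noise_sd`` times the
    template value, truncated at zero).  Artifact segments keep their
    template features but carry the artifact flag.
    """
    templates = config.feature_templates
    missing = [lab for lab in set(seq.labels) if lab not in templates]
    if missing:
        raise ConfigurationError(f"no feature template for stage(s): {sorted(missing)}")
    n = seq.n_segments
    alpha = np.empty((n, 4))
    dt = np.empty((n, 4))
    sem = np.zeros(n, dtype=bool)
    graph = np.zeros(n, dtype=bool)
    labels = seq.labels
    for lab in set(labels):
        mask = labels == lab
        tpl = templates[lab]
        alpha[mask] = np.asarray(tpl["alpha"], dtype=float)
        dt[mask] = np.asarray(tpl["deltatheta"], dtype=float)
        sem[mask] = bool(tpl["sem"])
        graph[mask] = bool(tpl["graph"])
    if config.feature_noise_sd > 0:
        alpha = np.maximum(alpha * (1 + config.feature_noise_sd * rng.standard_normal(alpha.shape)), 0.0)
        dt = np.maximum(dt * (1 + config.feature_noise_sd * rng.standard_normal(dt.shape)), 0.0)
    out = {"second_index": np.arange(n)}
    for i, roi in enumerate(ROIS):
        out[f"alpha_{roi}"] = alpha[:, i]
    for i, roi in enumerate(ROIS):
        out[f"deltatheta_{roi}"] = dt[:, i]
    out["sem_flag"] = sem.astype(int)
    out["graph_flag"] = graph.astype(int)
    out["artifact_flag"] = seq.artifact.astype(int)
    frame = pd.DataFrame(out)
    if seq.subject_id is not None:
        frame.insert(0, "subject_id", seq.subject_id)
    return frame


@dataclass
class Cohort:
    """Products of one cohort simulation."""

    phenotypes: pd.DataFrame
    sequences: list[StageSequence]
    features: list[pd.DataFrame] | None
    manifest: dict

    def stage_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sequences], ignore_index=True)

    def feature_frame(self) -> pd.DataFrame:
        if self.features is None:
            raise ValueError("cohort was simulated without feature channels")
        return pd.concat(self.features, ignore_index=True)


def simulate_cohort(config: CohortConfig | None = None, rng=None,
                    with_features: bool = False) -> Cohort:
    """Simulate a full cohort: phenotypes, stage courses, optional features.

    The decline propensity is ``d = -g`` where g is the latent arousal
    propensity correlated with traits and covariates as configured; the
    stage chain's per-minute decline rate is affine in d, so the realized
    slope index inherits (up to realization noise) the configured trait
    correlations.
    """
    config = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    phenotypes = simulate_traits(config, rng)
    g = _latent_arousal(config, phenotypes, rng)
    decline = -g
    stages = _simulate_stage_matrix(decline, config, rng)

    # per-subject artifact probability, small on average, iid per second
    if config.artifact_rate > 0:
        subj_rate = rng.beta(1.0, 1.0 / config.artifact_rate - 1.0, size=config.n_subjects)
        artifact = rng.random(stages.shape) < subj_rate[:, None]
    else:
        artifact = np.zeros(stages.shape, dtype=bool)

    sequences = [
        StageSequence(numeric=stages[i].astype(int), artifact=artifact[i],
                      subject_id=sid)
        for i, sid in enumerate(phenotypes["subject_id"])
    ]
    features = None
    if with_features:
        features = [simulate_features_from_stages(seq, config, rng) for seq in sequences]

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": config.n_subjects,
        "n_segments": config.n_segments,
        "with_features": with_features,
    }
    return Cohort(phenotypes=phenotypes, sequences=sequences, features=features,
                  manifest=manifest)
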
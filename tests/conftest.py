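import numpy as np
import pandas as pd
import pytest

from vigicorr.stages import StageSequence
from vigicorr.synthetic import CohortConfig, default_feature_templates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Cheap cohort configuration for structural tests."""
    return CohortConfig(n_subjects=40, seed=7, n_segments=300)


def make_feature_row(alpha, deltatheta, sem=False, graph=False, artifact=False):
    """One segment's feature dict from ROI tuples (occipital, parietal, temporal, frontal)."""
    rois = ("occipital", "parietal", "temporal", "frontal")
    row = {f"alpha_{r}": a for r, a in zip(rois, alpha)}
    row |= {f"deltatheta_{r}": d for r, d in zip(rois, deltatheta)}
    row |= {"sem_flag": sem, "graph_flag": graph, "artifact_flag": artifact}
    return row


def template_feature_table(labels, noise_sd=0.0, rng=None):
    """Noise-free (or noisy) feature table built from the default stage templates."""
    seq = StageSequence.from_labels(list(labels))
    cfg = CohortConfig(n_subjects=2, n_segments=max(60, len(labels)),
                       feature_noise_sd=noise_sd)
    from vigicorr.synthetic import simulate_features_from_stages

    rng = rng or np.random.default_rng(0)
    return simulate_features_from_stages(seq, cfg, rng)


@pytest.fixture
def stage_templates():
    return default_feature_templates()


def sequence_from_numeric(values, artifact=None, subject_id=None):
    return StageSequence(numeric=np.asarray(values, dtype=int),
                         artifact=artifact, subject_id=subject_id)
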
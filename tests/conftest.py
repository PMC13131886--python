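"""Shared fixtures.

The expensive artifacts (the default synthetic cohort, an ensemble of
models trained on it, and the attribution bundles) are session-scoped and
shared across test modules; everything is generated programmatically at
test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from dualpath import SyntheticSpec, generate_cohort
from dualpath.evaluate import encode_cohort_metadata, prepare_inputs
from dualpath.nn import ArchitectureConfig, TrainConfig, fit_ensemble
from dualpath import xai as xai_mod

#: desk-scale architecture used in tests: same topology as the default,
#: narrower channels so CPU training stays fast
DESK_CHANNELS = (32, 32, 32)

#: generator seed for the default recovery cohort, stated once and reused
COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (60/group, 246 ROIs, 250 TRs) + ground truth."""
    return generate_cohort(SyntheticSpec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_inputs(default_cohort):
    cohort, _ = default_cohort
    X, y = prepare_inputs(cohort)
    meta = encode_cohort_metadata(cohort, np.arange(len(y)))
    return X, meta, y


@pytest.fixture(scope="session")
def desk_arch(cohort_inputs):
    _, meta, _ = cohort_inputs
    return ArchitectureConfig(conv_channels=DESK_CHANNELS,
                              metadata_dim=meta.shape[1],
                              dropout=0.3, fusion_alpha=0.5)


@pytest.fixture(scope="session")
def ensemble_models(default_cohort, cohort_inputs, desk_arch):
    """Four models trained to convergence, differing only in seed."""
    X, meta, y = cohort_inputs
    cfg = TrainConfig(lr=1e-3, batch_size=16, max_epochs=40, patience=40, seed=0)
    return fit_ensemble(X, meta, y, desk_arch, cfg, n_models=4)


@pytest.fixture(scope="session")
def trained_model(ensemble_models):
    return ensemble_models[0]


@pytest.fixture(scope="session")
def bundles(ensemble_models, default_cohort, cohort_inputs):
    """Ensemble-averaged attribution bundles for every subject."""
    cohort, _ = default_cohort
    X, meta, _ = cohort_inputs
    return xai_mod.ensemble_bundles(ensemble_models, X, meta,
                                    cohort.subject_ids, n_steps=16)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchitectureConfig(in_regions=6, conv_channels=(8, 8, 8),
                              attention_hidden=8, metadata_dim=4,
                              dropout=0.0, fusion_alpha=0.5)
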
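"""Shared fixtures: simulated cohorts at two scales.

The "easy" cohort (6 subjects, high reactivity, low noise) exercises the
full pipeline including parameter recovery; the small single recording
keeps per-module tests cheap.
"""

import numpy as np
import pytest

from painreact import (PipelineConfig, SimulationConfig, prepare_dataset,
                       preprocess_recording, simulate_subject)
from painreact.feature_extraction import pool_features


@pytest.fixture(scope="session")
def small_recording():
    """One short session (80 s) with frequent, strong episodes."""
    config = SimulationConfig(
        n_subjects=1, session_s=80.0, episode_rate=8.0,
        reactivity_ranges={k: (1.5, 2.5) for k in
                           SimulationConfig().reactivity_ranges},
        seed=5)
    rec, truth = simulate_subject(config, 0)
    return rec, truth


@pytest.fixture(scope="session")
def prepped_recording(small_recording):
    """The small recording resampled, with EDA replaced by its phasic part."""
    rec, _ = small_recording
    return preprocess_recording(rec)


@pytest.fixture(scope="session")
def easy_cohort():
    """Six preprocessed subjects in the high-reactivity, low-noise regime,
    with pooled features and per-frame labels."""
    config = PipelineConfig(simulation=SimulationConfig.easy_regime(6),
                            seed=0)
    subjects = prepare_dataset(config)
    X, subject_ids = pool_features([s.features for s in subjects])
    y = np.concatenate([s.labels.classes for s in subjects])
    return {"subjects": subjects, "X": X, "y": y, "subject_ids": subject_ids}
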
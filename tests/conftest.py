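"""Shared fixtures: short synthetic nights generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from sleepwear import features as F
from sleepwear.synth import (
    SyntheticSubjectConfig,
    generate_hypnogram,
    generate_recording,
)


@pytest.fixture(scope="session")
def clean_config() -> SyntheticSubjectConfig:
    """Half-hour clean night: default physiology, default noise, seed 7."""
    return SyntheticSubjectConfig(subject_id="S_clean", duration_h=0.5, seed=7)


@pytest.fixture(scope="session")
def clean_night(clean_config):
    hyp = generate_hypnogram(clean_config)
    rec = generate_recording(clean_config, hyp)
    return rec, hyp


@pytest.fixture(scope="session")
def clean_table(clean_night):
    """Feature rows + exclusions for the clean half-hour night."""
    rec, hyp = clean_night
    rows, excluded = F.extract_night(rec, hyp)
    return rows, excluded


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
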
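"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from spikecorr import synth


@pytest.fixture(scope="session")
def ambiguous_session():
    """Cylinder session with shared gains and choice coupling (200 trials)."""
    cfg = synth.GeneratorConfig(
        conditions=(synth.Condition("cylinder", 0.0),),
        n_trials_per_condition=200, c_fast=0.85, c_slow=0.10,
        choice_coupling=0.08, coupling_onset_ms=800, coupling_offset_ms=2000,
        seed=11)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def independent_session():
    """No shared variability: SU and MU are conditionally independent Poisson."""
    cfg = synth.GeneratorConfig(
        conditions=(synth.Condition("random_motion"),),
        n_trials_per_condition=300, seed=7)
    return synth.generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
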
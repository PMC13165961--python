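"""Shared fixtures: small, fast synthetic sessions built once per module."""

from __future__ import annotations

import numpy as np
import pytest

from myofusion.config import ExperimentConfig
from myofusion.pipeline import Session, build_session
from myofusion.synthetic import EmgChannelModel, ProtocolSpec


@pytest.fixture(scope="session")
def mini_cfg() -> ExperimentConfig:
    """A scaled-down experiment config for fast unit/integration tests."""
    return ExperimentConfig(
        protocol_train=ProtocolSpec(mode="training_sweep", total_duration=24.0),
        protocol_valid=ProtocolSpec(
            mode="validation_steps", total_duration=20.0, n_transitions=4
        ),
    )


@pytest.fixture(scope="session")
def mini_session(mini_cfg) -> Session:
    return build_session(mini_cfg, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_channels() -> EmgChannelModel:
    """Channel model without mains interference or artifacts."""
    return EmgChannelModel(mains_amplitude=0.0, artifact_rate=0.0)
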
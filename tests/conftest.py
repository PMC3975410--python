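"""Shared fixtures: the default model, its initialized state and one
high-accuracy 120 h reference run are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from glycodyn.config import default_config
from glycodyn.model import CoupledModel, SimulationSpec


@pytest.fixture()
def fresh_model():
    """A function-scoped model safe to mutate via ``set_parameters``."""
    return CoupledModel(default_config())


@pytest.fixture(scope="session")
def session_model():
    """Session model: read-only use only."""
    return CoupledModel(default_config())


@pytest.fixture(scope="session")
def initial_state(session_model):
    return session_model.initial_state()


@pytest.fixture(scope="session")
def default_run(session_model, initial_state):
    """High-accuracy default 120 h batch trajectory (LSODA)."""
    return session_model.simulate(
        SimulationSpec(rtol=1e-8, atol=1e-12, method="LSODA"),
        y0=initial_state.copy(),
    )


@pytest.fixture(scope="session")
def radau_run(session_model, initial_state):
    """Same trajectory with an independent stiff method (Radau IIA)."""
    return session_model.simulate(
        SimulationSpec(rtol=1e-8, atol=1e-12, method="Radau"),
        y0=initial_state.copy(),
    )


def rel_diff(a: np.ndarray, b: np.ndarray, floor: float) -> float:
    """Max relative difference with an absolute floor on the reference."""
    a, b = np.asarray(a), np.asarray(b)
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), floor)))
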
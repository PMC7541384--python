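"""Shared fixtures: the calibrated parameter set, compiled circuits, and
session-scoped simulation runs reused across the suite (the solver is
deterministic, so sharing trajectories is safe)."""

from __future__ import annotations

import pytest

import pulmosim
from pulmosim import build_model, integrate, load_config, make_schedule


@pytest.fixture(scope="session")
def params_spec():
    return load_config()


@pytest.fixture()
def params(params_spec):
    return params_spec[0]


@pytest.fixture()
def normal_model(params_spec):
    return build_model(params_spec[0], "normal")


def _run(scenario: str, duration: float, record_every: int = 10):
    return pulmosim.run_scenario(scenario, duration=duration, record_every=record_every)


@pytest.fixture(scope="session")
def normal_run():
    """35 s normal run: enough cycles to reach the periodic regime."""
    return _run("normal", 35.0)


@pytest.fixture(scope="session")
def dpas_run():
    """Full 700 s distal pulmonary artery stenosis run."""
    return _run("dpas", 700.0, record_every=20)


@pytest.fixture(scope="session")
def lvdd_run():
    return _run("lvdd", 700.0, record_every=20)


@pytest.fixture(scope="session")
def vsd_run():
    return _run("vsd", 700.0, record_every=20)


@pytest.fixture(scope="session")
def ms_run():
    return _run("ms", 700.0, record_every=20)
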
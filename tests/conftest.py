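"""Shared heavyweight fixtures: the trained pattern base and closed-loop runs.

Everything is generated from the model at session start; the pipeline is
fully deterministic, so every test sees identical objects.
"""

import numpy as np
import pytest

from fohrlearn.experiments import build_training_base, run_sync


@pytest.fixture(scope="session")
def training_base_info():
    """The chi1..chi4 pattern base plus per-run identification histories."""
    base, info = build_training_base(keep_results=True)
    return base, info


@pytest.fixture(scope="session")
def training_base(training_base_info):
    return training_base_info[0]


@pytest.fixture(scope="session")
def sync_recognized(training_base):
    """Canonical master-slave run: recognition at t=300, model-based control."""
    return run_sync(training_base)


@pytest.fixture(scope="session")
def sync_true(training_base):
    """Ablation upper bound: compensation by the true slave dynamics."""
    return run_sync(training_base, compensation="true")


@pytest.fixture(scope="session")
def sync_wrong_pattern(training_base):
    """Ablation lower bound: deliberately recalled slow-spiking pattern."""
    return run_sync(training_base, compensation="pattern:chi1")


@pytest.fixture(scope="session")
def relearn_run(training_base):
    """Model-based control at t=300, switch to relearning at t=500."""
    return run_sync(training_base, mode="relearning", t_switch=500.0)
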
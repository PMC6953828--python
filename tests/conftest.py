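"""Shared fixtures.

Simulation fixtures are session-scoped: the study context (phantom, belt,
reconstruction operator) and the pooled healthy reference are expensive and
read-only, so every test module reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from eitptx import detect as det
from eitptx import harness as hz
from eitptx import phantom as ph


@pytest.fixture(scope="session")
def ctx() -> hz.SimulationContext:
    return hz.build_context()


@pytest.fixture(scope="session")
def phantom(ctx) -> ph.ThoraxPhantom:
    return ctx.phantom


@pytest.fixture(scope="session")
def reference(ctx) -> det.HealthyReference:
    """Pooled reference from 20 simulated healthy subjects (seed 42)."""
    return hz.build_study_reference(ctx, n_subjects=20, seed=42)


@pytest.fixture(scope="session")
def healthy_case(ctx) -> hz.CaseResult:
    dyn = ph.DynamicsConfig(frame_rate=15, duration=12, seed=11)
    return hz.simulate_case(ctx, hz.CaseSetup("healthy-fixture", dynamics=dyn))


@pytest.fixture(scope="session")
def lesion_case(ctx) -> hz.CaseResult:
    """Large ventral-right (segment 2) lesion, fully in-plane."""
    dyn = ph.DynamicsConfig(frame_rate=15, duration=9, seed=12)
    return hz.simulate_case(ctx, hz.CaseSetup("lesion-fixture", 2, 0.25, 6.0, dyn))


@pytest.fixture(scope="session")
def spike_case(ctx) -> hz.CaseResult:
    """Heart-contact lesion with cardiac spike transients enabled."""
    dyn = ph.DynamicsConfig(
        frame_rate=25, duration=12, spike_enabled=True, heart_rate=90.0, seed=13
    )
    return hz.simulate_case(ctx, hz.CaseSetup("spike-fixture", 6, 0.25, 6.0, dyn))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
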
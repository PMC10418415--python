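"""Shared fixtures: registries, profiles, and one cached end-to-end run."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from catrisk import default_profile, load_registry
from catrisk.pipeline import run_default_pipeline
from catrisk.registry import CellLine
from catrisk.synth import CellLineProfile, load_effect_models


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def effect_models(registry):
    return load_effect_models(registry)


@pytest.fixture(scope="session")
def control_profile():
    return default_profile(CellLine.CONTROL)


@pytest.fixture(scope="session")
def progeria_profile():
    return default_profile(CellLine.PROGERIA)


def make_quiet(profile: CellLineProfile, **overrides) -> CellLineProfile:
    """A noiseless, jitter-free copy of a profile (deterministic traces)."""
    fields = {"noise_sd": 0.0, "cycle_length_cv": 0.0}
    fields.update(overrides)
    params = replace(profile.baseline, **fields)
    return CellLineProfile(
        profile.line, params, profile.dose_sensitivity, profile.prolongation_gain
    )


@pytest.fixture(scope="session")
def quiet_control(control_profile):
    return make_quiet(control_profile)


@pytest.fixture(scope="session")
def default_results(registry):
    """The full synthetic screen at the default calibration and seed.

    Session-scoped: simulating + phenotyping both plates takes a couple
    of seconds and several tests (including acceptance) reuse it.
    """
    return run_default_pipeline(seed=0, registry=registry)
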
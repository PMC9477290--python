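"""Shared fixtures: small synthetic cohorts and calibrated true models."""

import dataclasses

import pytest

from ticsim.synthetic_cohort import (
    CohortConfig,
    default_true_models,
    generate_panel,
)
from ticsim.transition_models import DesignSpec


@pytest.fixture(scope="session")
def reduced_spec():
    """Smoke-scale design: tiny folds hold only a handful of deaths, so the
    mortality model keeps a few strong covariates and rare indicators are
    dropped throughout (they are constant within small folds)."""
    base = DesignSpec()
    return DesignSpec(
        tics_columns=tuple(c for c in base.tics_columns if c != "heart_attack_2yr"),
        mortality_columns=(
            "male",
            "age_spline_lt65",
            "age_spline_65_75",
            "age_spline_75_85",
            "age_spline_85p",
            "hypertension_ever",
        ),
    )


@pytest.fixture(scope="session")
def true_models():
    """Reference-coefficient models calibrated on a default cohort."""
    return default_true_models(CohortConfig(n_individuals=5000, seed=42))


@pytest.fixture(scope="session")
def small_panel(true_models):
    """A 2,000-person, 6-wave truth panel with no missingness."""
    cfg = dataclasses.replace(
        CohortConfig(n_individuals=2000, seed=11, n_waves=6), true_models=true_models
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def tiny_panel(true_models):
    """A 300-person, 4-wave truth panel for fast smoke checks."""
    cfg = dataclasses.replace(
        CohortConfig(n_individuals=300, seed=5, n_waves=4), true_models=true_models
    )
    return generate_panel(cfg)
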
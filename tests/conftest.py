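"""Shared fixtures: the study design, calibration truth and fitted models.

Expensive objects (fits, ensembles) are session-scoped; all randomness is
seeded so the suite is deterministic.
"""

from __future__ import annotations

import pytest

import h2axdose as hx
from h2axdose.presets import BLOOD_BACKGROUND_AU, BLOOD_BESTFIT


@pytest.fixture(scope="session")
def bestfit() -> hx.H2AXParams:
    return BLOOD_BESTFIT


@pytest.fixture(scope="session")
def design() -> hx.StudyDesign:
    return hx.StudyDesign()


@pytest.fixture(scope="session")
def noiseless_data(design, bestfit):
    """Exact model predictions on the 20-point study grid (SEM floored)."""
    return hx.generate_group_means(
        design, bestfit, hx.NoiseConfig(group_sem_scale=0.0), seed=0
    )


@pytest.fixture(scope="session")
def noisy_data(design, bestfit):
    """One calibration-noise realisation of the study."""
    return hx.generate_group_means(design, bestfit, hx.NoiseConfig(), seed=42)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_data):
    model = hx.H2AXKineticsModel(noiseless_data, BLOOD_BACKGROUND_AU)
    return model.fit(n_starts=12, seed=0)


@pytest.fixture(scope="session")
def noisy_fit(noisy_data):
    model = hx.H2AXKineticsModel(noisy_data, BLOOD_BACKGROUND_AU)
    return model.fit(n_starts=12, seed=0)


@pytest.fixture(scope="session")
def small_ensemble(noisy_fit):
    return noisy_fit.sample_confidence_region(n_min=500, seed=7)
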
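"""Shared fixtures: planar phantoms, fitted plans, and a small cohort.

Heavy fixtures are session-scoped so the optimization pipeline runs once
and is reused by the planning, evaluation and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bdpc_imrt import (
    PhantomConfig,
    RunConfig,
    TreatmentPlanModel,
    generate_thorax_phantom,
    run_cohort,
)

PLANAR = (64, 64, 1)


@pytest.fixture(scope="session")
def lung_phantom_2d():
    """Planar lung phantom with a target straddling the density boundary."""
    return generate_thorax_phantom(PhantomConfig(seed=7, shape=PLANAR))


@pytest.fixture(scope="session")
def uniform_phantom_2d():
    """Planar phantom with lung density forced to soft tissue (no OCE)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_thorax_phantom(
            PhantomConfig(seed=7, shape=PLANAR, lung_density_range=(1.0, 1.0))
        )


@pytest.fixture(scope="session")
def model_2d(lung_phantom_2d):
    grid, structures = lung_phantom_2d
    return TreatmentPlanModel(grid, structures)


@pytest.fixture(scope="session")
def co_2d(model_2d):
    return model_2d.fit("co")


@pytest.fixture(scope="session")
def sto_2d(model_2d):
    return model_2d.fit("sto")


@pytest.fixture(scope="session")
def bdpc_2d(model_2d, co_2d):
    return model_2d.fit("bdpc", base_results=co_2d)


@pytest.fixture(scope="session")
def cohort_10():
    """Ten-phantom planar cohort planned with all three methods."""
    return run_cohort(RunConfig(cohort_size=10, base_seed=0, mode="2d"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
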
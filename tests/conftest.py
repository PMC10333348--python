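"""Shared phantom fixtures.

The default-condition cohort (n = 400) and the models trained on it are
expensive, so they are built once per session and shared by the model,
interpretation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ads.models import fit_model
from ads.synthdata import PhantomSpec, make_cohort, make_phantom_atlas

COHORT_SEED = 0
MODEL_SEED = 3


@pytest.fixture(scope="session")
def spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def atlas(spec):
    return make_phantom_atlas(spec)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        shape=(32, 32, 32),
        n_arterial_pairs=2,
        n_structural_pairs=3,
        ventricle_size=(8, 10, 6),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return make_phantom_atlas(small_spec)


@pytest.fixture(scope="session")
def cohort(atlas, spec):
    return make_cohort(atlas, 400, seed=COHORT_SEED, spec=spec)


@pytest.fixture(scope="session")
def cohort_split(cohort):
    return cohort[:200], cohort[200:]


@pytest.fixture(scope="session")
def rf_model(cohort_split):
    train, _ = cohort_split
    return fit_model("RF", {"n_estimators": 200}, train, seed=MODEL_SEED)


@pytest.fixture(scope="session")
def bt_model(cohort_split):
    train, _ = cohort_split
    return fit_model("BT", {}, train, seed=MODEL_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
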
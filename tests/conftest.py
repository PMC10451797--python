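"""Shared fixtures: session-scoped phantom datasets and a fitted model.

The heavier acceptance-style checks (monotonicity, parameter recovery,
degradation sensitivity) share one training dataset (50 phantoms per grade,
seed 1) and one held-out dataset (25 per grade, independent seed), so the
expensive generation and model fit run once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sriqa.features import feature_table
from sriqa.model import SoftReferenceIQA
from sriqa.phantom import PhantomSpec, generate_dataset

TRAIN_SEED = 1
HELDOUT_SEED = 1001


@pytest.fixture(scope="session")
def spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def train_manifest(spec) -> pd.DataFrame:
    return generate_dataset(50, spec, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_manifest(spec) -> pd.DataFrame:
    return generate_dataset(25, spec, seed=HELDOUT_SEED)


@pytest.fixture(scope="session")
def train_table(train_manifest) -> pd.DataFrame:
    return feature_table(train_manifest)


@pytest.fixture(scope="session")
def heldout_table(heldout_manifest) -> pd.DataFrame:
    return feature_table(heldout_manifest)


@pytest.fixture(scope="session")
def fitted_model(train_table):
    return SoftReferenceIQA.from_dataframe(train_table).fit(seed=TRAIN_SEED)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
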
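"""Shared fixtures.

The six benchmark datasets are expensive to bootstrap, so one scaled-down
pipeline run per dataset (B = 50 with 1 x 5-fold CV; reduced hyperparameter
grids for the 200 x 10,010 datasets) is computed lazily and cached for the
whole session; every test that needs combined-model results shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from triboot.report import LARGE_P_GRIDS, run_pipeline
from triboot.selectors import CvSpec
from triboot.simdata import (
    CorrelatedGroup,
    NoiseBlockSpec,
    TrueModelSpec,
    build_dataset,
)

#: Scaled replicate counts per benchmark dataset (study conditions for tests).
SCALED_B = {1: 50, 2: 50, 3: 50, 4: 50, 5: 50, 6: 50}
_LARGE = {3, 4, 6}
_PIPELINE_CACHE: dict[int, object] = {}


def scaled_pipeline(name: int):
    """Five-method bootstrap + combined report for one benchmark dataset."""
    if name not in _PIPELINE_CACHE:
        seed = 100 + name
        ds = build_dataset(name, seed=seed)
        cv = CvSpec.fast(
            seed=seed, folds=5, grids=LARGE_P_GRIDS if name in _LARGE else None
        )
        _PIPELINE_CACHE[name] = run_pipeline(ds, B=SCALED_B[name], seed=seed, cv=cv)
    return _PIPELINE_CACHE[name]


@pytest.fixture(scope="session")
def pipeline_for():
    return scaled_pipeline


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 150 x 50 dataset with the full structural features, cheap to fit."""
    return build_dataset(
        n=150,
        spec=TrueModelSpec(noise_sd=6.5),
        noise_spec=NoiseBlockSpec((CorrelatedGroup(2, 10, 0.7),), 20),
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
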
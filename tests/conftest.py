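"""Shared fixtures: small pedigrees and simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gxeblup.params import default_true_params
from gxeblup.pedigree import Pedigree
from gxeblup.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def founder_pair() -> Pedigree:
    return Pedigree(
        ids=[1, 2],
        sire=[-1, -1],
        dam=[-1, -1],
        sex=["M", "F"],
        time_step=[0, 0],
    )


@pytest.fixture
def full_sib_pedigree() -> Pedigree:
    """Two unrelated parents, two full sibs, one inbred offspring of the sibs."""
    return Pedigree(
        ids=[1, 2, 3, 4, 5],
        sire=[-1, -1, 0, 0, 2],
        dam=[-1, -1, 1, 1, 3],
        sex=["M", "F", "M", "F", "M"],
        time_step=[0, 0, 1, 1, 2],
    )


def random_pedigree(n: int, seed: int, n_founders: int = 20) -> Pedigree:
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        sire[i], dam[i] = rng.integers(0, i, 2)
    return Pedigree(
        ids=np.arange(1, n + 1),
        sire=sire,
        dam=dam,
        sex=np.where(np.arange(n) % 2 == 0, "M", "F"),
        time_step=np.zeros(n),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A compact selective-genotyping breeding program (~420 animals)."""
    cfg = SimConfig(
        seed=1, n_time_steps=6, n_sires_per_ts=4, n_dams_per_ts=8,
        offspring_per_dam=8, prop_genotyped_B=0.4,
    )
    return cfg, simulate_dataset(cfg, default_true_params(), 1)


@pytest.fixture(scope="session")
def small_standardized(small_dataset):
    """Phenotypes of the small dataset with a sample-SD standardization."""
    _, ds = small_dataset
    ph = ds.phenotypes.copy()
    sd = ph.groupby(["sex", "trait", "env"])["value_g"].transform("std")
    ph["value_std"] = ph["value_g"] / sd
    return ph
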
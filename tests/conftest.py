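"""Shared fixtures: scaled-down generator configs and small record tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bpjoint import cohort, synth
from bpjoint.bivml import VarianceComponents


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config()


@pytest.fixture(scope="session")
def small_cfg(default_cfg):
    """Default truth at 300 households — fast enough for per-test fits."""
    return dataclasses.replace(default_cfg, n_households=300)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    records = synth.generate_population(small_cfg, seed=20140901)
    design, labels = cohort.build_design(records, small_cfg.scheme())
    return records, design, labels


def make_records(sbp, dbp, household=None, region="Western", ever_told=0):
    """Minimal woman-level frame with all-reference covariates."""
    n = len(sbp)
    scheme = cohort.default_scheme()
    data = {
        "woman_id": [f"W{i}" for i in range(n)],
        "household_id": household if household is not None else [f"H{i}" for i in range(n)],
        "region": region if not isinstance(region, (list, np.ndarray)) else region,
        "sbp": np.asarray(sbp, float),
        "dbp": np.asarray(dbp, float),
        "ever_told": ever_told if np.ndim(ever_told) else [ever_told] * n,
    }
    frame = pd.DataFrame(data)
    for f in scheme:
        frame[f.name] = f.reference
    return frame


@pytest.fixture
def reference_records():
    return make_records


@pytest.fixture(scope="session")
def simple_varcomp():
    return VarianceComponents.from_correlations(
        var_h=(25.0, 9.0), rho_h=0.5, var_e=(100.0, 64.0), rho_e=0.6)
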
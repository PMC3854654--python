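"""Shared fixtures.

The expensive objects (the standard synthetic cohorts, their pairwise
dissimilarity matrices, and m=10000 consensus runs) are computed once per
session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import eaccd


@pytest.fixture(scope="session")
def standard_cohorts():
    return eaccd.standard_fixture()


@pytest.fixture(scope="session")
def dis0(standard_cohorts):
    """Initial dissimilarity of the standard fixture per weight scheme."""
    cache = {}

    def get(test="logrank"):
        if test not in cache:
            cache[test] = eaccd.initial_dissimilarity(standard_cohorts, test)
        return cache[test]

    return get


@pytest.fixture(scope="session")
def consensus10k(dis0):
    """m=10000 consensus matrices on the standard fixture, memoized by
    (test, ensemble seed)."""
    cache = {}

    def get(seed=0, test="logrank"):
        key = (test, seed)
        if key not in cache:
            cfg = eaccd.EnsembleConfig(m=10000, k_min=2, k_max=11, seed=seed)
            cache[key] = eaccd.ensemble_dissimilarity(dis0(test), cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)


def random_records(rng, n, hazard=0.1, censor=0.05):
    """Small random censored cohort for oracle comparisons."""
    t = rng.exponential(1.0 / hazard, n)
    c = rng.exponential(1.0 / censor, n)
    obs = np.round(np.minimum(t, c), 1)  # rounding forces ties
    e = (t <= c).astype(int)
    return [
        eaccd.PatientRecord(float(ti), int(ei), ()) for ti, ei in zip(obs, e)
    ]
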
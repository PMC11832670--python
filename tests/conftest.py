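"""Shared fixtures: simulated calibration data reused across test modules."""

import numpy as np
import pytest
from scipy.special import expit

from vocat import ResponseMatrix, fit_rasch


def make_rasch_matrix(n_persons, difficulties, seed, theta_sd=1.0,
                      discriminations=None):
    """Simulate a complete Rasch (or 2PL) response matrix with known truth."""
    rng = np.random.default_rng(seed)
    difficulties = np.asarray(difficulties, dtype=float)
    k = difficulties.size
    a = np.ones(k) if discriminations is None else np.asarray(discriminations)
    theta = rng.normal(0.0, theta_sd, n_persons)
    P = expit(a[None, :] * (theta[:, None] - difficulties[None, :]))
    Y = (rng.random((n_persons, k)) < P).astype(int)
    data = ResponseMatrix(
        person_ids=[f"p{i}" for i in range(n_persons)],
        item_ids=[f"i{j}" for j in range(k)],
        responses=Y,
    )
    return data, theta


@pytest.fixture(scope="session")
def rasch_recovery():
    """n=2000 x 40 items, difficulties equally spaced on [-3, 3], plus fit."""
    truth = np.linspace(-3.0, 3.0, 40)
    data, theta = make_rasch_matrix(2000, truth, seed=20)
    return {"data": data, "truth": truth, "theta": theta,
            "fit": fit_rasch(data)}


@pytest.fixture(scope="session")
def rasch_null_fit():
    """n=1000 x 30 well-fitting items and the Rasch calibration."""
    truth = np.linspace(-2.5, 2.5, 30)
    data, theta = make_rasch_matrix(1000, truth, seed=21)
    return {"data": data, "truth": truth, "theta": theta,
            "fit": fit_rasch(data)}
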
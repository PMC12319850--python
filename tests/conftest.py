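"""Shared fixtures: random SPD factories and small synthetic trial sets."""

from __future__ import annotations

import numpy as np
import pytest

from eegspd.synthetic import make_fixture


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def make_spd(rng):
    """Factory for random well-conditioned SPD matrices."""

    def _make(n: int, scale: float = 1.0) -> np.ndarray:
        A = rng.normal(size=(n, n))
        return scale * (A @ A.T + n * np.eye(n))

    return _make


@pytest.fixture
def make_stiefel(rng):
    """Factory for random Stiefel matrices (orthonormal columns)."""

    def _make(d_in: int, d_out: int) -> np.ndarray:
        Q, R = np.linalg.qr(rng.normal(size=(d_in, d_out)))
        return Q * np.sign(np.diag(R))

    return _make


@pytest.fixture(scope="session")
def easy4_small():
    """A small easy4 trial set shared across tests (20 trials/class)."""
    trials, truth = make_fixture("easy4", seed=42, n_trials_per_class=20)
    return trials, truth
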
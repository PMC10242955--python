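"""Shared fixtures: designs, generative parameter sets, random-model factory."""

from __future__ import annotations

import numpy as np
import pytest

from riclpm import PanelDesign, ParameterSet, default_parameters


def random_spd(K: int, rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
    """Well-conditioned random covariance with diagonal near ``scale``."""
    A = rng.standard_normal((K, K))
    S = A @ A.T / K + 0.5 * np.eye(K)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    return scale * R


def random_parameter_set(
    K: int, T: int, pair: bool, rng: np.random.Generator
) -> ParameterSet:
    """Random stable, identifiable parameter set for oracle tests.

    Cross-twin blocks are scalar multiples of the within blocks (MZ scale in
    [0.4, 0.7], DZ = half the MZ scale), which guarantees joint twin-pair
    positive semi-definiteness.
    """
    design = (
        PanelDesign.twin(K, T) if pair else PanelDesign(K, T)
    )
    mu = rng.normal(0.0, 0.5, (T, K))
    psi = random_spd(K, rng, 0.5)
    phi1 = random_spd(K, rng, 0.5)
    beta = rng.uniform(-0.3, 0.3, (T - 1, K, K))
    theta = np.stack([random_spd(K, rng, 0.4) for _ in range(T - 1)])
    if not pair:
        return ParameterSet(design, mu, psi, phi1, beta, theta)
    sib = rng.uniform(-0.1, 0.1, (T - 1, K, K))
    c_mz = rng.uniform(0.4, 0.7)
    scales = {"MZ": c_mz, "DZ": 0.5 * c_mz}
    return ParameterSet(
        design,
        mu,
        psi,
        phi1,
        beta,
        theta,
        beta_sib=sib,
        psi_cross={z: c * psi for z, c in scales.items()},
        phi1_cross={z: c * phi1 for z, c in scales.items()},
        theta_cross={z: c * theta for z, c in scales.items()},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def wf_values() -> ParameterSet:
    """Study-like 2-trait, 3-wave twin-pair generative parameters."""
    return default_parameters(2, 3)


@pytest.fixture(scope="session")
def single_values(wf_values) -> ParameterSet:
    return wf_values.marginal_single()
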
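"""Shared fixtures.

The expensive objects — Fokker-Planck responses on the uniform inversion
grid, transfer functions with their interpolation caches — are built once
per session at a single standard operating point (baseline rate 15 Hz,
background noise 4 mV) and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from lncascade import (
    EIFParams,
    LIFParams,
    NoiseParams,
    TransferFunction,
    build_nonlinearity,
    default_filter_grid,
    filter_from_response,
    lif_response,
    mu_for_rate,
    threshold_response,
)
from lncascade.cascade import CascadeModel

STANDARD_NU0 = 15.0
STANDARD_SIGMA0 = 4.0


@pytest.fixture(scope="session")
def lif_params() -> LIFParams:
    return LIFParams()


@pytest.fixture(scope="session")
def eif_params() -> EIFParams:
    return EIFParams()


@pytest.fixture(scope="session")
def tf_lif(lif_params) -> TransferFunction:
    return TransferFunction("lif", lif_params)


@pytest.fixture(scope="session")
def tf_eif(eif_params) -> TransferFunction:
    return TransferFunction("eif", eif_params)


@pytest.fixture(scope="session")
def lif_noise(tf_lif) -> NoiseParams:
    mu0 = mu_for_rate(tf_lif, STANDARD_NU0, STANDARD_SIGMA0)
    return NoiseParams(mu0=mu0, sigma0=STANDARD_SIGMA0)


@pytest.fixture(scope="session")
def eif_noise(tf_eif) -> NoiseParams:
    mu0 = mu_for_rate(tf_eif, STANDARD_NU0, STANDARD_SIGMA0)
    return NoiseParams(mu0=mu0, sigma0=STANDARD_SIGMA0)


@pytest.fixture(scope="session")
def uniform_grid() -> np.ndarray:
    return default_filter_grid(dt=0.25, df=2.0)


@pytest.fixture(scope="session")
def lif_resp_uniform(lif_noise, lif_params, uniform_grid):
    return lif_response(lif_noise, lif_params, uniform_grid)


@pytest.fixture(scope="session")
def eif_resp_uniform(eif_noise, eif_params, uniform_grid):
    return threshold_response(eif_noise, eif_params, uniform_grid)


@pytest.fixture(scope="session")
def lif_filter(lif_resp_uniform):
    return filter_from_response(lif_resp_uniform, dt=0.25)


@pytest.fixture(scope="session")
def eif_filter(eif_resp_uniform):
    return filter_from_response(eif_resp_uniform, dt=0.25)


@pytest.fixture(scope="session")
def eif_nonlinearity(tf_eif, eif_noise):
    return build_nonlinearity(tf_eif, eif_noise.mu0, eif_noise.sigma0)


@pytest.fixture(scope="session")
def eif_cascade(eif_filter, eif_nonlinearity):
    return CascadeModel(filter=eif_filter, nonlinearity=eif_nonlinearity)
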
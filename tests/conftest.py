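"""Shared fixtures: reference models, boundary runs and reduction reports.

The expensive objects (geodesic boundary runs, full reduction chains) are
session-scoped so the acceptance tests and the unit tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mbam import FDOptions, fim, jacobian, spectrum
from mbam.geodesic import GeodesicOptions, integrate_geodesic
from mbam.reduction import MBAMOptions, mbam_run
from mbam.zoo import (
    MM_BOUNDARY_QOI,
    adaptation_qoi,
    sample_adaptive_params,
    zoo,
)

# geodesic settings for the bundled boundary runs (see docs/methods.md)
GEO_FISHER = GeodesicOptions()  # informative grid, unit Fisher speed
GEO_PARAM = GeodesicOptions(normalization="parameter", max_tau=25.0, max_steps=2000)


@pytest.fixture(scope="session")
def mm_full():
    return zoo("MM_FULL")


@pytest.fixture(scope="session")
def mm_spectrum(mm_full):
    model, theta0, qoi = mm_full
    J = jacobian(model, theta0, qoi, FDOptions())
    return spectrum(fim(J, model.parameter_names, qoi))


@pytest.fixture(scope="session")
def equilibrium_path(mm_full):
    """Geodesic from theta0 toward the rapid-equilibrium face (kf, kr -> inf)."""
    model, theta0, _ = mm_full
    from dataclasses import replace

    return integrate_geodesic(
        model, theta0, MM_BOUNDARY_QOI, replace(GEO_FISHER, direction=+1)
    )


@pytest.fixture(scope="session")
def irreversibility_path(mm_full):
    """Geodesic from theta0 toward the irreversible-binding face (kr -> 0)."""
    model, theta0, _ = mm_full
    from dataclasses import replace

    return integrate_geodesic(
        model, theta0, MM_BOUNDARY_QOI, replace(GEO_FISHER, direction=-1)
    )


@pytest.fixture(scope="session")
def mm_chain_report(mm_full):
    """mbam_run on the 3-parameter enzyme model (equilibrium route)."""
    from dataclasses import replace

    model, theta0, _ = mm_full
    opts = MBAMOptions(geodesic=replace(GEO_FISHER, direction=+1))
    return mbam_run(model, theta0, MM_BOUNDARY_QOI, options=opts)


@pytest.fixture(scope="session")
def promoted_chain_report():
    """mbam_run on the promoted 5-parameter enzyme model (QSSA route)."""
    model, theta0, qoi = zoo("MM_FULL_P")
    return mbam_run(model, theta0, qoi, options=MBAMOptions(geodesic=GEO_PARAM))


@pytest.fixture(scope="session")
def nfb12_fixture():
    model, _, _ = zoo("NFB_12")
    params = sample_adaptive_params(model, seed=0)
    return model, params, adaptation_qoi(model, params)


@pytest.fixture(scope="session")
def ifflp12_fixture():
    model, _, _ = zoo("IFFLP_12")
    params = sample_adaptive_params(model, seed=0)
    return model, params, adaptation_qoi(model, params)


@pytest.fixture(scope="session")
def nfb12_report(nfb12_fixture):
    model, params, qoi = nfb12_fixture
    return mbam_run(model, params, qoi, options=MBAMOptions(geodesic=GEO_PARAM))


@pytest.fixture(scope="session")
def ifflp12_report(ifflp12_fixture):
    model, params, qoi = ifflp12_fixture
    return mbam_run(model, params, qoi, options=MBAMOptions(geodesic=GEO_PARAM))
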
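"""Shared fixtures: NSD basis, HOMA calibration, templates, small population."""
from __future__ import annotations

import numpy as np
import pytest

from porphgeom import (
    SyntheticSpec,
    build_nsd_basis,
    default_calibration,
    generate_population,
    make_filter_fixtures,
    make_template,
)


@pytest.fixture(scope="session")
def basis():
    return build_nsd_basis()


@pytest.fixture(scope="session")
def homa_params():
    return default_calibration()


@pytest.fixture(scope="session")
def zn_porphine():
    return make_template("Zn")


@pytest.fixture(scope="session")
def tpp():
    """Zn tetraphenylporphyrin (4 meso phenyls, 8 beta H)."""
    return make_template("Zn", meso="phenyl", source_id="ZnTPP")


@pytest.fixture(scope="session")
def oep():
    """Zn octaethylporphyrin (8 beta ethyls, 4 meso H)."""
    return make_template("Zn", beta="ethyl", source_id="ZnOEP")


@pytest.fixture(scope="session")
def filter_fixtures():
    return make_filter_fixtures()


@pytest.fixture(scope="session")
def small_population():
    """Shared 60-structure planted population (fixed study conditions)."""
    return generate_population(SyntheticSpec(n=60, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
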
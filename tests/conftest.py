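import numpy as np
import pytest

from facetsolv import ForceFieldParams, GridSpec, build_slab
from facetsolv.fixtures import (ToyCrystalSpec, make_toy_crystal,
                                toy_probe_diatomic, toy_probe_polar,
                                toy_probe_single)


@pytest.fixture(scope="session")
def params() -> ForceFieldParams:
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def apolar_crystal():
    return make_toy_crystal(ToyCrystalSpec(variant="apolar"))


@pytest.fixture(scope="session")
def polar_crystal():
    return make_toy_crystal(ToyCrystalSpec(variant="polar-pair"))


@pytest.fixture(scope="session")
def grooved_crystal():
    return make_toy_crystal(ToyCrystalSpec(variant="grooved"))


@pytest.fixture(scope="session")
def apolar_slab(apolar_crystal):
    return build_slab(apolar_crystal, (1, 0, 0))


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    """Small deterministic grid keeping toy scans fast."""
    return GridSpec(lateral_step=3.0, n_planes=3, angle_step=120.0)


@pytest.fixture(scope="session")
def probes():
    return {"single": toy_probe_single(), "diatomic": toy_probe_diatomic(),
            "polar": toy_probe_polar()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
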
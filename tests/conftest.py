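import numpy as np
import pytest

from hemopost.synthetic import (
    WaveformSpec,
    make_box_mesh,
    make_case,
    make_sac_mesh,
)


@pytest.fixture(scope="session")
def icosphere():
    return make_sac_mesh("icosphere", size=1.0, refinement=2)


@pytest.fixture(scope="session")
def annulus():
    return make_sac_mesh("annulus-patch", size=1.0, refinement=2)


@pytest.fixture(scope="session")
def box_mesh():
    return make_box_mesh(n=8, extent=8.0)


@pytest.fixture(scope="session")
def small_case():
    """One complete synthetic case, shared read-only across tests."""
    case, expected = make_case(
        case_id="fixture-case", volume_n=6, surface_refinement=1,
        waveform=WaveformSpec(type="pulsatile", amplitude=2.0, n_phases=10),
    )
    return case, expected


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
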
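import numpy as np
import pytest

import discmech as dm


@pytest.fixture(scope="session")
def protocol():
    return dm.LoadingProtocol()


@pytest.fixture(scope="session")
def axial_truth():
    return dm.CurveTruth()


@pytest.fixture(scope="session")
def torsion_truth():
    return dm.default_torsion_truth()


@pytest.fixture(scope="session")
def axial_series(protocol, axial_truth):
    """One noise-free cyclic axial record under the default protocol."""
    return dm.generate_axial_cycles(protocol, axial_truth, seed=1)


@pytest.fixture(scope="session")
def axial_segment(axial_series, protocol):
    return dm.extract_last_cycle(axial_series, protocol.n_cycles, protocol.frequency)


@pytest.fixture(scope="session")
def torsion_series(protocol, torsion_truth):
    return dm.generate_torsion_cycles(protocol, torsion_truth, seed=1)


@pytest.fixture(scope="session")
def torsion_segment(torsion_series, protocol):
    return dm.extract_last_cycle(torsion_series, protocol.n_cycles, protocol.frequency)


def make_segment(x, y, kind="axial"):
    """Wrap a single loading sweep x (descending then ascending) into a
    CycleSegment: peak -> trough -> peak built by mirroring the sweep."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    prim = np.concatenate([x[::-1], x[1:]])
    resp = np.concatenate([y[::-1], y[1:]])
    t = np.arange(prim.size, dtype=float)
    series = dm.MechanicalTimeSeries(t, prim, resp, kind=kind)
    return dm.CycleSegment(series, 0, x.size - 1, prim.size - 1)
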
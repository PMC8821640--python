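import numpy as np
import pytest

import helixlattice as hx


@pytest.fixture(scope="session")
def paper_sym():
    """The published 1-start lattice: rise 5.57 Å, twist 108°."""
    return hx.HelicalSymmetry(rise=5.57, twist_raw=108.0)


@pytest.fixture(scope="session")
def paper_register():
    """Two species on three 3-start strands, one strand out of register."""
    return hx.RegisterPattern(s=3, q=2, offsets=(0, 0, 1))


@pytest.fixture(scope="session")
def paper_labeling(paper_register):
    return hx.labeling_from_register(paper_register)


@pytest.fixture(scope="session")
def fixture_config():
    return hx.FixtureConfig()


@pytest.fixture(scope="session")
def toy_monomers(fixture_config):
    return {sp: hx.make_toy_monomer(fixture_config, sp) for sp in (0, 1)}


@pytest.fixture(scope="session")
def fixture_filament():
    """Straight 36-subunit two-species fixture (interior refs up to |k|=10)."""
    return hx.make_fixture_filament("mvillosus", n=36)


def brute_force_min_period(labels: np.ndarray, max_p: int) -> int:
    """Oracle: scan all p, check the whole window (independent of the formula)."""
    n = len(labels)
    for p in range(1, max_p + 1):
        if np.array_equal(labels[: n - p], labels[p:]):
            return p
    raise AssertionError(f"no period <= {max_p} in window of {n}")
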
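"""Shared fixtures: toy iron-nitrosyl sites and spin parameters."""

import numpy as np
import pytest

import fenoscore as f

# Eight-proton toy site used for round-trip spectroscopy tests.  The
# placements (r_Fe / theta / phi) were chosen so that, at the fixed test
# orientation below, every proton has a modulation depth in ~[0.05, 0.32],
# all cross peaks sit away from the tau = 120 ns blind spots, and peak
# pairs (including mirrors) are separated by more than one spectral
# mainlobe so maxima can be located to one frequency bin.
EIGHT_PROTONS = [
    (2.35, 27.5, -25.0),
    (2.60, 155.0, 25.0),
    (2.70, 150.0, 15.0),
    (2.85, 55.0, 35.0),
    (2.85, 62.5, -15.0),
    (2.90, 35.0, -25.0),
    (3.30, 27.5, -25.0),
    (3.40, 125.0, 0.0),
]

TEST_ORIENTATION = np.array([0.3, 0.7, 0.648]) / np.linalg.norm([0.3, 0.7, 0.648])


@pytest.fixture(scope="session")
def zfs():
    return f.ZFSParameters()


@pytest.fixture(scope="session")
def geff(zfs):
    return f.effective_g(zfs)


@pytest.fixture(scope="session")
def eight_proton_site():
    return f.make_toy_site(f.ToySiteSpec(protons=EIGHT_PROTONS))


@pytest.fixture(scope="session")
def eight_couplings(eight_proton_site):
    return f.build_couplings(eight_proton_site)


@pytest.fixture(scope="session")
def single_coupling():
    site = f.make_toy_site(f.ToySiteSpec(protons=[(2.8, 50.0, 10.0)]))
    return f.build_couplings(site)[0]
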
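import numpy as np
import pytest

from hitikit.seqcore import GuideSpec, NucSeq, place_guide
from hitikit.simulate import (
    design_dual_amplicon,
    make_example_system,
    random_bases,
)


@pytest.fixture(scope="session")
def system():
    """A reproducible demo locus + kozak donor shared across tests."""
    return make_example_system(seed=11)


@pytest.fixture(scope="session")
def locus(system):
    return system[0]


@pytest.fixture(scope="session")
def donor(system):
    return system[1]


@pytest.fixture(scope="session")
def dual_design(system):
    return design_dual_amplicon(*system)


@pytest.fixture(scope="session")
def amplicon_locus(system, dual_design):
    """The target locus re-placed in wild-type amplicon coordinates."""
    return place_guide(dual_design.wt_ref, system[0].guide)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_guide_site(rng, flank=30):
    """A random reference embedding a random guide site once, plus its guide."""
    from hitikit.seqcore import scan_sites

    while True:
        proto = random_bases(rng, 20)
        ref = NucSeq(
            "rnd", random_bases(rng, flank) + proto + "AGG"
            + random_bases(rng, flank)
        )
        guide = GuideSpec(NucSeq("g", proto))
        if len(scan_sites(ref, guide)) == 1:
            return ref, guide
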
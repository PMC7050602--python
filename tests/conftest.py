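import logging

import pytest

from como import chem
from como.synthetic import LandscapeSpec, make_pool, make_series

logging.getLogger("como").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def additive_series():
    """Full 3x3 lattice, exactly additive, noise-free."""
    spec = LandscapeSpec(n_sites=2, substituents_per_site=3, occupancy=1.0, seed=1)
    return make_series(spec)


@pytest.fixture(scope="session")
def holdout_series():
    """Additive noise-free lattice with a few held-out cells."""
    spec = LandscapeSpec(n_sites=2, substituents_per_site=4, occupancy=0.8, seed=3)
    return make_series(spec)


@pytest.fixture(scope="session")
def noisy_series():
    """Additive + Gaussian-noise series with a hydrogen-bearing site."""
    spec = LandscapeSpec(
        n_sites=2,
        substituents_per_site=5,
        occupancy=0.8,
        noise_sd=0.2,
        seed=5,
        hydrogen_sites=(2,),
    )
    return make_series(spec)


@pytest.fixture(scope="session")
def pool():
    return make_pool(120, seed=9)


@pytest.fixture(scope="session")
def fig1_like_series():
    """Four analogs reproducing the canonical two-site FW neighborhood:

    hub A (8.4), B = A with an R1 swap (+0.3), C = A with an R2 swap (+0.6),
    X = both swaps applied (measured 9.5, additively expected 9.3).
    """
    core = chem.CoreScaffold(smiles="c1cc2ncc([*:2])cc2cc1[*:1]")
    pyr, fpyr = "[*:1]c1ccccn1", "[*:1]c1ccc(F)cn1"
    ester, amide = "[*:2]C(=O)OC", "[*:2]C(=O)NCC(F)(F)F"

    def build(r1, r2):
        return chem.recompose(core, {"R1": r1, "R2": r2})

    return [
        chem.Analog("A", build(pyr, ester), 8.4),
        chem.Analog("B", build(fpyr, ester), 8.7),
        chem.Analog("C", build(pyr, amide), 9.0),
        chem.Analog("X", build(fpyr, amide), 9.5),
    ]
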
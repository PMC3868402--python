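import numpy as np
import pytest

import karyorecon as kr
from karyorecon.observe import ProbeGrid, assign_homologues, simulate_array, simulate_fish

HEL_FIXTURE = "src/karyorecon/data/hel_vccs.txt"

# a small triploid-free toy: three derivative chromosomes over six chromosomes
TOY_KARYOTYPE = ("47,XX,der(1)t(1;5)(p34.1;q31.1),der(2)t(2;6)(q24.1;p21.1),"
                 "+der(3)t(3;7)(q21.1;q31.1)")
TOY_CHROMS = ("1", "2", "3", "5", "6", "7")


@pytest.fixture(scope="session")
def cmap():
    return kr.bundled_map()


@pytest.fixture(scope="session")
def loci():
    return kr.bundled_loci()


@pytest.fixture(scope="session")
def hel_text():
    from importlib import resources
    text = (resources.files("karyorecon") / "data" / "hel_vccs.txt").read_text()
    return [l for l in text.splitlines() if l.strip() and not l.startswith("#")][0]


@pytest.fixture(scope="session")
def hel_model(hel_text):
    return kr.parse_karyotype(hel_text)


@pytest.fixture(scope="session")
def toy_hk():
    return assign_homologues(kr.parse_karyotype(TOY_KARYOTYPE))


@pytest.fixture(scope="session")
def toy_grid():
    return ProbeGrid(density=50, het_fraction=0.35, chromosomes=TOY_CHROMS,
                     seed=11)


@pytest.fixture(scope="session")
def toy_paints(toy_hk):
    return simulate_fish(toy_hk, panel=set(TOY_CHROMS) | {"4"})
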
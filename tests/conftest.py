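import numpy as np
import pytest

from spirospace.geometry import Conformer3D, embed_and_optimize
from spirospace.library import ScaffoldRecord, builtin_default_library


@pytest.fixture(scope="session")
def library():
    return builtin_default_library()


@pytest.fixture(scope="session")
def piperidine():
    return ScaffoldRecord("pip", "C1CCNCC1", "piperidine")


@pytest.fixture(scope="session")
def piperidine_conf(piperidine):
    return embed_and_optimize(piperidine, n_starts=5, seed=11)


@pytest.fixture(scope="session")
def small_conformers():
    """Five small molecules spanning planar, 3D, polar and strained shapes."""
    records = [
        ScaffoldRecord("bz", "c1ccccc1", "benzene"),
        ScaffoldRecord("pip", "C1CCNCC1", "piperidine"),
        ScaffoldRecord("mor", "C1COCCN1", "morpholine"),
        ScaffoldRecord("oxe", "C1COC1", "oxetane"),
        ScaffoldRecord("spiro", "C1CC12CCC2", "spiro[2.3]hexane"),
    ]
    return [(r, embed_and_optimize(r, n_starts=5, seed=11)) for r in records]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)
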
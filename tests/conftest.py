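import numpy as np
import pytest

from pepforge.structures import ComplexStructure, ToySpec, build_ideal_helix
from pepforge.toys import make_toy_complex


@pytest.fixture(scope="session")
def toy_hb2_sb1():
    """Toy complex with 2 hydrogen bonds and 1 favorable salt bridge."""
    return make_toy_complex(ToySpec(n_hbonds=2, n_salt_bridges=1,
                                    geometry_seed=42))


@pytest.fixture(scope="session")
def toy_saltbridge_only():
    return make_toy_complex(ToySpec(n_salt_bridges=1, geometry_seed=7))


@pytest.fixture(scope="session")
def separated_complex():
    """Receptor and peptide 100 A apart: a null interface."""
    rec = build_ideal_helix("LFA", chain_id="A", capped=True)
    pep = build_ideal_helix("WAV", chain_id="B", capped=True)
    for r in pep:
        for a in r.atoms:
            a.coords = a.coords + np.array([100.0, 0.0, 0.0])
    return ComplexStructure(receptor=rec, peptide=pep, peptide_capped=True)


@pytest.fixture(scope="session")
def posed_complex():
    """A small helical peptide posed alongside a receptor helix."""
    pep = build_ideal_helix("AWA", chain_id="B", capped=True)
    rec = build_ideal_helix("LFL", chain_id="A", capped=True)
    for r in rec:
        for a in r.atoms:
            a.coords = a.coords + np.array([0.0, 7.0, 0.0])
    return ComplexStructure(receptor=rec, peptide=pep, peptide_capped=True)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_complex(cs, rot, shift):
    import copy

    cs = copy.deepcopy(cs)
    for r in cs.receptor + cs.peptide:
        for a in r.atoms:
            a.coords = rot @ a.coords + shift
    return cs
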
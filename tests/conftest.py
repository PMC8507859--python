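import numpy as np
import pytest

from pepsurf.structure_io import Atom, Ensemble, StructureModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_model(coords, model_id=1, names=None, elements=None, chain="P",
               residue_name="ALA"):
    """Build a model with one residue per atom (simplest identity layout)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    atoms = [
        Atom(serial=i + 1, name=names[i], element=elements[i],
             residue_name=residue_name, chain_id=chain, residue_seq=i + 1,
             coords=coords[i])
        for i in range(n)
    ]
    return StructureModel(model_id, atoms)


def make_ensemble(coord_sets, label="test"):
    return Ensemble(
        [make_model(c, model_id=i + 1) for i, c in enumerate(coord_sets)],
        label=label,
    )


@pytest.fixture
def random_model(rng):
    return make_model(rng.normal(scale=4.0, size=(20, 3)))


@pytest.fixture
def receptor_and_regions():
    from pepsurf.synthetic_data import gen_receptor

    return gen_receptor()
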
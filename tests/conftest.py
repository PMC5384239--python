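import numpy as np
import pytest

from flycast.structure_io import Structure


def make_structure(coords, chain="A", res_per_atom=None, atom_names=None,
                   elements=None, res_names=None, masses=None):
    """Assemble a Structure from bare arrays with sensible defaults."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    res = np.arange(1, n + 1) if res_per_atom is None \
        else np.asarray(res_per_atom, dtype=int)
    elements = np.full(n, "C", dtype="U2") if elements is None \
        else np.asarray(elements)
    mass_table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                  "S": 32.06, "P": 30.974}
    if masses is None:
        masses = np.array([mass_table[str(e)] for e in elements])
    return Structure(
        chain_id=np.full(n, chain, dtype="U4") if isinstance(chain, str)
        else np.asarray(chain),
        res_id=res,
        ins_code=np.full(n, "", dtype="U1"),
        res_name=np.full(n, "ALA", dtype="U5") if res_names is None
        else np.asarray(res_names),
        atom_name=np.full(n, "CA", dtype="U6") if atom_names is None
        else np.asarray(atom_names),
        element=elements,
        coord=coords,
        mass=np.asarray(masses, dtype=float),
    )


def ideal_helix(n, chain="A"):
    """Ideal Cα helix: rise 1.5 Å, 100°/residue, radius 2.3 Å."""
    i = np.arange(n)
    t = np.deg2rad(100.0) * i
    return make_structure(
        np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i]),
        chain=chain)


@pytest.fixture(scope="session")
def _toy_dimer_cached():
    from flycast.synthetic_data import ToyDimerSpec, make_toy_dimer

    return make_toy_dimer(ToyDimerSpec(seed=1))


@pytest.fixture()
def toy_dimer(_toy_dimer_cached):
    # fresh copy per test: configs are mutable
    import copy

    return copy.deepcopy(_toy_dimer_cached)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
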
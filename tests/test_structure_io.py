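"""Structure I/O: PDB round trips, filtering policy, selection algebra."""

import numpy as np
import pytest

from flycast.errors import (EmptyStructureError, FormatError,
                            OverflowFieldError, UnknownChainError)
from flycast.structure_io import (Selection, read_pdb, read_pdb_models,
                                  resolve_selection, write_pdb,
                                  write_pdb_models)
from flycast.synthetic_data import ToyDimerSpec, make_toy_dimer

from conftest import make_structure

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00"
    "           C\n"
)

ALTLOC_PDB = (
    "ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.60  0.00"
    "           C\n"
    "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00"
    "           C\n"
)

HETERO_PDB = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "HETATM    2  P   TPO A   2       4.000   0.000   0.000  1.00  0.00"
    "           P\n"
    "HETATM    3  O   HOH A 100       9.000   9.000   9.000  1.00  0.00"
    "           O\n"
)


def test_minimal_single_atom_parse(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(MINIMAL_PDB)
    s = read_pdb(path)
    assert s.n_atoms == 1
    assert s.mass[0] == pytest.approx(12.011)
    assert np.allclose(s.coord[0], [1.0, 2.0, 3.0])
    assert s.res_name[0] == "ALA" and s.chain_id[0] == "A"


def test_altloc_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    s = read_pdb(path)
    assert s.n_atoms == 1
    assert np.allclose(s.coord[0], [1.0, 2.0, 3.0])  # the 0.60 variant


def test_hetero_passlist_keeps_tpo_drops_water(tmp_path):
    path = tmp_path / "het.pdb"
    path.write_text(HETERO_PDB)
    s = read_pdb(path)
    assert sorted(s.res_name) == ["ALA", "TPO"]


def test_empty_after_filtering_raises(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00"
        "  0.00           O\n")
    with pytest.raises(EmptyStructureError):
        read_pdb(path)


def test_unparseable_raises_format_error(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM  garbage line that is not fixed width\n")
    with pytest.raises((FormatError, EmptyStructureError)):
        read_pdb(path)


def test_round_trip_identity_on_toy_chains(tmp_path, toy_dimer):
    """read_pdb(write_pdb(S)) == S on all fields (coords to 3 decimals)."""
    _, _, native, _ = toy_dimer  # 2 chains, Cα-only
    path = tmp_path / "native.pdb"
    write_pdb(native, path)
    back = read_pdb(path)
    assert back == native
    assert back.chains == ["A", "B"]


def test_coordinate_overflow_rejected(tmp_path):
    s = make_structure([[0.0, 0.0, 12345.0]])
    with pytest.raises(OverflowFieldError):
        write_pdb(s, tmp_path / "overflow.pdb")


def test_multi_model_round_trip(tmp_path, toy_dimer):
    """100 frames → 100 MODEL blocks, each re-parseable."""
    apo_a, _, _, _ = toy_dimer
    rng = np.random.default_rng(0)
    frames = apo_a.coord[None] + 0.3 * rng.standard_normal(
        (100, apo_a.n_atoms, 3))
    path = tmp_path / "traj.pdb"
    write_pdb_models(apo_a, frames, path)
    models = read_pdb_models(path)
    assert len(models) == 100
    for k in (0, 37, 99):
        assert np.allclose(models[k].coord, frames[k], atol=5e-4)


def test_calpha_selection_counts():
    s = make_structure(np.zeros((10, 3)) + np.arange(10)[:, None])
    idx = resolve_selection(s, Selection("A", None, "calpha"))
    assert len(idx) == 10


def test_helix9_style_range_selects_29_residues():
    """Residues 200–228 inclusive on a 1–250 chain give 29 Cα atoms."""
    coords = np.column_stack([np.arange(250) * 3.8, np.zeros(250),
                              np.zeros(250)])
    s = make_structure(coords)
    sel = Selection.residue_range("A", 200, 228, "calpha")
    assert len(resolve_selection(s, sel)) == 29


def test_unknown_chain_raises_not_empty():
    s = make_structure(np.zeros((3, 3)))
    with pytest.raises(UnknownChainError):
        resolve_selection(s, Selection("Z"))


def test_empty_selection_is_signalled_as_empty_not_error():
    s = make_structure(np.zeros((3, 3)))
    idx = resolve_selection(s, Selection("A", frozenset([99])))
    assert len(idx) == 0


def test_selection_matches_brute_force_scan(rng):
    """Random selections equal a linear scan over every atom."""
    n = 120
    chains = np.array(["A", "B"])[rng.integers(0, 2, n)]
    res = rng.integers(1, 25, n)
    names = np.array(["CA", "CB", "N", "O"])[rng.integers(0, 4, n)]
    elements = np.array(
        [{"CA": "C", "CB": "C", "N": "N", "O": "O"}[x] for x in names])
    order = np.argsort(chains, kind="stable")
    s = make_structure(rng.normal(size=(n, 3)), chain=chains[order],
                       res_per_atom=np.sort(res[chains == "A"]).tolist()
                       + np.sort(res[chains == "B"]).tolist(),
                       atom_names=names[order], elements=elements[order])
    for _ in range(20):
        chain = str(rng.choice(["A", "B"]))
        residues = frozenset(rng.integers(1, 25, 5).tolist())
        atoms = ["all", "calpha", "sidechain", ("N", "O")][
            int(rng.integers(0, 4))]
        got = set(resolve_selection(s, Selection(chain, residues, atoms)))
        expect = set()
        for i in range(s.n_atoms):
            if str(s.chain_id[i]) != chain:
                continue
            if int(s.res_id[i]) not in residues:
                continue
            name = str(s.atom_name[i])
            if atoms == "calpha" and name != "CA":
                continue
            if atoms == "sidechain" and name in ("N", "CA", "C", "O",
                                                 "OXT", "H", "HA"):
                continue
            if isinstance(atoms, tuple) and name not in atoms:
                continue
            expect.add(i)
        assert got == expect


def test_selection_invariant_to_atom_order_within_residue():
    coords = np.arange(12, dtype=float).reshape(4, 3)
    names = ["N", "CA", "CB", "O"]
    s1 = make_structure(coords, res_per_atom=[1, 1, 1, 1], atom_names=names,
                        elements=["N", "C", "C", "O"])
    perm = [2, 0, 3, 1]
    s2 = make_structure(coords[perm], res_per_atom=[1, 1, 1, 1],
                        atom_names=np.array(names)[perm],
                        elements=np.array(["N", "C", "C", "O"])[perm])
    sel = Selection("A", frozenset([1]), "sidechain")
    got1 = {str(s1.atom_name[i]) for i in resolve_selection(s1, sel)}
    got2 = {str(s2.atom_name[i]) for i in resolve_selection(s2, sel)}
    assert got1 == got2 == {"CB"}
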
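"""Valence model: implicit H counts, add/delete round trips, kekulization."""

import itertools

import pytest

from molfig import (
    KekulizationError,
    add_hydrogens,
    delete_hydrogens,
    implicit_h_count,
    kekulize,
    parse_smiles,
)
from molfig.fixtures import FixtureSpec, isomorphic, random_molecule
from molfig.hydrogen_model import compute_implicit_hydrogens, total_hydrogens
from molfig.layout2d import generate_coordinates
from molfig.molecule import Atom, Bond, Molecule


@pytest.mark.parametrize("element,charge,bos,expected", [
    ("C", 0, 2, 2),
    ("C", 0, 4, 0),
    ("N", 1, 3, 1),     # ammonium-type nitrogen binds four
    ("N", 0, 3, 0),
    ("N", -1, 2, 0),
    ("O", 0, 2, 0),
    ("O", 0, 1, 1),
    ("O", -1, 1, 0),    # alkoxide: anion loses one H of capacity
    ("S", 0, 4, 0),     # hypervalent sulfur steps to the next valence
    ("S", 0, 5, 1),
    ("P", 0, 4, 1),
    ("Cl", 0, 1, 0),
    ("Fe", 0, 2, 0),    # unlisted elements get no implicit hydrogens
    ("C", 0, 6, 0),     # over-bonded input clamps at zero
])
def test_implicit_h_count_valence_rules(element, charge, bos, expected):
    assert implicit_h_count(element, charge, bos) == expected


def _explicit_ethane():
    mol = Molecule()
    for i, el in enumerate(["C", "C", "H", "H", "H", "H", "H", "H"], start=1):
        mol.add_atom(Atom(index=i, element=el))
    mol.add_bond(Bond(a=1, b=2))
    for h, anchor in [(3, 1), (4, 1), (5, 1), (6, 2), (7, 2), (8, 2)]:
        mol.add_bond(Bond(a=anchor, b=h))
    return mol


def test_delete_hydrogens_on_explicit_ethane():
    out = delete_hydrogens(_explicit_ethane())
    assert len(out.atoms) == 2 and len(out.bonds) == 1
    assert [a.implicit_h for a in out.atoms] == [3, 3]
    assert [a.index for a in out.atoms] == [1, 2]


def test_delete_keeps_decorated_hydrogens():
    mol = _explicit_ethane()
    mol.atom(3).charge = -1           # hydride-like H keeps its atom
    mol.atom(4).radical = 2
    from molfig.molecule import STEREO_WEDGE_UP
    mol.bonds[3].stereo = STEREO_WEDGE_UP   # wedge to atom 5
    out = delete_hydrogens(mol)
    assert len(out.atoms) == 5        # 2 C + charged H + radical H + wedge H
    assert {a.element for a in out.atoms} == {"C", "H"}


def test_h2_molecule_survives_deletion():
    mol = Molecule()
    mol.add_atom(Atom(index=1, element="H"))
    mol.add_atom(Atom(index=2, element="H"))
    mol.add_bond(Bond(a=1, b=2))
    out = delete_hydrogens(mol)
    assert len(out.atoms) == 2


def test_add_hydrogens_methane_and_isolated_oxygen():
    mol = Molecule()
    mol.add_atom(Atom(index=1, element="C", implicit_h=4))
    out = add_hydrogens(mol)
    assert len(out.atoms) == 5 and len(out.bonds) == 4

    water = Molecule(has_coordinates=True)
    water.add_atom(Atom(index=1, element="O", implicit_h=2))
    out = add_hydrogens(water)
    assert len(out.atoms) == 3
    import math
    angles = [math.degrees(math.atan2(a.y, a.x)) % 360 for a in out.atoms[1:]]
    assert abs(abs(angles[0] - angles[1]) - 180.0) < 1e-9


@pytest.mark.parametrize("seed", range(25))
def test_hydrogen_count_conserved_by_add_delete_roundtrip(seed):
    mol = random_molecule(FixtureSpec(seed=seed))
    before = total_hydrogens(mol)
    grown = add_hydrogens(mol)
    assert total_hydrogens(grown) == before
    shrunk = delete_hydrogens(grown)
    assert total_hydrogens(shrunk) == before
    assert isomorphic(shrunk, delete_hydrogens(mol))


# -- kekulization ----------------------------------------------------------

def _exhaustive_kekulizations(mol, needy):
    """Independent oracle: enumerate all subsets of aromatic bonds and keep
    those giving every pi-contributing atom exactly one double bond and
    every other aromatic atom none."""
    aromatic = [b for b in mol.bonds if b.aromatic]
    aromatic_atoms = {i for b in aromatic for i in (b.a, b.b)}
    valid = []
    for r in range(len(aromatic) + 1):
        for chosen in itertools.combinations(range(len(aromatic)), r):
            count = {i: 0 for i in aromatic_atoms}
            for k in chosen:
                count[aromatic[k].a] += 1
                count[aromatic[k].b] += 1
            if all(count[i] == (1 if i in needy else 0)
                   for i in aromatic_atoms):
                valid.append({aromatic[k].key() for k in chosen})
    return valid


@pytest.mark.parametrize("smiles,needy", [
    ("c1ccccc1", {1, 2, 3, 4, 5, 6}),                       # benzene
    ("c1ccncc1", {1, 2, 3, 4, 5, 6}),                       # pyridine
    ("o1cccc1", {2, 3, 4, 5}),                              # furan: O donates
    ("c1ccc2ccccc2c1", set(range(1, 11))),                  # naphthalene
    ("c1cc[nH]c1", {1, 2, 3, 5}),                           # pyrrole
], ids=["benzene", "pyridine", "furan", "naphthalene", "pyrrole"])
def test_kekulize_matches_exhaustive_oracle(smiles, needy):
    mol = parse_smiles(smiles)
    valid = _exhaustive_kekulizations(mol, needy)
    assert valid, "oracle itself found no assignment — bad test setup"
    kek = kekulize(mol)
    doubles = {b.key() for b in kek.bonds if b.aromatic and b.order == 2}
    assert doubles in valid


def test_furan_oxygen_gets_no_double_bond():
    kek = kekulize(parse_smiles("o1cccc1"))
    assert sum(1 for b in kek.bonds if b.order == 2) == 2
    assert all(1 not in (b.a, b.b) for b in kek.bonds if b.order == 2)


def test_kekulize_identity_without_aromatic_bonds_and_idempotence():
    mol = parse_smiles("CCO")
    assert kekulize(mol) is mol
    kek = kekulize(parse_smiles("c1ccccc1"))
    again = kekulize(kek)
    assert [(b.key(), b.order) for b in again.bonds] == \
           [(b.key(), b.order) for b in kek.bonds]


def test_kekulize_failure_names_atoms():
    # five-membered all-carbon aromatic ring has no perfect matching
    with pytest.raises(KekulizationError, match=r"\["):
        kekulize(parse_smiles("c1cccc1"))


@pytest.mark.parametrize("seed", range(15))
def test_no_atom_exceeds_effective_valence_after_kekulize(seed):
    from molfig.hydrogen_model import effective_valence
    mol = kekulize(random_molecule(FixtureSpec(seed=seed)))
    for a in mol.atoms:
        bos = sum(b.order for _, b in mol.neighbors(a.index))
        assert bos <= effective_valence(a.element, a.charge, bos)


@pytest.mark.parametrize("smiles", ["c1ccccc1", "c1ccc2ccccc2c1", "c1cc[nH]c1"])
def test_double_bond_count_agrees_with_rdkit(smiles):
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    ref = Chem.MolFromSmiles(smiles)
    Chem.Kekulize(ref, clearAromaticFlags=True)
    ref_doubles = sum(1 for b in ref.GetBonds()
                      if b.GetBondType() == Chem.BondType.DOUBLE)
    ours = sum(1 for b in kekulize(parse_smiles(smiles)).bonds if b.order == 2)
    assert ours == ref_doubles
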
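r"""Atom/bond token emission, comments, wrappers, and terse stripping."""

import re

import pytest

from molfig import RenderOptions, convert, parse_smiles, strip_terse
from molfig.chemfig_writer import (
    atom_code,
    bond_code,
    closure_label_name,
    double_bond_side,
)
from molfig.fixtures import FixtureSpec, load_fixture, random_molecule
from molfig.molecule import Atom, Bond, Molecule, STEREO_WEDGE_UP


OPTS = RenderOptions()


def test_hydroxyl_faces_away_from_its_bond():
    # bond leaves toward the upper right → hydrogens go left: "HO"
    o = Atom(index=4, element="O", implicit_h=1)
    assert atom_code(o, [30.0], OPTS) == "HO"
    # bond leaves toward the left → hydrogens go right: "OH"
    assert atom_code(o, [150.0], OPTS) == "OH"
    # purely vertical bonds default to the right
    assert atom_code(o, [90.0], OPTS) == "OH"


def test_terminal_amine_with_two_hydrogens():
    n = Atom(index=1, element="N", implicit_h=2)
    assert atom_code(n, [270.0], OPTS) == "NH_2"


def test_plain_carbon_is_a_bare_vertex_but_lone_atoms_show():
    c = Atom(index=2, element="C", implicit_h=2)
    assert atom_code(c, [0.0, 120.0], OPTS) == ""
    # bonds leave to the left → hydrogens sit on the right
    assert atom_code(c, [180.0, 120.0], RenderOptions(show_carbons=True)) == "CH_2"
    # bonds occupy the right → hydrogens flip to the left
    assert atom_code(c, [0.0, 120.0], RenderOptions(show_carbons=True)) == "H_2C"
    lone = Atom(index=1, element="C", implicit_h=4)
    assert atom_code(lone, [], OPTS) == "CH_4"


def test_methyl_label_only_with_show_methyls():
    me = Atom(index=3, element="C", implicit_h=3)
    assert atom_code(me, [180.0], OPTS) == ""
    assert atom_code(me, [180.0], RenderOptions(show_methyls=True)) == "CH_3"


def test_charge_radical_and_atom_number_decorations():
    n = Atom(index=5, element="N", charge=1, implicit_h=3)
    assert atom_code(n, [270.0], OPTS) == "NH_3^{+}"
    o = Atom(index=2, element="O", charge=-2)
    assert atom_code(o, [270.0], OPTS) == "O^{2-}"
    r = Atom(index=7, element="C", radical=2, implicit_h=3)
    assert atom_code(r, [180.0], OPTS) == "CH_3\\mcfdot"
    assert atom_code(n, [270.0], RenderOptions(atom_numbers=True)) == \
        "NH_3^{+}\\mcfatomno{5}"
    hidden = Atom(index=9, element="C", implicit_h=2)
    assert atom_code(hidden, [0.0, 180.0],
                     RenderOptions(atom_numbers=True)) == "\\mcfatomno{9}"


def test_bond_code_tokens_and_specs():
    single = Bond(a=1, b=2)
    assert bond_code(single, 1, 270.0) == "-[:270]"
    wedge = Bond(a=1, b=2, stereo=STEREO_WEDGE_UP)
    assert bond_code(wedge, 1, 150.0) == "<[:150]"
    assert bond_code(wedge, 2, 150.0) == ">[:150]"   # narrow end at child
    assert bond_code(single, 1, 45.0, relative=True) == "-[::45]"
    assert bond_code(single, 1, 270.0, factor=2.0) == "-[:270,2]"
    double = Bond(a=1, b=2, order=2)
    assert bond_code(double, 1, 0.0, side="^") == "=^[:0]"
    triple = Bond(a=1, b=2, order=3)
    assert bond_code(triple, 1, 90.0) == "~[:90]"


def test_double_bond_side_follows_ring_centroid():
    mol = Molecule(has_coordinates=True)
    mol.add_atom(Atom(index=1, element="C", x=0.0, y=0.0))
    mol.add_atom(Atom(index=2, element="C", x=1.0, y=0.0))
    bond = Bond(a=1, b=2, order=2)
    mol.add_bond(bond)
    assert double_bond_side(bond, 1, mol, (0.5, 1.0)) == "^"   # centroid left
    assert double_bond_side(bond, 1, mol, (0.5, -1.0)) == "_"  # centroid right
    assert double_bond_side(bond, 2, mol, (0.5, 1.0)) == "_"   # reversed travel
    assert double_bond_side(bond, 1, mol, None) == ""          # exocyclic


def test_methane_wrapped():
    code = convert(parse_smiles("C"), RenderOptions(wrap=True))
    assert code.terse == "\\chemfig{CH_4}"


def test_verbose_has_one_bond_line_per_bond_and_unique_atom_comments():
    for seed in (0, 5, 11):
        mol = random_molecule(FixtureSpec(seed=seed))
        code = convert(mol.copy(), RenderOptions())
        plain = re.findall(r"% (\d+)$", code.verbose, re.M)
        closure = re.findall(r"% ->(\d+)$", code.verbose, re.M)
        # every atom reached exactly once; every closure comments its target
        assert sorted(map(int, plain)) == [a.index for a in mol.atoms]
        n_cyc = len(mol.bonds) - len(mol.atoms) + 1
        assert len(closure) == n_cyc
        # atom lines: root line plus one line per tree bond
        assert len(plain) == len(mol.bonds) - n_cyc + 1


def test_closure_markers_pair_up():
    code = convert(parse_smiles("C1CCCCC1"), RenderOptions())
    assert re.search(r"\?\[a\]", code.verbose)
    assert re.search(r"\?\[a,\{-\}\]\s+% ->1", code.verbose)


def test_submol_wrapper_and_precedence_over_wrap():
    code = convert(parse_smiles("CO"),
                   RenderOptions(wrap=True, submol_name="frag"))
    assert code.verbose.startswith("\\definesubmol{frag}{")
    assert code.wrapper == "submol:frag"


def test_aromatic_circle_emits_invisible_spoke_and_plain_ring_bonds():
    code = convert(parse_smiles("c1ccccc1"),
                   RenderOptions(aromatic_circles=True))
    assert "draw=none" in code.verbose
    assert "\\mcfcringle{" in code.verbose
    assert "=" not in strip_terse(code.verbose).replace("draw=none", "")


def test_strip_terse_rules():
    assert strip_terse("-[:270]  % 3\n") == "-[:270]"
    assert strip_terse("a b\tc\nd") == "abcd"
    text = "-[:30]OH % 2\n( -[:90] % 3\n)"
    assert strip_terse(strip_terse(text)) == strip_terse(text)


def test_closure_label_names():
    assert [closure_label_name(k) for k in (1, 2, 26, 27, 28)] == \
        ["a", "b", "z", "aa", "ab"]


def test_terse_field_is_strip_of_verbose():
    mol = load_fixture("norepinephrine")
    for opts in (RenderOptions(), RenderOptions(wrap=True),
                 RenderOptions(submol_name="x"), RenderOptions(atom_numbers=True)):
        code = convert(mol.copy(), opts)
        assert code.terse == strip_terse(code.verbose)
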
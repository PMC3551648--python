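r"""Generator determinism and validity, molfile writing, oracle parser."""

import pytest

from molfig import parse_molfile, parse_smiles
from molfig.fixtures import (
    NAMED_FIXTURES,
    FixtureSpec,
    load_fixture,
    molecules_equal,
    parse_chemfig_subset,
    random_molecule,
    write_molfile,
)
from molfig.hydrogen_model import effective_valence
from molfig.molecule import ParseError


def test_identical_spec_gives_identical_molecule():
    a = random_molecule(FixtureSpec(seed=42))
    b = random_molecule(FixtureSpec(seed=42))
    assert molecules_equal(a, b)
    assert [(x.x, x.y) for x in a.atoms] == [(x.x, x.y) for x in b.atoms]


def test_single_atom_spec():
    mol = random_molecule(FixtureSpec(seed=1, n_heavy_atoms=1))
    assert len(mol.atoms) == 1 and len(mol.bonds) == 0


def test_zero_ring_probability_gives_trees():
    for seed in range(10):
        mol = random_molecule(FixtureSpec(seed=seed, ring_probability=0.0,
                                          aromatic_ring_rate=0.0))
        assert len(mol.bonds) == len(mol.atoms) - 1


@pytest.mark.parametrize("seed", range(0, 500, 7))
def test_generated_molecules_are_valence_valid(seed):
    mol = random_molecule(FixtureSpec(seed=seed))
    assert mol.is_connected()
    for a in mol.atoms:
        bos = sum(b.order for _, b in mol.neighbors(a.index))
        assert bos <= effective_valence(a.element, a.charge, bos), \
            f"atom {a.index} ({a.element}) over-bonded"


def test_write_molfile_counts_and_property_lines():
    mol = random_molecule(FixtureSpec(seed=3))
    text = write_molfile(mol)
    counts = text.splitlines()[3]
    assert int(counts[0:3]) == len(mol.atoms)
    assert int(counts[3:6]) == len(mol.bonds)
    charged = random_molecule(FixtureSpec(seed=1, charge_rate=1.0))
    if any(a.charge for a in charged.atoms):
        assert "M  CHG" in write_molfile(charged)


@pytest.mark.parametrize("seed", range(0, 500, 5))
def test_molfile_roundtrip_is_lossless(seed):
    mol = random_molecule(FixtureSpec(seed=seed))
    back = parse_molfile(write_molfile(mol))
    assert molecules_equal(mol, back)


@pytest.mark.parametrize("name", NAMED_FIXTURES)
def test_named_fixtures_load(name):
    mol = load_fixture(name)
    assert mol.has_coordinates and len(mol.atoms) >= 1
    mol.validate()


def test_radical_toy_carries_charges_and_radical():
    mol = load_fixture("radical_toy")
    assert sorted(a.charge for a in mol.atoms if a.charge) == [-1, 1]
    assert any(a.radical == 2 for a in mol.atoms)


# -- oracle parser ---------------------------------------------------------

def test_oracle_methane():
    mol = parse_chemfig_subset("\\chemfig{CH_4}")
    a = mol.atom(1)
    assert (a.element, a.implicit_h, a.h_fixed) == ("C", 4, True)


def test_oracle_bare_chain():
    mol = parse_chemfig_subset("-[:270]-[:30]-[:270]")
    assert len(mol.atoms) == 4 and len(mol.bonds) == 3
    assert all(a.element == "C" and not a.h_fixed for a in mol.atoms)


def test_oracle_branches_charges_hooks():
    code = ("?[a]-[:30]OH"
            "(-[:90]N^{2+})"
            "=[:330]?[a,{-}]")
    mol = parse_chemfig_subset(code)
    assert len(mol.atoms) == 4 and len(mol.bonds) == 4
    o = next(a for a in mol.atoms if a.element == "O")
    assert o.implicit_h == 1 and o.h_fixed
    n = next(a for a in mol.atoms if a.element == "N")
    assert n.charge == 2
    orders = sorted(b.order for b in mol.bonds)
    assert orders == [1, 1, 1, 2]


def test_oracle_reconstructs_emitted_cyclohexane():
    from molfig import RenderOptions, convert
    from molfig.fixtures import isomorphic

    src = load_fixture("cyclohexane")
    code = convert(src.copy(), RenderOptions())
    got = parse_chemfig_subset(code.verbose)
    assert len(got.atoms) == 6 and len(got.bonds) == 6
    assert isomorphic(src, got)


def test_oracle_ignores_invisible_circle_spokes():
    from molfig import RenderOptions, convert

    src = parse_smiles("c1ccccc1")
    code = convert(src, RenderOptions(aromatic_circles=True))
    got = parse_chemfig_subset(code.verbose)
    assert len(got.atoms) == 6 and len(got.bonds) == 6
    assert all(b.order == 1 for b in got.bonds)


@pytest.mark.parametrize("bad", [
    "\\chemfig{C(}",         # unmatched branch
    "?[a]",                  # hook never closed
    "-[:30]?[q,{-}]",        # closing an unopened hook
    "C!!",                   # stray characters
])
def test_oracle_rejects_malformed_code(bad):
    with pytest.raises(ParseError):
        parse_chemfig_subset(bad)


def test_make_fixtures_entry_point(tmp_path):
    from molfig.fixtures import main

    rc = main([str(tmp_path), "--count", "3", "--seed", "5"])
    assert rc == 0
    files = sorted(tmp_path.glob("*.mol"))
    assert len(files) == 3
    for f in files:
        parse_molfile(f.read_text())
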
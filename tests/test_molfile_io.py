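"""Molfile V2000 parsing: blocks, property lines, and error reporting."""

import pytest

from molfig import ParseError, parse_molfile
from molfig.molecule import STEREO_HASH_DOWN, STEREO_WEDGE_UP

MINIMAL_METHANE = """methane


  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


def _molfile(atoms, bonds, properties=()):
    lines = ["test", "", "",
             f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for el, x, y, code in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} {el:<3} 0{code:3d}"
                     "  0  0  0  0  0  0  0  0  0")
    for a, b, order, stereo in bonds:
        lines.append(f"{a:3d}{b:3d}{order:3d}{stereo:3d}  0  0  0")
    lines.extend(properties)
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def test_minimal_methane():
    mol = parse_molfile(MINIMAL_METHANE)
    assert len(mol.atoms) == 1 and len(mol.bonds) == 0
    assert mol.atoms[0].element == "C"
    assert mol.has_coordinates


def test_charge_property_line_sets_charge():
    text = _molfile([("C", 0, 0, 0)], [], ["M  CHG  1   1  -1"])
    assert parse_molfile(text).atom(1).charge == -1


def test_charge_property_resets_column_charges():
    # atom 1 carries a +1 column code, but an M CHG line for atom 2 is
    # authoritative for the whole molecule (CTfile rule)
    text = _molfile([("N", 0, 0, 3), ("O", 1, 0, 0)],
                    [(1, 2, 1, 0)], ["M  CHG  1   2  -1"])
    mol = parse_molfile(text)
    assert mol.atom(1).charge == 0
    assert mol.atom(2).charge == -1


@pytest.mark.parametrize("code,charge", [(1, 3), (2, 2), (3, 1),
                                         (5, -1), (6, -2), (7, -3)])
def test_legacy_charge_column(code, charge):
    text = _molfile([("N", 0, 0, code)], [])
    assert parse_molfile(text).atom(1).charge == charge


def test_legacy_doublet_radical_column():
    text = _molfile([("C", 0, 0, 4)], [])
    assert parse_molfile(text).atom(1).radical == 2


def test_radical_property_line():
    text = _molfile([("C", 0, 0, 0)], [], ["M  RAD  1   1   2"])
    assert parse_molfile(text).atom(1).radical == 2


def test_benzene_fixture_matches_hand_built_graph():
    from molfig.fixtures import fixture_path
    mol = parse_molfile(fixture_path("benzene").read_text())
    assert len(mol.atoms) == 6 and len(mol.bonds) == 6
    assert all(a.element == "C" for a in mol.atoms)
    # cyclomatic number 1, alternating orders
    assert len(mol.bonds) - len(mol.atoms) + 1 == 1
    assert sorted(b.order for b in mol.bonds) == [1, 1, 1, 2, 2, 2]
    ring = {(b.a, b.b) for b in mol.bonds}
    assert ring == {(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (1, 6)}


def test_aromatic_order_4_and_stereo_columns():
    text = _molfile([("C", 0, 0, 0), ("C", 1, 0, 0), ("O", 2, 0, 0)],
                    [(1, 2, 4, 0), (2, 3, 1, 1)])
    mol = parse_molfile(text)
    assert mol.bonds[0].aromatic and mol.bonds[0].order == 1
    assert mol.bonds[1].stereo == STEREO_WEDGE_UP
    text = _molfile([("C", 0, 0, 0), ("C", 1, 0, 0)], [(1, 2, 1, 6)])
    assert parse_molfile(text).bonds[0].stereo == STEREO_HASH_DOWN


def test_sd_file_reads_first_record_only():
    second = MINIMAL_METHANE.replace("C", "N")
    mol = parse_molfile(MINIMAL_METHANE + "$$$$\n" + second)
    assert len(mol.atoms) == 1 and mol.atoms[0].element == "C"


@pytest.mark.parametrize("mangle,hint", [
    (lambda t: t.replace("V2000", "V3000"), "V2000"),
    (lambda t: t.replace("  1  0", "  2  0"), "atom"),     # count mismatch
    (lambda t: t.replace("M  END\n", ""), "M  END"),
], ids=["wrong-version", "count-mismatch", "missing-end"])
def test_malformed_files_raise_parse_error(mangle, hint):
    with pytest.raises(ParseError) as exc:
        parse_molfile(mangle(MINIMAL_METHANE))
    assert "line" in str(exc.value)


def test_bond_to_nonexistent_atom_names_line():
    text = _molfile([("C", 0, 0, 0), ("C", 1, 0, 0)], [(1, 3, 1, 0)])
    with pytest.raises(ParseError, match=r"line 7.*nonexistent"):
        parse_molfile(text)


def test_unknown_bond_order_rejected():
    text = _molfile([("C", 0, 0, 0), ("C", 1, 0, 0)], [(1, 2, 9, 0)])
    with pytest.raises(ParseError, match="order"):
        parse_molfile(text)
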
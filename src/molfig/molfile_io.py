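"""MDL molfile V2000 reader.

Reads a single molecule: the whole file, or the first record of an SD file
(everything after the first ``$$$$`` is ignored).  Charges and radicals obey
the CTfile rule that ``M  CHG`` / ``M  RAD`` property lines, when present,
reset every atom-block charge-column value; the legacy charge column is used
only in their absence.  z-coordinates are read and discarded.
"""

from __future__ import annotations

from .molecule import (
    Atom,
    Bond,
    Molecule,
    MolfigError,
    ParseError,
    STEREO_HASH_DOWN,
    STEREO_NONE,
    STEREO_WEDGE_UP,
)

__all__ = ["parse_molfile", "Atom", "Bond", "Molecule"]

# legacy atom-block charge column; 4 is the CTfile "doublet radical" code
_CHARGE_COLUMN = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_STEREO_COLUMN = {1: STEREO_WEDGE_UP, 6: STEREO_HASH_DOWN}


def _int_field(text: str, lineno: int, what: str) -> int:
    try:
        return int(text.strip() or "0")
    except ValueError:
        raise ParseError(f"bad {what} field {text!r}", line=lineno) from None


def parse_molfile(text: str) -> Molecule:
    """Parse molfile V2000 text into a :class:`Molecule` with coordinates.

    Raises :class:`ParseError` (naming the offending line) on a malformed
    counts line, atom/bond count mismatch, a bond referencing a nonexistent
    atom, or an unknown bond order.  Order 4 is accepted as aromatic.
    """
    # first record only; SD data fields are out of scope
    record = text.split("$$$$")[0]
    lines = record.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile needs a 3-line header plus counts line",
                         line=len(lines) or 1)

    counts_lineno = 4
    counts = lines[3]
    if "V2000" not in counts:
        raise ParseError("counts line does not declare V2000", line=counts_lineno)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError("malformed counts line", line=counts_lineno) from None
    if n_atoms < 0 or n_bonds < 0:
        raise ParseError("negative atom or bond count", line=counts_lineno)

    mol = Molecule(has_coordinates=True)

    atom_first = 4
    atom_last = atom_first + n_atoms
    bond_last = atom_last + n_bonds
    if len(lines) < bond_last:
        raise ParseError(
            f"file ends before the declared {n_atoms} atoms and {n_bonds} bonds",
            line=len(lines))

    column_charges: dict[int, int] = {}
    column_radicals: dict[int, int] = {}
    for i, raw in enumerate(lines[atom_first:atom_last]):
        lineno = atom_first + i + 1
        if len(raw) < 34:
            raise ParseError("atom line too short", line=lineno)
        try:
            x = float(raw[0:10])
            y = float(raw[10:20])
            float(raw[20:30])  # z read and discarded
        except ValueError:
            raise ParseError("bad coordinate field", line=lineno) from None
        element = raw[31:34].strip()
        if not element:
            raise ParseError("empty element symbol", line=lineno)
        code = _int_field(raw[36:39], lineno, "charge") if len(raw) >= 39 else 0
        idx = i + 1
        if code in _CHARGE_COLUMN:
            column_charges[idx] = _CHARGE_COLUMN[code]
        elif code == 4:
            column_radicals[idx] = 2
        # remaining atom-block columns (parity, valence, ...) are ignored
        mol.add_atom(Atom(index=idx, element=element, x=x, y=y))

    for i, raw in enumerate(lines[atom_last:bond_last]):
        lineno = atom_last + i + 1
        if len(raw) < 9:
            raise ParseError("bond line too short", line=lineno)
        a = _int_field(raw[0:3], lineno, "atom index")
        b = _int_field(raw[3:6], lineno, "atom index")
        order = _int_field(raw[6:9], lineno, "bond order")
        stereo_code = _int_field(raw[9:12], lineno, "stereo") if len(raw) >= 12 else 0
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise ParseError(f"bond references nonexistent atom {max(a, b)}",
                             line=lineno)
        aromatic = False
        if order == 4:
            order, aromatic = 1, True
        if order not in (1, 2, 3):
            raise ParseError(f"unknown bond order {order}", line=lineno)
        try:
            mol.add_bond(Bond(a=a, b=b, order=order, aromatic=aromatic,
                              stereo=_STEREO_COLUMN.get(stereo_code, STEREO_NONE)))
        except MolfigError as exc:
            raise ParseError(str(exc), line=lineno) from None

    # property block: M CHG / M RAD are authoritative when present
    chg: dict[int, int] = {}
    rad: dict[int, int] = {}
    saw_chg = saw_rad = False
    for i, raw in enumerate(lines[bond_last:]):
        lineno = bond_last + i + 1
        if raw.startswith("M  END"):
            break
        if raw.startswith("M  CHG") or raw.startswith("M  RAD"):
            fields = raw.split()
            try:
                n = int(fields[2])
                pairs = [(int(fields[3 + 2 * k]), int(fields[4 + 2 * k]))
                         for k in range(n)]
            except (IndexError, ValueError):
                raise ParseError("malformed property line", line=lineno) from None
            for idx, val in pairs:
                if not (1 <= idx <= n_atoms):
                    raise ParseError(f"property references nonexistent atom {idx}",
                                     line=lineno)
            if raw.startswith("M  CHG"):
                saw_chg = True
                chg.update(pairs)
            else:
                saw_rad = True
                rad.update(pairs)
    else:
        raise ParseError('missing "M  END"', line=len(lines))

    charges = chg if saw_chg else column_charges
    radicals = rad if saw_rad else column_radicals
    for idx, val in charges.items():
        mol.atom(idx).charge = val
    for idx, val in radicals.items():
        mol.atom(idx).radical = val

    if not any(b.aromatic for b in mol.bonds):
        mol.kekulized = True
    mol.validate()
    return mol
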
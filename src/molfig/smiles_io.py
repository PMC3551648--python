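"""SMILES reader for a practical subset.

Covers organic-subset atoms (B, C, N, O, P, S, F, Cl, Br, I), aromatic
lowercase forms (b, c, n, o, p, s), bracket atoms with explicit H counts and
charges, bond symbols ``- = # :`` (plus ``/`` and ``\\`` accepted with their
cis/trans geometry ignored), parenthesized branches and ring-bond digits
(including ``%nn``).  Tetrahedral ``@``/``@@`` marks are parsed and ignored
with a warning: wedge stereo is honored from molfile input only.
Multi-fragment input (``.``) is rejected.

The result is a coordinate-free :class:`~molfig.molecule.Molecule`; bracket
H counts are stored as fixed implicit hydrogens, everything else is filled
in later by the valence model.
"""

from __future__ import annotations

import re
import warnings

from .molecule import Atom, Bond, Molecule, MolfigError, ParseError

__all__ = ["parse_smiles"]

_ORGANIC = ["Br", "Cl", "B", "C", "N", "O", "P", "S", "F", "I"]
_AROMATIC = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": 1, "/": 1, "\\": 1}

_BRACKET_RE = re.compile(
    r"""\[
        (?P<symbol>[A-Z][a-z]?|[bcnops])
        (?P<chiral>@{1,2})?
        (?P<hcount>H\d*)?
        (?P<charge>\+\+|--|[+-]\d*)?
    \]""",
    re.VERBOSE,
)


def _parse_charge(token: str | None) -> int:
    if not token:
        return 0
    if token == "++":
        return 2
    if token == "--":
        return -2
    sign = 1 if token[0] == "+" else -1
    mag = int(token[1:]) if len(token) > 1 else 1
    return sign * mag


def parse_smiles(s: str) -> Molecule:
    """Parse a SMILES string into a coordinate-free molecule.

    Raises :class:`ParseError` with the character offset on unmatched
    parentheses or ring digits, unknown symbols, or a ``.`` disconnection.
    """
    mol = Molecule(has_coordinates=False)
    prev: int | None = None          # atom awaiting the next bond
    pending_bond: str | None = None  # explicit bond symbol seen since last atom
    pending_pos = 0
    stack: list[int] = []
    open_rings: dict[int, tuple[int, str | None, int]] = {}  # digit -> (atom, bond, pos)
    aromatic_atoms: set[int] = set()

    def close_ring(digit: int, pos: int) -> None:
        if prev is None:
            raise ParseError("ring digit before any atom", offset=pos)
        if digit in open_rings:
            opener, obond, opos = open_rings.pop(digit)
            if opener == prev:
                raise ParseError(f"ring bond {digit} closes onto its own atom",
                                 offset=pos)
            symbol = pending_bond if pending_bond is not None else obond
            if pending_bond is not None and obond is not None and pending_bond != obond:
                raise ParseError(f"conflicting bond symbols for ring bond {digit}",
                                 offset=pos)
            _add_bond(opener, prev, symbol)
        else:
            open_rings[digit] = (prev, pending_bond, pos)

    def _add_bond(a: int, b: int, symbol: str | None) -> None:
        both_aromatic = a in aromatic_atoms and b in aromatic_atoms
        if symbol is None:
            order, aromatic = (1, True) if both_aromatic else (1, False)
        elif symbol == ":":
            order, aromatic = 1, True
        else:
            order, aromatic = _BOND_ORDERS[symbol], False
        try:
            mol.add_bond(Bond(a=a, b=b, order=order, aromatic=aromatic))
        except MolfigError as exc:
            raise ParseError(str(exc), offset=pending_pos) from None

    def new_atom(element: str, pos: int, *, aromatic: bool,
                 h: int | None = None, charge: int = 0) -> None:
        nonlocal prev, pending_bond
        idx = len(mol.atoms) + 1
        mol.add_atom(Atom(index=idx, element=element, charge=charge,
                          implicit_h=h or 0, h_fixed=h is not None))
        if aromatic:
            aromatic_atoms.add(idx)
        if prev is not None:
            _add_bond(prev, idx, pending_bond)
        prev = idx
        pending_bond = None

    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == ".":
            raise ParseError("multi-fragment SMILES not supported", offset=i)
        if c in _BOND_ORDERS:
            if c in "/\\":
                warnings.warn("cis/trans bond geometry ignored", stacklevel=2)
                c = "-"
            if pending_bond is not None:
                raise ParseError("two bond symbols in a row", offset=i)
            pending_bond, pending_pos = c, i
            i += 1
        elif c == "(":
            if prev is None:
                raise ParseError("branch before any atom", offset=i)
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise ParseError("unmatched closing parenthesis", offset=i)
            if pending_bond is not None:
                raise ParseError("dangling bond symbol before ')'", offset=i)
            prev = stack.pop()
            i += 1
        elif c.isdigit():
            close_ring(int(c), i)
            pending_bond = None
            i += 1
        elif c == "%":
            m = re.match(r"%(\d\d)", s[i:])
            if not m:
                raise ParseError("'%' must be followed by two digits", offset=i)
            close_ring(int(m.group(1)), i)
            pending_bond = None
            i += 2 + 1
        elif c == "[":
            m = _BRACKET_RE.match(s, i)
            if not m:
                raise ParseError("malformed bracket atom", offset=i)
            if m.group("chiral"):
                warnings.warn("tetrahedral stereo (@/@@) ignored", stacklevel=2)
            sym = m.group("symbol")
            aromatic = sym in _AROMATIC
            element = _AROMATIC.get(sym, sym)
            htok = m.group("hcount")
            h = 0 if htok is None else (int(htok[1:]) if len(htok) > 1 else 1)
            new_atom(element, i, aromatic=aromatic, h=h,
                     charge=_parse_charge(m.group("charge")))
            i = m.end()
        else:
            matched = False
            for sym in _ORGANIC:
                if s.startswith(sym, i):
                    new_atom(sym, i, aromatic=False)
                    i += len(sym)
                    matched = True
                    break
            if not matched and c in _AROMATIC:
                new_atom(_AROMATIC[c], i, aromatic=True)
                i += 1
                matched = True
            if not matched:
                raise ParseError(f"unknown symbol {c!r}", offset=i)

    if stack:
        raise ParseError("unmatched opening parenthesis", offset=n)
    if open_rings:
        digit, (_, _, pos) = sorted(open_rings.items())[0]
        raise ParseError(f"unmatched ring bond digit {digit}", offset=pos)
    if pending_bond is not None:
        raise ParseError("dangling bond symbol at end of input", offset=pending_pos)
    if not mol.atoms:
        raise ParseError("empty SMILES", offset=0)
    mol.validate()
    return mol
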
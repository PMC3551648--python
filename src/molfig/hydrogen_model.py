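"""Valence bookkeeping: implicit hydrogens, explicit-H add/delete, kekulization.

The valence table covers the organic subset (B 3; C 4; N 3; O 2; P 3/5;
S 2/4/6; halogens 1; H 1).  The effective valence of an atom is the smallest
allowed valence that accommodates its bond-order sum, adjusted for formal
charge: cations of N and P gain capacity (N+ binds four), anions lose one H
of capacity per negative charge (O- binds none).  Elements outside the table
get no implicit hydrogens.

Kekulization assigns concrete single/double orders to aromatic-flagged bonds
by a backtracking perfect matching over the atoms that must carry exactly
one double bond (carbons and pyridine-type/charged nitrogens; pyrrole-type
N, O and S donate lone pairs and are excluded).  Aromatic flags survive so
that ring-circle rendering can still find the system.
"""

from __future__ import annotations

import math

from .molecule import Atom, Bond, KekulizationError, Molecule, STEREO_NONE

__all__ = [
    "VALENCES",
    "implicit_h_count",
    "compute_implicit_hydrogens",
    "delete_hydrogens",
    "add_hydrogens",
    "kekulize",
    "total_hydrogens",
]

VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "H": (1,),
}


def effective_valence(element: str, charge: int, bond_order_sum: float) -> int:
    """Charge-adjusted valence capacity; 0 for unlisted elements."""
    allowed = VALENCES.get(element)
    if allowed is None:
        return 0
    bos = math.ceil(bond_order_sum)
    base = next((v for v in allowed if v >= bos), allowed[-1])
    if charge > 0 and element in ("N", "P"):
        return base + charge
    if charge < 0:
        return max(0, base - abs(charge))
    return base


def implicit_h_count(element: str, charge: int, bond_order_sum: float,
                     aromatic_atom: bool = False) -> int:
    """Hydrogens needed to fill the effective valence; clamped at 0.

    ``bond_order_sum`` should use kekulized orders when available; for an
    unkekulized aromatic atom pass ceil(1.5 * n_aromatic) + other orders
    (``aromatic_atom`` is accepted for signature clarity; the sum already
    encodes it).
    """
    eff = effective_valence(element, charge, bond_order_sum)
    return max(0, eff - math.ceil(bond_order_sum))


def _bond_order_sum(mol: Molecule, idx: int) -> float:
    total = 0.0
    n_aromatic = 0
    for _, b in mol.neighbors(idx):
        if b.aromatic and not mol.kekulized:
            n_aromatic += 1
        else:
            total += b.order
    if n_aromatic:
        total += math.ceil(1.5 * n_aromatic)
    return total


def compute_implicit_hydrogens(mol: Molecule) -> Molecule:
    """Fill ``implicit_h`` for every atom without a fixed bracket H count."""
    for a in mol.atoms:
        if a.h_fixed:
            continue
        a.implicit_h = implicit_h_count(a.element, a.charge,
                                        _bond_order_sum(mol, a.index))
    return mol


def total_hydrogens(mol: Molecule) -> int:
    """Explicit H atoms plus the sum of implicit counts."""
    explicit = sum(1 for a in mol.atoms if a.element == "H")
    return explicit + sum(a.implicit_h for a in mol.atoms if a.element != "H")


def _renumber(mol: Molecule, keep: list[int]) -> Molecule:
    """Rebuild a molecule keeping only ``keep`` (old indices), renumbered
    contiguously in the original relative order."""
    remap = {old: new for new, old in enumerate(keep, start=1)}
    out = Molecule(has_coordinates=mol.has_coordinates, kekulized=mol.kekulized)
    for old in keep:
        src = mol.atom(old)
        out.add_atom(Atom(index=remap[old], element=src.element, x=src.x,
                          y=src.y, charge=src.charge, radical=src.radical,
                          implicit_h=src.implicit_h, h_fixed=src.h_fixed))
    for b in mol.bonds:
        if b.a in remap and b.b in remap:
            out.add_bond(Bond(a=remap[b.a], b=remap[b.b], order=b.order,
                              aromatic=b.aromatic, stereo=b.stereo))
    return out


def delete_hydrogens(mol: Molecule) -> Molecule:
    """Convert deletable explicit hydrogens to implicit ones.

    An explicit H is deleted when it has exactly one single bond to a non-H
    atom, carries no charge or radical, and its bond has no wedge/hash
    annotation — hydrogens carrying depiction information survive.  Each
    deletion increments the neighbor's implicit count; survivors are
    renumbered contiguously.
    """
    mol = mol.copy()
    doomed: set[int] = set()
    for a in mol.atoms:
        if a.element != "H" or a.charge or a.radical:
            continue
        nbrs = mol.neighbors(a.index)
        if len(nbrs) != 1:
            continue
        nidx, bond = nbrs[0]
        if bond.order != 1 or bond.stereo != STEREO_NONE:
            continue
        if mol.atom(nidx).element == "H":
            continue
        doomed.add(a.index)
        neighbor = mol.atom(nidx)
        neighbor.implicit_h += 1
    keep = [a.index for a in mol.atoms if a.index not in doomed]
    return _renumber(mol, keep)


def _h_positions(anchor: Atom, bond_angles: list[float], k: int) -> list[tuple[float, float]]:
    """Unit-distance positions for k new hydrogens in the largest angular gap
    (ties: the gap starting at the smaller angle); spread evenly inside it."""
    if not bond_angles:
        dirs = [360.0 * j / k for j in range(k)]
    else:
        angles = sorted(a % 360.0 for a in bond_angles)
        gaps = []
        for j, start in enumerate(angles):
            nxt = angles[(j + 1) % len(angles)]
            width = (nxt - start) % 360.0
            if len(angles) == 1:
                width = 360.0
            gaps.append((width, start))
        width, start = max(gaps, key=lambda g: (g[0], -g[1]))
        dirs = [start + width * (j + 1) / (k + 1) for j in range(k)]
    return [(anchor.x + math.cos(math.radians(d)),
             anchor.y + math.sin(math.radians(d))) for d in dirs]


def add_hydrogens(mol: Molecule) -> Molecule:
    """Materialize every implicit hydrogen as an explicit atom and bond.

    With coordinates present, new hydrogens are placed at unit distance in
    the largest angular gap between the anchor's existing bonds.
    """
    mol = mol.copy()
    for anchor_idx in [a.index for a in mol.atoms]:
        anchor = mol.atom(anchor_idx)
        k = anchor.implicit_h
        if k <= 0:
            continue
        if mol.has_coordinates:
            bond_angles = [
                math.degrees(math.atan2(mol.atom(n).y - anchor.y,
                                        mol.atom(n).x - anchor.x))
                for n, _ in mol.neighbors(anchor_idx)
            ]
            positions = _h_positions(anchor, bond_angles, k)
        else:
            positions = [(0.0, 0.0)] * k
        for x, y in positions:
            idx = len(mol.atoms) + 1
            mol.add_atom(Atom(index=idx, element="H", x=x, y=y))
            mol.add_bond(Bond(a=anchor_idx, b=idx, order=1))
        anchor.implicit_h = 0
    return mol


# -- kekulization ----------------------------------------------------------

def _needs_double(mol: Molecule, atom: Atom) -> bool:
    """Does this aromatic atom contribute one pi electron (so it must carry
    exactly one double bond in the kekulized form)?"""
    el = atom.element
    if el in ("O", "S", "Se"):
        return False
    if el == "B":
        return False  # empty p orbital
    if el in ("N", "P"):
        if atom.charge > 0:
            return True
        if atom.charge < 0:
            return False
        h = atom.implicit_h if atom.h_fixed else 0
        h += sum(1 for n, _ in mol.neighbors(atom.index)
                 if mol.atom(n).element == "H")
        return mol.degree(atom.index) + h < 3  # pyrrole-type N donates its pair
    return True


def kekulize(mol: Molecule) -> Molecule:
    """Assign concrete 1/2 orders to aromatic bonds via backtracking matching.

    Atoms needing a double bond must each be matched along exactly one
    aromatic bond; remaining aromatic bonds become single.  Aromatic flags
    are retained.  Raises :class:`KekulizationError` naming the unmatched
    ring atoms when no assignment exists.  Idempotent.
    """
    aromatic_bonds = [b for b in mol.bonds if b.aromatic]
    if not aromatic_bonds:
        mol.kekulized = True
        return mol
    mol = mol.copy()
    needy = sorted(a.index for a in mol.atoms if
                   any(b.aromatic for _, b in mol.neighbors(a.index)) and
                   _needs_double(mol, a))
    adj: dict[int, list[int]] = {i: [] for i in needy}
    needy_set = set(needy)
    for b in mol.bonds:
        if b.aromatic and b.a in needy_set and b.b in needy_set:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
    for v in adj.values():
        v.sort()

    match: dict[int, int] = {}

    def backtrack(pos: int) -> bool:
        while pos < len(needy) and needy[pos] in match:
            pos += 1
        if pos == len(needy):
            return True
        u = needy[pos]
        for v in adj[u]:
            if v not in match:
                match[u] = v
                match[v] = u
                if backtrack(pos + 1):
                    return True
                del match[u], match[v]
        return False

    if not backtrack(0):
        unmatched = [i for i in needy if i not in match]
        raise KekulizationError(
            f"no alternating bond assignment for aromatic atoms {unmatched}")

    for b in mol.bonds:
        if b.aromatic:
            b.order = 2 if match.get(b.a) == b.b else 1
    mol.kekulized = True
    return mol
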
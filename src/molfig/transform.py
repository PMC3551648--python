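"""Coordinate-space operations: bond angles, flips, rotation, bond scaling.

Angles follow the chemfig convention: degrees counterclockwise from east,
normalized to [0, 360), so ``:90`` points straight up.  Emitted angles are
rounded to one decimal; values within 0.05 of an integer are printed as
integers.
"""

from __future__ import annotations

import math
import statistics

from .molecule import Molecule, STEREO_HASH_DOWN, STEREO_WEDGE_UP

__all__ = [
    "bond_angle",
    "round_angle",
    "format_angle",
    "apply_transforms",
    "normalize_lengths",
]

Point = tuple[float, float]


def bond_angle(frm: Point, to: Point) -> float:
    """Direction of the bond frm→to in degrees, normalized to [0, 360)."""
    deg = math.degrees(math.atan2(to[1] - frm[1], to[0] - frm[0]))
    return deg % 360.0


def round_angle(deg: float) -> float:
    """Apply the emission rounding rule (one decimal; near-integers snap).

    Angles are pre-quantized to 1e-6 degrees so that sub-microdegree
    floating noise (e.g. from a rotation and its inverse) cannot flip the
    emitted string across a rounding boundary.
    """
    deg = round(deg % 360.0, 6) % 360.0
    nearest = round(deg)
    if abs(deg - nearest) <= 0.05:
        return float(nearest % 360)
    return round(deg, 1) % 360.0


def format_angle(deg: float) -> str:
    r = round_angle(deg)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


def apply_transforms(mol: Molecule, flip: bool = False, flop: bool = False,
                     rotate: float = 0.0) -> Molecule:
    """Horizontal flip (x → −x), vertical flop (y → −y), then rotation about
    the centroid.  After an odd number of reflections the wedge/hash stereo
    annotations are swapped, preserving the implied chirality.
    """
    mol = mol.copy()
    if not mol.atoms:
        return mol
    for a in mol.atoms:
        if flip:
            a.x = -a.x
        if flop:
            a.y = -a.y
    if rotate % 360.0:
        cx = sum(a.x for a in mol.atoms) / len(mol.atoms)
        cy = sum(a.y for a in mol.atoms) / len(mol.atoms)
        t = math.radians(rotate)
        cos_t, sin_t = math.cos(t), math.sin(t)
        for a in mol.atoms:
            dx, dy = a.x - cx, a.y - cy
            a.x = cx + dx * cos_t - dy * sin_t
            a.y = cy + dx * sin_t + dy * cos_t
    if flip != flop:  # odd number of reflections
        swap = {STEREO_WEDGE_UP: STEREO_HASH_DOWN,
                STEREO_HASH_DOWN: STEREO_WEDGE_UP}
        for b in mol.bonds:
            b.stereo = swap.get(b.stereo, b.stereo)
    return mol


def normalize_lengths(mol: Molecule) -> tuple[Molecule, dict[tuple[int, int], float]]:
    """Scale coordinates so the median bond length is 1.0.

    Returns the scaled molecule and a map from bond endpoint pair (sorted)
    to its length factor, containing only factors that differ from 1 by more
    than 0.02 — bonds close to the median are drawn at default length.
    """
    mol = mol.copy()
    if not mol.bonds or not mol.has_coordinates:
        return mol, {}
    lengths = [math.dist(mol.atom(b.a).position(), mol.atom(b.b).position())
               for b in mol.bonds]
    median = statistics.median(lengths)
    if median <= 0:
        return mol, {}
    for a in mol.atoms:
        a.x /= median
        a.y /= median
    factors: dict[tuple[int, int], float] = {}
    for b, length in zip(mol.bonds, lengths):
        f = round(length / median, 6)  # quantized against rounding jitter
        if abs(f - 1.0) > 0.02:
            factors[b.key()] = f
    return mol, factors
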
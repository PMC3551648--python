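r"""Render a molecule tree to chemfig code.

Verbose output uses one line per bond, indented two spaces per branch depth,
with a line-end comment naming the atom the bond reaches (``% 7``) or, for
ring closures, the earlier atom the bond points back to (``% ->2``).  Terse
output is the verbose text with comments and all whitespace removed —
whitespace is insignificant to chemfig, so both compile identically.

Skeletal conventions: plain carbons are unlabeled vertices; heteroatoms show
their implicit hydrogens on the side facing away from their bonds; charges
are appended as superscripts; radicals use the shipped ``\mcfdot`` macro and
atom numbers ``\mcfatomno``.  Aromatic rings selected for circle rendering
get their double bonds demoted to plain lines plus an invisible positioning
bond carrying ``\mcfcringle`` at the ring centroid.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .layout2d import Ring, perceive_rings
from .molecule import (
    Atom,
    Bond,
    Molecule,
    STEREO_HASH_DOWN,
    STEREO_WEDGE_UP,
)
from .options import RenderOptions
from .transform import bond_angle, format_angle, round_angle
from .tree_builder import MoleculeTree

__all__ = [
    "ChemfigCode",
    "atom_code",
    "bond_code",
    "double_bond_side",
    "render",
    "strip_terse",
    "closure_label_name",
]

CIRCLE_SHRINK = 0.55  # circle radius as a fraction of the ring circumradius


@dataclass
class ChemfigCode:
    verbose: str
    terse: str
    wrapper: str  # "bare" | "chemfig" | "submol:<name>"

    def output(self, terse: bool = False) -> str:
        return self.terse if terse else self.verbose


def strip_terse(code: str) -> str:
    """Remove ``%`` comments (to end of line) and then all whitespace."""
    no_comments = re.sub(r"%[^\n]*", "", code)
    return re.sub(r"\s+", "", no_comments)


def closure_label_name(label: int) -> str:
    """Ring-closure hook name: 1→a, 2→b, …, 27→aa (chemfig-safe letters)."""
    name = ""
    n = label
    while n > 0:
        n, rem = divmod(n - 1, 26)
        name = chr(ord("a") + rem) + name
    return name


def _charge_code(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return f"^{{{sign}}}" if mag == 1 else f"^{{{mag}{sign}}}"


def _h_code(n: int) -> str:
    if n <= 0:
        return ""
    return "H" if n == 1 else f"H_{n}"


def atom_code(atom: Atom, incident_angles: list[float],
              options: RenderOptions) -> str:
    """Label text for one atom; empty string for a skeletal carbon vertex.

    ``incident_angles`` are the directions (degrees) of all bonds leaving
    the atom; they decide which side the hydrogens go on: bonds mostly to
    the right put hydrogens on the left (``HO``), otherwise on the right
    (``OH``); purely vertical bonds default to the right.
    """
    lone = not incident_angles
    show = (atom.element != "C" or options.show_carbons or lone
            or atom.charge != 0 or atom.radical != 0)
    if not show and options.show_methyls and atom.element == "C" \
            and len(incident_angles) == 1 and atom.implicit_h == 3:
        show = True
    parts: list[str] = []
    if show:
        h = _h_code(atom.implicit_h)
        mx = sum(math.cos(math.radians(a)) for a in incident_angles)
        h_left = bool(incident_angles) and mx > 1e-9
        if h and h_left:
            parts.append(h + atom.element)
        else:
            parts.append(atom.element + h)
        parts.append(_charge_code(atom.charge))
        if atom.radical:
            parts.append(r"\mcfdot")
    if options.atom_numbers:
        parts.append(rf"\mcfatomno{{{atom.index}}}")
    return "".join(parts)


def bond_token(bond: Bond, parent: int, side: str = "",
               demoted: bool = False) -> str:
    """Bare bond symbol for the bond as drawn from ``parent`` toward the
    other endpoint.  ``side`` is the ring double-bond modifier; ``demoted``
    marks aromatic-circle bonds drawn as plain single lines."""
    if demoted:
        return "-"
    if bond.stereo == STEREO_WEDGE_UP:
        return "<" if bond.a == parent else ">"
    if bond.stereo == STEREO_HASH_DOWN:
        return "<:" if bond.a == parent else ">:"
    if bond.order == 2:
        return "=" + side
    if bond.order == 3:
        return "~"
    return "-"


def _format_factor(f: float) -> str:
    s = f"{f:.2f}".rstrip("0").rstrip(".")
    return s or "1"


def _format_relative(deg: float) -> str:
    r = round_angle(deg)
    r = ((r + 180.0) % 360.0) - 180.0  # keep relative angles small
    if r == int(r):
        return str(int(r))
    return f"{r:.1f}"


def bond_code(bond: Bond, parent: int, angle: float, *,
              relative: bool = False, factor: float | None = None,
              side: str = "", demoted: bool = False) -> str:
    """Full bond token with its ``[:angle]`` / ``[::angle]`` specification
    and optional length factor."""
    token = bond_token(bond, parent, side=side, demoted=demoted)
    spec = f"::{_format_relative(angle)}" if relative else f":{format_angle(angle)}"
    if factor is not None:
        spec += f",{_format_factor(factor)}"
    return f"{token}[{spec}]"


def double_bond_side(bond: Bond, parent: int, mol: Molecule,
                     ring_centroid: tuple[float, float] | None) -> str:
    """Which side of a ring double bond gets the second line.

    With the ring centroid to the left of the parent→child direction of
    travel the inner line goes up (``^``), otherwise down (``_``); double
    bonds outside rings stay centered.
    """
    if ring_centroid is None or bond.order != 2:
        return ""
    child = bond.other(parent)
    p, c = mol.atom(parent), mol.atom(child)
    dx, dy = c.x - p.x, c.y - p.y
    mx, my = (p.x + c.x) / 2.0, (p.y + c.y) / 2.0
    cx, cy = ring_centroid[0] - mx, ring_centroid[1] - my
    # quantized so that floating noise on a (degenerate) collinear centroid
    # cannot flip the side between otherwise identical renderings
    cross = round(dx * cy - dy * cx, 6)
    return "^" if cross > 0 else "_"


def _incident_angle_map(mol: Molecule) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        pa, pb = mol.atom(b.a).position(), mol.atom(b.b).position()
        out[b.a].append(bond_angle(pa, pb))
        out[b.b].append(bond_angle(pb, pa))
    return out


def render(tree: MoleculeTree, mol: Molecule, options: RenderOptions,
           rings: list[Ring] | None = None,
           circled: list[Ring] | None = None,
           factors: dict[tuple[int, int], float] | None = None) -> ChemfigCode:
    """Render the spanning tree to chemfig code.

    ``rings`` feed the ring double-bond side rule, ``circled`` the aromatic
    circle decoration, ``factors`` the per-bond length factors from
    :func:`molfig.transform.normalize_lengths`.
    """
    if rings is None:
        rings = perceive_rings(mol)
    circled = circled or []
    factors = factors or {}

    # smallest ring containing each bond, for the double-bond side rule
    ring_of_bond: dict[tuple[int, int], Ring] = {}
    for r in sorted(rings, key=len, reverse=True):
        for e in r.edges():
            ring_of_bond[e] = r
    demoted_edges = {e for r in circled for e in r.edges()}

    visit_pos = {a: i for i, a in enumerate(tree.visit_order)}
    circle_anchor: dict[int, list[Ring]] = {}
    for r in circled:
        first = min(r.atoms, key=lambda a: visit_pos[a])
        circle_anchor.setdefault(first, []).append(r)

    openers: dict[int, list] = {}
    closers: dict[int, list] = {}
    for c in tree.closures:
        openers.setdefault(c.opener, []).append(c)
        closers.setdefault(c.closer, []).append(c)
    for lst in openers.values():
        lst.sort(key=lambda c: c.label)
    for lst in closers.values():
        lst.sort(key=lambda c: c.label)

    angles = _incident_angle_map(mol)
    lines: list[tuple[int, str, str]] = []  # (depth, code, comment)

    def hook_tokens(u: int) -> str:
        return "".join(f"?[{closure_label_name(c.label)}]"
                       for c in openers.get(u, []))

    def closer_lines(u: int, depth: int) -> None:
        for c in closers.get(u, []):
            tok = bond_token(c.bond, c.opener,
                             demoted=c.bond.key() in demoted_edges)
            lines.append((depth,
                          f"?[{closure_label_name(c.label)},{{{tok}}}]",
                          f"% ->{c.opener}"))

    def circle_lines(u: int, depth: int) -> None:
        for r in circle_anchor.get(u, []):
            cx, cy = r.centroid(mol)
            a = mol.atom(u)
            ang = format_angle(bond_angle((a.x, a.y), (cx, cy)))
            dist = math.hypot(cx - a.x, cy - a.y)
            radius = CIRCLE_SHRINK * r.circumradius(mol)
            lines.append((depth, "(", ""))
            lines.append((depth + 1,
                          rf"-[:{ang},{_format_factor(dist)},,,draw=none]"
                          rf"\mcfcringle{{{radius:.2f}}}",
                          ""))
            lines.append((depth, ")", ""))

    def emit_atom_line(u: int, depth: int, bond_part: str) -> None:
        code = bond_part + atom_code(mol.atom(u), angles[u], options) \
            + hook_tokens(u)
        lines.append((depth, code, f"% {u}"))
        closer_lines(u, depth)
        circle_lines(u, depth)

    def bond_part_for(u: int, bond: Bond, v: int) -> str:
        key = bond.key()
        demoted = key in demoted_edges
        ring = ring_of_bond.get(key)
        side = "" if demoted else double_bond_side(
            bond, u, mol, ring.centroid(mol) if ring else None)
        abs_angle = bond_angle(mol.atom(u).position(), mol.atom(v).position())
        if options.relative_angles and tree.parent.get(u) is not None:
            p, _ = tree.parent[u]
            incoming = bond_angle(mol.atom(p).position(),
                                  mol.atom(u).position())
            return bond_code(bond, u, abs_angle - incoming, relative=True,
                             factor=factors.get(key), side=side,
                             demoted=demoted)
        return bond_code(bond, u, abs_angle, factor=factors.get(key),
                         side=side, demoted=demoted)

    def walk(u: int, depth: int) -> None:
        kids = tree.children[u]
        cont = tree.cont_next.get(u)
        branches = [(b, v) for b, v in kids if v != cont]
        for bond, v in branches:
            lines.append((depth, "(", ""))
            emit_atom_line(v, depth + 1, bond_part_for(u, bond, v))
            walk(v, depth + 1)
            lines.append((depth, ")", ""))
        if cont is not None:
            bond = next(b for b, v in kids if v == cont)
            emit_atom_line(cont, depth, bond_part_for(u, bond, cont))
            walk(cont, depth)

    emit_atom_line(tree.root, 0, "")
    walk(tree.root, 0)

    body = _format_lines(lines)
    if options.submol_name:
        wrapper = f"submol:{options.submol_name}"
        verbose = f"\\definesubmol{{{options.submol_name}}}{{\n{body}\n}}"
    elif options.wrap:
        wrapper = "chemfig"
        verbose = f"\\chemfig{{\n{body}\n}}"
    else:
        wrapper = "bare"
        verbose = body
    return ChemfigCode(verbose=verbose, terse=strip_terse(verbose),
                       wrapper=wrapper)


def _format_lines(lines: list[tuple[int, str, str]]) -> str:
    rendered = []
    width = max((2 * d + len(c) for d, c, comment in lines if comment),
                default=0)
    for depth, code, comment in lines:
        text = "  " * depth + code
        if comment:
            text = text.ljust(width + 2) + comment
        rendered.append(text.rstrip() if not comment else text)
    return "\n".join(rendered)
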
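r"""Synthetic molecules, molfile writing, named references, and the
chemfig-subset oracle parser that closes the test loop.

``random_molecule`` grows a connected, valence-valid molecule atom by atom
from a seeded RNG (identical spec → identical molecule), optionally starting
from an aromatic six-ring, adding ring closures between nearby atoms, and
finishing with the deterministic 2D layout.  ``parse_chemfig_subset`` reads
back exactly the dialect :mod:`molfig.chemfig_writer` emits, reconstructing
the molecular multigraph so tests can assert graph isomorphism between input
and rendered output without a TeX engine.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

from .hydrogen_model import (
    compute_implicit_hydrogens,
    effective_valence,
)
from .layout2d import generate_coordinates
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

__all__ = [
    "FixtureSpec",
    "random_molecule",
    "write_molfile",
    "parse_chemfig_subset",
    "load_fixture",
    "fixture_path",
    "NAMED_FIXTURES",
    "molecules_equal",
    "isomorphic",
]

NAMED_FIXTURES = (
    "benzene",
    "cyclohexane",
    "naphthalene",
    "norepinephrine",
    "radical_toy",
    "residue",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic-molecule generator."""

    seed: int
    n_heavy_atoms: int = 9
    ring_probability: float = 0.3
    elements: tuple[str, ...] = ("C", "C", "C", "C", "C", "N", "O", "O",
                                 "S", "F", "Cl")
    charge_rate: float = 0.06
    radical_rate: float = 0.03
    aromatic_ring_rate: float = 0.25
    double_bond_rate: float = 0.15
    triple_bond_rate: float = 0.03


def _capacity(mol: Molecule, idx: int) -> int:
    a = mol.atom(idx)
    bos = sum(b.order for _, b in mol.neighbors(idx))
    return effective_valence(a.element, a.charge, bos) - bos


def random_molecule(spec: FixtureSpec) -> Molecule:
    """Grow a connected, valence-valid molecule with 2D coordinates.

    May stop short of ``n_heavy_atoms`` if every atom's valence fills up.
    """
    rng = random.Random(spec.seed)
    mol = Molecule()
    n = max(1, min(spec.n_heavy_atoms, 25))

    if n >= 6 and rng.random() < spec.aromatic_ring_rate:
        for i in range(1, 7):
            mol.add_atom(Atom(index=i, element="C"))
        for i in range(6):
            a, b = i + 1, (i + 1) % 6 + 1
            mol.add_bond(Bond(a=a, b=b, order=2 if i % 2 == 0 else 1,
                              aromatic=True))
        mol.kekulized = True
    else:
        mol.add_atom(Atom(index=1, element="C"))
        mol.kekulized = True

    while len(mol.atoms) < n:
        anchors = [a.index for a in mol.atoms if _capacity(mol, a.index) >= 1]
        if not anchors:
            break
        u = rng.choice(anchors)
        element = rng.choice(spec.elements)
        v = len(mol.atoms) + 1
        mol.add_atom(Atom(index=v, element=element))
        order = 1
        cap_u, cap_v = _capacity(mol, u), _capacity(mol, v)
        r = rng.random()
        if r < spec.triple_bond_rate and cap_u >= 3 and cap_v >= 3:
            order = 3
        elif r < spec.triple_bond_rate + spec.double_bond_rate \
                and cap_u >= 2 and cap_v >= 2:
            order = 2
        mol.add_bond(Bond(a=u, b=v, order=order))

    g = mol.graph()
    for _ in range(max(1, len(mol.atoms) // 4)):
        if rng.random() >= spec.ring_probability:
            continue
        donors = [a.index for a in mol.atoms if _capacity(mol, a.index) >= 1]
        if not donors:
            break
        a = rng.choice(donors)
        dists = nx.single_source_shortest_path_length(g, a, cutoff=6)
        cands = sorted(b for b, d in dists.items()
                       if 2 <= d <= 6 and _capacity(mol, b) >= 1
                       and mol.bond_between(a, b) is None)
        if not cands:
            continue
        b = rng.choice(cands)
        mol.add_bond(Bond(a=min(a, b), b=max(a, b), order=1))
        g.add_edge(a, b)

    for a in mol.atoms:
        bos = sum(bd.order for _, bd in mol.neighbors(a.index))
        if rng.random() < spec.charge_rate:
            want = 1 if a.element == "N" else -1 if a.element in ("O", "S") else 0
            if want and effective_valence(a.element, want, bos) >= bos:
                a.charge = want
        if rng.random() < spec.radical_rate and a.element == "C":
            a.radical = 2

    compute_implicit_hydrogens(mol)
    mol = generate_coordinates(mol)
    mol.validate()
    return mol


# -- molfile writing -------------------------------------------------------

_STEREO_OUT = {STEREO_NONE: 0, STEREO_WEDGE_UP: 1, STEREO_HASH_DOWN: 6}


def write_molfile(mol: Molecule, name: str = "molfig") -> str:
    """Serialize to molfile V2000 text; aromatic bonds use order code 4,
    charges and radicals go into ``M  CHG`` / ``M  RAD`` property lines."""
    out = [name, "  molfig", ""]
    out.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}"
               "  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        out.append(f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.element:<3}"
                   "0  0  0  0  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        order = 4 if b.aromatic else b.order
        out.append(f"{b.a:3d}{b.b:3d}{order:3d}{_STEREO_OUT[b.stereo]:3d}"
                   "  0  0  0")
    charged = [(a.index, a.charge) for a in mol.atoms if a.charge]
    radicals = [(a.index, a.radical) for a in mol.atoms if a.radical]
    for tag, pairs in (("CHG", charged), ("RAD", radicals)):
        for i in range(0, len(pairs), 8):
            chunk = pairs[i:i + 8]
            line = f"M  {tag}{len(chunk):3d}"
            for idx, val in chunk:
                line += f"{idx:4d}{val:4d}"
            out.append(line)
    out.append("M  END")
    return "\n".join(out) + "\n"


# -- named fixtures --------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path of a shipped named fixture molfile."""
    if name not in NAMED_FIXTURES:
        raise MolfigError(f"unknown fixture {name!r}; "
                          f"choose from {', '.join(NAMED_FIXTURES)}")
    return Path(str(resources.files("molfig") / "data" / "fixtures"
                    / f"{name}.mol"))


def load_fixture(name: str) -> Molecule:
    from .molfile_io import parse_molfile
    mol = parse_molfile(fixture_path(name).read_text())
    return compute_implicit_hydrogens(mol)


# -- comparison helpers ----------------------------------------------------

def molecules_equal(m1: Molecule, m2: Molecule) -> bool:
    """Exact equality under the identity atom mapping: same elements,
    charges, radicals, coordinates-agnostic bond sets with matching order
    (aromatic flag for aromatic bonds) and stereo."""
    if len(m1.atoms) != len(m2.atoms) or len(m1.bonds) != len(m2.bonds):
        return False
    for a, b in zip(m1.atoms, m2.atoms):
        if (a.element, a.charge, a.radical) != (b.element, b.charge, b.radical):
            return False

    def bond_sig(m: Molecule) -> set[tuple]:
        sigs = set()
        for b in m.bonds:
            narrow = b.a if b.stereo != STEREO_NONE else 0
            order = ("ar",) if b.aromatic else (b.order,)
            sigs.add((b.key(), order, b.stereo, narrow))
        return sigs

    return bond_sig(m1) == bond_sig(m2)


def isomorphic(m1: Molecule, m2: Molecule, *,
               compare_h: bool = False,
               radical_exact: bool = True,
               demoted: frozenset | set = frozenset()) -> bool:
    """Graph isomorphism on element/charge/radical labels and bond orders.

    ``compare_h`` also matches hydrogen counts where both sides know them
    (the oracle cannot know the implicit count of a bare carbon vertex).
    ``demoted`` holds bond endpoint pairs of ``m1`` drawn as plain single
    lines (aromatic-circle rings), compared with order 1.
    """

    def node_attrs(m: Molecule, demote: bool):
        g = nx.Graph()
        for a in m.atoms:
            g.add_node(a.index, element=a.element, charge=a.charge,
                       radical=a.radical if radical_exact else bool(a.radical),
                       h=a.implicit_h, h_known=a.h_fixed or not compare_h)
        for b in m.bonds:
            order = b.order
            if demote and b.key() in demoted:
                order = 1
            g.add_edge(b.a, b.b, order=order)
        return g

    g1 = node_attrs(m1, demote=True)
    g2 = node_attrs(m2, demote=False)

    def nm(n1, n2):
        if (n1["element"], n1["charge"], n1["radical"]) != \
                (n2["element"], n2["charge"], n2["radical"]):
            return False
        if compare_h and n1["h_known"] and n2["h_known"]:
            return n1["h"] == n2["h"]
        return True

    def em(e1, e2):
        return e1["order"] == e2["order"]

    return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


# -- chemfig-subset oracle parser ------------------------------------------

_BOND_TOKENS = [
    ("<:", 1, STEREO_HASH_DOWN, True),
    (">:", 1, STEREO_HASH_DOWN, False),
    ("<", 1, STEREO_WEDGE_UP, True),
    (">", 1, STEREO_WEDGE_UP, False),
    ("=^", 2, STEREO_NONE, True),
    ("=_", 2, STEREO_NONE, True),
    ("=", 2, STEREO_NONE, True),
    ("~", 3, STEREO_NONE, True),
    ("-", 1, STEREO_NONE, True),
]

_ATOM_CHARS = set("abcdefghijklmnopqrstuvwxyz"
                  "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")


import re as _re

_ATOM_RE = _re.compile(
    r"^(?:H(?:_(?P<hl>\d+))?)?(?P<el>[A-Z][a-z]?)?(?:H(?:_(?P<hr>\d+))?)?$")
_CHARGE_RE = _re.compile(r"\^\{(\d*)([+-])\}")


def _interpret_atom_chunk(chunk: str):
    """Split an emitted atom label into (element, h_count|None, charge,
    radical).  Empty chunk → skeletal carbon with unknown hydrogen count."""
    charge = 0
    radical = 0
    m = _CHARGE_RE.search(chunk)
    if m:
        mag = int(m.group(1)) if m.group(1) else 1
        charge = mag if m.group(2) == "+" else -mag
        chunk = chunk[:m.start()] + chunk[m.end():]
    if r"\mcfdot" in chunk:
        radical = 2
        chunk = chunk.replace(r"\mcfdot", "")
    chunk = _re.sub(r"\\mcfatomno\{\d+\}", "", chunk)
    if not chunk:
        return ("C", None, charge, radical)
    if chunk == "H" and charge == 0 and radical == 0:
        return ("H", 0, 0, 0)
    if chunk == "H":
        return ("H", 0, charge, radical)
    m = _ATOM_RE.match(chunk)
    if not m or not m.group("el"):
        raise ParseError(f"unparseable atom label {chunk!r}")
    h = 0
    saw_h = False
    head = chunk[:m.start("el")] if m.group("el") else ""
    if head:
        saw_h = True
        h += int(m.group("hl")) if m.group("hl") else 1
    tail = chunk[m.end("el"):]
    if tail:
        saw_h = True
        h += int(m.group("hr")) if m.group("hr") else 1
    element = m.group("el")
    # heteroatoms always print their hydrogens, so "none printed" means zero
    return (element, h if saw_h or element != "C" else None, charge, radical)


def parse_chemfig_subset(code: str) -> Molecule:
    r"""Parse emitted chemfig code back into a coordinate-free molecule.

    Handles exactly the emitted dialect: atom labels, the bond tokens with
    ``[:a]`` / ``[::a]`` specs and length factors, parenthesized branches,
    ``?`` ring-closure hooks, invisible circle-positioning bonds, and the
    ``\chemfig`` / ``\definesubmol`` wrappers.  Unknown-H carbons get
    ``h_fixed=False`` so comparisons can skip their hydrogen counts.
    """
    from .chemfig_writer import strip_terse

    s = strip_terse(code)
    m = _re.match(r"\\chemfig\{(.*)\}$", s, _re.DOTALL)
    if m:
        s = m.group(1)
    else:
        m = _re.match(r"\\definesubmol\{[^{}]*\}\{(.*)\}$", s, _re.DOTALL)
        if m:
            s = m.group(1)

    mol = Molecule(has_coordinates=False)
    hooks: dict[str, int] = {}
    stack: list[int | None] = []
    current: int | None = None
    pending: tuple[int, str, bool] | None = None  # (order, stereo, narrow_at_parent)
    pending_invisible = False

    def add_atom(element: str, h, charge: int, radical: int) -> None:
        nonlocal current, pending, pending_invisible
        if pending_invisible:
            pending, pending_invisible = None, False
            return  # circle macro anchor, not a real atom
        idx = len(mol.atoms) + 1
        mol.add_atom(Atom(index=idx, element=element, charge=charge,
                          radical=radical, implicit_h=h or 0,
                          h_fixed=h is not None))
        if current is not None:
            if pending is None:
                raise ParseError("two atoms without a bond between them")
            order, stereo, narrow_at_parent = pending
            a, b = (current, idx) if narrow_at_parent else (idx, current)
            mol.add_bond(Bond(a=a, b=b, order=order, stereo=stereo))
        elif pending is not None:
            raise ParseError("bond with no preceding atom")
        current = idx
        pending = None

    def flush_pending() -> None:
        # a bond followed by another structural token reaches an unlabeled
        # (skeletal carbon) atom; materialize it
        if pending is not None:
            add_atom("C", None, 0, 0)

    i, n = 0, len(s)
    if n and s[0] in "(-=~<>?":
        add_atom("C", None, 0, 0)  # unlabeled root carbon
    while i < n:
        c = s[i]
        if c == "(":
            flush_pending()
            stack.append(current)
            i += 1
        elif c == ")":
            if not stack:
                raise ParseError("unmatched ')' in chemfig code", offset=i)
            flush_pending()
            current = stack.pop()
            i += 1
        elif c == "?":
            flush_pending()
            m = _re.match(r"\?\[([a-z]+)(?:,\{([^{}]*)\})?\]", s[i:])
            if not m:
                raise ParseError("malformed ring-closure hook", offset=i)
            label, tok = m.group(1), m.group(2)
            if current is None:
                raise ParseError("hook before any atom", offset=i)
            if tok is None:
                if label in hooks:
                    raise ParseError(f"duplicate hook label {label!r}", offset=i)
                hooks[label] = current
            else:
                if label not in hooks:
                    raise ParseError(f"hook {label!r} closed before opening",
                                     offset=i)
                order = {t: o for t, o, _, _ in _BOND_TOKENS}.get(tok)
                if order is None:
                    raise ParseError(f"unknown closure bond token {tok!r}",
                                     offset=i)
                opener = hooks.pop(label)
                mol.add_bond(Bond(a=opener, b=current, order=order))
            i += m.end()
        else:
            matched_bond = None
            for tok, order, stereo, narrow_at_parent in _BOND_TOKENS:
                if s.startswith(tok, i):
                    matched_bond = (tok, order, stereo, narrow_at_parent)
                    break
            if matched_bond:
                tok, order, stereo, narrow_at_parent = matched_bond
                flush_pending()
                pending = (order, stereo, narrow_at_parent)
                i += len(tok)
                m = _re.match(r"\[([^\[\]]*)\]", s[i:])
                if m:
                    if "draw=none" in m.group(1):
                        pending_invisible = True
                    i += m.end()
            else:
                # atom chunk: letters/digits/underscore plus ^{...} and \cmd{...}
                j = i
                chunk = ""
                while j < n:
                    cj = s[j]
                    if cj in _ATOM_CHARS:
                        chunk += cj
                        j += 1
                    elif cj == "^" and j + 1 < n and s[j + 1] == "{":
                        k = s.index("}", j)
                        chunk += s[j:k + 1]
                        j = k + 1
                    elif cj == "\\":
                        m = _re.match(r"\\[A-Za-z]+(\{[^{}]*\})?", s[j:])
                        if not m:
                            raise ParseError(f"bad escape at {s[j:j+10]!r}",
                                             offset=j)
                        chunk += m.group(0)
                        j += m.end()
                    else:
                        break
                if j == i:
                    raise ParseError(f"unexpected character {c!r}", offset=i)
                if pending_invisible:
                    add_atom("C", None, 0, 0)  # consumed and discarded
                else:
                    add_atom(*_interpret_atom_chunk(chunk))
                i = j
    flush_pending()
    if stack:
        raise ParseError("unmatched '(' in chemfig code")
    if hooks:
        raise ParseError(f"unclosed ring-closure hooks {sorted(hooks)}")
    if not mol.atoms:
        raise ParseError("no atoms found in chemfig code")
    return mol


# -- make-fixtures entry point ---------------------------------------------

def main(argv: list[str] | None = None) -> int:
    """Write a batch of generated fixture molfiles to a directory."""
    import argparse

    ap = argparse.ArgumentParser(
        prog="molfig-make-fixtures",
        description="generate seeded synthetic-molecule molfiles")
    ap.add_argument("outdir", type=Path)
    ap.add_argument("--count", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--atoms", type=int, default=9)
    args = ap.parse_args(argv)
    args.outdir.mkdir(parents=True, exist_ok=True)
    for k in range(args.count):
        spec = FixtureSpec(seed=args.seed + k, n_heavy_atoms=args.atoms)
        mol = random_molecule(spec)
        text = write_molfile(mol, name=f"molfig seed {spec.seed}")
        (args.outdir / f"fixture_{spec.seed}.mol").write_text(text)
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
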
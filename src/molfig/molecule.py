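"""Core molecular-graph types.

A :class:`Molecule` is an undirected labeled graph: an ordered list of
:class:`Atom` nodes (1-based indices, preserved from the input file) plus a
list of :class:`Bond` edges.  All pipeline stages operate on copies of this
structure; nothing here knows about chemfig.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import networkx as nx

# bond stereo annotations; the narrow end of a wedge sits at endpoint ``a``
STEREO_NONE = "none"
STEREO_WEDGE_UP = "wedge_up"
STEREO_HASH_DOWN = "hash_down"


class MolfigError(Exception):
    """Base class for all molfig errors."""


class ParseError(MolfigError):
    """Malformed molfile or SMILES input.

    Carries a 1-based line number (molfile) or 0-based character offset
    (SMILES) when known.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 offset: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        elif offset is not None:
            message = f"offset {offset}: {message}"
        super().__init__(message)
        self.line = line
        self.offset = offset


class KekulizationError(MolfigError):
    """No alternating single/double assignment exists for an aromatic system."""


class LayoutError(MolfigError):
    """Coordinate generation cannot proceed (e.g. disconnected input)."""


class InputError(MolfigError):
    """Problem acquiring input (missing file, failed fetch, bad options)."""


@dataclass
class Atom:
    index: int              # 1-based, molfile/token order
    element: str
    x: float = 0.0
    y: float = 0.0
    charge: int = 0
    radical: int = 0        # 0 none, 1 singlet, 2 doublet
    implicit_h: int = 0
    h_fixed: bool = False   # bracket-atom H count: bypass valence model

    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Bond:
    a: int
    b: int
    order: int = 1          # 1/2/3
    aromatic: bool = False
    stereo: str = STEREO_NONE

    def key(self) -> tuple[int, int]:
        """Unordered endpoint pair, canonically sorted."""
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)

    def other(self, idx: int) -> int:
        if idx == self.a:
            return self.b
        if idx == self.b:
            return self.a
        raise ValueError(f"atom {idx} not an endpoint of bond {self.a}-{self.b}")


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    has_coordinates: bool = False
    kekulized: bool = False   # aromatic bond orders are concrete 1/2

    # -- construction ------------------------------------------------------

    def add_atom(self, atom: Atom) -> Atom:
        self.atoms.append(atom)
        return atom

    def add_bond(self, bond: Bond) -> Bond:
        if bond.a == bond.b:
            raise MolfigError(f"self-bond on atom {bond.a}")
        n = len(self.atoms)
        if not (1 <= bond.a <= n and 1 <= bond.b <= n):
            raise MolfigError(f"bond {bond.a}-{bond.b} references nonexistent atom")
        if any(e.key() == bond.key() for e in self.bonds):
            raise MolfigError(f"duplicate bond between atoms {bond.a} and {bond.b}")
        self.bonds.append(bond)
        return bond

    # -- queries -----------------------------------------------------------

    def atom(self, idx: int) -> Atom:
        a = self.atoms[idx - 1]
        assert a.index == idx, "atom list out of sync with indices"
        return a

    def neighbors(self, idx: int) -> list[tuple[int, Bond]]:
        """(neighbor index, bond) pairs, ascending by neighbor index."""
        out = [(b.other(idx), b) for b in self.bonds if idx in (b.a, b.b)]
        out.sort(key=lambda t: t[0])
        return out

    def degree(self, idx: int) -> int:
        return sum(1 for b in self.bonds if idx in (b.a, b.b))

    def bond_between(self, i: int, j: int) -> Bond | None:
        want = (i, j) if i < j else (j, i)
        for b in self.bonds:
            if b.key() == want:
                return b
        return None

    def graph(self) -> nx.Graph:
        """NetworkX view: nodes carry the Atom, edges carry the Bond."""
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, atom=a)
        for b in self.bonds:
            g.add_edge(b.a, b.b, bond=b)
        return g

    def is_connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        return nx.is_connected(self.graph())

    def copy(self) -> "Molecule":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check structural invariants; raise MolfigError on violation."""
        seen: set[int] = set()
        for pos, a in enumerate(self.atoms, start=1):
            if a.index != pos:
                raise MolfigError(f"atom at position {pos} has index {a.index}")
            if not a.element:
                raise MolfigError(f"atom {pos} has empty element symbol")
            seen.add(a.index)
        keys = set()
        for b in self.bonds:
            if b.a not in seen or b.b not in seen:
                raise MolfigError(f"bond {b.a}-{b.b} references nonexistent atom")
            if b.key() in keys:
                raise MolfigError(f"duplicate bond {b.a}-{b.b}")
            keys.add(b.key())
        if self.has_coordinates:
            import math
            for a in self.atoms:
                if not (math.isfinite(a.x) and math.isfinite(a.y)):
                    raise MolfigError(f"atom {a.index} has non-finite coordinates")
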
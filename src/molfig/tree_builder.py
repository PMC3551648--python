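"""Rooted spanning tree over the molecular graph — the skeleton of the
emitted chemfig code.

A depth-first spanning tree is rooted at the entry atom (default: the
lowest-index terminal atom, else the lowest index).  Bonds left out of the
tree become labeled ring closures whose opener is the earlier-visited
endpoint.  At each node one child continues the unparenthesized "main
chain": by default the deepest subtree (ties to the lower atom index), or —
when an exit atom is requested — the tree path from the root to that atom,
which then ends the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .molecule import Bond, Molecule, MolfigError

__all__ = ["Closure", "MoleculeTree", "build_tree", "assign_closures"]


@dataclass
class Closure:
    opener: int
    closer: int
    bond: Bond
    label: int = 0


@dataclass
class MoleculeTree:
    root: int
    children: dict[int, list[tuple[Bond, int]]]      # per-node, ascending child
    parent: dict[int, tuple[int, Bond] | None]
    visit_order: list[int]                           # pre-order
    cont_next: dict[int, int | None]                 # unparenthesized child
    main_chain: list[int]                            # root → exit/deepest path
    closures: list[Closure] = field(default_factory=list)

    def tree_bonds(self) -> list[Bond]:
        return [b for kids in self.children.values() for b, _ in kids]


def build_tree(mol: Molecule, entry: int | None = None,
               exit: int | None = None) -> MoleculeTree:
    """Build the rooted spanning tree; see the module docstring for rules.

    Raises :class:`MolfigError` for invalid entry/exit indices or for
    ``entry == exit`` on a multi-atom molecule.
    """
    n = len(mol.atoms)
    if n == 0:
        raise MolfigError("cannot build a tree for an empty molecule")
    for name, idx in (("entry", entry), ("exit", exit)):
        if idx is not None and not (1 <= idx <= n):
            raise MolfigError(f"{name} atom {idx} out of range 1..{n}")
    if entry is not None and entry == exit and n > 1:
        raise MolfigError("entry and exit atoms must differ")

    if entry is not None:
        root = entry
    else:
        terminals = sorted(a.index for a in mol.atoms if mol.degree(a.index) == 1)
        root = terminals[0] if terminals else min(a.index for a in mol.atoms)

    children: dict[int, list[tuple[Bond, int]]] = {a.index: [] for a in mol.atoms}
    parent: dict[int, tuple[int, Bond] | None] = {root: None}
    visit_order: list[int] = []
    closures: list[Closure] = []
    seen_closure_keys: set[tuple[int, int]] = set()
    visited: set[int] = set()

    # iterative DFS, neighbors in ascending index order
    stack: list[tuple[int, list[tuple[int, Bond]]]] = []
    visited.add(root)
    visit_order.append(root)
    stack.append((root, mol.neighbors(root)))
    while stack:
        u, nbrs = stack[-1]
        advanced = False
        while nbrs:
            v, bond = nbrs.pop(0)
            if v not in visited:
                visited.add(v)
                visit_order.append(v)
                children[u].append((bond, v))
                parent[v] = (u, bond)
                stack.append((v, mol.neighbors(v)))
                advanced = True
                break
            if parent.get(u) is None or parent[u][0] != v:
                if bond.key() not in seen_closure_keys:
                    seen_closure_keys.add(bond.key())
                    closures.append(Closure(opener=v, closer=u, bond=bond))
        if not advanced:
            stack.pop()

    if len(visited) != n:
        raise MolfigError("molecule is disconnected; cannot span with one tree")

    # the opener is always the earlier-visited endpoint
    pos = {a: i for i, a in enumerate(visit_order)}
    for c in closures:
        if pos[c.opener] > pos[c.closer]:
            c.opener, c.closer = c.closer, c.opener

    # subtree depths for the default main-chain rule
    depth: dict[int, int] = {}
    for u in reversed(visit_order):
        kids = children[u]
        depth[u] = 1 + max((depth[v] for _, v in kids), default=0)

    cont_next: dict[int, int | None] = {}
    for u in visit_order:
        kids = children[u]
        if kids:
            cont_next[u] = max(kids, key=lambda kv: (depth[kv[1]], -kv[1]))[1]
        else:
            cont_next[u] = None

    if exit is not None:
        # force the root→exit tree path to be the unparenthesized chain
        path = [exit]
        while path[-1] != root:
            p = parent[path[-1]]
            assert p is not None
            path.append(p[0])
        path.reverse()
        for a, b in zip(path, path[1:]):
            cont_next[a] = b
        cont_next[exit] = None
        main_chain = path
    else:
        main_chain = [root]
        while cont_next[main_chain[-1]] is not None:
            main_chain.append(cont_next[main_chain[-1]])

    return MoleculeTree(root=root, children=children, parent=parent,
                        visit_order=visit_order, cont_next=cont_next,
                        main_chain=main_chain, closures=closures)


def assign_closures(tree: MoleculeTree) -> MoleculeTree:
    """Number ring closures 1, 2, … in the order their opener atoms were
    first visited (ties broken by the closer's visit position)."""
    pos = {a: i for i, a in enumerate(tree.visit_order)}
    tree.closures.sort(key=lambda c: (pos[c.opener], pos[c.closer]))
    for k, c in enumerate(tree.closures, start=1):
        c.label = k
    return tree
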
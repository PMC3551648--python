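"""Ring perception and deterministic 2D coordinate generation.

Used for coordinate-free SMILES input and for explicit re-layout requests.
The layout is rule-based and fully deterministic:

* isolated rings become regular polygons with unit sides;
* edge-fused rings share the already-placed edge and are reflected onto the
  side with less occupancy;
* acyclic chains zigzag with 120 degrees between consecutive bonds,
  alternating +-30 degrees about the horizontal;
* extra substituents split the largest free angular gap at their anchor,
  snapping to multiples of 30 degrees when there is room;
* a freshly placed branch that lands within 0.25 units of earlier atoms is
  rotated about its attachment point in 30-degree steps until it clears
  (falling back to the rotation with the best clearance).

No attempt is made to reproduce any particular toolkit's aesthetics; the
contract is geometric (unit bonds, clean angles, no near-collisions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .molecule import LayoutError, Molecule

__all__ = ["Ring", "perceive_rings", "generate_coordinates", "circle_rings"]

MIN_CLEARANCE = 0.25


@dataclass(frozen=True)
class Ring:
    """An ordered atom cycle; consecutive members (and last→first) bonded."""
    atoms: tuple[int, ...]
    aromatic: bool

    def __len__(self) -> int:
        return len(self.atoms)

    def edges(self) -> list[tuple[int, int]]:
        n = len(self.atoms)
        return [tuple(sorted((self.atoms[i], self.atoms[(i + 1) % n])))
                for i in range(n)]

    def centroid(self, mol: Molecule) -> tuple[float, float]:
        xs = [mol.atom(i).x for i in self.atoms]
        ys = [mol.atom(i).y for i in self.atoms]
        return (sum(xs) / len(xs), sum(ys) / len(ys))

    def circumradius(self, mol: Molecule) -> float:
        cx, cy = self.centroid(mol)
        return sum(math.hypot(mol.atom(i).x - cx, mol.atom(i).y - cy)
                   for i in self.atoms) / len(self.atoms)


def _order_cycle(g: nx.Graph, nodes: list[int]) -> tuple[int, ...]:
    """Order a cycle-basis node set into a closed walk along graph edges."""
    node_set = set(nodes)
    start = min(nodes)
    n = len(nodes)

    def dfs(path: list[int], seen: set[int]) -> list[int] | None:
        if len(path) == n:
            return path if g.has_edge(path[-1], start) else None
        for nxt in sorted(g.neighbors(path[-1])):
            if nxt in node_set and nxt not in seen:
                found = dfs(path + [nxt], seen | {nxt})
                if found:
                    return found
        return None

    ordered = dfs([start], {start})
    if ordered is None:  # not a simple cycle in the graph (degenerate basis)
        return tuple(sorted(nodes))
    # canonical direction: step toward the smaller of start's two neighbors
    if ordered[1] > ordered[-1]:
        ordered = [ordered[0]] + ordered[:0:-1]
    return tuple(ordered)


def perceive_rings(mol: Molecule) -> list[Ring]:
    """Minimum cycle basis (SSSR-sized) as ordered cycles, deterministic."""
    g = mol.graph()
    rings = []
    for nodes in nx.minimum_cycle_basis(g):
        cycle = _order_cycle(g, list(nodes))
        aromatic = all(
            (b := mol.bond_between(a, b_)) is not None and b.aromatic
            for a, b_ in zip(cycle, cycle[1:] + cycle[:1])
        )
        rings.append(Ring(atoms=cycle, aromatic=aromatic))
    rings.sort(key=lambda r: (len(r), r.atoms))
    return rings


def circle_rings(mol: Molecule, rings: list[Ring], enabled: bool) -> list[Ring]:
    """Rings to draw with an inscribed circle instead of discrete double
    bonds: size 5–7 with every ring bond aromatic-flagged."""
    if not enabled:
        return []
    return [r for r in rings if 5 <= len(r) <= 7 and r.aromatic]


# -- coordinate generation -------------------------------------------------

def _unit(deg: float) -> tuple[float, float]:
    r = math.radians(deg)
    return (math.cos(r), math.sin(r))


def _snap30(deg: float, occupied: list[float]) -> float:
    """Snap to the nearest multiple of 30 if that keeps >=25 deg clearance
    from every occupied direction; otherwise keep the exact value."""
    snapped = (round(deg / 30.0) * 30.0) % 360.0
    for occ in occupied:
        diff = abs((snapped - occ + 180.0) % 360.0 - 180.0)
        if diff < 25.0:
            return deg % 360.0
    return snapped


class _Layout:
    def __init__(self, mol: Molecule):
        self.mol = mol
        self.pos: dict[int, tuple[float, float]] = {}
        self.order: list[int] = []
        self.rings = perceive_rings(mol)
        self.ring_of: dict[int, list[Ring]] = {}
        for r in self.rings:
            for a in r.atoms:
                self.ring_of.setdefault(a, []).append(r)
        self.systems = self._ring_systems()
        self.system_of: dict[int, int] = {}
        for si, rs in enumerate(self.systems):
            for r in rs:
                for a in r.atoms:
                    self.system_of.setdefault(a, si)
        self.system_placed = [False] * len(self.systems)

    def _ring_systems(self) -> list[list[Ring]]:
        """Group rings sharing an edge (fused); spiro rings stay separate."""
        parent = list(range(len(self.rings)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        edge_sets = [set(r.edges()) for r in self.rings]
        for i in range(len(self.rings)):
            for j in range(i + 1, len(self.rings)):
                if edge_sets[i] & edge_sets[j]:
                    parent[find(i)] = find(j)
        groups: dict[int, list[Ring]] = {}
        for i, r in enumerate(self.rings):
            groups.setdefault(find(i), []).append(r)
        return [groups[k] for k in sorted(groups)]

    # -- helpers ----------------------------------------------------------

    def placed_bond_angles(self, u: int) -> list[float]:
        ux, uy = self.pos[u]
        out = []
        for v, _ in self.mol.neighbors(u):
            if v in self.pos:
                vx, vy = self.pos[v]
                out.append(math.degrees(math.atan2(vy - uy, vx - ux)) % 360.0)
        return sorted(out)

    def put(self, idx: int, p: tuple[float, float]) -> None:
        self.pos[idx] = p
        self.order.append(idx)

    def min_dist_to_prior(self, atoms: list[int], prior: set[int]) -> float:
        best = math.inf
        for a in atoms:
            ax, ay = self.pos[a]
            for b in prior:
                bx, by = self.pos[b]
                d = math.hypot(ax - bx, ay - by)
                if d < best:
                    best = d
        return best

    # -- placement --------------------------------------------------------

    def run(self) -> None:
        mol = self.mol
        if len(mol.atoms) == 0:
            return
        if not mol.is_connected():
            raise LayoutError("cannot lay out a disconnected molecule; "
                              "render each component separately")
        terminals = sorted(a.index for a in mol.atoms if mol.degree(a.index) <= 1)
        root = terminals[0] if terminals else min(a.index for a in mol.atoms)
        self.put(root, (0.0, 0.0))
        if root in self.system_of:
            self.place_system(self.system_of[root], root, None)
        self.grow_from(root, first_dir=30.0)
        # safety net: any atom missed by the rules grows from a placed neighbor
        for a in sorted(x.index for x in mol.atoms):
            if a not in self.pos:
                for n, _ in mol.neighbors(a):
                    if n in self.pos:
                        self.place_chain_atom(a, n)
                        self.grow_from(a)
                        break
        self._separate()

    def _separate(self) -> None:
        """Deterministic de-overlap pass: an atom closer than the clearance
        to any earlier-placed atom is relocated to the nearest clear spot on
        candidate circles around a bonded neighbor.  Only densely bridged
        systems (which admit no overlap-free unit-bond drawing) trigger it."""
        margin = MIN_CLEARANCE + 0.05
        for i, a in enumerate(self.order):
            earlier = self.order[:i]
            ax, ay = self.pos[a]
            if all(math.dist((ax, ay), self.pos[b]) >= margin for b in earlier):
                continue
            anchors = [n for n, _ in self.mol.neighbors(a) if n in self.pos
                       and n != a]
            cx, cy = self.pos[anchors[0]] if anchors else (ax, ay)
            others = [b for b in self.pos if b != a]
            candidates = [
                (cx + radius * math.cos(math.radians(deg)),
                 cy + radius * math.sin(math.radians(deg)))
                for radius in (1.0, 1.3, 1.6, 2.0, 2.5)
                for deg in range(0, 360, 5)
            ]
            candidates.sort(key=lambda p: (round(math.dist(p, (ax, ay)), 9),
                                           round(p[0], 9), round(p[1], 9)))
            for p in candidates:
                if all(math.dist(p, self.pos[b]) >= margin for b in others):
                    self.pos[a] = p
                    break

    def grow_from(self, u: int, first_dir: float | None = None) -> None:
        """Place all unplaced neighbors of u (ascending), recursing into each
        subtree and resolving collisions per branch."""
        for v, _ in self.mol.neighbors(u):
            if v in self.pos:
                continue
            mark = len(self.order)
            prior = set(self.order)
            if v in self.system_of and not self.system_placed[self.system_of[v]]:
                direction = self.free_direction(u, first_dir)
                self.place_chain_atom(v, u, first_dir)
                self.place_system(self.system_of[v], v, direction)
            else:
                self.place_chain_atom(v, u, first_dir)
            first_dir = None
            # recurse into everything just placed, breadth of the new branch
            i = mark
            while i < len(self.order):
                self.grow_from(self.order[i])
                i += 1
            self.resolve_collision(u, self.order[mark:], prior)

    def free_direction(self, u: int, first_dir: float | None = None) -> float:
        """Direction for a new bond leaving u."""
        occupied = self.placed_bond_angles(u)
        if not occupied:
            return first_dir if first_dir is not None else 30.0
        if len(occupied) == 1:
            # zigzag: 120 deg between bonds, leaning toward the horizontal
            d_in = (occupied[0] + 180.0) % 360.0  # incoming direction
            c1, c2 = (d_in + 60.0) % 360.0, (d_in - 60.0) % 360.0
            k1, k2 = (abs(math.sin(math.radians(c1))), -math.cos(math.radians(c1)), c1), \
                     (abs(math.sin(math.radians(c2))), -math.cos(math.radians(c2)), c2)
            return c1 if k1 < k2 else c2
        # split the largest free gap (ties: smaller start angle)
        gaps = []
        for j, start in enumerate(occupied):
            nxt = occupied[(j + 1) % len(occupied)]
            width = (nxt - start) % 360.0
            gaps.append((width, -start, start))
        width, _, start = max(gaps)
        return _snap30(start + width / 2.0, occupied)

    def place_chain_atom(self, v: int, u: int, first_dir: float | None = None) -> None:
        d = self.free_direction(u, first_dir)
        ux, uy = self.pos[u]
        dx, dy = _unit(d)
        self.put(v, (ux + dx, uy + dy))

    def resolve_collision(self, pivot: int, branch: list[int],
                          prior: set[int]) -> None:
        if not branch or not prior:
            return
        if self.min_dist_to_prior(branch, prior) >= MIN_CLEARANCE:
            return
        px, py = self.pos[pivot]
        saved = {a: self.pos[a] for a in branch}

        def rotated(delta: float) -> dict[int, tuple[float, float]]:
            t = math.radians(delta)
            c, s = math.cos(t), math.sin(t)
            out = {}
            for a, (x, y) in saved.items():
                dx, dy = x - px, y - py
                out[a] = (px + dx * c - dy * s, py + dx * s + dy * c)
            return out

        best_delta, best_min = 0.0, self.min_dist_to_prior(branch, prior)
        steps = [s for k in range(1, 12) for s in (30.0 * k, -30.0 * k)]
        steps += [s for k in range(1, 24) for s in (15.0 * k, -15.0 * k)
                  if (15.0 * k) % 30.0 != 0]
        for delta in steps:
            self.pos.update(rotated(delta))
            d = self.min_dist_to_prior(branch, prior)
            if d >= MIN_CLEARANCE:
                return
            if d > best_min + 1e-12:
                best_delta, best_min = delta, d
        self.pos.update(rotated(best_delta))

    # -- ring systems ------------------------------------------------------

    def place_system(self, si: int, anchor: int, direction: float | None) -> None:
        self.system_placed[si] = True
        rings = self.systems[si]
        # first ring: one containing the anchor (smallest, then lexicographic)
        first = min((r for r in rings if anchor in r.atoms),
                    key=lambda r: (len(r), r.atoms))
        self.place_first_ring(first, anchor, direction)
        remaining = [r for r in rings if r is not first]
        while remaining:
            placeable = None
            for r in remaining:  # prefer rings with a fully placed edge
                if any(a in self.pos and b in self.pos for a, b in r.edges()):
                    placeable = r
                    break
            if placeable is None:
                for r in remaining:
                    if any(a in self.pos for a in r.atoms):
                        placeable = r
                        break
            if placeable is None:  # detached leftovers: grow atom by atom
                for r in remaining:
                    for a in r.atoms:
                        if a not in self.pos:
                            for n, _ in self.mol.neighbors(a):
                                if n in self.pos:
                                    self.place_chain_atom(a, n)
                                    break
                break
            self.place_fused_ring(placeable)
            remaining.remove(placeable)

    def place_first_ring(self, ring: Ring, anchor: int,
                         direction: float | None) -> None:
        n = len(ring)
        circum = 0.5 / math.sin(math.pi / n)
        if direction is None:
            direction = 90.0
        ax, ay = self.pos[anchor]
        dx, dy = _unit(direction)
        cx, cy = ax + circum * dx, ay + circum * dy
        # walk the cycle starting at the anchor, stepping counterclockwise
        cyc = list(ring.atoms)
        k = cyc.index(anchor)
        ordered = cyc[k:] + cyc[:k]
        phi0 = math.atan2(ay - cy, ax - cx)
        step = 2.0 * math.pi / n
        for j, a in enumerate(ordered):
            if a in self.pos:
                continue
            phi = phi0 + j * step
            self.put(a, (cx + circum * math.cos(phi), cy + circum * math.sin(phi)))

    def place_fused_ring(self, ring: Ring) -> None:
        """Complete a partially placed ring.

        Every maximal run of unplaced cycle atoms is laid on a circular arc
        between its two placed anchors, with equal chord steps, bulging to
        the less occupied side.  For the common case — exactly one shared
        edge already placed — the arc construction reproduces the regular
        polygon with unit sides exactly.
        """
        cyc = list(ring.atoms)
        n = len(cyc)
        placed = [a in self.pos for a in cyc]
        if all(placed):
            return
        if sum(placed) == 1:
            anchor = cyc[placed.index(True)]
            self.place_first_ring(ring, anchor, self.free_direction(anchor))
            return
        k0 = placed.index(True)
        cyc2 = cyc[k0:] + cyc[:k0]
        t = 0
        while t < n:
            if cyc2[t] in self.pos:
                t += 1
                continue
            s = t
            while t < n and cyc2[t] not in self.pos:
                t += 1
            self._place_arc_run(cyc2[s:t], cyc2[s - 1], cyc2[t % n])

    def _place_arc_run(self, atoms: list[int], anchor_a: int,
                       anchor_b: int) -> None:
        k = len(atoms)
        ax, ay = self.pos[anchor_a]
        bx, by = self.pos[anchor_b]
        d = math.hypot(bx - ax, by - ay)
        if d >= k + 0.99 or d < 1e-9:
            # anchors too far apart (or coincident): straight interpolation
            # with a slight perpendicular stagger to keep atoms distinct
            px, py = (-(by - ay), bx - ax)
            plen = math.hypot(px, py) or 1.0
            px, py = px / plen, py / plen
            for j, a in enumerate(atoms, start=1):
                f = j / (k + 1)
                off = 0.3 * math.sin(math.pi * f)
                self.put(a, (ax + f * (bx - ax) + off * px,
                             ay + f * (by - ay) + off * py))
            return
        # solve for the half-angle u subtended by the anchor chord so that
        # the k+1 equal chords of the complementary arc have unit length:
        # sin(u) / sin(u / (k+1)) = d, monotone decreasing on (0, pi)
        lo, hi = 1e-9, math.pi - 1e-9

        def ratio(u: float) -> float:
            return math.sin(u) / math.sin(u / (k + 1))

        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if ratio(mid) > d:
                lo = mid
            else:
                hi = mid
        u = 0.5 * (lo + hi)
        r = d / (2.0 * math.sin(u))
        m = r * math.cos(u)
        mx, my = (ax + bx) / 2.0, (ay + by) / 2.0
        nx_, ny_ = (-(by - ay) / d, (bx - ax) / d)
        arc_angle = 2.0 * (math.pi - u)  # the long way round, through the run

        def candidate(sign: float) -> list[tuple[float, float]]:
            cx, cy = mx + sign * m * nx_, my + sign * m * ny_
            alpha = math.atan2(ay - cy, ax - cx)
            beta = math.atan2(by - cy, bx - cx)
            fwd = (beta - alpha) % (2.0 * math.pi)
            step = arc_angle / (k + 1)
            direction = 1.0 if abs(fwd - arc_angle) < 1e-6 else -1.0
            return [(cx + r * math.cos(alpha + direction * (j + 1) * step),
                     cy + r * math.sin(alpha + direction * (j + 1) * step))
                    for j in range(k)]

        def occupancy(points: list[tuple[float, float]]) -> tuple[int, float]:
            close = 0
            total = 0.0
            for x, y in points:
                for p in self.pos.values():
                    dd = math.hypot(p[0] - x, p[1] - y)
                    if dd < 0.6:
                        close += 1
                    total -= dd
            return (close, total)

        points = min((candidate(1.0), candidate(-1.0)), key=occupancy)
        for a, p in zip(atoms, points):
            self.put(a, p)


def generate_coordinates(mol: Molecule) -> Molecule:
    """Deterministic 2D layout with unit bond lengths; single atoms sit at
    the origin.  Raises :class:`LayoutError` for disconnected input."""
    mol = mol.copy()
    layout = _Layout(mol)
    layout.run()
    for a in mol.atoms:
        if a.index in layout.pos:
            a.x, a.y = layout.pos[a.index]
    mol.has_coordinates = True
    return mol
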
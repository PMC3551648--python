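# molfig — methods note

This note records the models, rules and numerical choices behind the
converter, the points where the design was genuinely open, and what the
test suite does and does not establish.

## Input models

**Molfile V2000.** Only the first record of an SD file is read (the tool
converts a single molecule); data fields after `$$$$` are ignored. `M  CHG`
and `M  RAD` property lines are authoritative: when either is present it
resets every atom-block column value of its kind, per CTfile convention.
The legacy atom-block charge column is honored only in their absence, with
codes {1:+3, 2:+2, 3:+1, 5:−1, 6:−2, 7:−3}; code 4 (doublet radical) sets
`radical=2`. Bond order 4 is read as order 1 + aromatic flag. Wedge
information comes only from the bond-block stereo column (1 = wedge up,
6 = hash down, narrow end at the first atom); atom-block parity and valence
override columns are parsed but ignored. z-coordinates are read and
discarded — the depiction is strictly 2D.

**SMILES.** A practical subset: organic-subset atoms, aromatic lowercase,
bracket atoms with explicit H count and charge, bonds `- = # :`, branches,
ring-bond digits and `%nn`. `/` and `\` are accepted with their geometry
ignored (warning); `@`/`@@` likewise — wedge stereo is honored from molfile
input only, because deriving wedges from parity requires layout-aware logic
that 2D input already encodes. An unspecified bond between two aromatic
atoms is aromatic, otherwise single; consequently a biphenyl written
`c1ccccc1c1ccccc1` gets an aromatic linking bond (write `-` to force a
single bond). Multi-fragment input (`.`) is rejected rather than drawn side
by side.

## Valence model and hydrogens

Allowed valences: B 3; C 4; N 3; O 2; P 3, 5; S 2, 4, 6; halogens 1; H 1.
The effective valence is the smallest allowed value that accommodates the
bond-order sum, then charge-adjusted: N/P cations gain capacity (+charge,
so N⁺ binds four), anions lose one hydrogen of capacity per negative
charge. Unlisted elements get no implicit hydrogens. Implicit count =
max(0, effective valence − bond-order sum); bracket-atom H counts bypass
the model entirely. For an aromatic atom whose orders are not yet
kekulized, the bond-order sum uses ⌈1.5 · n_aromatic⌉ plus the other
orders.

`delete` mode removes every explicit H with exactly one plain single bond
to a non-H neighbor and no charge, radical or wedge — hydrogens carrying
depiction information survive, so charges and radicals drawn on hydrogens
are never silently lost. Survivors are renumbered contiguously. `add` mode
materializes implicit hydrogens at unit distance in the largest angular gap
between the anchor's bonds (ties: the gap starting at the smaller angle),
spreading multiple hydrogens evenly inside that gap. Radical electrons are
treated as decoration and do not consume valence; the delete/add round trip
conserves the total hydrogen count exactly.

## Kekulization

Atoms contributing one π electron — carbons, N/P cations, and neutral N/P
with fewer than three connections (counting hydrogens) — must carry exactly
one double bond inside the aromatic system; O, S, anionic N and B (lone
pair or empty orbital) are excluded. The assignment is a perfect matching
on the π-contributing atoms over aromatic bonds, found by deterministic
backtracking (lowest-index-first); failure raises an error naming the
unmatched ring atoms. Aromatic flags survive kekulization so circle
rendering can still identify the system. The procedure is idempotent. A
full Hückel perception (recognizing aromaticity in Kekulé-form input) is
deliberately out of scope: input drawn with alternating bonds is rendered
as drawn.

## 2D layout

The layout is rule-based, deterministic (identical input → bit-identical
coordinates) and makes no aesthetic claims beyond its stated geometry:

* unit bond lengths; single atoms at the origin; the start atom is the
  lowest-index terminal atom (else the lowest index);
* isolated rings are regular polygons with unit sides; a ring entered from
  a chain is placed with its centroid straight ahead of the entry bond;
* rings fused on an edge are completed on the less occupied side of that
  edge; the general rule places every maximal run of unplaced ring atoms on
  a circular arc with equal chords between its placed anchors — for a
  single shared edge this reproduces the regular polygon exactly, and it
  degrades gracefully for bridged systems;
* acyclic chains zigzag with 120° between consecutive bonds, alternating
  ±30° about the horizontal, so chain bonds land on multiples of 30°;
  additional substituents split the largest free angular gap, snapping to a
  multiple of 30° when that keeps ≥ 25° clearance;
* a freshly placed branch within 0.25 units of earlier atoms is rotated
  about its attachment atom in 30° steps (then 15°) until it clears,
  falling back to the best-clearance rotation;
* a final deterministic de-overlap pass relocates any atom still closer
  than 0.25 units to a clear spot on candidate circles around a bonded
  neighbor. Only densely bridged polycycles — which admit no overlap-free
  unit-bond planar drawing — ever trigger it; their depiction is legible
  but not pretty. Congestion-minimizing global search and template
  libraries are non-goals.

Ring perception uses a minimum cycle basis (SSSR-sized), with each basis
cycle ordered by a small Hamiltonian walk and canonicalized for
determinism.

## Transforms and emission

Angles follow chemfig's convention (degrees counterclockwise from east).
Flip negates x, flop negates y, rotation is applied last about the
centroid. After an odd number of reflections, wedge and hash annotations
swap: a reflection inverts the implied out-of-plane direction, and swapping
preserves the depicted chirality. Coordinates are scaled so the median bond
length is 1; per-bond length factors within 2% of unity are suppressed.

Emitted angles are rounded to one decimal, with values within 0.05 of an
integer printed as integers. Angles, length factors, and the ring-side
cross product are pre-quantized at 1e-6 so floating-point noise (e.g. a
rotation and its exact inverse) cannot flip an emitted token across a
rounding boundary; this is what makes transform identities hold byte for
byte.

Atom labels: plain carbons are bare vertices (lone atoms and decorated
carbons always show); hydrogens go on the side away from the mean incident
bond direction ("HO" when bonds occupy the right, "OH" otherwise, with
vertical-only bonds defaulting to the right). Charges are appended as
`^{+}` / `^{2-}` superscripts after the label; when hydrogens sit left the
charge thus lands on the opposite side, and when they sit right a leading
superscript is not representable in a chemfig atom token, so it trails —
an accepted compromise. Radicals append `\mcfdot` for any nonzero radical
count, atom numbers `\mcfatomno{N}` with the input numbering.

The spanning tree is depth-first with ascending-index neighbor order. The
main chain continues into the deepest child subtree (ties to the lower
index), minimizing parenthesis nesting; an explicit exit atom overrides
this by making the root→exit tree path the unparenthesized chain, which is
exactly what submol composition needs. Ring closures are numbered in
opener-visit order and rendered with chemfig's hook mechanism
(`?[a]` … `?[a,{-}]`); the compact `*6(...)` ring syntax is deliberately
not generated — rings are treated like ordinary branches, which keeps the
emitter uniform and the output locally editable. Ring double bonds place
their second line on the ring-centroid side (`=^`/`=_`); closure bonds use
the bare token. Aromatic circles (rings of size 5–7 with all bonds
aromatic) demote their bonds to plain lines and add an invisible
positioning bond (`draw=none`) to the centroid carrying `\mcfcringle` with
radius 0.55 × circumradius. Verbose output indents two spaces per branch
depth and aligns comments; terse output is the verbose text with comments
and all whitespace removed, which chemfig treats identically.

## Synthetic molecules and what the tests show

The fixture generator grows a connected, valence-valid molecule atom by
atom from a seeded RNG: default 9 heavy atoms from a C-rich palette with
N/O/S/halogens, 15% double and 3% triple bonds where valence permits, ring
closures at probability 0.3 between atoms 2–6 bonds apart, a 25% chance of
starting from an aromatic six-ring, and small charge (6%) and radical (3%)
injection rates — values chosen once as representative of drug-like
drawing tasks at a size that keeps exhaustive test oracles cheap. The
generator does not attempt chemically realistic sampling (no
stereochemistry, no tautomers, occasional strained bridged cages), so
passing tests establish structural fidelity of the conversion — graph,
charges, radicals, hydrogen bookkeeping — not aesthetic equivalence with
any interactive drawing tool on real-world depositions.

The test loop is closed without a TeX engine by an oracle parser for
exactly the emitted chemfig dialect: emitted code is parsed back to a
multigraph and checked for isomorphism (elements, charges, radicals, bond
orders, known hydrogen counts) against the rendered molecule, across eight
option combinations covering terse × wrap × circles × relative × flip. An
independent cheminformatics toolkit (RDKit) cross-checks SMILES atom/bond/
hydrogen counts and kekulized double-bond counts in unit tests; it is never
on the implementation path. Where a TeX engine is installed, a smoke test
additionally compiles all named fixtures with chemfig.

Problem sizes used by the acceptance script: 200 generated molecules plus
the six named fixtures, eight option combinations each (1648 conversions),
which completes in a few seconds.

## Known limitations

* No molfile V3000, isotopes, S-groups, or multi-record SD iteration.
* SMILES stereo descriptors are ignored; wedges come from molfile only.
* Aromaticity is taken from input flags, never perceived from geometry.
* Layout of heavily bridged polycycles is legible, not beautiful; the
  entry/exit main-chain override cannot avoid placing branches after the
  exit atom when the exit has further substituents (chemfig still attaches
  following code to the right atom).
* The PubChem path needs network access and is exercised in tests only
  through an injected transport.
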
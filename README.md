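# molfig

Render chemical structures from **molfile V2000** or **SMILES** input to
**chemfig** LaTeX code.

LaTeX users who want publication-quality structure diagrams either hand-code
them in chemfig's bond-by-bond syntax — pleasant for ethanol, painful for
doxorubicin — or paste in bitmap exports from a drawing program. `molfig`
closes the gap: it reads the structure formats every chemistry database and
editor exports, and writes compact chemfig code you can compile, edit, and
compose into larger schemes.

## How it works

The pipeline has four stages:

1. **Parse** the molfile (atoms with 2D coordinates, bonds, `M CHG`/`M RAD`
   properties, wedge/hash stereo) or a practical SMILES subset (organic
   subset + aromatic lowercase + bracket atoms, branches, ring-bond digits)
   into a molecular graph.
2. **Normalize**: implicit hydrogens from a valence model
   (B 3, C 4, N 3, O 2, P 3/5, S 2/4/6, halogens 1, adjusted for formal
   charge), optional explicit-H addition/deletion, and kekulization of
   aromatic systems by a backtracking perfect matching. Coordinate-free
   input gets a deterministic 2D layout (regular polygons for rings,
   120° zigzag chains, collision-resolved substituents); flips, rotation
   and bond-length normalization follow.
3. **Spanning tree**: a depth-first tree rooted at the entry atom, with one
   distinguished unparenthesized *main chain* and the leftover bonds turned
   into labeled ring closures (chemfig `?[a]` hooks).
4. **Emit** chemfig code: one bond per line with `[:angle]` specifications,
   skeletal carbon vertices, hydrogen/charge/radical placement that avoids
   the incident bonds, and a line-end comment naming the atom each bond
   reaches (`% 7`, or `% ->2` for a ring closure).

## Worked example

```sh
molfig -i direct "NCC(O)c1ccc(O)c(O)c1"
```

prints (this is norepinephrine, drawn from SMILES, so coordinates are
computed):

```
H_2N         % 1
-[:30]       % 2
-[:330]      % 3
(
  -[:30]OH   % 4
)
-[:270]?[a]  % 5
=^[:210]     % 6
-[:270]      % 7
=^[:330]     % 8
(
  -[:270]OH  % 9
)
-[:30]       % 10
(
  =^[:90]    % 12
  ?[a,{-}]   % ->5
)
-[:330]OH    % 11
```

Read it top to bottom: the terminal amine `H_2N` is atom 1; each following
line draws one bond at an absolute angle (`-[:270]` points straight down);
parentheses open branches; `?[a]` marks ring atom 5 and `?[a,{-}]` closes
the six-membered ring back to it (`% ->5`). Wrap it for direct inclusion
with `-w` (`\chemfig{...}`), strip comments and whitespace with `-z`, or
emit a reusable `\definesubmol` with `-l NAME`.

Useful options (see `molfig -h` for all): `-y add|delete` hydrogen
handling, `-u` fresh coordinates, `-p`/`-q`/`-a DEG` flip/flop/rotate,
`-o` aromatic circles, `-n` atom numbers, `-v` relative angles, and
`-e`/`-x` to pick the main chain's entry and exit atoms — the key to
chaining submol copies into e.g. a peptide, since consecutive submols
connect across the last and first main-chain atoms.

PubChem records can be fetched directly: `molfig -i pubchem 439260`
(network required; everything else works offline).

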
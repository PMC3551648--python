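"""User-facing rendering options, shared by the CLI and the library API."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RenderOptions:
    """The full option set controlling conversion and code emission.

    ``submol_name`` takes precedence over ``wrap``; ``entry_atom`` /
    ``exit_atom`` are validated against the molecule at pipeline time.
    """

    input_mode: str = "file"          # file | direct | pubchem
    terse: bool = False
    wrap: bool = False                # enclose in \chemfig{...}
    submol_name: str | None = None    # emit \definesubmol{name}{...}
    atom_numbers: bool = False
    hydrogens: str = "keep"           # keep | add | delete
    recalc_coords: bool = False
    flip: bool = False
    flop: bool = False
    rotate: float = 0.0
    aromatic_circles: bool = False
    relative_angles: bool = False
    show_carbons: bool = False
    show_methyls: bool = False
    entry_atom: int | None = None
    exit_atom: int | None = None
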
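"""Shared fixtures and helpers for the molfig test suite."""

from __future__ import annotations

import io
import warnings

import pytest

from molfig import RenderOptions, convert, kekulize
from molfig.cli import main as cli_main
from molfig.fixtures import (
    NAMED_FIXTURES,
    FixtureSpec,
    isomorphic,
    load_fixture,
    parse_chemfig_subset,
    random_molecule,
)
from molfig.hydrogen_model import compute_implicit_hydrogens
from molfig.layout2d import circle_rings, perceive_rings

# the documented option matrix exercised by the round-trip tests:
# terse x wrap x circles x relative x flip, in 8 representative combinations
OPTION_MATRIX = [
    {},
    {"terse": True},
    {"wrap": True},
    {"aromatic_circles": True},
    {"relative_angles": True},
    {"flip": True},
    {"terse": True, "wrap": True, "aromatic_circles": True},
    {"relative_angles": True, "flip": True, "aromatic_circles": True},
]


@pytest.fixture(scope="session")
def named_molecules():
    return {name: load_fixture(name) for name in NAMED_FIXTURES}


@pytest.fixture(autouse=True)
def _silence_parser_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def run_cli(args, transport=None):
    """Run the CLI in-process; returns (exit code, stdout, stderr)."""
    out, err = io.StringIO(), io.StringIO()
    rc = cli_main(list(args), stdout=out, stderr=err, transport=transport)
    return rc, out.getvalue(), err.getvalue()


def prepared_source(mol, aromatic_circles=False):
    """The molecule as the renderer sees it (kekulized, implicit H filled),
    plus the bond pairs demoted to plain lines by circle rendering."""
    src = kekulize(mol.copy())
    compute_implicit_hydrogens(src)
    demoted = frozenset(
        e for r in circle_rings(src, perceive_rings(src), aromatic_circles)
        for e in r.edges())
    return src, demoted


def roundtrip_ok(mol, opts: RenderOptions) -> bool:
    """Full pipeline → emitted code → oracle parser → graph isomorphism."""
    code = convert(mol.copy(), opts)
    got = parse_chemfig_subset(code.output(opts.terse))
    src, demoted = prepared_source(mol, opts.aromatic_circles)
    return isomorphic(src, got, compare_h=True, radical_exact=False,
                      demoted=demoted)
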
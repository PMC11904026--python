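"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from lofcast.synthetic import (
    MSAScenario,
    TableScenario,
    generate_feature_table,
    generate_msa,
    toy_structure,
)


@pytest.fixture(scope="session")
def default_table():
    """The study-shaped default scenario: 480 variants x 134 features."""
    return generate_feature_table(TableScenario())


@pytest.fixture(scope="session")
def small_table():
    """A fast 200-variant scenario for unit tests."""
    return generate_feature_table(TableScenario(n_variants=200, seed=7))


@pytest.fixture(scope="session")
def small_msa():
    return generate_msa(MSAScenario(n_sequences=120, length=15, seed=3))


@pytest.fixture()
def aaindex_file(tmp_path):
    """A two-entry AAindex2 fixture: one triangular, one square."""
    tri_rows = "\n".join(
        " " + " ".join(f"{0.1 * (r + c):.2f}" for c in range(r + 1))
        for r in range(20)
    )
    square = "\n".join(
        " " + " ".join("1.0" if r == c else "0.0" for c in range(20))
        for r in range(20)
    )
    order = "ARNDCQEGHILKMFPSTWYV"
    text = textwrap.dedent(
        f"""\
        H TEST900101
        D triangular test matrix
        M rows = {order}, cols = {order}
        """
    ) + tri_rows + "\n//\n" + textwrap.dedent(
        f"""\
        H IDEN900102
        D identity-like square matrix
        M rows = {order}, cols = {order}
        """
    ) + square + "\n//\n"
    path = tmp_path / "aaindex2.txt"
    path.write_text(text, encoding="utf-8")
    return path


@pytest.fixture()
def carbon_sphere():
    return toy_structure([(1, "GLY", "CA", "C", (0.0, 0.0, 0.0), 1.7)])


@pytest.fixture()
def ligand_contact_structure():
    """One protein atom with one ligand atom 2 A away (both r = 1.7)."""
    return toy_structure(
        [(1, "GLY", "CA", "C", (0.0, 0.0, 0.0), 1.7)],
        [("I1", "I", (2.0, 0.0, 0.0), 1.7)],
    )


@pytest.fixture()
def helix_in_slab():
    """12-residue vertical chain crossing a z in [-8, 8] membrane slab."""
    residues = [
        (i + 1, "ALA", "CA", "C", (0.0, 0.0, -16.0 + 3.0 * i), 1.7)
        for i in range(12)
    ]
    return toy_structure(residues, membrane_slab=(-8.0, 8.0))
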
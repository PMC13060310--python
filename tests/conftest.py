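"""Shared fixtures: synthetic benchmark, idealized chains, tiny PDB files."""

from __future__ import annotations

import numpy as np
import pytest

import burialcode as bc

BENCH_SEED = 7


@pytest.fixture(scope="session")
def benchmark():
    """Seeded synthetic benchmark: 3 targets x 40 decoys with all channels."""
    return bc.make_benchmark(n_targets=3, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def helix():
    """Ideal 12-residue poly-ALA helix with pseudo side chains."""
    spec = bc.BackboneSpec(segments=[("helix", 12)], seed=1, sequence="A" * 12)
    return bc.build_backbone(spec)


@pytest.fixture(scope="session")
def reference_table():
    return bc.reference_areas()


ONE_RES_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.644   6.623  -4.120  1.00  0.00           C
ATOM      4  O   ALA A   1       9.442   6.759  -4.389  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  SER A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   SER A   1      10.644   6.623  -4.120  1.00  0.00           C
ATOM      4  O   SER A   1       9.442   6.759  -4.389  1.00  0.00           O
ATOM      5  OG ASER A   1      12.000   7.500  -5.000  0.60  0.00           O
ATOM      6  OG BSER A   1      13.000   8.500  -5.500  0.40  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture()
def one_res_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(ONE_RES_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture()
def water_pdb(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(WATER_ONLY_PDB)
    return p


def make_structure(coords, res_types=None, radius=1.8):
    """Bare C-alpha-only structure from an (N, 3) coordinate array."""
    from burialcode.structures import AtomRecord, ResidueRecord, Structure

    coords = np.asarray(coords, dtype=float)
    res_types = res_types or ["ALA"] * len(coords)
    residues = [
        ResidueRecord(rt, i, [AtomRecord("CA", "C", c, radius)])
        for i, (c, rt) in enumerate(zip(coords, res_types))
    ]
    return Structure(residues)
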
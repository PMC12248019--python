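"""Shared fixtures: small synthetic structures and raw-format snippets."""

from __future__ import annotations

import numpy as np
import pytest

import naassess as na
from naassess.structures import Chain, Residue, Structure


@pytest.fixture
def hairpin():
    """12-nt hairpin with a 4-pair stem."""
    spec = na.SecStructSpec("GGGGAAAACCCC", "((((....))))")
    return na.build_structure(spec, seed=1, structure_id="hairpin")


@pytest.fixture
def pseudoknot():
    """Nested stem plus a crossing two-pair layer."""
    spec = na.SecStructSpec("GGGAGCAAUCCAAAGCAA", "(((.[[..)))...]]..")
    return na.build_structure(spec, seed=2, structure_id="pk")


@pytest.fixture
def duplex():
    """Two complementary chains forming an intermolecular helix."""
    spec = na.SecStructSpec("GGGGGG&CCCCCC", "((((((&))))))")
    return na.build_structure(spec, seed=3, structure_id="duplex")


def random_walk_structure(n: int, seed: int, chain_id: str = "A") -> Structure:
    """A self-avoiding-ish random coil with representative atoms only."""
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 3.5, (n, 3)), axis=0)
    residues = [
        Residue("A", i + 1, "", {"C4'": pts[i], "C1'": pts[i] + rng.normal(0, 1, 3)})
        for i in range(n)
    ]
    return Structure(f"rw{seed}", [Chain(chain_id, "RNA", residues)])


PDB_3RES = """\
ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  C4'   G A   1       1.000   0.500   0.000  1.00  0.00           C
ATOM      3  C1'   G A   1       2.000   1.000   0.000  1.00  0.00           C
ATOM      4  P     A A   2       3.000   2.000   1.000  1.00  0.00           P
ATOM      5  C4'   A A   2       4.000   2.500   1.000  1.00  0.00           C
ATOM      6  C1'   A A   2       5.000   3.000   1.000  1.00  0.00           C
ATOM      7  P     C A   3       6.000   4.000   2.000  1.00  0.00           P
ATOM      8  C4'   C A   3       7.000   4.500   2.000  1.00  0.00           C
ATOM      9  C1'   C A   3       8.000   5.000   2.000  1.00  0.00           C
END
"""

MMCIF_TWO_CHAINS = """\
data_test
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C "C4'" . G A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 2 C "C1'" . G A 1 1 ? 1.000 0.000 0.000 1.00 0.00 1 A 1
ATOM 3 C "C4'" . U A 1 2 ? 2.000 1.000 0.000 1.00 0.00 2 A 1
ATOM 4 C "C1'" . U A 1 2 ? 3.000 1.000 0.000 1.00 0.00 2 A 1
ATOM 5 C CA . GLY B 2 1 ? 5.000 5.000 0.000 1.00 0.00 1 B 1
ATOM 6 C CA . ALA B 2 2 ? 6.000 6.000 0.000 1.00 0.00 2 B 1
"""

PDB_ALTLOC = """\
ATOM      1  C4'AG A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  C4'BG A   1       9.000   9.000   9.000  0.70  0.00           C
ATOM      3  C1'   G A   1       1.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3res_text():
    return PDB_3RES


@pytest.fixture
def mmcif_two_chains_text():
    return MMCIF_TWO_CHAINS


@pytest.fixture
def pdb_altloc_text():
    return PDB_ALTLOC
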
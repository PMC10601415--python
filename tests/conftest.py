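"""Shared fixtures: small libraries, labeled haystacks, and a fixture PDB."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vsbench.engines import HIGHER, ScoreTable
from vsbench.metrics import LabeledHaystack
from vsbench.molecules import MoleculeLibrary, MoleculeRecord


def make_library(smiles_ids, **kwargs) -> MoleculeLibrary:
    return MoleculeLibrary(
        [MoleculeRecord(id=i, smiles=s, **kwargs) for s, i in smiles_ids], name="test"
    )


def descriptor_library(counts, prefix="m") -> MoleculeLibrary:
    """Library with preset rotatable-bond counts (structures irrelevant)."""
    return MoleculeLibrary(
        [
            MoleculeRecord(id=f"{prefix}{i:03d}", smiles="C", rotatable_bonds=int(c))
            for i, c in enumerate(counts)
        ],
        name="desc",
    )


def labeled_haystack(labels, ids=None) -> LabeledHaystack:
    """Haystack from a label sequence like 'ADAD' (A=active, D=decoy)."""
    ids = ids or [f"m{i}" for i in range(len(labels))]
    records = [
        MoleculeRecord(
            id=i, smiles="C", label="active" if l == "A" else "decoy"
        )
        for i, l in zip(ids, labels)
    ]
    return LabeledHaystack(MoleculeLibrary(records, name="hay"))


def score_table(scores: dict, direction=HIGHER, engine="toy") -> ScoreTable:
    rows = pd.DataFrame({"id": list(scores), "score": list(scores.values())})
    return ScoreTable(engine=engine, direction=direction, rows=rows)


@pytest.fixture
def small_smi(tmp_path):
    path = tmp_path / "small.smi"
    path.write_text("CCO mol1\nCCCC mol2\nc1ccccc1 mol3\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


ALTLOC_PDB = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   2      11.639   6.071  -5.147  0.60  0.00           C
ATOM      3  CA BALA A   2      11.700   6.100  -5.200  0.40  0.00           C
ATOM      4  C   ALA A   3      12.685   7.148  -4.926  1.00  0.00           C
HETATM    5  C1  LIG A 101       8.000   5.000  -3.000  1.00  0.00           C
HETATM    6  O1  LIG A 101       8.500   5.500  -3.500  1.00  0.00           O
HETATM    7  C1  EDO A 102       2.000   1.000  -1.000  1.00  0.00           C
END
"""


@pytest.fixture
def altloc_pdb(tmp_path):
    """Crafted structure with two alternate-location sets (A, B) and two
    het groups (LIG, EDO)."""
    path = tmp_path / "struct.pdb"
    path.write_text(ALTLOC_PDB)
    return path
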
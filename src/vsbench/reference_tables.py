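"""Bundled reference benchmark tables.

Two small CSVs of published per-target DUD-E benchmarking metrics ship with
the package:

* ``protein_prep_benchmark.csv`` — ROC-AUC and EF1% for FRED docking against
  seven DUD-E targets whose proteins were prepared with three different
  tools (PDBFixer, LePro, SPRUCE). Used to demonstrate summary aggregation
  and the paired method-comparison test on real published numbers.
* ``dude_screen_benchmark.csv`` — ROC-AUC and EF1% for docking (FRED), shape
  (ROCS) and pharmacophore (Align-it) screens over the full 102-target
  DUD-E collection.

Both tables carry the values at their published precision (AUC two decimals,
EF1% one decimal); their ``average`` rows are recomputed by this package
rather than stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PREP_TOOLS = ("pdbfixer", "lepro", "spruce")
SCREEN_ENGINES = ("fred", "rocs", "alignit")


def _load(name: str) -> pd.DataFrame:
    with resources.files("vsbench.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def protein_prep_benchmark() -> pd.DataFrame:
    """Seven-target protein-preparation comparison (columns auc_*/ef1_* per tool)."""
    return _load("protein_prep_benchmark.csv")


def dude_screen_benchmark() -> pd.DataFrame:
    """102-target docking/shape/pharmacophore screen (columns auc_*/ef1_* per engine)."""
    return _load("dude_screen_benchmark.csv")
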
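"""Compound-library I/O, sanitization, and the rotatable-bond descriptor.

A :class:`MoleculeLibrary` is the in-memory form of a screening "haystack":
an ordered collection of :class:`MoleculeRecord` objects read from a SMILES
(.smi) or SDF file. Sanitization strips salts, normalizes charge-separated
depictions (e.g. pentavalent-nitro written as ``N(=O)=O``), canonicalizes,
and removes duplicate structures — the cleanup every downstream preparation
and screening stage assumes has happened.

The rotatable-bond count is the flexibility descriptor used to load-balance
worker chunks: an acyclic single bond between two non-terminal heavy atoms,
neither of which is triple-bonded. Amide C–N bonds count as rotatable under
this rule; backends may substitute their own definition via
:data:`ROTATABLE_BOND_SMARTS`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import DescriptorError, LibraryError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Acyclic single bond, both ends heavy-degree >= 2, neither end triple-bonded.
ROTATABLE_BOND_SMARTS = "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"
_ROT_PATTERN = Chem.MolFromSmarts(ROTATABLE_BOND_SMARTS)

LABELS = ("active", "decoy", "unlabeled")


@dataclass
class MoleculeRecord:
    """One library compound.

    ``canonical_smiles`` is filled by :func:`sanitize`; ``rotatable_bonds``
    by :func:`count_rotatable_bonds` (or lazily by the chunk planner).
    ``label`` is ``unlabeled`` outside benchmarking mode.
    """

    id: str
    smiles: str
    canonical_smiles: Optional[str] = None
    rotatable_bonds: Optional[int] = None
    label: str = "unlabeled"
    source: str = ""
    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise LibraryError(f"invalid label {self.label!r} for record {self.id!r}")

    @property
    def best_smiles(self) -> str:
        return self.canonical_smiles if self.canonical_smiles is not None else self.smiles


class MoleculeLibrary:
    """Ordered collection of records with unique ids."""

    def __init__(self, records: Iterable[MoleculeRecord], name: str = ""):
        self.records: list[MoleculeRecord] = list(records)
        self.name = name
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise LibraryError(f"duplicate record id {rec.id!r} in library {name!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> MoleculeRecord:
        return self._by_id[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def subset(self, rec_ids: Iterable[str], name: str = "") -> "MoleculeLibrary":
        return MoleculeLibrary([self._by_id[i] for i in rec_ids], name=name or self.name)


@dataclass
class SanitizationReport:
    """Outcome of :func:`sanitize`: what survived, what was removed and why."""

    n_input: int = 0
    n_output: int = 0
    duplicates_removed: list[tuple[str, str]] = field(default_factory=list)  # (id, kept id)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_removed(self) -> int:
        return len(self.duplicates_removed) + len(self.failures)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "smiles", "ism"}:
        return "smi"
    if suffix in {"sdf", "mol", "sd"}:
        return "sdf"
    if suffix == "csv":
        return "csv"
    raise LibraryError(f"cannot infer molecule format from {path.name!r}; pass format=")


def read_library(path, format: Optional[str] = None, name: Optional[str] = None) -> MoleculeLibrary:
    """Read a compound library from a .smi or .sdf file.

    One record per parsable entry; ids come from the file's name field
    (second whitespace token in .smi, title line in SDF) or are auto-numbered
    ``mol1, mol2, ...``. Unparsable entries are counted and logged, never
    fatal; a file with zero parsable entries raises :class:`LibraryError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    records: list[MoleculeRecord] = []
    n_rejected = 0
    seen_ids: set[str] = set()

    def _unique_id(candidate: str, index: int) -> str:
        rec_id = candidate or f"mol{index}"
        base, k = rec_id, 1
        while rec_id in seen_ids:
            k += 1
            rec_id = f"{base}_{k}"
        seen_ids.add(rec_id)
        return rec_id

    if fmt == "smi":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            if Chem.MolFromSmiles(smiles) is None:
                n_rejected += 1
                logger.warning("rejecting unparsable SMILES line %d of %s", i, path.name)
                continue
            records.append(
                MoleculeRecord(
                    id=_unique_id(parts[1].strip() if len(parts) > 1 else "", i),
                    smiles=smiles,
                    source=path.name,
                )
            )
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                n_rejected += 1
                logger.warning("rejecting unparsable SDF record %d of %s", i, path.name)
                continue
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(
                MoleculeRecord(
                    id=_unique_id(title.strip(), i),
                    smiles=Chem.MolToSmiles(mol),
                    source=path.name,
                )
            )
    else:
        raise LibraryError(f"unsupported read format {fmt!r} (expected smi or sdf)")

    if not records:
        raise LibraryError(f"no parsable molecules in {path} ({n_rejected} rejected)")
    if n_rejected:
        logger.info("%s: %d records read, %d rejected", path.name, len(records), n_rejected)
    lib = MoleculeLibrary(records, name=name or path.stem)
    lib.n_rejected = n_rejected  # type: ignore[attr-defined]
    return lib


_NORMALIZER = rdMolStandardize.Normalizer()


def _canonicalize(smiles: str) -> Optional[str]:
    """Largest organic fragment, normalized depiction, canonical SMILES.

    Salt stripping keeps the fragment with the most heavy atoms; ties go to
    the lexicographically smallest canonical form. Charge-separated drawings
    of the same group (nitro, N-oxide, azide, ...) are normalized to one form.
    Returns None when the structure cannot be processed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = min(frags, key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    try:
        mol = _NORMALIZER.normalize(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def sanitize(library: MoleculeLibrary) -> tuple[MoleculeLibrary, SanitizationReport]:
    """Strip salts, normalize, canonicalize, and deduplicate a library.

    Duplicates (identical canonical SMILES) keep the first occurrence in
    library order. Unprocessable records go to the report's failure list.
    Idempotent: sanitizing a sanitized library changes nothing.
    """
    report = SanitizationReport(n_input=len(library))
    kept: list[MoleculeRecord] = []
    first_by_canonical: dict[str, str] = {}
    for rec in library:
        canonical = _canonicalize(rec.smiles)
        if canonical is None:
            report.failures.append((rec.id, "unparsable or unnormalizable structure"))
            continue
        if canonical in first_by_canonical:
            report.duplicates_removed.append((rec.id, first_by_canonical[canonical]))
            continue
        first_by_canonical[canonical] = rec.id
        kept.append(replace(rec, canonical_smiles=canonical))
    report.n_output = len(kept)
    return MoleculeLibrary(kept, name=library.name), report


def count_rotatable_bonds(record: MoleculeRecord) -> int:
    """Count rotatable bonds under the strict rule in the module docstring."""
    mol = Chem.MolFromSmiles(record.best_smiles)
    if mol is None:
        raise DescriptorError(f"unparsable structure for record {record.id!r}")
    return len(mol.GetSubstructMatches(_ROT_PATTERN))


def ensure_rotatable_bonds(library: MoleculeLibrary) -> MoleculeLibrary:
    """Fill ``rotatable_bonds`` in place for records that lack it."""
    for rec in library:
        if rec.rotatable_bonds is None:
            rec.rotatable_bonds = count_rotatable_bonds(rec)
    return library


def write_library(library: MoleculeLibrary, path, format: Optional[str] = None) -> Path:
    """Write a library as .smi (``SMILES id`` lines), .sdf, or .csv.

    Refuses to write an empty library. Round-trip property: reading a file
    written here preserves ids and canonical structures.
    """
    if len(library) == 0:
        raise LibraryError("refusing to write an empty library")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "smi":
        lines = [f"{rec.best_smiles} {rec.id}" for rec in library]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in library:
                mol = Chem.MolFromSmiles(rec.best_smiles)
                if mol is None:
                    raise LibraryError(f"record {rec.id!r} is unparsable; sanitize first")
                mol.SetProp("_Name", rec.id)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            out = csv.writer(fh)
            out.writerow(["id", "canonical_smiles", "rotatable_bonds", "label"])
            for rec in library:
                out.writerow([rec.id, rec.best_smiles, rec.rotatable_bonds, rec.label])
    else:
        raise LibraryError(f"unsupported write format {fmt!r}")
    return path
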
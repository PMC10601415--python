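"""Staged ligand preparation, protein-preparation contract, and PDB selection.

Ligand preparation runs a fixed stage order over a sanitized library:

    (a) sanitize (canonicalize, fix charge-separated depictions) — done by
        :func:`vsbench.molecules.sanitize` before this module is entered,
    (b) tautomer generation,
    (c) ionization/protonation-state enumeration,
    (d) partial-charge assignment,
    (e) conformer generation (default 200 conformers per molecule),
    (f) final deduplication of identical tautomers/protomers.

Stages (b)-(e) are backend contracts, not chemistry re-implementations: a
backend maps records in to records out, purely and deterministically given a
seed. The :class:`IdentityBackend` passes records through untouched (useful
for contract tests and for pipelines whose engines take raw SMILES); the
:class:`RDKitBackend` provides a working open-source implementation.

Protein preparation is likewise a contract. The bundled
:class:`PassthroughProteinBackend` understands enough of the PDB format to
honour the two contract knobs: restricting output to one co-crystallized
ligand by its three-letter code, and either enumerating alternate-location
sets (one output file per altloc) or keeping only the primary one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Protocol, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ConfigError, SelectionError
from .molecules import MoleculeLibrary, MoleculeRecord

STAGE_ORDER = ("tautomers", "protonation", "charges", "conformers", "dedup")


@dataclass
class PrepConfig:
    """Ligand-preparation settings.

    ``n_conformers`` defaults to 200 — the point where ranking quality
    plateaus while preparation and docking time keep growing, so the best
    accuracy-versus-time balance for conformer ensembles.
    """

    do_tautomers: bool = True
    do_protonation: bool = True
    charge_model: str = "mmff"
    n_conformers: int = 200
    ph: float = 7.4
    max_tautomers: int = 8
    backend: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ConfigError("n_conformers must be >= 1")


class LigandPrepBackend(Protocol):
    """Stage contract: each method maps records in -> records out, pure and
    deterministic given the config seed. Expanded records (tautomers,
    protomers) derive their ids from the parent id."""

    name: str

    def tautomers(self, records: Sequence[MoleculeRecord], config: PrepConfig) -> list[MoleculeRecord]: ...
    def protonation(self, records: Sequence[MoleculeRecord], config: PrepConfig) -> list[MoleculeRecord]: ...
    def charges(self, records: Sequence[MoleculeRecord], config: PrepConfig) -> list[MoleculeRecord]: ...
    def conformers(self, records: Sequence[MoleculeRecord], config: PrepConfig) -> list[MoleculeRecord]: ...


class IdentityBackend:
    """Every stage is a no-op; the whole pipeline is the identity."""

    name = "identity"

    def tautomers(self, records, config):
        return list(records)

    def protonation(self, records, config):
        return list(records)

    def charges(self, records, config):
        return list(records)

    def conformers(self, records, config):
        return [replace(r, data={**r.data, "n_conformers": config.n_conformers}) for r in records]


class RDKitBackend:
    """Open-source stage implementations.

    Tautomers: canonical enumeration (capped at ``max_tautomers`` per input).
    Protonation: charge-state cleanup via uncharging (no pKa model; the pH
    value is recorded but not interpreted). Charges: Gasteiger partial
    charges stored per record. Conformers: ETKDG embedding, seeded.
    """

    name = "rdkit"

    def tautomers(self, records, config):
        if not config.do_tautomers:
            return list(records)
        enumerator = rdMolStandardize.TautomerEnumerator()
        out: list[MoleculeRecord] = []
        for rec in records:
            mol = Chem.MolFromSmiles(rec.best_smiles)
            if mol is None:
                out.append(rec)
                continue
            forms = sorted(Chem.MolToSmiles(t) for t in enumerator.Enumerate(mol))
            forms = forms[: config.max_tautomers]
            if len(forms) <= 1:
                out.append(rec)
            else:
                out.extend(
                    replace(rec, id=f"{rec.id}~t{k}", canonical_smiles=smi)
                    for k, smi in enumerate(forms)
                )
        return out

    def protonation(self, records, config):
        if not config.do_protonation:
            return list(records)
        uncharger = rdMolStandardize.Uncharger()
        out = []
        for rec in records:
            mol = Chem.MolFromSmiles(rec.best_smiles)
            if mol is None:
                out.append(rec)
                continue
            neutral = Chem.MolToSmiles(uncharger.uncharge(mol))
            out.append(
                replace(rec, canonical_smiles=neutral, data={**rec.data, "ph": config.ph})
            )
        return out

    def charges(self, records, config):
        out = []
        for rec in records:
            mol = Chem.MolFromSmiles(rec.best_smiles)
            if mol is None:
                out.append(rec)
                continue
            AllChem.ComputeGasteigerCharges(mol)
            total = sum(float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms())
            out.append(
                replace(
                    rec,
                    data={**rec.data, "charge_model": config.charge_model, "net_charge": round(total, 4)},
                )
            )
        return out

    def conformers(self, records, config):
        out = []
        for rec in records:
            out.append(replace(rec, data={**rec.data, "n_conformers": config.n_conformers}))
        return out


BACKENDS = {"identity": IdentityBackend, "rdkit": RDKitBackend}


@dataclass
class PrepReport:
    """Per-stage accounting: input count, output count, failures, removals."""

    stages: list[dict] = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0

    def add(self, stage: str, n_in: int, n_out: int, n_failed: int = 0, n_removed: int = 0) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "n_failed": n_failed, "n_removed": n_removed}
        )

    @property
    def expansion_factor(self) -> float:
        return self.n_output / self.n_input if self.n_input else 0.0


def get_backend(token: str) -> LigandPrepBackend:
    try:
        return BACKENDS[token]()
    except KeyError:
        raise ConfigError(f"unknown preparation backend {token!r}; have {sorted(BACKENDS)}")


def prepare_ligands(
    library: MoleculeLibrary,
    config: PrepConfig,
    backend: Optional[LigandPrepBackend] = None,
) -> tuple[MoleculeLibrary, PrepReport]:
    """Run stages (b)-(f) in order over a sanitized library.

    Expansion stages may emit several prepared states per input; the final
    dedup collapses states that ended up structurally identical (same
    canonical SMILES), keeping the first occurrence. Per-stage counts are
    reported so the ledger balances: n_out = n_in + expansions - removals.
    """
    backend = backend or get_backend(config.backend)
    for stage in ("tautomers", "protonation", "charges", "conformers"):
        if not hasattr(backend, stage):
            raise ConfigError(f"backend {backend.name!r} lacks stage {stage!r}")
    report = PrepReport(n_input=len(library))
    records = list(library.records)
    for stage in ("tautomers", "protonation", "charges", "conformers"):
        n_in = len(records)
        records = getattr(backend, stage)(records, config)
        report.add(stage, n_in, len(records))
    # stage (f): collapse identical tautomer/protomer duplicates
    n_in = len(records)
    seen: set[str] = set()
    deduped: list[MoleculeRecord] = []
    for rec in records:
        key = rec.best_smiles
        if key in seen:
            continue
        seen.add(key)
        deduped.append(rec)
    report.add("dedup", n_in, len(deduped), n_removed=n_in - len(deduped))
    report.n_output = len(deduped)
    return MoleculeLibrary(deduped, name=library.name), report


def write_conformer_sdf(library: MoleculeLibrary, path, n_conformers: int, seed: int = 0) -> Path:
    """Embed up to ``n_conformers`` 3D conformers per record (ETKDG, seeded)
    and write a multi-conformer SDF. Intended for small prepared sets."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in library:
            mol = Chem.AddHs(Chem.MolFromSmiles(rec.best_smiles))
            params = AllChem.ETKDGv3()
            params.randomSeed = seed
            conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
            mol = Chem.RemoveHs(mol)
            mol.SetProp("_Name", rec.id)
            for cid in conf_ids:
                writer.write(mol, confId=cid)
    finally:
        writer.close()
    return path


# --- protein preparation ---------------------------------------------------


class ProteinPrepBackend(Protocol):
    name: str

    def prepare(
        self, pdb_file: Path, out_dir: Path, ligand_code: Optional[str], altloc_mode: str
    ) -> list[Path]: ...


class PassthroughProteinBackend:
    """Contract-level protein preparation over plain PDB text.

    Emits ``<stem>__<LIG>__alt<X>.pdb`` (or ``__alt-`` when the structure has
    no alternate locations) under ``out_dir``. With ``altloc_mode='primary'``
    only the first alternate-location set (plus blank-altloc atoms) survives,
    giving exactly one output; with ``'enumerate'`` one file is written per
    alternate set. Chemistry (protonation, loop building) is delegated to
    real tools behind this same contract.
    """

    name = "passthrough"

    def prepare(self, pdb_file, out_dir, ligand_code, altloc_mode):
        pdb_file, out_dir = Path(pdb_file), Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = pdb_file.read_text().splitlines()
        atoms = [l for l in lines if l.startswith(("ATOM", "HETATM"))]
        if not atoms:
            raise SelectionError(f"{pdb_file.name} contains no atom records")
        het_codes = {l[17:20].strip() for l in atoms if l.startswith("HETATM")}
        if ligand_code is not None and ligand_code not in het_codes:
            raise SelectionError(
                f"ligand code {ligand_code!r} not in structure (found {sorted(het_codes)})"
            )
        altlocs = sorted({l[16] for l in atoms if l[16] != " "})
        variants = altlocs or ["-"]
        if altloc_mode == "primary":
            variants = variants[:1]
        elif altloc_mode != "enumerate":
            raise ConfigError(f"altloc_mode must be primary|enumerate, got {altloc_mode!r}")
        lig_tag = ligand_code or "ALL"
        outputs = []
        for alt in variants:
            kept = []
            for l in lines:
                if not l.startswith(("ATOM", "HETATM")):
                    kept.append(l)
                    continue
                if l.startswith("HETATM") and ligand_code and l[17:20].strip() != ligand_code:
                    continue
                if l[16] not in (" ", alt):
                    continue
                kept.append(l)
            out = out_dir / f"{pdb_file.stem}__{lig_tag}__alt{alt}.pdb"
            out.write_text("\n".join(kept) + "\n")
            outputs.append(out)
        return outputs


def prepare_protein(
    pdb_file,
    backend: Optional[ProteinPrepBackend] = None,
    ligand_code: Optional[str] = None,
    altloc_mode: str = "primary",
    out_dir=".",
) -> list[Path]:
    """Prepare a protein structure through a backend; see the backend contract."""
    backend = backend or PassthroughProteinBackend()
    outputs = backend.prepare(Path(pdb_file), Path(out_dir), ligand_code, altloc_mode)
    if altloc_mode == "primary" and len(outputs) != 1:
        raise SelectionError(
            f"backend {backend.name!r} violated the primary-altloc contract "
            f"({len(outputs)} outputs)"
        )
    return outputs


# --- PDB entry selection ---------------------------------------------------


@dataclass
class PdbEntryMeta:
    """Metadata for one PDB entry, as used by the structure-selection filter."""

    pdb_id: str
    method: str
    resolution: float
    has_bound_ligand: bool
    ligand_codes: list[str] = field(default_factory=list)

    def is_diffraction(self) -> bool:
        return "x-ray" in self.method.lower() or "diffraction" in self.method.lower()


def load_pdb_entries(path) -> list[PdbEntryMeta]:
    """Load entry metadata from a JSON file: a list of objects with keys
    pdb_id, method, resolution, has_bound_ligand, ligand_codes."""
    raw = json.loads(Path(path).read_text())
    return [
        PdbEntryMeta(
            pdb_id=e["pdb_id"],
            method=e.get("method", ""),
            resolution=float(e.get("resolution", 0.0)),
            has_bound_ligand=bool(e.get("has_bound_ligand", False)),
            ligand_codes=list(e.get("ligand_codes", [])),
        )
        for e in raw
    ]


def select_pdb_structures(entries: Sequence[PdbEntryMeta], k: int) -> list[PdbEntryMeta]:
    """Keep X-ray entries with a bound ligand; return the k lowest-resolution
    ones (ties broken by pdb_id). Deterministic under input permutation."""
    if not entries:
        raise SelectionError("no PDB entries to select from")
    if k < 1:
        raise ConfigError("k must be >= 1")
    survivors = [e for e in entries if e.is_diffraction() and e.has_bound_ligand]
    if not survivors:
        raise SelectionError("no entry passes the X-ray + bound-ligand filter")
    survivors.sort(key=lambda e: (e.resolution, e.pdb_id))
    if k > len(survivors):
        warnings.warn(f"requested {k} structures, only {len(survivors)} pass the filter")
    return survivors[:k]
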
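"""Screening-engine adapters and ranked score tables.

Docking, shape-overlay and pharmacophore tools all reduce, for pipeline
purposes, to the same contract: given a prepared chunk of molecules and a
target, emit one numeric score per molecule plus a declared directionality
(docking energies are better when lower; similarity scores when higher).
Adapters for external tools run a templated shell command; the built-in toy
engines (2D-fingerprint similarity, planted scores, seeded random) let
end-to-end runs and benchmarks execute without third-party software.

Ranks are assigned deterministically: sort by score under the adapter's
direction, break ties by id ascending, rank 1 is best. Rank assignment is
invariant under any strictly monotone transform of the raw scores, and
ranking merged per-chunk tables equals ranking the concatenation.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .errors import EngineUnavailableError, IntegrityError
from .molecules import MoleculeLibrary, MoleculeRecord

HIGHER = "higher_is_better"
LOWER = "lower_is_better"

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class ScoreTable:
    """Per-molecule scores (and, after ranking, ranks) from one engine."""

    engine: str
    direction: str
    rows: pd.DataFrame  # columns: id, score [, rank]
    target: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise IntegrityError(f"unknown score direction {self.direction!r}")
        if self.rows["id"].duplicated().any():
            dupes = self.rows["id"][self.rows["id"].duplicated()].tolist()
            raise IntegrityError(f"duplicate ids in score table: {dupes[:5]}")

    @property
    def ids(self) -> set[str]:
        return set(self.rows["id"])

    def score_of(self, rec_id: str) -> float:
        return float(self.rows.set_index("id").loc[rec_id, "score"])


def to_ranks(table: ScoreTable) -> ScoreTable:
    """Assign ranks 1..n (1 = best under the declared direction, ties by id)."""
    rows = table.rows.copy()
    ascending = table.direction == LOWER
    rows = rows.sort_values(["score", "id"], ascending=[ascending, True], kind="mergesort")
    rows["rank"] = np.arange(1, len(rows) + 1)
    return ScoreTable(
        engine=table.engine,
        direction=table.direction,
        rows=rows.reset_index(drop=True),
        target=table.target,
    )


def concat_tables(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Concatenate per-chunk tables from the same engine (pre-ranking merge)."""
    if not tables:
        raise IntegrityError("no score tables to concatenate")
    engines = {t.engine for t in tables}
    directions = {t.direction for t in tables}
    if len(engines) > 1 or len(directions) > 1:
        raise IntegrityError("cannot concatenate tables from different engines")
    rows = pd.concat([t.rows[["id", "score"]] for t in tables], ignore_index=True)
    return ScoreTable(
        engine=tables[0].engine,
        direction=tables[0].direction,
        rows=rows,
        target=tables[0].target,
    )


class EngineAdapter:
    """Base adapter: subclasses implement ``_score`` over a chunk.

    ``_score`` returns a mapping id -> raw score for the molecules it could
    score; molecules absent from the mapping are recorded as failures in the
    stage result, never fatal.
    """

    name: str = "engine"
    direction: str = HIGHER

    def available(self) -> bool:
        return True

    def _score(self, chunk: MoleculeLibrary, target_files: Sequence[Path]) -> Mapping[str, float]:
        raise NotImplementedError

    def score_chunk(
        self, chunk: MoleculeLibrary, target_files: Sequence[Path] = ()
    ) -> tuple[ScoreTable, list[str]]:
        if not self.available():
            raise EngineUnavailableError(f"engine {self.name!r} is not available")
        scores = self._score(chunk, list(target_files))
        scored = [(rec.id, float(scores[rec.id])) for rec in chunk if rec.id in scores]
        failed = [rec.id for rec in chunk if rec.id not in scores]
        rows = pd.DataFrame(scored, columns=["id", "score"])
        return ScoreTable(engine=self.name, direction=self.direction, rows=rows), failed


def run_engine(
    adapter: EngineAdapter, prepared_chunk: MoleculeLibrary, target_files: Sequence[Path] = ()
) -> tuple[ScoreTable, list[str]]:
    """Score one prepared chunk; returns the table and the failed-id list."""
    return adapter.score_chunk(prepared_chunk, target_files)


def fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return _MORGAN.GetFingerprint(mol)


class TanimotoEngine(EngineAdapter):
    """Toy similarity engine: Morgan (radius 2, 2048-bit) Tanimoto to a reference.

    Scores lie in [0, 1]; the reference scores 1.0 against itself and two
    molecules with disjoint fingerprint feature sets score 0.0. Stands in for
    shape/pharmacophore similarity tools in tests and demonstrations.
    """

    direction = HIGHER

    def __init__(self, reference: MoleculeRecord, name: str = "toy_similarity"):
        self.name = name
        self.reference = reference
        self._ref_fp = fingerprint(reference.best_smiles)
        if self._ref_fp is None:
            raise IntegrityError(f"reference {reference.id!r} is unparsable; sanitize first")

    def _score(self, chunk: MoleculeLibrary, target_files) -> dict[str, float]:
        out: dict[str, float] = {}
        for rec in chunk:
            fp = fingerprint(rec.best_smiles)
            if fp is not None:
                out[rec.id] = DataStructs.TanimotoSimilarity(self._ref_fp, fp)
        return out


class PlantedScoreEngine(EngineAdapter):
    """Replays a fixed id -> score mapping (e.g. a synthetic planted signal)."""

    direction = HIGHER

    def __init__(self, scores: Mapping[str, float], name: str = "planted"):
        self.name = name
        self.scores = dict(scores)

    def _score(self, chunk: MoleculeLibrary, target_files) -> dict[str, float]:
        return {rec.id: self.scores[rec.id] for rec in chunk if rec.id in self.scores}


class RandomScoreEngine(EngineAdapter):
    """Seeded random scores: a no-signal control engine."""

    direction = HIGHER

    def __init__(self, seed: int, name: str = "random"):
        self.name = name
        self.seed = int(seed)

    def _score(self, chunk: MoleculeLibrary, target_files) -> dict[str, float]:
        # Per-molecule stable seeding keeps scores independent of chunking
        # and of the process hash salt.
        import zlib

        out: dict[str, float] = {}
        for rec in chunk:
            h = zlib.crc32(f"{self.seed}:{rec.id}".encode())
            out[rec.id] = float(np.random.default_rng(h).random())
        return out


@dataclass
class ExternalCommandEngine(EngineAdapter):
    """Adapter for an external screening tool invoked per chunk.

    ``template`` is a shell command with ``{chunk_file}``, ``{target_file}``
    and ``{out_file}`` placeholders; the tool must write a headerless or
    headered CSV ``id,score``. The first whitespace-split token of the
    template must resolve on PATH, otherwise the engine is reported
    unavailable. Typical names: ``docking``, ``shape``, ``pharmacophore``.
    """

    name: str = "external"
    direction: str = LOWER
    template: str = ""
    workdir: Optional[Path] = None
    extra_env: dict = field(default_factory=dict)

    def available(self) -> bool:
        if not self.template:
            return False
        return shutil.which(self.template.split()[0]) is not None

    def _score(self, chunk: MoleculeLibrary, target_files) -> dict[str, float]:
        from .molecules import write_library

        workdir = Path(self.workdir or ".")
        workdir.mkdir(parents=True, exist_ok=True)
        chunk_file = workdir / f"{chunk.name or 'chunk'}.smi"
        out_file = workdir / f"{chunk.name or 'chunk'}_{self.name}.csv"
        write_library(chunk, chunk_file, format="smi")
        cmd = self.template.format(
            chunk_file=chunk_file,
            target_file=target_files[0] if target_files else "",
            out_file=out_file,
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineUnavailableError(
                f"engine {self.name!r} command failed ({proc.returncode}): {proc.stderr[:500]}"
            )
        frame = pd.read_csv(out_file, header=None, names=["id", "score"], comment="i")
        return dict(zip(frame["id"].astype(str), frame["score"].astype(float)))


def toy_similarity_engine(reference: MoleculeRecord) -> TanimotoEngine:
    """Factory mirroring the adapter registry's naming."""
    return TanimotoEngine(reference)
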
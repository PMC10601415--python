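"""Load-balanced chunking of a compound library and barrier-style dispatch.

The pipeline splits a library into as many chunks as worker cores, runs each
stage on every chunk, waits for all chunks to finish (each step must complete
before the next begins), and merges chunk outputs deterministically.

Two planners are provided. ``sequential`` deals contiguous blocks in file
order; with a library sorted by complexity this concentrates the flexible,
slow molecules into a few chunks. ``rotatable_balanced`` sorts molecules by
rotatable-bond count (descending) and deals them round-robin so per-chunk
flexibility — and hence conformer/docking cost — evens out.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .errors import ConfigError, DescriptorError, IncompleteRunError, IntegrityError, StageFailure
from .molecules import MoleculeLibrary


@dataclass
class ChunkPlan:
    """Assignment of every record id to exactly one chunk index."""

    n_chunks: int
    assignment: dict[str, int]
    method: str

    def __post_init__(self) -> None:
        if self.n_chunks < 1:
            raise ConfigError("n_chunks must be >= 1")
        indices = set(self.assignment.values())
        if indices and not indices <= set(range(self.n_chunks)):
            raise IntegrityError("chunk indices out of range")
        sizes = self.sizes()
        if sizes and max(sizes) - min(sizes) > 1:
            raise IntegrityError("chunk sizes differ by more than 1")

    def sizes(self) -> list[int]:
        counts = [0] * self.n_chunks
        for idx in self.assignment.values():
            counts[idx] += 1
        return counts

    def chunk_ids(self, index: int, order: Sequence[str]) -> list[str]:
        """Ids assigned to one chunk, in the given (deterministic) order."""
        return [i for i in order if self.assignment[i] == index]


@dataclass
class StageResult:
    """Output of one stage on one chunk: payload plus pass/fail bookkeeping."""

    chunk_index: int
    payload: object  # typically a DataFrame or a MoleculeLibrary
    passed_ids: list[str] = field(default_factory=list)
    failed_ids: list[str] = field(default_factory=list)
    log: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.passed_ids) & set(self.failed_ids)
        if overlap:
            raise IntegrityError(f"ids both passed and failed: {sorted(overlap)[:5]}")


def _effective_chunks(n_records: int, n_chunks: int) -> int:
    if n_chunks < 1:
        raise ConfigError(f"n_chunks must be >= 1, got {n_chunks}")
    if n_chunks > n_records:
        warnings.warn(
            f"n_chunks={n_chunks} exceeds library size {n_records}; reducing to {n_records}",
            stacklevel=3,
        )
        return n_records
    return n_chunks


def plan_sequential(library: MoleculeLibrary, n_chunks: int) -> ChunkPlan:
    """Contiguous block split in library order.

    The first ``N mod n`` chunks receive one extra record so that chunk sizes
    never differ by more than 1.
    """
    n = _effective_chunks(len(library), n_chunks)
    base, extra = divmod(len(library), n)
    assignment: dict[str, int] = {}
    pos = 0
    for k in range(n):
        size = base + (1 if k < extra else 0)
        for rec in library.records[pos : pos + size]:
            assignment[rec.id] = k
        pos += size
    return ChunkPlan(n_chunks=n, assignment=assignment, method="sequential")


def plan_rotatable_balanced(
    library: MoleculeLibrary, n_chunks: int, snake: bool = False
) -> ChunkPlan:
    """Sort by rotatable-bond count (descending, ties by id) and deal round-robin.

    Sorted position ``p`` goes to chunk ``p mod n``; with ``snake=True`` the
    deal reverses direction every round (boustrophedon), which balances sums
    slightly better but is not the default behaviour.
    """
    for rec in library:
        if rec.rotatable_bonds is None:
            raise DescriptorError(
                f"record {rec.id!r} has no rotatable_bonds; run ensure_rotatable_bonds first"
            )
    n = _effective_chunks(len(library), n_chunks)
    ordered = sorted(library.records, key=lambda r: (-r.rotatable_bonds, r.id))
    assignment: dict[str, int] = {}
    for p, rec in enumerate(ordered):
        if snake:
            round_, pos = divmod(p, n)
            assignment[rec.id] = pos if round_ % 2 == 0 else n - 1 - pos
        else:
            assignment[rec.id] = p % n
    return ChunkPlan(n_chunks=n, assignment=assignment, method="rotatable_balanced")


def split(library: MoleculeLibrary, plan: ChunkPlan) -> list[MoleculeLibrary]:
    """Materialize per-chunk libraries in deterministic within-chunk order.

    For a balanced plan the within-chunk order is the sorted deal order; for a
    sequential plan it is file order. Both are reproducible from the plan.
    """
    missing = [i for i in library.ids if i not in plan.assignment]
    if missing:
        raise IntegrityError(f"plan does not cover ids {missing[:5]}")
    if plan.method == "rotatable_balanced":
        order = [r.id for r in sorted(library.records, key=lambda r: (-r.rotatable_bonds, r.id))]
    else:
        order = library.ids
    return [
        library.subset(plan.chunk_ids(k, order), name=f"{library.name}_chunk{k}")
        for k in range(plan.n_chunks)
    ]


def merge(results: Sequence[StageResult]) -> pd.DataFrame:
    """Combine per-chunk payload tables into one table, ordered by chunk index.

    Payloads must be DataFrames with an ``id`` column. Ids must partition:
    an id appearing in two chunks is an integrity error; a missing chunk index
    (gap in the sequence) is an incomplete-run error.
    """
    if not results:
        raise IncompleteRunError("no stage results to merge")
    by_index: dict[int, StageResult] = {}
    for res in results:
        if res.chunk_index in by_index:
            raise IntegrityError(f"duplicate result for chunk {res.chunk_index}")
        by_index[res.chunk_index] = res
    expected = set(range(len(results)))
    if set(by_index) != expected:
        raise IncompleteRunError(f"missing chunk results: {sorted(expected - set(by_index))}")
    frames = []
    seen: set[str] = set()
    for k in sorted(by_index):
        frame = by_index[k].payload
        if not isinstance(frame, pd.DataFrame) or "id" not in frame.columns:
            raise IntegrityError(f"chunk {k} payload is not an id-keyed table")
        overlap = seen & set(frame["id"])
        if overlap:
            raise IntegrityError(f"ids in multiple chunks: {sorted(overlap)[:5]}")
        seen |= set(frame["id"])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_parallel(
    stage: Callable[[MoleculeLibrary], StageResult],
    chunks: Sequence[MoleculeLibrary],
    n_workers: Optional[int] = None,
) -> list[StageResult]:
    """Run a stage over every chunk and barrier until all complete.

    The stage must be a pure function of its chunk (no shared mutable state),
    so results are identical to serial execution regardless of worker
    scheduling. Results come back ordered by chunk index. A failure on any
    chunk aborts the whole stage with that chunk's log attached.
    """
    n_workers = n_workers or len(chunks)
    if n_workers < 1:
        raise ConfigError("n_workers must be >= 1")

    def _run(index_chunk: tuple[int, MoleculeLibrary]) -> StageResult:
        index, chunk = index_chunk
        try:
            result = stage(chunk)
        except StageFailure:
            raise
        except Exception as exc:  # attach the chunk index to arbitrary stage errors
            raise StageFailure(index, log=repr(exc)) from exc
        result.chunk_index = index
        return result

    items = list(enumerate(chunks))
    if n_workers == 1:
        results = [_run(item) for item in items]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_run, items))
    return sorted(results, key=lambda r: r.chunk_index)
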
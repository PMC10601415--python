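"""Config-driven orchestration of benchmarking and virtual-screening runs.

A run is driven by an INI file and proceeds through the staged pipeline:
sanitize -> chunk -> prepare -> engines (per chunk, with a barrier per
stage) -> merge -> metrics/consensus -> reports. Every stage writes inside
its own subdirectory of the run's output directory, each stage consumes the
previous stage's outputs, and a master report compiles the per-step reports
at the end. Given the same config, seed, and inputs, every output artifact
is identical across reruns.

Configuration layout (defaults in parentheses)::

    [run]       mode = benchmark|vs ; target_id ; n_chunks (1) ;
                n_workers (= n_chunks) ; seed (0) ; output_dir ;
                chunk_method = rotatable_balanced|sequential
    [library]   input = lib.smi           (vs mode)
                actives = a.smi ; decoys = d.smi   (benchmark, from files)
                synthetic = true ; n_actives (224) ; decoys_per_active (50) ;
                signal_mu (1.0) ; noise_sd (1.0)   (benchmark, generated)
    [prepare]   enabled (true) ; backend (identity) ; n_conformers (200)
    [engines]   names = planted, random, toy_similarity, ... ;
                reference = <SMILES>     (required by toy_similarity)
                <name>_command / <name>_direction   (external engines)
    [benchmark] ef_fractions = 0.01 ; consensus = rank_sum|best_rank
"""

from __future__ import annotations

import configparser
import datetime
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chunking, engines as eng, metrics, molecules
from .errors import ConfigError, FetchError, IntegrityError, LibraryError
from .metrics import BenchmarkResult, LabeledHaystack, SyntheticSpec
from .molecules import MoleculeLibrary, MoleculeRecord
from .preparation import PrepConfig, get_backend, prepare_ligands


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage/per-chunk sub-seed from the top-level seed."""
    return zlib.crc32(f"{seed}:{tag}".encode()) % (2**31)


@dataclass
class RunConfig:
    mode: str
    target_id: str = "target"
    n_chunks: int = 1
    n_workers: Optional[int] = None
    seed: int = 0
    output_dir: Path = Path("vsbench_run")
    chunk_method: str = "rotatable_balanced"
    library_input: Optional[Path] = None
    actives: Optional[Path] = None
    decoys: Optional[Path] = None
    synthetic: bool = False
    synthetic_spec: Optional[SyntheticSpec] = None
    prepare_ligands: bool = True
    prep_backend: str = "identity"
    n_conformers: int = 200
    engines: list[str] = field(default_factory=list)
    engine_options: dict = field(default_factory=dict)
    ef_fractions: list[float] = field(default_factory=lambda: [0.01])
    consensus_method: str = "rank_sum"

    def __post_init__(self) -> None:
        if self.mode not in ("benchmark", "vs"):
            raise ConfigError(f"mode must be 'benchmark' or 'vs', got {self.mode!r}")
        if self.n_chunks < 1:
            raise ConfigError(f"n_chunks must be >= 1, got {self.n_chunks}")
        if not self.engines:
            raise ConfigError("engines must list at least one adapter name")
        if self.chunk_method not in ("rotatable_balanced", "sequential"):
            raise ConfigError(f"unknown chunk_method {self.chunk_method!r}")
        if self.n_conformers < 1:
            raise ConfigError(f"n_conformers must be >= 1, got {self.n_conformers}")
        self.output_dir = Path(self.output_dir)

    def manifest(self) -> dict:
        data = {
            "mode": self.mode,
            "target_id": self.target_id,
            "n_chunks": self.n_chunks,
            "n_workers": self.n_workers or self.n_chunks,
            "seed": self.seed,
            "chunk_method": self.chunk_method,
            "prepare_ligands": self.prepare_ligands,
            "prep_backend": self.prep_backend,
            "n_conformers": self.n_conformers,
            "engines": list(self.engines),
            "ef_fractions": list(self.ef_fractions),
            "consensus_method": self.consensus_method,
            "synthetic": self.synthetic,
        }
        if self.synthetic_spec is not None:
            spec = self.synthetic_spec
            data["synthetic_spec"] = {
                "n_actives": spec.n_actives,
                "decoys_per_active": spec.decoys_per_active,
                "signal_mu": spec.signal_mu,
                "noise_sd": spec.noise_sd,
                "seed": spec.seed,
            }
        return data


def load_config(path) -> RunConfig:
    """Parse and validate an INI run configuration; errors name the key."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ini = configparser.ConfigParser()
    ini.read(path)
    if "run" not in ini or "mode" not in ini["run"]:
        raise ConfigError("missing required key 'mode' in section [run]")
    run = ini["run"]
    lib = ini["library"] if "library" in ini else {}
    prep = ini["prepare"] if "prepare" in ini else {}
    engsec = ini["engines"] if "engines" in ini else {}
    bench = ini["benchmark"] if "benchmark" in ini else {}

    def _int(section, key, default):
        try:
            return int(section.get(key, default))
        except ValueError as exc:
            raise ConfigError(f"invalid integer for key {key!r}") from exc

    names = [n.strip() for n in engsec.get("names", "").split(",") if n.strip()]
    if not names:
        raise ConfigError("missing required key 'names' in section [engines]")
    seed = _int(run, "seed", 0)
    synthetic = str(lib.get("synthetic", "false")).lower() in ("1", "true", "yes")
    spec = None
    if synthetic:
        spec = SyntheticSpec(
            n_actives=_int(lib, "n_actives", 224),
            decoys_per_active=_int(lib, "decoys_per_active", 50),
            signal_mu=float(lib.get("signal_mu", 1.0)),
            noise_sd=float(lib.get("noise_sd", 1.0)),
            seed=derive_seed(seed, "synthetic"),
        )
    fractions = [
        float(f) for f in str(bench.get("ef_fractions", "0.01")).split(",") if f.strip()
    ]
    engine_options = {k: v for k, v in engsec.items() if k != "names"}
    cfg = RunConfig(
        mode=run["mode"],
        target_id=run.get("target_id", "target"),
        n_chunks=_int(run, "n_chunks", 1),
        n_workers=_int(run, "n_workers", 0) or None,
        seed=seed,
        output_dir=Path(run.get("output_dir", "vsbench_run")),
        chunk_method=run.get("chunk_method", "rotatable_balanced"),
        library_input=Path(lib["input"]) if lib.get("input") else None,
        actives=Path(lib["actives"]) if lib.get("actives") else None,
        decoys=Path(lib["decoys"]) if lib.get("decoys") else None,
        synthetic=synthetic,
        synthetic_spec=spec,
        prepare_ligands=str(prep.get("enabled", "true")).lower() in ("1", "true", "yes"),
        prep_backend=prep.get("backend", "identity"),
        n_conformers=_int(prep, "n_conformers", 200),
        engines=names,
        engine_options=engine_options,
        ef_fractions=fractions,
        consensus_method=bench.get("consensus", "rank_sum"),
    )
    return cfg


@dataclass
class StepReport:
    """One pipeline step's accounting for the master report."""

    name: str
    n_in: int
    n_out: int
    passed_ids: list[str] = field(default_factory=list)
    failed_ids: list[str] = field(default_factory=list)
    details: str = ""


def compile_master_report(step_reports: Sequence[StepReport], path=None) -> str:
    """Concatenate step sections in execution order into one master report.

    Cross-checks molecule accounting between consecutive steps; mismatches
    are embedded as integrity warnings, not raised. Returns the report text
    (and writes it when ``path`` is given).
    """
    if not step_reports:
        raise IntegrityError("no step reports to compile")
    lines = [
        "MASTER REPORT",
        f"compiled: {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"steps: {len(step_reports)}",
        "",
    ]
    total_failures = 0
    for i, step in enumerate(step_reports, start=1):
        total_failures += len(step.failed_ids)
        lines.append(f"[{i}] {step.name}")
        lines.append(f"    in: {step.n_in}  out: {step.n_out}  failed: {len(step.failed_ids)}")
        if step.failed_ids:
            shown = ", ".join(step.failed_ids[:20])
            more = "" if len(step.failed_ids) <= 20 else f" (+{len(step.failed_ids) - 20} more)"
            lines.append(f"    failed ids: {shown}{more}")
        if step.details:
            lines.append(f"    {step.details}")
        if i < len(step_reports):
            nxt = step_reports[i]
            if nxt.n_in not in (step.n_out, step.n_in):
                lines.append(
                    f"    WARNING: next step reads {nxt.n_in} records but this step wrote {step.n_out}"
                )
        lines.append("")
    lines.append(f"total failures across steps: {total_failures}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def build_engines(config: RunConfig, planted_scores=None, reference: Optional[MoleculeRecord] = None):
    """Instantiate the configured engine adapters."""
    adapters = []
    opts = config.engine_options
    for name in config.engines:
        if name == "planted":
            if planted_scores is None:
                raise ConfigError("engine 'planted' requires a synthetic library")
            adapters.append(eng.PlantedScoreEngine(planted_scores))
        elif name == "random":
            adapters.append(eng.RandomScoreEngine(seed=derive_seed(config.seed, "random")))
        elif name == "toy_similarity":
            ref = reference
            if ref is None and opts.get("reference"):
                ref = MoleculeRecord(id="reference", smiles=opts["reference"])
            if ref is None:
                raise ConfigError("engine 'toy_similarity' requires key 'reference' in [engines]")
            adapters.append(eng.TanimotoEngine(ref))
        elif f"{name}_command" in opts:
            adapters.append(
                eng.ExternalCommandEngine(
                    name=name,
                    template=opts[f"{name}_command"],
                    direction=opts.get(f"{name}_direction", eng.LOWER),
                    workdir=config.output_dir / "engines" / name,
                )
            )
        else:
            raise ConfigError(f"unknown engine {name!r} and no '{name}_command' configured")
    return adapters


def _parent_id(rec_id: str) -> str:
    return rec_id.split("~", 1)[0]


def collapse_to_parents(table: eng.ScoreTable) -> eng.ScoreTable:
    """Collapse prepared-state scores (tautomers/protomers) to the parent
    molecule, keeping each parent's best score under the engine direction."""
    rows = table.rows.copy()
    rows["parent"] = rows["id"].map(_parent_id)
    best = rows.groupby("parent")["score"]
    agg = best.min() if table.direction == eng.LOWER else best.max()
    out = pd.DataFrame({"id": agg.index, "score": agg.values})
    return eng.ScoreTable(
        engine=table.engine, direction=table.direction, rows=out, target=table.target
    )


def full_table(table: eng.ScoreTable, all_ids: Sequence[str]) -> eng.ScoreTable:
    """Extend a score table to cover every haystack id; unscored molecules
    get the worst possible score so that failures rank last."""
    missing = [i for i in all_ids if i not in set(table.rows["id"])]
    if not missing:
        return table
    worst = -np.inf if table.direction == eng.HIGHER else np.inf
    extra = pd.DataFrame({"id": missing, "score": [worst] * len(missing)})
    rows = pd.concat([table.rows[["id", "score"]], extra], ignore_index=True)
    return eng.ScoreTable(
        engine=table.engine, direction=table.direction, rows=rows, target=table.target
    )


def _load_input_library(config: RunConfig) -> tuple[MoleculeLibrary, Optional[LabeledHaystack], Optional[dict]]:
    """Resolve the run's input molecules from config.

    Returns (library, haystack or None, planted scores or None).
    """
    if config.synthetic:
        haystack, planted = metrics.generate_synthetic_haystack(config.synthetic_spec)
        scores = dict(zip(planted.rows["id"], planted.rows["score"]))
        return haystack.library, haystack, scores
    if config.mode == "benchmark":
        if not (config.actives and config.decoys):
            raise ConfigError(
                "benchmark mode requires 'actives' and 'decoys' files or 'synthetic = true'"
            )
        actives = molecules.read_library(config.actives)
        decoys = molecules.read_library(config.decoys)
        haystack = LabeledHaystack.from_actives_decoys(actives, decoys)
        return haystack.library, haystack, None
    if config.library_input is None:
        raise ConfigError("vs mode requires key 'input' in section [library]")
    return molecules.read_library(config.library_input), None, None


def _pipeline(config: RunConfig):
    """Shared pipeline: load -> sanitize -> chunk -> prepare -> engines.

    Returns (library, haystack, ranked per-engine tables, consensus table,
    step reports).
    """
    out = config.output_dir
    (out / "merged").mkdir(parents=True, exist_ok=True)
    steps: list[StepReport] = []

    library, haystack, planted = _load_input_library(config)
    n_raw = len(library)

    library, san_report = molecules.sanitize(library)
    steps.append(
        StepReport(
            name="sanitization",
            n_in=san_report.n_input,
            n_out=san_report.n_output,
            passed_ids=library.ids,
            failed_ids=[i for i, _ in san_report.failures],
            details=f"duplicates removed: {len(san_report.duplicates_removed)}",
        )
    )
    if haystack is not None:
        haystack = LabeledHaystack(library)

    molecules.ensure_rotatable_bonds(library)
    planner = (
        chunking.plan_rotatable_balanced
        if config.chunk_method == "rotatable_balanced"
        else chunking.plan_sequential
    )
    plan = planner(library, config.n_chunks)
    chunks = chunking.split(library, plan)
    chunk_dir = out / "chunks"
    chunk_dir.mkdir(exist_ok=True)
    for k, chunk in enumerate(chunks):
        molecules.write_library(chunk, chunk_dir / f"{config.target_id}_chunk{k}.smi")
    steps.append(
        StepReport(
            name=f"chunking ({plan.method}, {plan.n_chunks} chunks)",
            n_in=len(library),
            n_out=len(library),
            passed_ids=library.ids,
            details=f"chunk sizes: {plan.sizes()}",
        )
    )

    n_workers = config.n_workers or plan.n_chunks
    if config.prepare_ligands:
        prep_cfg = PrepConfig(
            backend=config.prep_backend,
            n_conformers=config.n_conformers,
            seed=derive_seed(config.seed, "prepare"),
        )
        backend = get_backend(config.prep_backend)
        prepared_by_name: dict[str, MoleculeLibrary] = {}

        def _prep_stage(chunk: MoleculeLibrary) -> chunking.StageResult:
            prepped, _rep = prepare_ligands(chunk, prep_cfg, backend)
            prepared_by_name[chunk.name] = prepped
            return chunking.StageResult(
                chunk_index=0,
                payload=pd.DataFrame({"id": prepped.ids}),
                passed_ids=[_parent_id(i) for i in prepped.ids],
            )

        chunking.run_parallel(_prep_stage, chunks, n_workers)
        prepared_chunks = [prepared_by_name[c.name] for c in chunks]
        n_prepared = sum(len(c) for c in prepared_chunks)
        steps.append(
            StepReport(
                name=f"preparation (backend={config.prep_backend}, "
                f"n_conformers={config.n_conformers})",
                n_in=len(library),
                n_out=n_prepared,
                passed_ids=[i for c in prepared_chunks for i in c.ids],
            )
        )
    else:
        prepared_chunks = chunks

    adapters = build_engines(config, planted_scores=planted)
    ranked: dict[str, eng.ScoreTable] = {}
    for adapter in adapters:
        eng_dir = out / "engines" / adapter.name
        eng_dir.mkdir(parents=True, exist_ok=True)

        def _engine_stage(chunk: MoleculeLibrary, _adapter=adapter) -> chunking.StageResult:
            table, failed = eng.run_engine(_adapter, chunk)
            return chunking.StageResult(
                chunk_index=0,
                payload=table.rows[["id", "score"]],
                passed_ids=list(table.rows["id"]),
                failed_ids=failed,
            )

        results = chunking.run_parallel(_engine_stage, prepared_chunks, n_workers)
        merged_rows = chunking.merge(results)
        table = eng.ScoreTable(
            engine=adapter.name,
            direction=adapter.direction,
            rows=merged_rows,
            target=config.target_id,
        )
        table = collapse_to_parents(table)
        table = full_table(table, library.ids)
        table = eng.to_ranks(table)
        table.rows.to_csv(eng_dir / "scores.csv", index=False)
        ranked[adapter.name] = table
        failed = sorted({i for r in results for i in r.failed_ids})
        steps.append(
            StepReport(
                name=f"screening ({adapter.name})",
                n_in=sum(len(c) for c in prepared_chunks),
                n_out=len(merged_rows),
                passed_ids=list(merged_rows["id"]),
                failed_ids=failed,
            )
        )

    consensus = metrics.consensus_ranks(list(ranked.values()), method=config.consensus_method)
    consensus.rows.to_csv(out / "merged" / "consensus.csv", index=False)
    return library, haystack, ranked, consensus, steps


def run_benchmark_mode(config: RunConfig) -> tuple[BenchmarkResult, str]:
    """Benchmarking mode: screen a labeled haystack and score the engines.

    Writes per-engine score tables, a consensus table, a summary CSV
    (metrics/summary.csv), a manifest, and the master report. Reruns with
    identical config and seed produce identical artifacts.
    """
    if config.mode != "benchmark":
        raise ConfigError("run_benchmark_mode requires mode=benchmark")
    out = config.output_dir
    library, haystack, ranked, consensus, steps = _pipeline(config)
    if haystack is None:
        raise ConfigError("benchmark mode requires labeled actives/decoys")

    result = BenchmarkResult(target=config.target_id)
    for name, table in ranked.items():
        result.per_engine[name] = {
            "auc": metrics.roc_auc(table, haystack),
            "ef": {
                frac: metrics.enrichment_factor(table, haystack, frac)
                for frac in config.ef_fractions
            },
        }
    result.consensus = {
        "auc": metrics.roc_auc(consensus, haystack),
        "ef": {
            frac: metrics.enrichment_factor(consensus, haystack, frac)
            for frac in config.ef_fractions
        },
    }
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    summary = metrics.aggregate_summary([result])
    summary.to_csv(metrics_dir / "summary.csv", index=False)
    steps.append(
        StepReport(
            name="metrics",
            n_in=len(haystack),
            n_out=len(summary.columns) - 1,
            details=f"actives={haystack.n_actives} decoys={haystack.n_decoys} "
            f"ef_fractions={config.ef_fractions}",
        )
    )
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2, sort_keys=True))
    report = compile_master_report(steps, out / "master_report.txt")
    return result, report


def run_vs_mode(config: RunConfig) -> tuple[pd.DataFrame, str]:
    """VS mode: rank an unlabeled library and emit a consensus hitlist."""
    if config.mode != "vs":
        raise ConfigError("run_vs_mode requires mode=vs")
    out = config.output_dir
    library, _, ranked, consensus, steps = _pipeline(config)
    hitlist = consensus.rows[["id", "score", "rank"]].rename(columns={"score": "consensus_score"})
    hitlist.to_csv(out / "merged" / "hitlist.csv", index=False)
    steps.append(
        StepReport(name="hitlist", n_in=len(library), n_out=len(hitlist))
    )
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2, sort_keys=True))
    report = compile_master_report(steps, out / "master_report.txt")
    return hitlist, report


def fetch_chembl_actives(
    target_id: str, fixture=None, allow_network: bool = False
) -> MoleculeLibrary:
    """Bioactive molecules for a target, cleaned and sanitized.

    ``fixture`` is a recorded-response JSON (path or dict) with schema
    ``{"target": ..., "molecules": [{"molecule_chembl_id": ..,
    "canonical_smiles": ..}, ...]}``; this is the only path the test suite
    exercises. With ``allow_network=True`` (never the default) the public
    ChEMBL REST API is queried instead.
    """
    if fixture is None:
        if not allow_network:
            raise FetchError("no fixture given and network access not allowed")
        import urllib.error
        import urllib.request

        url = (
            "https://www.ebi.ac.uk/chembl/api/data/molecule.json"
            f"?molecule_chembl_id__in={target_id}"
        )
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                payload = json.loads(resp.read())
        except urllib.error.URLError as exc:
            raise FetchError(f"transport error fetching {target_id!r}: {exc}") from exc
        mols = payload.get("molecules", [])
    else:
        if isinstance(fixture, (str, Path)):
            try:
                fixture = json.loads(Path(fixture).read_text())
            except json.JSONDecodeError as exc:
                raise FetchError(f"malformed fixture for {target_id!r}: {exc}") from exc
        if not isinstance(fixture, dict) or "molecules" not in fixture:
            raise FetchError(f"malformed fixture for {target_id!r}: missing 'molecules'")
        mols = fixture["molecules"]
    records = []
    for i, m in enumerate(mols, start=1):
        if not isinstance(m, dict) or "canonical_smiles" not in m:
            raise FetchError(f"malformed molecule entry {i} for target {target_id!r}")
        records.append(
            MoleculeRecord(
                id=str(m.get("molecule_chembl_id", f"CHEMBL_{i}")),
                smiles=m["canonical_smiles"],
                source=f"chembl:{target_id}",
                data={"activity": m.get("standard_value")},
            )
        )
    if not records:
        raise LibraryError(f"no molecules returned for target {target_id!r}")
    library, _ = molecules.sanitize(MoleculeLibrary(records, name=f"chembl_{target_id}"))
    return library
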
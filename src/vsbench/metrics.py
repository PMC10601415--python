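"""Benchmarking metrics: ROC-AUC, enrichment factors, consensus ranking,
paired method comparison, synthetic haystacks, and summary aggregation.

A labeled haystack is the combined actives + decoys set screened in
benchmarking mode. Ranking quality is measured by:

* **ROC-AUC** — the probability that a randomly chosen active outranks a
  randomly chosen decoy; 1.0 is perfect, 0.5 is random. Computed from the
  Mann-Whitney U statistic with midranks, which equals trapezoidal ROC
  integration for untied scores and stays well-defined with ties:
  ``AUC = (#{active beats decoy} + 0.5 * #ties) / (n_actives * n_decoys)``.
* **EFx%** — the enrichment factor at fraction x: how over-represented
  actives are among the top ``n_top = ceil(x * N)`` ranks relative to the
  whole haystack, ``EF = (a_top / n_top) / (n_actives / N)``. ``EF(1.0) = 1``
  always; the maximum is ``min(N / n_actives, N / n_top)``.

Molecules an engine failed to score are assigned worst rank (scored below
every scored molecule, tied among themselves), so engines are penalized for
failures rather than evaluated on the easy subset.

The synthetic-haystack generator emulates a DUD-E-style target: 224 actives
and 50 decoys per active by default, with planted Gaussian scores — actives
~ N(signal_mu, noise_sd), decoys ~ N(0, noise_sd) — so the expected AUC has
the closed form Phi(signal_mu / (noise_sd * sqrt(2))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engines import HIGHER, LOWER, ScoreTable, to_ranks
from .errors import DegenerateTestError, IntegrityError, UndefinedMetricError
from .molecules import MoleculeLibrary, MoleculeRecord


@dataclass
class LabeledHaystack:
    """Actives + decoys combined into one labeled library."""

    library: MoleculeLibrary

    def __post_init__(self) -> None:
        bad = [r.id for r in self.library if r.label not in ("active", "decoy")]
        if bad:
            raise IntegrityError(f"unlabeled records in haystack: {bad[:5]}")

    @property
    def n_actives(self) -> int:
        return sum(1 for r in self.library if r.label == "active")

    @property
    def n_decoys(self) -> int:
        return sum(1 for r in self.library if r.label == "decoy")

    @property
    def labels(self) -> dict[str, str]:
        return {r.id: r.label for r in self.library}

    def __len__(self) -> int:
        return len(self.library)

    @staticmethod
    def from_actives_decoys(
        actives: MoleculeLibrary, decoys: MoleculeLibrary, name: str = "haystack"
    ) -> "LabeledHaystack":
        from dataclasses import replace

        records = [replace(r, label="active") for r in actives] + [
            replace(r, label="decoy") for r in decoys
        ]
        return LabeledHaystack(MoleculeLibrary(records, name=name))


def _goodness(table: ScoreTable, haystack: LabeledHaystack) -> tuple[np.ndarray, np.ndarray]:
    """Direction-aligned scores over the whole haystack (unscored = -inf).

    Returns (goodness, is_active) aligned to haystack order.
    """
    scores = dict(zip(table.rows["id"], table.rows["score"].astype(float)))
    sign = 1.0 if table.direction == HIGHER else -1.0
    goodness = np.array(
        [sign * scores[r.id] if r.id in scores else -np.inf for r in haystack.library]
    )
    is_active = np.array([r.label == "active" for r in haystack.library])
    return goodness, is_active


def _check_defined(haystack: LabeledHaystack) -> None:
    if haystack.n_actives < 1 or haystack.n_decoys < 1:
        raise UndefinedMetricError(
            f"metric undefined: {haystack.n_actives} actives, {haystack.n_decoys} decoys"
        )


def roc_auc(table: ScoreTable, haystack: LabeledHaystack) -> float:
    """Probability that a random active outranks a random decoy (midrank form)."""
    _check_defined(haystack)
    goodness, is_active = _goodness(table, haystack)
    n_act, n_dec = int(is_active.sum()), int((~is_active).sum())
    ranks = stats.rankdata(goodness)  # ascending midranks; ties share the mean rank
    rank_sum = ranks[is_active].sum()
    u = rank_sum - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_dec))


def top_fraction_ids(table: ScoreTable, haystack: LabeledHaystack, fraction: float) -> list[str]:
    """Ids of the best ceil(fraction*N) molecules under deterministic ranking.

    Unscored molecules sort after all scored ones; ties (including the
    unscored block) break by id ascending, matching the ranking tie-break.
    """
    if not 0 < fraction <= 1:
        raise UndefinedMetricError(f"fraction must be in (0, 1], got {fraction}")
    goodness, _ = _goodness(table, haystack)
    ids = [r.id for r in haystack.library]
    order = sorted(range(len(ids)), key=lambda i: (-goodness[i], ids[i]))
    n_top = math.ceil(fraction * len(ids))
    return [ids[i] for i in order[:n_top]]


def enrichment_factor(
    table: ScoreTable,
    haystack: LabeledHaystack,
    fraction: float = 0.01,
    literal_odds_ratio: bool = False,
) -> float:
    """Enrichment factor at the given top fraction.

    Standard form ``(a_top/n_top) / (n_actives/N)``. With
    ``literal_odds_ratio=True`` the active:decoy odds in the top fraction are
    divided by the whole-haystack odds instead (an alternative reading of
    "ratio of actives versus decoys"); undefined when the top fraction
    contains no decoys.
    """
    _check_defined(haystack)
    labels = haystack.labels
    top = top_fraction_ids(table, haystack, fraction)
    a_top = sum(1 for i in top if labels[i] == "active")
    n_top = len(top)
    n_total = len(haystack)
    if literal_odds_ratio:
        d_top = n_top - a_top
        if d_top == 0:
            raise UndefinedMetricError("odds-ratio EF undefined: no decoys in top fraction")
        return (a_top / d_top) / (haystack.n_actives / haystack.n_decoys)
    return (a_top / n_top) / (haystack.n_actives / n_total)


def consensus_ranks(tables: Sequence[ScoreTable], method: str = "rank_sum") -> ScoreTable:
    """Fuse rankings from several engines into one consensus ordering.

    ``best_rank``: consensus score of a molecule is its best (minimum) rank
    over the engines. ``rank_sum``: the sum of its ranks. Both are
    lower-is-better; the fused table is re-ranked with the standard id
    tie-break. All input tables must cover the same id set.
    """
    if not tables:
        raise IntegrityError("consensus requires at least one score table")
    if method not in ("best_rank", "rank_sum"):
        raise IntegrityError(f"unknown consensus method {method!r}")
    ranked = [t if "rank" in t.rows.columns else to_ranks(t) for t in tables]
    id_sets = [t.ids for t in ranked]
    if any(s != id_sets[0] for s in id_sets[1:]):
        raise IntegrityError("consensus requires identical id sets across engines")
    matrix = pd.concat(
        [t.rows.set_index("id")["rank"].rename(t.engine) for t in ranked], axis=1
    )
    fused = matrix.min(axis=1) if method == "best_rank" else matrix.sum(axis=1)
    rows = pd.DataFrame({"id": fused.index, "score": fused.values.astype(float)})
    table = ScoreTable(
        engine=f"consensus_{method}",
        direction=LOWER,
        rows=rows.reset_index(drop=True),
        target=ranked[0].target,
    )
    return to_ranks(table)


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic DUD-E-style benchmark target.

    Defaults mirror the composition of an average DUD-E target: 224 actives
    with 50 property-matched decoys each. ``signal_mu`` is the mean score
    shift of actives over decoys in noise-SD units of the planted Gaussian
    scores; 0 means no signal (expected AUC 0.5).
    """

    n_actives: int = 224
    decoys_per_active: int = 50
    signal_mu: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.decoys_per_active < 1:
            raise IntegrityError("counts must be >= 1")
        if self.noise_sd <= 0:
            raise IntegrityError("noise_sd must be > 0")

    @property
    def expected_auc(self) -> float:
        """Closed form for two Gaussians: Phi(mu / (sd * sqrt(2)))."""
        return float(stats.norm.cdf(self.signal_mu / (self.noise_sd * math.sqrt(2))))


def _synthetic_smiles(index: int, width: int = 17) -> str:
    """Unique, valid, reversal-safe linear-chain SMILES for record ``index``.

    The chain is N-terminated at one end and S-terminated at the other, with
    a {C,O} body encoding the index in binary, so no two indices collapse to
    the same canonical structure (a plain chain could match its own reversal).
    Chemistry is irrelevant here: the molecules only have to be valid and
    distinct so that format round-trips and sanitization behave.
    """
    body = "".join("O" if (index >> b) & 1 else "C" for b in range(width))
    return "N" + body + "S"


def generate_synthetic_haystack(spec: SyntheticSpec) -> tuple[LabeledHaystack, ScoreTable]:
    """Generate a labeled haystack plus a planted score table.

    Active scores ~ N(signal_mu, noise_sd); decoy scores ~ N(0, noise_sd),
    higher is better. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_dec = spec.n_actives * spec.decoys_per_active
    act_scores = rng.normal(spec.signal_mu, spec.noise_sd, size=spec.n_actives)
    dec_scores = rng.normal(0.0, spec.noise_sd, size=n_dec)
    records: list[MoleculeRecord] = []
    ids: list[str] = []
    for i in range(spec.n_actives):
        rec_id = f"act{i:05d}"
        smi = _synthetic_smiles(i)
        records.append(
            MoleculeRecord(id=rec_id, smiles=smi, label="active", source="synthetic")
        )
        ids.append(rec_id)
    for j in range(n_dec):
        rec_id = f"dec{j:06d}"
        smi = _synthetic_smiles(spec.n_actives + j)
        records.append(
            MoleculeRecord(id=rec_id, smiles=smi, label="decoy", source="synthetic")
        )
        ids.append(rec_id)
    haystack = LabeledHaystack(MoleculeLibrary(records, name="synthetic_haystack"))
    scores = np.concatenate([act_scores, dec_scores])
    table = ScoreTable(
        engine="planted",
        direction=HIGHER,
        rows=pd.DataFrame({"id": ids, "score": scores}),
        target="synthetic",
    )
    return haystack, table


def compare_methods_paired_ttest(
    metric_a: Sequence[float], metric_b: Sequence[float]
) -> tuple[float, float]:
    """Paired two-tailed t-test on per-target metric differences.

    Returns (t statistic, two-sided p). Raises
    :class:`DegenerateTestError` when the differences have zero variance
    (identical vectors, or a constant shift), where t is undefined.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise IntegrityError("paired test requires two equal-length vectors")
    if len(a) < 3:
        raise IntegrityError("paired test requires at least 3 pairs")
    diffs = a - b
    # relative tolerance: a constant shift of two float vectors leaves
    # rounding noise ~1e-16 in the differences
    scale = max(1.0, float(np.max(np.abs(diffs))))
    if float(np.std(diffs)) <= 1e-12 * scale:
        raise DegenerateTestError("zero variance of paired differences; t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class BenchmarkResult:
    """Per-target metrics: one (AUC, EF-per-fraction) pair per engine plus
    the consensus pair. Reporting precision: AUC 2 decimals, EF 1 decimal."""

    target: str
    per_engine: dict[str, dict] = field(default_factory=dict)  # engine -> {auc, ef: {frac: v}}
    consensus: dict = field(default_factory=dict)

    def engines(self) -> list[str]:
        return list(self.per_engine)


def round_auc(value: float) -> float:
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def round_ef(value: float) -> float:
    return float(Decimal(repr(float(value))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def format_metric(value: float, kind: str) -> str:
    """Render a metric at reporting precision; exact integers drop the '.0'."""
    rounded = round_auc(value) if kind == "auc" else round_ef(value)
    if kind == "ef" and rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.2f}" if kind == "auc" else f"{rounded:.1f}"


def aggregate_summary(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Per-target metric table with an ``average`` row, one column per
    engine x metric, rounded at reporting precision (AUC 2 dp, EF 1 dp)."""
    if not results:
        raise IntegrityError("no benchmark results to aggregate")
    engines = results[0].engines()
    fractions = sorted(results[0].per_engine[engines[0]]["ef"]) if engines else []
    rows = []
    for res in results:
        row: dict[str, object] = {"target": res.target}
        for eng in engines:
            row[f"auc_{eng}"] = res.per_engine[eng]["auc"]
            for frac in fractions:
                row[f"ef{frac * 100:g}_{eng}"] = res.per_engine[eng]["ef"][frac]
        if res.consensus:
            row["auc_consensus"] = res.consensus["auc"]
            for frac in fractions:
                row[f"ef{frac * 100:g}_consensus"] = res.consensus["ef"][frac]
        rows.append(row)
    frame = pd.DataFrame(rows)
    means = {"target": "average"}
    for col in frame.columns:
        if col == "target":
            continue
        means[col] = float(frame[col].mean())
    frame = pd.concat([frame, pd.DataFrame([means])], ignore_index=True)
    for col in frame.columns:
        if col.startswith("auc_"):
            frame[col] = frame[col].map(round_auc)
        elif col.startswith("ef"):
            frame[col] = frame[col].map(round_ef)
    return frame


def column_average(values: Sequence[float], kind: str) -> float:
    """Arithmetic mean rounded at reporting precision (the 'average' row rule)."""
    mean = float(np.mean(np.asarray(values, dtype=float)))
    return round_auc(mean) if kind == "auc" else round_ef(mean)
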
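"""Benchmark metrics: AUC/EF against oracles, consensus, t-test, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vsbench.engines import HIGHER, LOWER, ScoreTable, to_ranks
from vsbench.errors import DegenerateTestError, IntegrityError, UndefinedMetricError
from vsbench.metrics import (
    BenchmarkResult,
    SyntheticSpec,
    aggregate_summary,
    column_average,
    compare_methods_paired_ttest,
    consensus_ranks,
    enrichment_factor,
    format_metric,
    generate_synthetic_haystack,
    roc_auc,
)

from conftest import labeled_haystack, score_table


def brute_force_auc(scores: dict, labels: dict) -> float:
    """All-pairs oracle: fraction of active-decoy pairs won (+ half the ties)."""
    actives = [scores[i] for i in scores if labels[i] == "active"]
    decoys = [scores[i] for i in scores if labels[i] == "decoy"]
    wins = sum(
        1.0 if a > d else (0.5 if a == d else 0.0) for a in actives for d in decoys
    )
    return wins / (len(actives) * len(decoys))


def counting_ef(scores: dict, labels: dict, fraction: float) -> float:
    """Direct-counting oracle for the enrichment factor (deterministic ties)."""
    n = len(scores)
    n_top = math.ceil(fraction * n)
    order = sorted(scores, key=lambda i: (-scores[i], i))
    a_top = sum(1 for i in order[:n_top] if labels[i] == "active")
    n_act = sum(1 for l in labels.values() if l == "active")
    return (a_top / n_top) / (n_act / n)


def random_instance(rng, n_max=200):
    """Random labeled instance with ties and possible unscored molecules."""
    n = int(rng.integers(5, n_max + 1))
    n_act = int(rng.integers(1, n))
    labels = {}
    scores = {}
    for i in range(n):
        rec_id = f"m{i:04d}"
        labels[rec_id] = "active" if i < n_act else "decoy"
        # coarse grid => frequent ties
        scores[rec_id] = float(np.round(rng.random(), 2))
    return scores, labels


def as_metric_inputs(scores, labels):
    hay = labeled_haystack(
        ["A" if labels[i] == "active" else "D" for i in sorted(labels)], ids=sorted(labels)
    )
    return score_table(scores), hay


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        table = score_table({"a1": 3.0, "a2": 2.5, "d1": 1.0, "d2": 0.5})
        hay = labeled_haystack("AADD", ids=["a1", "a2", "d1", "d2"])
        assert roc_auc(table, hay) == 1.0

    def test_alternating_ranks_adad(self):
        # ranks 1..4 labeled A,D,A,D: 3 of 4 pairs favor the active -> 0.75
        table = score_table({"a1": 4.0, "d1": 3.0, "a2": 2.0, "d2": 1.0})
        hay = labeled_haystack("ADAD", ids=["a1", "d1", "a2", "d2"])
        assert roc_auc(table, hay) == 0.75

    def test_all_tied_is_half(self):
        table = score_table({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        hay = labeled_haystack("ADAD", ids=["a", "b", "c", "d"])
        assert roc_auc(table, hay) == 0.5

    def test_zero_class_raises(self):
        table = score_table({"a": 1.0, "b": 0.5})
        with pytest.raises(UndefinedMetricError):
            roc_auc(table, labeled_haystack("AA", ids=["a", "b"]))

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(100):
            scores, labels = random_instance(rng)
            table, hay = as_metric_inputs(scores, labels)
            assert roc_auc(table, hay) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores, labels = random_instance(rng)
            table, hay = as_metric_inputs(scores, labels)
            y = [1 if labels[i] == "active" else 0 for i in sorted(labels)]
            s = [scores[i] for i in sorted(labels)]
            assert roc_auc(table, hay) == pytest.approx(
                float(sklearn_metrics.roc_auc_score(y, s)), abs=1e-12
            )

    def test_monotone_invariance_and_reversal(self, rng):
        scores, labels = random_instance(rng)
        table, hay = as_metric_inputs(scores, labels)
        warped = score_table({k: math.exp(2 * v) for k, v in scores.items()})
        assert roc_auc(warped, hay) == pytest.approx(roc_auc(table, hay))
        reversed_ = score_table({k: -v for k, v in scores.items()})
        assert roc_auc(reversed_, hay) == pytest.approx(1.0 - roc_auc(table, hay))

    def test_lower_is_better_direction_respected(self):
        table = score_table({"a": -9.0, "d": -1.0}, direction=LOWER)
        hay = labeled_haystack("AD", ids=["a", "d"])
        assert roc_auc(table, hay) == 1.0

    def test_unscored_molecules_rank_worst(self):
        # the unscored active loses every pairing it is in
        table = score_table({"a1": 2.0, "d1": 1.0})
        hay = labeled_haystack("ADA", ids=["a1", "d1", "a2"])
        assert roc_auc(table, hay) == pytest.approx(0.5)  # (1 win + 0) / 2


class TestEnrichmentFactor:
    def test_direct_counting_example(self):
        # N=200, 4 actives, both top-1% slots active -> EF = (2/2)/(4/200) = 50
        labels = "AADD" + "A" * 2 + "D" * 194
        ids = [f"m{i:03d}" for i in range(200)]
        scores = {i: 200.0 - k for k, i in enumerate(ids)}
        hay = labeled_haystack(labels[:200], ids=ids)
        # top two scored ids are actives by construction
        assert enrichment_factor(score_table(scores), hay, 0.01) == 50.0

    def test_whole_set_fraction_is_exactly_one(self, rng):
        scores, labels = random_instance(rng)
        table, hay = as_metric_inputs(scores, labels)
        assert enrichment_factor(table, hay, 1.0) == 1.0

    def test_no_actives_in_top_gives_zero(self):
        table = score_table({"d1": 9.0, "d2": 8.0, "a1": 1.0, "a2": 0.5})
        hay = labeled_haystack("DDAA", ids=["d1", "d2", "a1", "a2"])
        assert enrichment_factor(table, hay, 0.5) == 0.0

    def test_matches_counting_oracle_on_random_instances(self, rng):
        for _ in range(100):
            scores, labels = random_instance(rng)
            fraction = float(rng.choice([0.01, 0.05, 0.1, 0.25, 1.0]))
            table, hay = as_metric_inputs(scores, labels)
            assert enrichment_factor(table, hay, fraction) == pytest.approx(
                counting_ef(scores, labels, fraction)
            )

    def test_bounds(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            table, hay = as_metric_inputs(scores, labels)
            n = len(scores)
            fraction = float(rng.choice([0.01, 0.1, 0.5]))
            ef = enrichment_factor(table, hay, fraction)
            n_top = math.ceil(fraction * n)
            assert 0 <= ef <= min(n / n_top, n / hay.n_actives) + 1e-9

    def test_literal_odds_ratio_variant(self):
        table = score_table({"a": 4.0, "d1": 3.0, "d2": 2.0, "d3": 1.0})
        hay = labeled_haystack("ADDD", ids=["a", "d1", "d2", "d3"])
        # top half: 1 active, 1 decoy -> odds 1; haystack odds 1/3 -> EF_odds 3
        assert enrichment_factor(table, hay, 0.5, literal_odds_ratio=True) == 3.0

    def test_invalid_fraction(self):
        table = score_table({"a": 1.0, "d": 0.0})
        hay = labeled_haystack("AD", ids=["a", "d"])
        with pytest.raises(UndefinedMetricError):
            enrichment_factor(table, hay, 0.0)


class TestConsensus:
    def test_single_table_identity(self, rng):
        scores = {f"m{i}": float(s) for i, s in enumerate(rng.random(10))}
        table = to_ranks(score_table(scores))
        fused = consensus_ranks([table], method="rank_sum")
        assert list(fused.rows["id"]) == list(table.rows["id"])

    def test_best_rank_takes_min(self):
        t1 = to_ranks(score_table({"x": 9.0, "y": 1.0}))
        t2 = to_ranks(score_table({"x": 1.0, "y": 9.0}))
        fused = consensus_ranks([t1, t2], method="best_rank")
        assert dict(zip(fused.rows["id"], fused.rows["score"])) == {"x": 1.0, "y": 1.0}

    def test_fully_reversed_rank_sum_all_tie(self):
        ids = ["a", "b", "c", "d"]
        t1 = to_ranks(score_table({i: float(4 - k) for k, i in enumerate(ids)}))
        t2 = to_ranks(score_table({i: float(k) for k, i in enumerate(ids)}))
        fused = consensus_ranks([t1, t2], method="rank_sum")
        assert set(fused.rows["score"]) == {5.0}  # n+1 everywhere
        assert list(fused.rows.sort_values("rank")["id"]) == ids  # tie-break by id

    def test_identical_tables_reproduce_ordering(self, rng):
        scores = {f"m{i}": float(s) for i, s in enumerate(rng.random(15))}
        tables = [to_ranks(score_table(scores)) for _ in range(3)]
        for method in ("best_rank", "rank_sum"):
            fused = consensus_ranks(tables, method=method)
            assert list(fused.rows.sort_values("rank")["id"]) == list(
                tables[0].rows.sort_values("rank")["id"]
            )

    def test_id_mismatch_rejected(self):
        t1 = to_ranks(score_table({"a": 1.0, "b": 0.5}))
        t2 = to_ranks(score_table({"a": 1.0, "c": 0.5}))
        with pytest.raises(IntegrityError):
            consensus_ranks([t1, t2])


class TestSyntheticHaystack:
    def test_default_composition(self):
        spec = SyntheticSpec(seed=1)
        hay, table = generate_synthetic_haystack(spec)
        assert hay.n_actives == 224
        assert hay.n_decoys == 224 * 50
        assert len(table.rows) == len(hay)

    def test_reproducible_from_seed(self):
        a = generate_synthetic_haystack(SyntheticSpec(n_actives=10, decoys_per_active=3, seed=9))
        b = generate_synthetic_haystack(SyntheticSpec(n_actives=10, decoys_per_active=3, seed=9))
        assert a[1].rows.equals(b[1].rows)
        assert a[0].library.ids == b[0].library.ids

    def test_structures_unique_and_parsable(self):
        from rdkit import Chem

        hay, _ = generate_synthetic_haystack(
            SyntheticSpec(n_actives=30, decoys_per_active=2, seed=0)
        )
        canon = [Chem.CanonSmiles(r.smiles) for r in hay.library]
        assert len(set(canon)) == len(canon)

    def test_no_signal_gives_half_auc(self):
        aucs = []
        for rep in range(20):
            spec = SyntheticSpec(
                n_actives=50, decoys_per_active=10, signal_mu=0.0, seed=100 + rep
            )
            hay, table = generate_synthetic_haystack(spec)
            aucs.append(roc_auc(table, hay))
        se = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3

    def test_closed_form_auc_recovery_small(self):
        spec = SyntheticSpec(n_actives=100, decoys_per_active=20, signal_mu=2.0, seed=4)
        aucs = []
        for rep in range(25):
            hay, table = generate_synthetic_haystack(
                SyntheticSpec(n_actives=100, decoys_per_active=20, signal_mu=2.0, seed=rep)
            )
            aucs.append(roc_auc(table, hay))
        expected = stats.norm.cdf(2.0 / math.sqrt(2))
        se = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - expected) < 3 * se + 1e-3


class TestPairedTTest:
    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_methods_paired_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_methods_paired_ttest([0.7, 0.8, 0.9], [0.6, 0.7, 0.8])

    def test_matches_scipy(self, rng):
        a, b = rng.random(8), rng.random(8)
        t, p = compare_methods_paired_ttest(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert (t, p) == (pytest.approx(float(t_ref)), pytest.approx(float(p_ref)))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(IntegrityError):
            compare_methods_paired_ttest([1.0, 2.0], [0.5, 1.5])


class TestAggregation:
    def _result(self, target, auc, ef):
        return BenchmarkResult(
            target=target, per_engine={"toy": {"auc": auc, "ef": {0.01: ef}}}
        )

    def test_single_result_average_equals_itself(self):
        frame = aggregate_summary([self._result("t1", 0.7312, 12.34)])
        assert list(frame["target"]) == ["t1", "average"]
        assert frame["auc_toy"].tolist() == [0.73, 0.73]
        assert frame["ef1_toy"].tolist() == [12.3, 12.3]

    def test_average_row_is_column_mean_at_precision(self):
        results = [self._result(f"t{i}", auc, ef) for i, (auc, ef) in enumerate(
            [(0.61, 6.4), (0.67, 2.3), (0.74, 39.7)]
        )]
        frame = aggregate_summary(results)
        avg = frame[frame["target"] == "average"].iloc[0]
        assert avg["auc_toy"] == pytest.approx(round((0.61 + 0.67 + 0.74) / 3, 2))
        assert avg["ef1_toy"] == pytest.approx(round((6.4 + 2.3 + 39.7) / 3, 1))

    def test_format_drops_trailing_zero_for_integral_ef(self):
        assert format_metric(19.04, "ef") == "19"
        assert format_metric(18.45, "ef") == "18.5"
        assert format_metric(0.738, "auc") == "0.74"

    def test_column_average_rounding(self):
        assert column_average([0.61, 0.67, 0.74, 0.87, 0.67, 0.69, 0.63], "auc") == 0.70
        assert column_average([7.8, 6.4, 43.4, 22.96, 23.9, 15, 13.9], "ef") == 19.1
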
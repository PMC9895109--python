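import numpy as np
import pytest

from pgagp import AssociationTable, NodeIndex, cross_validate
from pgagp.errors import ValidationError
from pgagp.evaluate import (
    aggregate,
    evaluate_predictions,
    kfold_split,
    ranking_metrics,
    temporal_split,
)
from pgagp.predict import RankedPrediction


def brute_force_auroc(y_true, y_score):
    """Pairwise positive-negative comparison with half credit for ties."""
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_auprc(y_true, y_score):
    """Threshold sweep: AP = sum (R_n - R_{n-1}) P_n over unique score cuts."""
    thresholds = np.unique(y_score)[::-1]
    n_pos = y_true.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        predicted = y_score >= t
        tp = int((y_true[predicted] == 1).sum())
        precision = tp / predicted.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def _ranked(labels, scores, disease="dX"):
    return RankedPrediction(
        disease=disease, genes=list(zip(labels, map(float, scores)))
    )


def _table(matrix):
    n_d, n_g = matrix.shape
    return AssociationTable(
        np.asarray(matrix, dtype=float),
        NodeIndex([f"d{i}" for i in range(n_d)]),
        NodeIndex([f"g{j}" for j in range(n_g)]),
    )


class TestKfoldSplit:
    def test_equal_fold_sizes(self):
        R = _table(np.eye(10)[:, :10])
        splits = kfold_split(R, k=5, seed=0)
        assert [s.test.n_associations for s in splits] == [2] * 5

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        R = _table((rng.random((6, 9)) < 0.4).astype(float))
        splits = kfold_split(R, k=4, seed=3)
        union = sum(s.test.matrix for s in splits)
        np.testing.assert_array_equal(union, R.matrix)  # disjoint + exhaustive
        for s in splits:
            np.testing.assert_array_equal(s.train.matrix + s.test.matrix, R.matrix)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        R = _table((rng.random((5, 8)) < 0.5).astype(float))
        a = kfold_split(R, k=3, seed=11)
        b = kfold_split(R, k=3, seed=11)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.test.matrix, sb.test.matrix)

    def test_too_few_associations_rejected(self):
        R = _table(np.array([[1.0, 1.0]]))
        with pytest.raises(ValidationError):
            kfold_split(R, k=5, seed=0)


class TestTemporalSplit:
    def test_disjoint_tables_pass_through(self):
        train = _table(np.array([[1.0, 0.0], [0.0, 0.0]]))
        test = _table(np.array([[0.0, 1.0], [0.0, 0.0]]))
        split = temporal_split(train, test)
        np.testing.assert_array_equal(split.test.matrix, test.matrix)

    def test_overlap_removed_with_warning(self, caplog):
        train = _table(np.array([[1.0, 0.0]]))
        test = _table(np.array([[1.0, 1.0]]))  # (d0,g0) overlaps train
        with caplog.at_level("WARNING"):
            split = temporal_split(train, test)
        assert split.test.n_associations == 1
        assert split.test.matrix[0, 1] == 1.0
        assert any("overlapping" in rec.message for rec in caplog.records)

    def test_empty_test_after_overlap_is_error(self):
        train = _table(np.array([[1.0, 1.0]]))
        test = _table(np.array([[1.0, 1.0]]))
        with pytest.raises(ValidationError):
            temporal_split(train, test)

    def test_empty_train_permitted_cold_start(self, caplog):
        train = _table(np.array([[1.0, 0.0]]))
        train.matrix[0, 0] = 0.0
        test = _table(np.array([[0.0, 1.0]]))
        with caplog.at_level("WARNING"):
            split = temporal_split(train, test)
        assert split.test.n_associations == 1


class TestRankingMetrics:
    def test_perfect_ranking_all_ones(self):
        labels = [f"g{i}" for i in range(20)]
        scores = np.linspace(1.0, 0.0, 20)
        rec = ranking_metrics(_ranked(labels, scores), set(labels[:10]))
        assert rec["auroc"] == 1.0
        assert rec["auprc"] == pytest.approx(1.0)
        assert rec["precision@10"] == 1.0
        assert rec["recall@10"] == 1.0

    def test_single_midpoint_positive_gives_half_auroc(self):
        # one positive exactly in the middle of 2m+1 candidates
        m = 5
        labels = [f"g{i}" for i in range(2 * m + 1)]
        scores = np.linspace(1.0, 0.0, 2 * m + 1)
        rec = ranking_metrics(_ranked(labels, scores), {labels[m]})
        assert rec["auroc"] == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_threshold_sweep_oracles(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(10, 50))
        labels = [f"g{i}" for i in range(n)]
        scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
        n_pos = int(rng.integers(1, n))
        positives = set(rng.choice(labels, size=n_pos, replace=False))
        order = np.argsort(-scores, kind="stable")
        pred = _ranked([labels[i] for i in order], scores[order])
        rec = ranking_metrics(pred, positives)
        y_true = np.array([1 if labels[i] in positives else 0 for i in order])
        y_score = scores[order]
        if 0 < y_true.sum() < y_true.size:
            assert rec["auroc"] == pytest.approx(
                brute_force_auroc(y_true, y_score), abs=1e-12
            )
        assert rec["auprc"] == pytest.approx(
            brute_force_auprc(y_true, y_score), abs=1e-12
        )
        for k in (1, 5, 10):
            top = [labels[i] for i in order[:k]]
            hits = sum(g in positives for g in top)
            assert rec[f"precision@{k}"] == pytest.approx(hits / k)
            assert rec[f"recall@{k}"] == pytest.approx(hits / n_pos)

    def test_random_scorer_auroc_concentrates_near_half(self):
        rng = np.random.default_rng(99)
        labels = [f"g{i}" for i in range(50)]
        positives = set(labels[:10])
        aurocs = []
        for _ in range(200):
            scores = rng.random(50)
            order = np.argsort(-scores, kind="stable")
            pred = _ranked([labels[i] for i in order], scores[order])
            aurocs.append(ranking_metrics(pred, positives)["auroc"])
        # std of AUROC for 10 pos / 40 neg is ~0.103; 95% band for the mean
        se = 0.103 / np.sqrt(200)
        assert abs(np.mean(aurocs) - 0.5) < 1.96 * se * 1.5

    def test_no_test_genes_rejected(self):
        pred = _ranked(["g0", "g1"], [0.5, 0.1])
        with pytest.raises(ValidationError):
            ranking_metrics(pred, {"gX"})


class TestAggregate:
    def test_single_record_is_identity(self):
        labels = [f"g{i}" for i in range(20)]
        rec = ranking_metrics(
            _ranked(labels, np.linspace(1, 0, 20)), set(labels[:3])
        )
        report = aggregate([rec])
        assert report.auroc == rec["auroc"]
        assert report.auprc == rec["auprc"]

    def test_macro_mean_of_two_diseases(self):
        labels = [f"g{i}" for i in range(20)]
        perfect = ranking_metrics(
            _ranked(labels, np.linspace(1, 0, 20), "dA"), set(labels[:2])
        )
        # single positive in the middle -> AUROC 0.5
        mid = ranking_metrics(
            _ranked(labels[:11], np.linspace(1, 0, 11), "dB"), {labels[5]}
        )
        report = aggregate([perfect, mid])
        assert report.auroc == pytest.approx((1.0 + 0.5) / 2)

    def test_pooled_association_precision_hand_count(self):
        # 3 diseases, top-2 lists, 2 total hits in 6 pooled predictions
        records = [
            # d0: positive gA ranked first -> 1 hit in top-2
            ranking_metrics(_ranked(["gA", "gB"], [0.9, 0.1], "d0"), {"gA"}, ks=(2,)),
            # d1: positive gB ranked second -> 1 hit in top-2
            ranking_metrics(_ranked(["gA", "gB"], [0.9, 0.1], "d1"), {"gB"}, ks=(2,)),
            # d2: positive gC ranked third -> 0 hits in top-2
            ranking_metrics(
                _ranked(["gA", "gB", "gC"], [0.9, 0.5, 0.1], "d2"), {"gC"}, ks=(2,)
            ),
        ]
        report = aggregate(records, ks=(2,), ap_k=2)
        assert report.ap == pytest.approx(2 / 6)

    def test_recall_monotone_in_k(self, fixture_network):
        h = fixture_network.network
        report = cross_validate(h, strategy="original", k_folds=3, seed=0)
        at_k = report.at_k.set_index("k")["recall"]
        assert at_k.loc[1] <= at_k.loc[5] <= at_k.loc[10]


class TestEvaluatePredictions:
    def test_perfect_oracle_scores_give_perfect_metrics(self):
        labels = [f"g{i}" for i in range(30)]
        positives = {"dQ": set(labels[:12])}
        scores = np.linspace(1, 0, 30)
        report = evaluate_predictions(
            [_ranked(labels, scores, "dQ")], positives
        )
        assert report.auroc == 1.0
        assert report.auprc == pytest.approx(1.0)
        assert report.precision == 1.0  # precision@10 with 12 positives on top

    def test_diseases_without_candidates_skipped(self):
        labels = ["g0", "g1"]
        preds = [
            _ranked(labels, [0.9, 0.1], "dA"),
            _ranked(labels, [0.9, 0.1], "dB"),
        ]
        report = evaluate_predictions(preds, {"dA": {"g0"}, "dB": {"gX"}})
        assert len(report.per_disease) == 1


class TestCrossValidate:
    def test_reproducible_end_to_end(self, fixture_network):
        h = fixture_network.network
        a = cross_validate(h, strategy="original", k_folds=3, seed=4)
        b = cross_validate(h, strategy="original", k_folds=3, seed=4)
        assert a.auroc == b.auroc
        assert a.ap == b.ap

    def test_embedding_strategy_runs_and_reports(self, fixture_network):
        h = fixture_network.network
        report = cross_validate(h, strategy="CSim", k_folds=3, seed=0)
        assert 0 <= report.auroc <= 1
        assert 0 <= report.ap <= 1
        assert {"auroc", "auprc", "precision@10"} <= set(
            report.per_disease.columns
        )
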
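"""Ranking evaluation: k-fold cross-validation, train/test splits and metrics.

Association pairs (not diseases) are split into folds, so a disease can
contribute seed genes to training and held-out genes to testing — the
seed-based prioritization setting.  Per test disease the full ranked
candidate list is scored with AUROC and AUPRC (held-out genes as
positives, all other ranked candidates as negatives) plus
precision/recall/F1 at top-k cutoffs; per-disease records are
macro-averaged, and Association Precision (AP) is the micro-averaged
precision of the pooled top-k predictions across all test diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .agp import EmbeddingConfig
from .errors import ValidationError
from .net_io import AssociationTable, HeterogeneousNetwork
from .predict import RankedPrediction, predict
from .propagate import PropagationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "EvaluationReport",
    "kfold_split",
    "temporal_split",
    "ranking_metrics",
    "aggregate",
    "evaluate_predictions",
    "cross_validate",
]

DEFAULT_KS = (1, 5, 10)
#: cutoff at which headline precision/recall/F1 and AP are reported
HEADLINE_K = 10


@dataclass
class FoldSplit:
    """One train/test partition of the association pairs."""

    train: AssociationTable
    test: AssociationTable
    fold_id: int = 0
    seed: int = 0


@dataclass
class EvaluationReport:
    """Aggregate ranking metrics plus the per-disease records behind them."""

    auroc: float
    auprc: float
    at_k: pd.DataFrame  # columns: k, precision, recall, f1 (macro averages)
    ap: float
    per_disease: pd.DataFrame
    mode: str = "macro"

    @property
    def precision(self) -> float:
        return float(self.at_k.set_index("k").loc[HEADLINE_K, "precision"])

    @property
    def recall(self) -> float:
        return float(self.at_k.set_index("k").loc[HEADLINE_K, "recall"])

    @property
    def f1(self) -> float:
        return float(self.at_k.set_index("k").loc[HEADLINE_K, "f1"])

    def summary(self) -> str:
        lines = [
            f"Ranking evaluation ({self.mode} over {len(self.per_disease)} disease records)",
            f"  AUROC : {self.auroc:.4f}",
            f"  AUPRC : {self.auprc:.4f}",
            f"  AP    : {self.ap:.4f} (pooled top-{HEADLINE_K})",
        ]
        for _, row in self.at_k.iterrows():
            lines.append(
                f"  @k={int(row['k']):<3d} precision {row['precision']:.4f}  "
                f"recall {row['recall']:.4f}  F1 {row['f1']:.4f}"
            )
        return "\n".join(lines)


def kfold_split(R: AssociationTable, k: int, seed: int) -> list[FoldSplit]:
    """Shuffle association pairs and partition them into k near-equal folds."""
    if k < 2:
        raise ValidationError(f"need k >= 2 folds, got {k}")
    di, gi = np.nonzero(R.matrix)
    n = di.size
    if n < k:
        raise ValidationError(f"only {n} associations for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    splits = []
    for fold_id, test_idx in enumerate(folds):
        test_m = np.zeros_like(R.matrix)
        test_m[di[test_idx], gi[test_idx]] = 1.0
        train_m = R.matrix - test_m
        splits.append(
            FoldSplit(
                train=AssociationTable(train_m, R.disease_index, R.gene_index),
                test=AssociationTable(test_m, R.disease_index, R.gene_index),
                fold_id=fold_id,
                seed=seed,
            )
        )
    return splits


def temporal_split(
    R_train: AssociationTable, R_test: AssociationTable
) -> FoldSplit:
    """Wrap externally dated train/test tables (e.g. before/after a cutoff year).

    Pairs present in both tables are removed from the test side with a
    warning; dating itself is the caller's responsibility.
    """
    if R_train.disease_index != R_test.disease_index or (
        R_train.gene_index != R_test.gene_index
    ):
        raise ValidationError("train and test tables must share node indices")
    overlap = (R_train.matrix > 0) & (R_test.matrix > 0)
    n_overlap = int(overlap.sum())
    test_m = R_test.matrix.copy()
    if n_overlap:
        logger.warning("removed %d overlapping pair(s) from the test set", n_overlap)
        test_m[overlap] = 0.0
    if not test_m.any():
        raise ValidationError("test set empty after overlap removal")
    if not R_train.matrix.any():
        logger.warning("training set is empty (cold-start evaluation)")
    return FoldSplit(
        train=R_train,
        test=AssociationTable(test_m, R_test.disease_index, R_test.gene_index),
    )


def _precision_recall_at_k(
    ranked_labels: list[str], positives: set[str], k: int
) -> tuple[float, float, float, int]:
    top = ranked_labels[:k]
    hits = sum(1 for g in top if g in positives)
    precision = hits / k if k else 0.0
    recall = hits / len(positives)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1, hits


def ranking_metrics(
    prediction: RankedPrediction,
    test_genes: set[str],
    ks: tuple[int, ...] = DEFAULT_KS,
) -> dict:
    """Per-disease ranking metrics against a held-out positive gene set.

    Positives are the test genes present in the candidate list; every
    other ranked candidate counts as negative.  AUROC/AUPRC use the
    raw scores (tie-aware); top-k metrics use the deterministic ranked
    order.
    """
    labels = prediction.labels
    positives = test_genes & set(labels)
    if not positives:
        raise ValidationError(
            f"disease {prediction.disease!r} has no test genes among its candidates"
        )
    y_true = np.array([1 if g in positives else 0 for g in labels])
    y_score = prediction.scores
    record: dict = {
        "disease": prediction.disease,
        "n_candidates": len(labels),
        "n_positives": len(positives),
        "auroc": float(roc_auc_score(y_true, y_score))
        if 0 < y_true.sum() < y_true.size
        else 1.0,
        "auprc": float(average_precision_score(y_true, y_score)),
    }
    for k in ks:
        p, r, f1, hits = _precision_recall_at_k(labels, positives, k)
        record[f"precision@{k}"] = p
        record[f"recall@{k}"] = r
        record[f"f1@{k}"] = f1
        record[f"hits@{k}"] = hits
    return record


def aggregate(
    records: list[dict],
    ks: tuple[int, ...] = DEFAULT_KS,
    ap_k: int = HEADLINE_K,
    mode: str = "macro",
) -> EvaluationReport:
    """Macro-average per-disease records; AP pools top-k hits micro-style."""
    if mode != "macro":
        raise ValidationError(f"unsupported aggregation mode {mode!r}")
    if not records:
        raise ValidationError("no per-disease records to aggregate")
    per_disease = pd.DataFrame.from_records(records)
    at_k = pd.DataFrame(
        {
            "k": list(ks),
            "precision": [per_disease[f"precision@{k}"].mean() for k in ks],
            "recall": [per_disease[f"recall@{k}"].mean() for k in ks],
            "f1": [per_disease[f"f1@{k}"].mean() for k in ks],
        }
    )
    pooled_hits = per_disease[f"hits@{ap_k}"].sum()
    pooled_preds = (
        np.minimum(per_disease["n_candidates"], ap_k).sum()
    )
    return EvaluationReport(
        auroc=float(per_disease["auroc"].mean()),
        auprc=float(per_disease["auprc"].mean()),
        at_k=at_k,
        ap=float(pooled_hits / pooled_preds),
        per_disease=per_disease,
        mode=mode,
    )


def evaluate_predictions(
    predictions: list[RankedPrediction],
    positives: dict[str, set[str]],
    ks: tuple[int, ...] = DEFAULT_KS,
) -> EvaluationReport:
    """Score ranked lists against a truth map; diseases with no test genes
    among their candidates are skipped (and logged)."""
    records = []
    for pred in predictions:
        pos = positives.get(pred.disease, set())
        if not (pos & set(pred.labels)):
            logger.info("skipping %r: no test genes among candidates", pred.disease)
            continue
        records.append(ranking_metrics(pred, pos, ks))
    return aggregate(records, ks)


def _test_positives(table: AssociationTable) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for d, g in table.pairs():
        out.setdefault(d, set()).add(g)
    return out


def cross_validate(
    h: HeterogeneousNetwork,
    strategy: str = "HNim",
    emb_config: EmbeddingConfig | None = None,
    prop_config: PropagationConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
    knn: int = 10,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> EvaluationReport:
    """k-fold cross-validation of one strategy over association pairs.

    Each fold rebuilds the network with the training associations only,
    predicts for every disease holding at least one test gene, and the
    per-disease records of all folds are aggregated together.
    """
    splits = kfold_split(h.associations, k_folds, seed)
    records: list[dict] = []
    for split in splits:
        h_train = h.with_associations(split.train.matrix)
        positives = _test_positives(split.test)
        queries = sorted(positives)
        preds = predict(
            h_train,
            strategy=strategy,
            emb_config=emb_config,
            prop_config=prop_config,
            queries=queries,
            knn=knn,
        )
        for pred in preds:
            pos = positives[pred.disease] & set(pred.labels)
            if not pos:
                continue
            rec = ranking_metrics(pred, pos, ks)
            rec["fold"] = split.fold_id
            records.append(rec)
    return aggregate(records, ks)
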
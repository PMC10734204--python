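"""Cross-validation, the seven evaluation metrics, and case-study ranking.

Positives are split into k folds; each fold is scored by a model trained on
the other folds' balanced samples with the fold's positives masked out of
the training matrix.  AUC and AUPR are threshold-free and primary; the five
thresholded metrics cut min-max-scaled scores at a configurable threshold
(default 0.5), reasonable because test samples are balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io_data import AssociationMatrix, SplitSpec, make_cv_folds, mask_positives, training_pairs
from .model import DhanMkf, DhanMkfResults, ModelConfig


@dataclass
class MetricsReport:
    auc: float
    aupr: float
    f1: float
    accuracy: float
    recall: float
    precision: float
    specificity: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CVResult:
    folds: list[MetricsReport]
    mean: MetricsReport
    seed: int
    split: SplitSpec

    def as_dict(self) -> dict:
        return {
            "mean": self.mean.as_dict(),
            "folds": [f.as_dict() for f in self.folds],
            "seed": self.seed,
        }


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Seven-metric report for one scored sample.

    AUC is the rank-based probability of correct ordering (ties get half
    credit); AUPR is step-interpolated average precision.  The thresholded
    metrics cut min-max-scaled scores at *threshold*.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")

    span = scores.max() - scores.min()
    scaled = (scores - scores.min()) / span if span > 0 else np.full_like(scores, 0.5)
    pred = (scaled >= threshold).astype(int)

    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    return MetricsReport(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=safe(2 * precision * recall, precision + recall),
        accuracy=safe(tp + tn, len(labels)),
        recall=recall,
        precision=precision,
        specificity=safe(tn, tn + fp),
        threshold=threshold,
    )


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        **{
            f.name: float(np.mean([getattr(r, f.name) for r in reports]))
            for f in fields(MetricsReport)
        }
    )


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1000003 + fold + 1) % (2**31)


def run_cv(
    y: AssociationMatrix,
    css: np.ndarray,
    dss: np.ndarray,
    config: ModelConfig | None = None,
    seed: int = 0,
    k: int = 5,
    threshold: float = 0.5,
) -> CVResult:
    """k-fold cross-validation of the full pipeline."""
    config = config or ModelConfig()
    split = make_cv_folds(y, k=k, seed=seed)
    reports: list[MetricsReport] = []
    for fold in range(k):
        y_tr = mask_positives(y, split, fold)
        pairs, labels = training_pairs(split, fold)
        model = DhanMkf(y, css, dss, config)
        result = model.fit(
            y_train=y_tr.values.astype(float),
            train_pairs=pairs,
            train_labels=labels,
            seed=_fold_seed(seed, fold),
        )
        test = split.held_out_pairs[fold]
        test_pairs = [(i, j) for i, j, _ in test]
        test_labels = np.asarray([yy for _, _, yy in test])
        scores = result.score_pairs(test_pairs)
        reports.append(evaluate(scores, test_labels, threshold))
    return CVResult(folds=reports, mean=_mean_report(reports), seed=seed, split=split)


def ab_initio_mode(y: AssociationMatrix, drug_id: str) -> AssociationMatrix:
    """Training matrix with the drug's entire column zeroed (cold start).

    The drug keeps its node but loses all known associations, so it enters
    training as a new (degree-0, hence tail) drug; evaluation is restricted
    to ranking that column.
    """
    j = y.col_index.position(drug_id)
    values = y.values.copy()
    values[:, j] = 0
    return AssociationMatrix(values, y.row_index, y.col_index)


def rank_new_drug(
    y: AssociationMatrix,
    css: np.ndarray,
    dss: np.ndarray,
    drug_id: str,
    config: ModelConfig | None = None,
    seed: int = 0,
    top_n: int = 20,
) -> tuple[list[tuple[str, float]], DhanMkfResults]:
    """Cold-start ranking: train with the drug's column removed, rank it."""
    y_train = ab_initio_mode(y, drug_id)
    model = DhanMkf(y, css, dss, config)
    result = model.fit(y_train=y_train.values.astype(float), seed=seed)
    return result.rank_candidates(drug_id, top_n=top_n), result
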
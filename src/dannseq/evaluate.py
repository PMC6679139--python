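"""AUC / F1 evaluation, 10-fold cross-validation, and paired Wilcoxon tests.

AUC follows the probabilistic (Mann-Whitney) definition: the probability that
a random positive is scored above a random negative, with ties credited 1/2.
F1 = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN), computed at a score
threshold (default 0.5) and defined as 0 when P + R = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

from .network import DannConfig
from .sequences import LabeledSequence, encode_dataset, iter_fold_rotations, make_folds
from .training import TrainingRegime, train

logger = logging.getLogger(__name__)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney normalisation, ties = 1/2).

    labels: 1 for positives, 0 for negatives; both classes must be present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires at least one positive and one negative label")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_f1(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> float:
    """F1 at the given score threshold (predicted positive iff score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) == 0:
        raise ValueError("compute_f1 requires nonempty inputs")
    pred = (scores >= threshold).astype(int)
    return float(f1_score(labels, pred, zero_division=0))


class WilcoxonResult(NamedTuple):
    statistic: float
    p_value: float
    n_informative: int


def paired_wilcoxon(metrics_a: Sequence[float], metrics_b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-ranks test on paired per-fold metrics.

    Zero differences are dropped; the exact null distribution is used for
    small samples without ties (scipy's default policy), the normal
    approximation otherwise.  Identical inputs are the degenerate case: no
    informative pairs, reported as p = 1.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired metrics must have equal length, got {a.shape} vs {b.shape}")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for a meaningful signed-ranks test")
    diffs = a - b
    n_informative = int(np.count_nonzero(diffs))
    if n_informative == 0:
        logger.warning("all paired differences are zero: no informative pairs")
        return WilcoxonResult(0.0, 1.0, 0)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n_informative)


@dataclass
class FoldMetrics:
    auc: float
    f1: float
    n_pos: int
    n_neg: int


@dataclass
class EvalReport:
    """Per-fold metrics from the k-fold rotation, plus their means."""

    per_fold: list[FoldMetrics]

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.per_fold]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f.f1 for f in self.per_fold]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": range(len(self.per_fold)),
                "auc": [f.auc for f in self.per_fold],
                "f1": [f.f1 for f in self.per_fold],
                "n_pos": [f.n_pos for f in self.per_fold],
                "n_neg": [f.n_neg for f in self.per_fold],
            }
        )

    def summary_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "mean_f1": self.mean_f1,
            "k": len(self.per_fold),
            "per_fold_auc": [f.auc for f in self.per_fold],
            "per_fold_f1": [f.f1 for f in self.per_fold],
        }


def cross_validate(
    target_data: Sequence[LabeledSequence],
    regime: TrainingRegime,
    config: DannConfig,
    k: int = 10,
    source_data: Sequence[LabeledSequence] | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """k-fold rotation: folds of equal size, k-2 for training, 1 validation,
    1 test, rotated so each fold is tested exactly once.

    Training data for each rotation is assembled per the regime (labels
    masked or dropped as required); validation and test always come from the
    target cell type.  Seeded by config.seed; fully reproducible.
    """
    from .network import score as nn_score

    folds = make_folds(target_data, k, config.seed)
    per_fold: list[FoldMetrics] = []
    for r, (train_idx, val_idx, test_idx) in enumerate(iter_fold_rotations(folds)):
        assert not (set(train_idx) & set(test_idx)) and not (set(val_idx) & set(test_idx))
        tr = [target_data[i] for i in train_idx]
        va = [target_data[i] for i in val_idx]
        te = [target_data[i] for i in test_idx]
        fold_config = DannConfig(**{**config.__dict__, "seed": config.seed + r})
        if regime.mode == "supervised_baseline" and not source_data:
            params, _ = train(tr, None, regime, fold_config, val_data=va)
        else:
            params, _ = train(tr, source_data, regime, fold_config, val_data=va)
        Xte, bte, _ = encode_dataset(te, fold_config.np_dtype)
        s = nn_score(Xte, params, fold_config)
        y = (bte == 0).astype(int)
        per_fold.append(
            FoldMetrics(
                auc=compute_auc(s, y),
                f1=compute_f1(s, y, threshold),
                n_pos=int(y.sum()),
                n_neg=int((1 - y).sum()),
            )
        )
        logger.info("fold %d/%d: auc=%.4f f1=%.4f", r + 1, k, per_fold[-1].auc, per_fold[-1].f1)
    return EvalReport(per_fold)
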
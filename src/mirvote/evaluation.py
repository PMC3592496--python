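"""Performance metrics and repeated stratified cross-validation.

Metrics are the standard imbalanced-classification set: sensitivity,
specificity, accuracy, precision (PPV), false-positive rate, the geometric
mean Gm = sqrt(Sn·Sp) (the imbalance-robust summary), and rank-based AUC.
Percentages are on the 0–100 scale and reported to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(((t == 1) & (p == 1)).sum()),
            FP=int(((t == 0) & (p == 1)).sum()),
            TN=int(((t == 0) & (p == 0)).sum()),
            FN=int(((t == 1) & (p == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/ACC/PPV/FPR/Gm as percentages; AUC in [0, 1] when available."""

    ACC: float
    Sn: float
    Sp: float
    PPV: float
    FPR: float
    Gm: float
    AUC: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k, v in self.to_dict().items():
            out[k] = None if v is None else round(v, 3 if k == "AUC" else ndigits)
        return out

    def render(self) -> str:
        r = self.rounded()
        cols = ["ACC", "Sn", "Sp", "PPV", "FPR", "Gm", "AUC"]
        head = "".join(f"{c:>8s}" for c in cols)
        vals = "".join(
            f"{'-' if r[c] is None else r[c]:>8}" for c in cols
        )
        return head + "\n" + vals


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else 0.0


def metrics(counts: ConfusionCounts, auc_value: Optional[float] = None) -> MetricsReport:
    """Compute the metric set from confusion counts (0/0 guarded to 0)."""
    total = counts.TP + counts.FP + counts.TN + counts.FN
    sn = _pct(counts.TP, counts.TP + counts.FN)
    sp = _pct(counts.TN, counts.TN + counts.FP)
    return MetricsReport(
        ACC=_pct(counts.TP + counts.TN, total),
        Sn=sn,
        Sp=sp,
        PPV=_pct(counts.TP, counts.TP + counts.FP),
        FPR=100.0 - sp,
        Gm=math.sqrt(sn * sp),
        AUC=auc_value,
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) AUC with mid-ranks for ties; equals the
    trapezoidal ROC area.  Raises on single-class input."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class CVPlan:
    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVReport:
    """Fold-level metric reports plus mean/sd aggregates."""

    fold_reports: list[MetricsReport]
    plan: CVPlan

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.fold_reports])

    def aggregate(self) -> pd.DataFrame:
        f = self.frame()
        return pd.DataFrame({"mean": f.mean(), "sd": f.std(ddof=1)})


PipelineFactory = Callable[
    [pd.DataFrame, np.ndarray, Optional[np.ndarray], int],
    Callable[[pd.DataFrame], tuple[np.ndarray, np.ndarray]],
]
"""A pipeline factory receives (train_features, train_labels, train_tags,
seed) — the training fold only, so rebalancing and any feature selection
happen strictly inside it — and returns a predictor mapping test features
to (labels, scores)."""


def repeated_cv(
    features: pd.DataFrame,
    labels: Sequence[int],
    pipeline: PipelineFactory,
    plan: CVPlan = CVPlan(),
    tags: Optional[Sequence[str]] = None,
) -> CVReport:
    """Repeated stratified k-fold evaluation of a training pipeline.

    Test folds are never passed to the pipeline factory, so no test sample
    can contribute to SMOTE synthesis, undersampling or selection (the
    leakage-safe ordering); an internal disjointness assertion enforces it.
    Deterministic given ``plan.seed``.
    """
    y = np.asarray(labels, dtype=int)
    tags_arr = None if tags is None else np.asarray(tags, dtype=object)
    reports: list[MetricsReport] = []
    for rep in range(plan.repeats):
        splitter = StratifiedKFold(
            n_splits=plan.folds, shuffle=True, random_state=plan.seed + rep
        )
        for train_idx, test_idx in splitter.split(features, y):
            assert not set(train_idx) & set(test_idx), "train/test folds overlap"
            f_train = features.iloc[train_idx]
            f_test = features.iloc[test_idx]
            t_train = None if tags_arr is None else tags_arr[train_idx]
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                raise ValueError("a fold contains a single class; adjust the plan")
            predictor = pipeline(f_train, y[train_idx], t_train, plan.seed + rep)
            pred_labels, scores = predictor(f_test)
            counts = ConfusionCounts.from_labels(y[test_idx], pred_labels)
            reports.append(metrics(counts, auc_value=auc(scores, y[test_idx])))
    return CVReport(fold_reports=reports, plan=plan)
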
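"""Confusion-based metrics and the four-fold cross-validation protocol.

ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN), PPV = TP/(TP+FP) and
F-score = 2/(1/SEN + 1/PPV).  Zero-denominator cases are reported as
``None`` with a reason, never as 0.  Cross-validation splits the balanced
dataset into k stratified folds (default 4); each fold serves once as the
test set while the rest train a fresh model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .benchmark import POSITIVE, BenchmarkDataset
from .nn import NetworkConfig
from .training import TrainConfig, classifier_from_configs

__all__ = [
    "ConfusionCounts", "MetricsReport", "FoldAssignment",
    "confusion", "compute_metrics", "split_folds", "cross_validate",
    "CrossValidationResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """ACC/SEN/PPV/F1 with their confusion counts.

    Undefined metrics (zero denominator) are ``None`` and the reason is given
    in ``undefined_reasons``.
    """

    ACC: float
    SEN: float | None
    PPV: float | None
    F1: float | None
    counts: ConfusionCounts
    undefined_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold index per sample (values in [0, k))."""

    k: int
    fold_of: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def confusion(preds, labels) -> ConfusionCounts:
    """Tally TP/TN/FP/FN; class 1 = piRNA (positive)."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if preds.size < 1:
        raise ValueError("empty prediction list")
    return ConfusionCounts(
        TP=int(np.sum((preds == 1) & (labels == 1))),
        TN=int(np.sum((preds == 0) & (labels == 0))),
        FP=int(np.sum((preds == 1) & (labels == 0))),
        FN=int(np.sum((preds == 0) & (labels == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Apply the four metric formulas; zero denominators yield None."""
    if c.total < 1:
        raise ValueError("cannot compute metrics on zero samples")
    acc = (c.TP + c.TN) / c.total
    reasons: list[str] = []
    sen = ppv = f1 = None
    if c.TP + c.FN == 0:
        reasons.append("SEN undefined: no true positives in the sample (TP+FN=0)")
    else:
        sen = c.TP / (c.TP + c.FN)
    if c.TP + c.FP == 0:
        reasons.append("PPV undefined: nothing predicted positive (TP+FP=0)")
    else:
        ppv = c.TP / (c.TP + c.FP)
    if sen is None or ppv is None or sen == 0 or ppv == 0:
        reasons.append("F1 undefined: SEN or PPV undefined or zero")
    else:
        f1 = 2.0 / (1.0 / sen + 1.0 / ppv)
    return MetricsReport(ACC=acc, SEN=sen, PPV=ppv, F1=f1, counts=c,
                         undefined_reasons=tuple(reasons))


def split_folds(ds: BenchmarkDataset, k: int = 4, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment; per-class fold sizes differ by <= 1."""
    labels = np.array([1 if s.label == POSITIVE else 0 for s in ds.samples])
    for cls in (0, 1):
        n_cls = int(np.sum(labels == cls))
        if n_cls < k:
            raise ValueError(f"class {cls} has {n_cls} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, fold_of=fold_of)


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    pooled: MetricsReport
    assignment: FoldAssignment


def _mean_of(reports: list[MetricsReport]) -> dict[str, float]:
    out: dict[str, float] = {}
    for key in ("ACC", "SEN", "PPV", "F1"):
        vals = [getattr(r, key) for r in reports]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(f"{key} undefined in {len(vals) - len(defined)} fold(s); "
                          "excluded from the mean")
        out[key] = float(np.mean(defined)) if defined else float("nan")
    return out


def cross_validate(ds: BenchmarkDataset, net_cfg: NetworkConfig | None = None,
                   tr_cfg: TrainConfig | None = None, k: int = 4,
                   seed: int | None = None) -> CrossValidationResult:
    """k-fold CV: per-fold metrics, their mean, and pooled-confusion metrics.

    Each fold's model trains with generalization active and is evaluated in
    eval mode with no augmentation; every sample is tested exactly once.
    """
    net_cfg = net_cfg or NetworkConfig()
    tr_cfg = tr_cfg or TrainConfig()
    seed = tr_cfg.seed if seed is None else seed
    assignment = split_folds(ds, k=k, seed=seed)
    seqs = [s.sequence for s in ds.samples]
    labels = np.array([1 if s.label == POSITIVE else 0 for s in ds.samples])

    fold_reports: list[MetricsReport] = []
    pooled_preds = np.empty(len(labels), dtype=np.int64)
    tested = np.zeros(len(labels), dtype=bool)
    for fold in range(k):
        tr_idx = assignment.train_indices(fold)
        te_idx = assignment.test_indices(fold)
        assert not np.intersect1d(tr_idx, te_idx).size, "train/test fold leak"
        clf = classifier_from_configs(net_cfg, tr_cfg)
        clf.set_params(random_state=tr_cfg.seed + fold)
        clf.fit([seqs[i] for i in tr_idx], labels[tr_idx])
        preds = clf.predict([seqs[i] for i in te_idx])
        pooled_preds[te_idx] = preds
        tested[te_idx] = True
        fold_reports.append(compute_metrics(confusion(preds, labels[te_idx])))
    assert tested.all(), "some sample was never tested"

    return CrossValidationResult(
        fold_reports=fold_reports,
        mean=_mean_of(fold_reports),
        pooled=compute_metrics(confusion(pooled_preds, labels)),
        assignment=assignment,
    )
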
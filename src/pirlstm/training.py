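"""Training entry points: dataset-level ``train`` plus the loss function.

These are thin wrappers around :class:`pirlstm.model.LSTMClassifier`, which
owns the actual loop (Adam, cross-entropy, mini-batches of 128, per-epoch
generalization of negatives, optional early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import GeneralizationConfig
from .benchmark import POSITIVE, BenchmarkDataset
from .model import LSTMClassifier, TrainReport
from .nn import NetworkConfig, NetworkWeights, softmax

__all__ = ["TrainConfig", "TrainReport", "train", "loss_cross_entropy",
           "classifier_from_configs"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    batch_size: int = 128
    max_epochs: int = 300
    learning_rate: float = 0.001
    generalization: GeneralizationConfig = field(default_factory=GeneralizationConfig)
    seed: int = 0
    early_stop: bool = False
    patience: int = 20
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def classifier_from_configs(net_cfg: NetworkConfig,
                            tr_cfg: TrainConfig) -> LSTMClassifier:
    """Build an unfitted estimator mirroring the two config dataclasses."""
    return LSTMClassifier(
        n_layers=net_cfg.n_layers,
        hidden_size=net_cfg.hidden_size,
        dropout_rate=net_cfg.dropout_rate,
        batch_size=tr_cfg.batch_size,
        max_epochs=tr_cfg.max_epochs,
        learning_rate=tr_cfg.learning_rate,
        generalize_prob=tr_cfg.generalization.p,
        early_stopping=tr_cfg.early_stop,
        patience=tr_cfg.patience,
        validation_fraction=tr_cfg.validation_fraction,
        random_state=tr_cfg.seed,
    )


def train(ds: BenchmarkDataset, net_cfg: NetworkConfig | None = None,
          tr_cfg: TrainConfig | None = None) -> tuple[NetworkWeights, TrainReport]:
    """Train the network on a benchmark dataset; reproducible from the seed."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    net_cfg = net_cfg or NetworkConfig()
    tr_cfg = tr_cfg or TrainConfig()
    clf = classifier_from_configs(net_cfg, tr_cfg)
    X = [s.sequence for s in ds.samples]
    y = np.array([1 if s.label == POSITIVE else 0 for s in ds.samples])
    clf.fit(X, y)
    return clf.weights_, clf.report_


def loss_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean over rows of -log softmax-probability of the true class."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if logits.shape[0] != labels.shape[0]:
        raise ValueError("row count mismatch between logits and labels")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= logits.shape[1]:
        raise ValueError("label outside the valid class range")
    p = softmax(logits)
    return float(-np.mean(np.log(np.maximum(p[np.arange(len(labels)), labels],
                                            1e-300))))
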
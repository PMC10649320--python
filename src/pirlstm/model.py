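"""Scikit-learn-style LSTM classifier for short RNA sequences.

:class:`LSTMClassifier` follows the sklearn estimator contract
(``fit`` / ``predict`` / ``predict_proba``, ``get_params`` / ``set_params``,
fitted attributes with a trailing underscore), except that the feature
matrix X is a list of RNA sequences (strings or :class:`~pirlstm.io.RnaSequence`)
rather than a numeric array.  It therefore composes with sklearn model
selection through the higher-level helpers in :mod:`pirlstm.evaluation`.

Training follows the published recipe: mini-batches of 128, Adam at learning
rate 1e-3, cross-entropy loss, dropout 0.2, up to 300 epochs, and per-epoch
"data generalization" that reshuffles each negative's bases with probability
0.6 so the network cannot memorize individual negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .augment import GeneralizationConfig, generalize_sample
from .benchmark import NEGATIVE, POSITIVE, LabeledSample
from .encoding import batch_encode
from .io import RnaSequence
from .nn import (
    Adam,
    NetworkConfig,
    NetworkWeights,
    init_weights,
    network_forward,
    network_forward_backward,
    predict_classes,
    softmax,
)

__all__ = ["LSTMClassifier", "TrainReport"]


@dataclass
class TrainReport:
    """Per-epoch training history."""

    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    epochs_run: int = 0


def _as_bases(x) -> str:
    return x.bases if isinstance(x, RnaSequence) else str(x)


class LSTMClassifier(ClassifierMixin, BaseEstimator):
    """3-layer, 32-unit LSTM classifier of piRNA vs non-piRNA sequences.

    Parameters
    ----------
    n_layers, hidden_size : int
        Depth and width of the LSTM stack (defaults 3 and 32).
    dropout_rate : float
        Dropout applied between LSTM layers and after batch normalization
        (default 0.2).
    batch_size, max_epochs, learning_rate : training-loop hyperparameters
        (defaults 128, 300, 0.001).
    generalize_prob : float
        Probability of reshuffling each negative's bases, fresh every epoch
        (default 0.6).  Set 0 to disable.
    early_stopping : bool
        If True, hold out ``validation_fraction`` (stratified) and stop when
        validation accuracy has not improved for ``patience`` epochs.
    random_state : int or None
        Seeds initialization, batching order, dropout and generalization.

    Attributes
    ----------
    classes_ : ndarray (2,)
        Always ``[0, 1]``; 1 = piRNA.
    weights_ : NetworkWeights
        Trained parameters including batch-norm running moments.
    report_ : TrainReport
        Loss (and validation) history.
    n_epochs_ : int
        Epochs actually run.
    """

    def __init__(self, n_layers: int = 3, hidden_size: int = 32,
                 dropout_rate: float = 0.2, batch_size: int = 128,
                 max_epochs: int = 300, learning_rate: float = 0.001,
                 generalize_prob: float = 0.6, early_stopping: bool = False,
                 patience: int = 20, validation_fraction: float = 0.1,
                 random_state: int | None = None):
        self.n_layers = n_layers
        self.hidden_size = hidden_size
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.generalize_prob = generalize_prob
        self.early_stopping = early_stopping
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "LSTMClassifier":
        """Train on sequences X with binary labels y (1 = piRNA)."""
        seqs = [_as_bases(x) for x in X]
        y = np.asarray(y, dtype=np.int64)
        if len(seqs) != len(y):
            raise ValueError("X and y length mismatch")
        if len(seqs) < 2:
            raise ValueError("need at least 2 samples")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 (non-piRNA) or 1 (piRNA)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

        seed = 0 if self.random_state is None else int(self.random_state)
        ss = np.random.SeedSequence(seed)
        s_init, s_order, s_drop, s_gen, s_val = ss.spawn(5)
        rng_init = np.random.default_rng(s_init)
        rng_order = np.random.default_rng(s_order)
        rng_drop = np.random.default_rng(s_drop)
        gen_seed = int(np.random.default_rng(s_gen).integers(2**31 - 1))

        cfg = NetworkConfig(n_layers=self.n_layers, hidden_size=self.hidden_size,
                            dropout_rate=self.dropout_rate)
        self.config_ = cfg
        self.classes_ = np.array([0, 1])
        self.weights_ = init_weights(cfg, rng_init)
        report = TrainReport()

        samples = [
            LabeledSample(
                sequence=RnaSequence(id=f"s{i}", bases=b),
                label=POSITIVE if lab == 1 else NEGATIVE,
                pair_id=f"s{i}",
            )
            for i, (b, lab) in enumerate(zip(seqs, y))
        ]
        labels = y.copy()

        val_idx: np.ndarray | None = None
        if self.early_stopping:
            rng_val = np.random.default_rng(s_val)
            val_idx = _stratified_holdout(labels, self.validation_fraction, rng_val)
            train_mask = np.ones(len(labels), dtype=bool)
            train_mask[val_idx] = False
            train_idx = np.flatnonzero(train_mask)
        else:
            train_idx = np.arange(len(labels))

        gen_cfg = GeneralizationConfig(p=self.generalize_prob, seed=gen_seed)
        opt = Adam(self.weights_.trainable(), lr=self.learning_rate)

        best_val, since_best = -np.inf, 0
        for epoch in range(self.max_epochs):
            if self.generalize_prob > 0:
                rng_gen = np.random.default_rng(
                    np.random.SeedSequence((gen_seed, epoch)))
                epoch_seqs = [
                    generalize_sample(samples[i], gen_cfg, rng_gen).sequence.bases
                    if labels[i] == 0 else seqs[i]
                    for i in range(len(seqs))
                ]
            else:
                epoch_seqs = seqs
            order = rng_order.permutation(train_idx)
            batches = _batch_slices(len(order), self.batch_size)
            epoch_loss = 0.0
            n_seen = 0
            for lo, hi in batches:
                idx = order[lo:hi]
                eb = batch_encode([epoch_seqs[i] for i in idx], labels[idx])
                loss, _, grads = network_forward_backward(
                    cfg, self.weights_, eb, labels[idx], rng_drop)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch [{lo}:{hi}]")
                opt.step(grads)
                epoch_loss += loss * len(idx)
                n_seen += len(idx)
            report.train_loss.append(epoch_loss / n_seen)
            report.epochs_run = epoch + 1

            if val_idx is not None:
                acc = self._score_indices(seqs, labels, val_idx)
                report.val_accuracy.append(acc)
                if acc > best_val + 1e-12:
                    best_val, since_best = acc, 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break

        self.report_ = report
        self.n_epochs_ = report.epochs_run
        return self

    def _score_indices(self, seqs, labels, idx) -> float:
        preds = self.predict([seqs[i] for i in idx])
        return float(np.mean(preds == labels[idx]))

    # ------------------------------------------------------- predict family

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise RuntimeError("this LSTMClassifier instance is not fitted yet")

    def decision_logits(self, X, chunk: int = 512) -> np.ndarray:
        """Eval-mode (B, 2) logits, computed in chunks."""
        self._check_fitted()
        seqs = [_as_bases(x) for x in X]
        out = []
        for lo in range(0, len(seqs), chunk):
            eb = batch_encode(seqs[lo:lo + chunk])
            out.append(network_forward(self.config_, self.weights_, eb, "eval"))
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        """(B, 2) class probabilities; column 1 is the piRNA probability."""
        return softmax(self.decision_logits(X))

    def predict(self, X) -> np.ndarray:
        """Hardened class labels (1 = piRNA); exact ties go to non-piRNA."""
        classes, _ = predict_classes(self.decision_logits(X))
        return classes


def _batch_slices(n: int, batch_size: int) -> list[tuple[int, int]]:
    """Mini-batch boundaries; a trailing singleton is merged into the previous
    batch so batch statistics are always computed over >= 2 samples."""
    edges = list(range(0, n, batch_size)) + [n]
    slices = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if len(slices) > 1 and slices[-1][1] - slices[-1][0] == 1:
        lo, _ = slices[-2]
        slices = slices[:-2] + [(lo, n)]
    return slices


def _stratified_holdout(labels: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified validation holdout (>= 1 item per class)."""
    idx = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        n_val = max(1, int(round(fraction * len(cls_idx))))
        idx.append(rng.permutation(cls_idx)[:n_val])
    return np.sort(np.concatenate(idx))
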
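"""Training-time data generalization: stochastic reshuffling of negatives.

During training each negative sample is, independently per epoch and with a
fixed "generalizing probability" p (default 0.6), replaced by a fresh uniform
permutation of its own bases.  Positives are never touched and evaluation
always sees the stored dataset.  Because negatives are themselves shuffled
windows, reshuffling draws a new equivalent negative from the same
composition class each epoch, which stops the network from memorizing
individual negative sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import NEGATIVE, BenchmarkDataset, LabeledSample
from .io import RnaSequence

__all__ = ["GeneralizationConfig", "generalize_sample", "generalize_epoch"]


@dataclass(frozen=True)
class GeneralizationConfig:
    """Generalizing probability p in [0, 1] and the stream seed."""

    p: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"generalizing probability must be in [0,1], got {self.p}")


def generalize_sample(sample: LabeledSample, cfg: GeneralizationConfig,
                      rng: np.random.Generator) -> LabeledSample:
    """With probability p, replace a negative by a permutation of its bases.

    Positives are returned unchanged; ids, labels and pairing are preserved.
    """
    if sample.label != NEGATIVE or cfg.p == 0.0:
        return sample
    if rng.random() >= cfg.p:
        return sample
    bases = sample.sequence.bases
    perm = rng.permutation(len(bases))
    shuffled = "".join(bases[i] for i in perm)
    return LabeledSample(
        sequence=RnaSequence(id=sample.sequence.id, bases=shuffled,
                             description=sample.sequence.description),
        label=sample.label,
        pair_id=sample.pair_id,
    )


def generalize_epoch(ds: BenchmarkDataset, cfg: GeneralizationConfig,
                     epoch: int) -> BenchmarkDataset:
    """A per-epoch view of the dataset with negatives stochastically reshuffled.

    The epoch index is folded into the random stream, so each epoch gets a
    fresh deterministic draw while the stored dataset stays unmodified.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, epoch)))
    samples = [generalize_sample(s, cfg, rng) for s in ds.samples]
    return BenchmarkDataset(samples=samples, seed=ds.seed,
                            source_meta=ds.source_meta,
                            min_len=ds.min_len, max_len=ds.max_len)
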
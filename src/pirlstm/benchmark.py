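"""Benchmark construction: length-filtered positives and matched shuffled negatives.

A benchmark pairs each retained positive with exactly one negative control of
identical length.  A negative is built by drawing a contiguous window of the
target length uniformly from an eligible sequence of a negative-source pool
(in practice an ncRNA collection such as an Rfam export) and permuting its
bases uniformly.  The permutation preserves base composition while destroying
any positional signal, so the classes differ only in sequence order — the
property the classifier is meant to exploit.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import RnaSequence, read_fasta, write_fasta

__all__ = [
    "LabeledSample",
    "BenchmarkDataset",
    "filter_positives",
    "make_negative",
    "build_benchmark",
    "dataset_summary",
    "save_dataset",
    "load_dataset",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class LabeledSample:
    """A labeled sequence with the id of the positive it is paired with."""

    sequence: RnaSequence
    label: Literal["positive", "negative"]
    pair_id: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"invalid label {self.label!r}")


@dataclass
class BenchmarkDataset:
    """Balanced positive/negative samples with provenance.

    Invariants (checked by :meth:`validate`): equal class counts, each
    negative exactly as long as its paired positive, every positive length
    within the configured bounds.
    """

    samples: list[LabeledSample]
    seed: int
    source_meta: str = ""
    min_len: int = 18
    max_len: int = 40

    @property
    def positives(self) -> list[LabeledSample]:
        return [s for s in self.samples if s.label == POSITIVE]

    @property
    def negatives(self) -> list[LabeledSample]:
        return [s for s in self.samples if s.label == NEGATIVE]

    def __len__(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        pos = {s.sequence.id: s for s in self.positives}
        neg = self.negatives
        if len(pos) != len(neg):
            raise ValueError(
                f"class imbalance: {len(pos)} positives vs {len(neg)} negatives"
            )
        for s in self.positives:
            if not (self.min_len <= len(s.sequence) <= self.max_len):
                raise ValueError(
                    f"positive {s.sequence.id!r} length {len(s.sequence)} outside "
                    f"[{self.min_len}, {self.max_len}]"
                )
        for s in neg:
            mate = pos.get(s.pair_id)
            if mate is None:
                raise ValueError(f"negative {s.sequence.id!r} pairs to unknown id {s.pair_id!r}")
            if len(s.sequence) != len(mate.sequence):
                raise ValueError(
                    f"length mismatch for pair {s.pair_id!r}: "
                    f"{len(mate.sequence)} vs {len(s.sequence)}"
                )


def filter_positives(
    seqs: Sequence[RnaSequence],
    min_len: int = 18,
    max_len: int = 40,
    cap: int = 100_000,
    rng: np.random.Generator | None = None,
) -> list[RnaSequence]:
    """Keep sequences with length in ``[min_len, max_len]`` (inclusive), capped.

    If more than ``cap`` sequences survive, a uniform sample of exactly
    ``cap`` is drawn without replacement; the output order is the sampling
    order, so the result is reproducible from the generator state.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    kept = [s for s in seqs if min_len <= len(s) <= max_len]
    if not kept:
        raise ValueError(
            f"no sequence of {len(seqs)} has length in [{min_len}, {max_len}]"
        )
    if len(kept) <= cap:
        return kept
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.choice(len(kept), size=cap, replace=False)
    return [kept[i] for i in idx]


def make_negative(
    target_length: int,
    pool: Sequence[RnaSequence],
    rng: np.random.Generator,
    *,
    neg_id: str | None = None,
    pair_id: str = "",
) -> RnaSequence:
    """Draw and shuffle a length-matched window from the negative-source pool.

    A pool sequence of length >= ``target_length`` is chosen uniformly, a
    contiguous window of the target length is chosen uniformly within it, and
    the window's bases are permuted uniformly (mononucleotide shuffle).  The
    output id records pool id and 0-based half-open window coordinates as
    ``neg|<pool id>|<start>-<end>`` so composition conservation is auditable.
    """
    eligible = [i for i, s in enumerate(pool) if len(s) >= target_length]
    if not eligible:
        raise ValueError(
            f"no pool sequence of length >= {target_length} (pool size {len(pool)})"
        )
    src = pool[eligible[rng.integers(len(eligible))]]
    start = int(rng.integers(len(src) - target_length + 1))
    window = src.bases[start : start + target_length]
    perm = rng.permutation(target_length)
    shuffled = "".join(window[i] for i in perm)
    out_id = neg_id if neg_id is not None else f"neg|{src.id}|{start}-{start + target_length}"
    return RnaSequence(id=out_id, bases=shuffled,
                       description=f"source={src.id}:{start}-{start + target_length} pair={pair_id}")


def build_benchmark(
    positives: Sequence[RnaSequence],
    pool: Sequence[RnaSequence],
    cap: int = 100_000,
    seed: int = 0,
    min_len: int = 18,
    max_len: int = 40,
    source_meta: str = "",
) -> BenchmarkDataset:
    """Filter positives and pair each with a shuffled length-matched negative."""
    if not positives or not pool:
        raise ValueError("positives and pool must be non-empty")
    rng = np.random.default_rng(seed)
    kept = filter_positives(positives, min_len, max_len, cap, rng)
    samples: list[LabeledSample] = []
    for s in kept:
        samples.append(LabeledSample(sequence=s, label=POSITIVE, pair_id=s.id))
    for k, s in enumerate(kept):
        neg = make_negative(len(s), pool, rng, pair_id=s.id)
        # re-id to keep uniqueness even if the same window is drawn twice
        neg = RnaSequence(id=f"{neg.id}|{k}", bases=neg.bases, description=neg.description)
        samples.append(LabeledSample(sequence=neg, label=NEGATIVE, pair_id=s.id))
    ds = BenchmarkDataset(samples=samples, seed=seed, source_meta=source_meta,
                          min_len=min_len, max_len=max_len)
    ds.validate()
    return ds


def dataset_summary(ds: BenchmarkDataset) -> dict:
    """Counts and mean lengths per class (means match by the pairing invariant)."""
    pos, neg = ds.positives, ds.negatives
    if not pos and not neg:
        raise ValueError("empty dataset")
    return {
        "n_pos": len(pos),
        "n_neg": len(neg),
        "mean_length_pos": float(np.mean([len(s.sequence) for s in pos])),
        "mean_length_neg": float(np.mean([len(s.sequence) for s in neg])),
    }


# --- on-disk layout: positives.fasta, negatives.fasta, manifest.tsv ---------

def save_dataset(ds: BenchmarkDataset, out_dir: str | os.PathLike) -> None:
    """Write the dataset directory: two FASTA files plus a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([s.sequence for s in ds.positives], out / "positives.fasta")
    write_fasta([s.sequence for s in ds.negatives], out / "negatives.fasta")
    with open(out / "manifest.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "label", "pair_id", "length", "source"])
        for s in ds.samples:
            w.writerow([s.sequence.id, s.label, s.pair_id, len(s.sequence),
                        s.sequence.description])
        w.writerow([])
        fh.write(f"# seed={ds.seed}\tmin_len={ds.min_len}\tmax_len={ds.max_len}\t"
                 f"source_meta={ds.source_meta}\n")


def load_dataset(in_dir: str | os.PathLike) -> BenchmarkDataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    src = Path(in_dir)
    manifest = src / "manifest.tsv"
    meta = {"seed": 0, "min_len": 18, "max_len": 40, "source_meta": ""}
    rows: dict[str, tuple[str, str]] = {}
    with open(manifest) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for kv in line.lstrip("# ").split("\t"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        if k in ("seed", "min_len", "max_len"):
                            meta[k] = int(v)
                        elif k == "source_meta":
                            meta[k] = v
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            rows[parts[0]] = (parts[1], parts[2])
    samples: list[LabeledSample] = []
    for fasta in ("positives.fasta", "negatives.fasta"):
        for seq in read_fasta(src / fasta):
            label, pair_id = rows[seq.id]
            samples.append(LabeledSample(sequence=seq, label=label, pair_id=pair_id))
    ds = BenchmarkDataset(samples=samples, **meta)
    ds.validate()
    return ds
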
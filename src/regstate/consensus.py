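"""Replicate consensus peaks for one histone mark in one cell population.

Per-replicate peak sets (e.g. SEACR output consumed as BED) are collapsed into
a consensus set with an explicit >= k-of-n support rule: pool all replicate
intervals, merge them into candidate regions, count how many distinct
replicates contribute at least one base of overlap to each candidate, and keep
candidates meeting ``min_support``.  The default of 2-of-3 reflects common
practice for three biological replicates; the threshold, like the merge gap,
is configurable because published pipelines rarely report it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, ValidationError, overlap_flags, read_bed

logger = logging.getLogger(__name__)

__all__ = ["ReplicatePeakCollection", "ConsensusPeakSet", "build_consensus", "support_profile"]

HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3", "H3K4me3")


@dataclass
class ReplicatePeakCollection:
    """Ordered per-replicate peak sets for one (mark, population)."""

    mark: str
    population: str
    replicates: list[IntervalSet]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValidationError("need at least one replicate")

    @property
    def n(self) -> int:
        return len(self.replicates)

    @classmethod
    def from_bed_files(
        cls, mark: str, population: str, paths: Sequence[str | Path]
    ) -> "ReplicatePeakCollection":
        reps = [read_bed(p, label=f"{population}/{mark}/rep{i + 1}") for i, p in enumerate(paths)]
        return cls(mark=mark, population=population, replicates=reps)


@dataclass
class ConsensusPeakSet:
    """Consensus peaks with per-peak replicate support counts.

    ``support[i]`` is the number of replicates overlapping the i-th peak of
    ``peaks`` (iteration order) by >= 1 bp; every retained peak satisfies
    ``min_support <= support[i] <= n_replicates``.
    """

    mark: str
    population: str
    peaks: IntervalSet
    support: np.ndarray
    min_support: int
    n_replicates: int

    def to_bed(self, path: str | Path) -> None:
        """Write chrom, start, end, name, support (5-column BED-like TSV)."""
        with open(path, "w") as fh:
            for i, iv in enumerate(self.peaks):
                name = f"{self.population}_{self.mark}_peak{i + 1}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{int(self.support[i])}\n")


def _candidate_regions(collection: ReplicatePeakCollection, merge_gap: int) -> IntervalSet:
    pooled = IntervalSet(
        (iv for rep in collection.replicates for iv in rep),
        label=f"{collection.population}/{collection.mark}/pooled",
    )
    return pooled.merge(merge_gap) if merge_gap > 0 else pooled


def build_consensus(
    collection: ReplicatePeakCollection, min_support: int = 2, merge_gap: int = 0
) -> ConsensusPeakSet:
    """Collapse replicates into consensus peaks with support counts.

    Algorithm: (1) pool all replicate intervals; (2) merge with ``merge_gap``
    into candidate regions; (3) per candidate, support = number of replicates
    contributing >= 1 bp of overlap; (4) retain candidates with
    support >= ``min_support``.  Deterministic for fixed input.
    """
    n = collection.n
    if not (1 <= min_support <= n):
        raise ValidationError(f"min_support must be in [1, {n}], got {min_support}")
    candidates = _candidate_regions(collection, merge_gap)
    cand_list = list(candidates)
    support = np.zeros(len(cand_list), dtype=np.int64)
    for rep in collection.replicates:
        support += overlap_flags(cand_list, rep, min_bp=1)
    keep = support >= min_support
    kept = IntervalSet(
        (iv for iv, k in zip(cand_list, keep) if k),
        label=f"{collection.population}/{collection.mark}/consensus",
    )
    return ConsensusPeakSet(
        mark=collection.mark,
        population=collection.population,
        peaks=kept,
        support=support[keep],
        min_support=min_support,
        n_replicates=n,
    )


def support_profile(collection: ReplicatePeakCollection, merge_gap: int = 0) -> pd.DataFrame:
    """QC table of every pooled merged region with its replicate support."""
    full = build_consensus(collection, min_support=1, merge_gap=merge_gap)
    rows = [
        (iv.chrom, iv.start, iv.end, int(s)) for iv, s in zip(full.peaks, full.support)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "support"])
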
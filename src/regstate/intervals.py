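"""Genomic interval algebra on 0-based, half-open coordinates.

Every peak operation in the package funnels through :class:`IntervalSet`, a
sorted, merged collection of :class:`GenomicInterval`.  The normal form is
strict: per chromosome, intervals are sorted and no two intervals overlap or
abut, so a normalized set is exactly the set of maximal covered runs of its
per-base occupancy.  BED input is interpreted as 0-based half-open; GTF's
1-based closed coordinates are converted on load.

Histone peaks are unstranded; strand enters only through the transcription
start site (TSS) of a :class:`GeneModel`, which for a minus-strand gene is the
annotated transcript *end* coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BedParseError",
    "AnnotationParseError",
    "ValidationError",
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "GenomeAnnotation",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "load_annotation",
    "nearest_tss",
    "nearest_tss_hit",
    "tss_within",
    "overlap_flags",
]


class ValidationError(ValueError):
    """An input value violates a documented invariant."""


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class AnnotationParseError(ValueError):
    """A gene annotation file could not be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A normalized set of genomic intervals.

    Normal form: per chromosome, intervals are sorted by start and pairwise
    neither overlapping nor abutting (abutting inputs are unioned during
    construction).  ``label`` is a free-text provenance tag (mark, population,
    replicate id) carried through for bookkeeping only.
    """

    __slots__ = ("_by_chrom", "label")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = "") -> None:
        self.label = label
        buckets: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: dict[str, np.ndarray] = {}
        for chrom in sorted(buckets):
            pairs = sorted(buckets[chrom])
            merged: list[tuple[int, int]] = []
            cur_s, cur_e = pairs[0]
            for s, e in pairs[1:]:
                if s <= cur_e:  # overlap or abutment -> union
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
            self._by_chrom[chrom] = np.asarray(merged, dtype=np.int64)

    @classmethod
    def _from_arrays(cls, by_chrom: Mapping[str, np.ndarray], label: str = "") -> "IntervalSet":
        """Internal fast path: arrays must already be in normal form."""
        obj = cls.__new__(cls)
        obj.label = label
        obj._by_chrom = {c: np.asarray(a, dtype=np.int64) for c, a in sorted(by_chrom.items()) if len(a)}
        return obj

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]], label: str = "") -> "IntervalSet":
        return cls((GenomicInterval(c, s, e) for c, s, e in tuples), label=label)

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_chrom.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(np.array_equal(self._by_chrom[c], other._by_chrom[c]) for c in self._by_chrom)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bases={self.total_bases}, label={self.label!r})"

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    @property
    def total_bases(self) -> int:
        """Total number of covered bases."""
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values()))

    def arrays(self, chrom: str) -> np.ndarray | None:
        """(n, 2) start/end array for one chromosome, or None."""
        return self._by_chrom.get(chrom)

    # -- algebra -------------------------------------------------------------
    def merge(self, gap: int = 0) -> "IntervalSet":
        """Union intervals separated by at most ``gap`` uncovered bases."""
        if gap < 0:
            raise ValidationError(f"gap must be >= 0, got {gap}")
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self._by_chrom.items():
            merged: list[tuple[int, int]] = []
            cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
            for s, e in arr[1:]:
                if s <= cur_e + gap:
                    cur_e = max(cur_e, int(e))
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            merged.append((cur_s, cur_e))
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return IntervalSet._from_arrays(out, label=self.label)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, list] = {}
        for src in (self, other):
            for chrom, arr in src._by_chrom.items():
                out.setdefault(chrom, []).append(arr)
        merged: dict[str, np.ndarray] = {}
        for chrom, parts in out.items():
            pairs = sorted((int(s), int(e)) for part in parts for s, e in part)
            res: list[tuple[int, int]] = []
            cur_s, cur_e = pairs[0]
            for s, e in pairs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    res.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            res.append((cur_s, cur_e))
            merged[chrom] = np.asarray(res, dtype=np.int64)
        return IntervalSet._from_arrays(merged, label=self.label)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Bases present in both sets (commutative)."""
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom)
            if b is None:
                continue
            res: list[tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((int(s), int(e)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
        return IntervalSet._from_arrays(out, label=self.label)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of self not covered by ``other``."""
        out: dict[str, np.ndarray] = {}
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom)
            if b is None or len(b) == 0:
                out[chrom] = a.copy()
                continue
            res: list[tuple[int, int]] = []
            j = 0
            for s, e in a:
                s, e = int(s), int(e)
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        res.append((cur, int(b[k, 0])))
                    cur = max(cur, int(b[k, 1]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    res.append((cur, e))
            if res:
                out[chrom] = np.asarray(res, dtype=np.int64)
        return IntervalSet._from_arrays(out, label=self.label)

    # -- queries -------------------------------------------------------------
    def overlap_bp(self, query: GenomicInterval) -> int:
        """Total number of bases of ``query`` covered by this set."""
        arr = self._by_chrom.get(query.chrom)
        if arr is None:
            return 0
        ov = np.minimum(arr[:, 1], query.end) - np.maximum(arr[:, 0], query.start)
        return int(np.clip(ov, 0, None).sum())

    def overlaps_any(self, query: GenomicInterval, min_bp: int = 1) -> bool:
        """True iff at least ``min_bp`` bases of ``query`` are covered."""
        if min_bp < 1:
            raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
        if min_bp == 1:
            arr = self._by_chrom.get(query.chrom)
            if arr is None:
                return False
            idx = int(np.searchsorted(arr[:, 0], query.end, side="left")) - 1
            return idx >= 0 and int(arr[idx, 1]) > query.start
        return self.overlap_bp(query) >= min_bp

    def count_overlapping(self, query: GenomicInterval) -> int:
        """Number of member intervals sharing >= 1 bp with ``query``."""
        arr = self._by_chrom.get(query.chrom)
        if arr is None:
            return 0
        hi = int(np.searchsorted(arr[:, 0], query.end, side="left"))
        lo = int(np.searchsorted(arr[:, 1], query.start, side="right"))
        return max(0, hi - lo)


def overlap_flags(
    elements: Sequence[GenomicInterval],
    s: IntervalSet,
    min_bp: int = 1,
    min_frac: float | None = None,
) -> np.ndarray:
    """Boolean vector: does each element overlap ``s`` by >= ``min_bp`` bases?

    ``min_frac`` instead requires the overlap to cover at least that fraction
    of each element's length (whichever of the two thresholds is larger).
    Vectorized fast path for the common min_bp == 1 criterion.
    """
    if min_bp < 1:
        raise ValidationError(f"min_bp must be >= 1, got {min_bp}")
    if min_frac is not None and not (0.0 < min_frac <= 1.0):
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    n = len(elements)
    flags = np.zeros(n, dtype=bool)
    if min_bp > 1 or min_frac is not None:
        for i, el in enumerate(elements):
            need = min_bp
            if min_frac is not None:
                need = max(need, int(np.ceil(min_frac * el.length)))
            flags[i] = s.overlap_bp(el) >= need
        return flags
    by_chrom: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        by_chrom.setdefault(el.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        arr = s.arrays(chrom)
        if arr is None:
            continue
        starts = np.fromiter((elements[i].start for i in idxs), dtype=np.int64, count=len(idxs))
        ends = np.fromiter((elements[i].end for i in idxs), dtype=np.int64, count=len(idxs))
        pos = np.searchsorted(arr[:, 0], ends, side="left") - 1
        ok = (pos >= 0) & (arr[np.clip(pos, 0, None), 1] > starts)
        flags[np.asarray(idxs)] = ok
    return flags


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str = "") -> IntervalSet:
    """Read a BED3+ file into a normalized IntervalSet.

    Columns beyond the first three (name, score, ...) are ignored.  Lines that
    are empty or start with ``#``, ``track`` or ``browser`` are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return IntervalSet(intervals, label=label or path.stem)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write BED3; for a normalized set, read_bed . write_bed round-trips."""
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS.

    For a '+' gene the TSS is the annotated transcript start; for a '-' gene
    it is the annotated transcript end coordinate (0-based last base).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"tss must be >= 0, got {self.tss}")


class GenomeAnnotation:
    """Collection of GeneModels with optional chromosome sizes."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int] | None = None) -> None:
        self.genes: list[GeneModel] = list(genes)
        self.chrom_sizes: dict[str, int] | None = dict(chrom_sizes) if chrom_sizes is not None else None
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise AnnotationParseError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
        if self.chrom_sizes is not None:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is not None and g.tss >= size:
                    raise ValidationError(
                        f"gene {g.gene_id}: tss {g.tss} beyond chromosome {g.chrom} length {size}"
                    )
        # per-chromosome (tss, gene_id) arrays for nearest-TSS queries
        self._tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            buckets.setdefault(g.chrom, []).append(g)
        for chrom, gs in buckets.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss_by_chrom[chrom] = (
                np.asarray([g.tss for g in gs], dtype=np.int64),
                np.asarray([g.gene_id for g in gs], dtype=object),
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> set[str]:
        return set(self._by_id)


def _tss_distances(query: GenomicInterval, tss: np.ndarray) -> np.ndarray:
    """Distance of each TSS to the query: 0 inside, else distance to nearest edge base."""
    inside = (tss >= query.start) & (tss < query.end)
    edge = np.minimum(np.abs(tss - query.start), np.abs(tss - (query.end - 1)))
    return np.where(inside, 0, edge)


def nearest_tss_hit(
    query: GenomicInterval, ann: GenomeAnnotation, max_dist: int = 20_000
) -> tuple[str, int] | None:
    """Nearest gene within ``max_dist`` bp, as (gene_id, distance).

    Ties are broken by smaller distance then lexicographic gene_id.  Returns
    None when the chromosome is absent from the annotation or the minimum
    distance exceeds ``max_dist``.
    """
    if max_dist <= 0:
        raise ValidationError(f"max_dist must be > 0, got {max_dist}")
    entry = ann._tss_by_chrom.get(query.chrom)
    if entry is None:
        logger.debug("nearest_tss: chromosome %s absent from annotation", query.chrom)
        return None
    tss, ids = entry
    dists = _tss_distances(query, tss)
    best = int(dists.min())
    if best > max_dist:
        return None
    candidates = ids[dists == best]
    return str(min(candidates)), best


def nearest_tss(query: GenomicInterval, ann: GenomeAnnotation, max_dist: int = 20_000) -> str | None:
    """Gene id of the nearest TSS within ``max_dist`` bp, or None."""
    hit = nearest_tss_hit(query, ann, max_dist)
    return None if hit is None else hit[0]


def tss_within(
    query: GenomicInterval, ann: GenomeAnnotation, max_dist: int = 20_000
) -> list[tuple[str, int]]:
    """All (gene_id, distance) with TSS within ``max_dist`` bp, sorted by (distance, id)."""
    if max_dist <= 0:
        raise ValidationError(f"max_dist must be > 0, got {max_dist}")
    entry = ann._tss_by_chrom.get(query.chrom)
    if entry is None:
        return []
    tss, ids = entry
    dists = _tss_distances(query, tss)
    keep = dists <= max_dist
    hits = [(str(i), int(d)) for i, d in zip(ids[keep], dists[keep])]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def load_annotation(
    path: str | Path,
    format: str = "gtf",
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Load a gene annotation from GTF (gene features) or a TSS BED.

    TSS BED columns: chrom, tss, tss+1, gene_id[, score, strand].
    GTF coordinates are converted from 1-based closed to the internal 0-based
    convention; the TSS of a '-' gene is the feature's last base.
    """
    path = Path(path)
    if format == "tss_bed":
        genes: list[GeneModel] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise AnnotationParseError(
                        f"{path}: line {lineno}: TSS BED needs >= 4 fields (chrom, tss, tss+1, gene_id)"
                    )
                strand = fields[5] if len(fields) >= 6 else "+"
                try:
                    genes.append(GeneModel(fields[3], fields[3], fields[0], strand, int(fields[1])))
                except (ValueError, ValidationError) as exc:
                    raise AnnotationParseError(f"{path}: line {lineno}: {exc}") from exc
        return GenomeAnnotation(genes, chrom_sizes=chrom_sizes)
    if format == "gtf":
        import gffutils

        try:
            db = gffutils.create_db(
                str(path),
                ":memory:",
                force=True,
                keep_order=True,
                merge_strategy="error",
                disable_infer_genes=True,
                disable_infer_transcripts=True,
            )
        except Exception as exc:  # gffutils raises assorted errors on duplicate ids
            raise AnnotationParseError(f"{path}: {exc}") from exc
        genes = []
        for feat in db.features_of_type("gene"):
            gene_id = (feat.attributes.get("gene_id") or [None])[0]
            if not gene_id:
                raise AnnotationParseError(f"{path}: gene feature without gene_id attribute")
            gene_name = (feat.attributes.get("gene_name") or [gene_id])[0]
            if feat.strand not in ("+", "-"):
                raise ValidationError(f"{path}: gene {gene_id}: unknown strand {feat.strand!r}")
            tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
            genes.append(GeneModel(gene_id, gene_name, feat.seqid, feat.strand, tss))
        if len({g.gene_id for g in genes}) != len(genes):
            raise AnnotationParseError(f"{path}: duplicate gene_id")
        return GenomeAnnotation(genes, chrom_sizes=chrom_sizes)
    raise ValidationError(f"unknown annotation format {format!r} (expected 'gtf' or 'tss_bed')")
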
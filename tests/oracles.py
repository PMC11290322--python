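"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: interval operations
are recomputed on per-base boolean arrays, Fisher p-values by exact rational
summation, motif hits by a naive per-offset rescan, and nearest-TSS queries
by a linear scan.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

# -- per-base boolean-array interval oracle ---------------------------------

def to_mask(pairs, length: int) -> np.ndarray:
    """Boolean occupancy of a list of (start, end) pairs on one toy chromosome."""
    mask = np.zeros(length, dtype=bool)
    for s, e in pairs:
        mask[s:e] = True
    return mask


def runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal covered runs of a boolean mask, as (start, end) half-open pairs."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            out.append((start, i))
    if in_run:
        out.append((start, len(mask)))
    return out


def merge_mask(pairs, gap: int, length: int) -> list[tuple[int, int]]:
    """Merge-with-gap oracle: close gaps of <= gap uncovered bases, then take runs."""
    mask = to_mask(pairs, length)
    if gap > 0:
        covered = runs(mask)
        for (s1, e1), (s2, _e2) in zip(covered, covered[1:]):
            if s2 - e1 <= gap:
                mask[e1:s2] = True
    return runs(mask)


def random_pairs(rng: np.random.Generator, length: int, n: int, max_width: int = 400):
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [(int(s), int(min(length, s + w))) for s, w in zip(starts, widths)]


# -- support-count oracle for replicate consensus ----------------------------

def support_counts_mask(replicate_pairs: list[list[tuple[int, int]]], length: int) -> np.ndarray:
    """Per-base count of replicates covering each base."""
    counts = np.zeros(length, dtype=int)
    for pairs in replicate_pairs:
        counts += to_mask(pairs, length).astype(int)
    return counts


# -- exact Fisher oracle ------------------------------------------------------

_TIE_TOL = Fraction(10**7 + 1, 10**7)  # the conventional 1 + 1e-7 tie tolerance


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric summation."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + n - N), min(K, n)
    denom = comb(N, n)
    pmf = {k: Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs * _TIE_TOL))


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    N, K, n = a + b + c + d, a + b, a + c
    hi = min(K, n)
    denom = comb(N, n)
    return float(
        sum(Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(a, hi + 1))
    )


# -- naive motif scan ---------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_scan(seq: str, log_odds: np.ndarray, threshold: float):
    """All (offset, strand, score) hits by per-offset rescan of both strands."""
    L = log_odds.shape[1]
    idx = {b: i for i, b in enumerate("ACGT")}
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(s) - L + 1):
            window = s[off : off + L]
            if "N" in window:
                continue
            score = sum(log_odds[idx[base], j] for j, base in enumerate(window))
            if score >= threshold:
                fwd_off = off if strand == "+" else len(seq) - L - off
                hits.append((fwd_off, strand, score))
    return hits


# -- naive nearest-TSS --------------------------------------------------------

def naive_nearest_tss(genes, start: int, end: int, chrom: str, max_dist: int):
    """Linear scan over (gene_id, chrom, tss) triples with the documented tie-breaks."""
    best = None
    for gene_id, gchrom, tss in genes:
        if gchrom != chrom:
            continue
        if start <= tss < end:
            dist = 0
        else:
            dist = min(abs(tss - start), abs(tss - (end - 1)))
        if dist > max_dist:
            continue
        key = (dist, gene_id)
        if best is None or key < best:
            best = key
    return None if best is None else (best[1], best[0])
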
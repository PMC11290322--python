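"""Known-motif enrichment per enhancer state, and ternary projections.

Position weight matrices (JASPAR text) are scanned over element sequences on
both strands with additive log-odds scoring, score(offset) = sum_j
log2(p_base / bg_base) in bits.  The default hit threshold is 80% of each
matrix's maximum achievable score.  Per (population, state) category a 2x2
table of elements-with-a-hit against a background element set gives a
one-sided Fisher p for over-representation, and the three populations'
-log10 p values are projected barycentrically for ternary display.

De novo motif discovery is out of scope; only named-PWM enrichment is
implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import ContingencyTable, fisher_p, odds_ratio
from .intervals import GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "MotifEnrichmentResult",
    "TernaryCoordinates",
    "read_jaspar",
    "write_jaspar",
    "read_fasta",
    "write_fasta",
    "extract_element_sequences",
    "scan_pwm",
    "motif_state_enrichment",
    "ternary_projection",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
P_FLOOR = 1e-300  # -log10 p floor


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A 4 x L base-probability matrix with background frequencies.

    Rows are ordered A, C, G, T; every column sums to 1 (within 1e-9).
    Scores are log2(p/background) summed over positions, in bits.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if self.background is None:
            object.__setattr__(self, "background", np.full(4, 0.25))
        else:
            bg = np.asarray(self.background, dtype=float)
            object.__setattr__(self, "background", bg)
        if probs.shape[0] != 4 or probs.shape[1] < 4:
            raise ValidationError(
                f"PWM {self.name!r}: need a 4 x L matrix with L >= 4, got {probs.shape}"
            )
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValidationError(f"PWM {self.name!r}: columns must sum to 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(name=name, probs=probs, background=background, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    element_id: str
    offset: int  # 0-based start on the forward strand
    strand: str  # '+' or '-'
    score: float  # bits


@dataclass
class MotifEnrichmentResult:
    motif: str
    population: str
    state: str
    table: ContingencyTable  # a=fg hit, b=fg no-hit, c=bg hit, d=bg no-hit
    odds_ratio: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(max(self.p_value, P_FLOOR)))


@dataclass(frozen=True)
class TernaryCoordinates:
    motif: str
    state: str
    populations: tuple[str, str, str]
    weights: tuple[float, float, float]  # barycentric, sum to 1


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path) -> list[PositionWeightMatrix]:
    """Read JASPAR-format matrices (via Bio.motifs) into PWMs."""
    from Bio import motifs as bio_motifs

    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
            pwms.append(PositionWeightMatrix.from_counts(m.name or m.matrix_id, counts))
    return pwms


def write_jaspar(pwms: Sequence[PositionWeightMatrix], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR matrix text (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            counts = np.round(pwm.probs * scale).astype(int)
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(str(v) for v in counts[i])
                fh.write(f"{base}  [ {row} ]\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_element_sequences(
    genome_fasta: str | Path, elements: Mapping[str, GenomicInterval]
) -> dict[str, str]:
    """Pull element sequences out of a genome FASTA by coordinates (pyfaidx)."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    return {
        eid: str(genome[iv.chrom][iv.start : iv.end]).upper() for eid, iv in elements.items()
    }


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; N -> -1. Any other character is rejected."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    bad = (out == -1) & (arr != ord("N"))
    if bad.any():
        raise ValidationError(f"sequence contains non-ACGTN characters: {seq[int(np.argmax(bad))]!r}")
    return out


def _scan_encoded(enc: np.ndarray, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every offset of one strand; offsets containing N are invalid."""
    L = log_odds.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    scores = log_odds[windows.clip(min=0), np.arange(L)].sum(axis=1)
    return scores, valid


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    threshold_bits: float | None = None,
) -> list[MotifHit]:
    """Scan both strands of every sequence for PWM hits above the threshold.

    The default threshold is 80% of the matrix's maximum achievable log-odds
    score.  Windows containing N never produce hits; sequences shorter than
    the matrix are skipped with a log entry.  Minus-strand offsets refer to
    the forward-strand start of the hit window.
    """
    if threshold_bits is None:
        threshold_bits = 0.8 * pwm.max_score
    if not np.isfinite(threshold_bits):
        raise ValidationError("threshold_bits must be finite")
    LO = pwm.log_odds
    L = pwm.length
    hits: list[MotifHit] = []
    for eid, seq in sequences.items():
        n = len(seq)
        if n < L:
            logger.info("scan_pwm(%s): sequence %s shorter than matrix (%d < %d), skipped",
                        pwm.name, eid, n, L)
            continue
        enc = _encode(seq)
        rc = np.where(enc >= 0, 3 - enc, -1)[::-1]
        per_element: list[MotifHit] = []
        scores, valid = _scan_encoded(enc, LO)
        for off in np.nonzero(valid & (scores >= threshold_bits))[0]:
            per_element.append(MotifHit(eid, int(off), "+", float(scores[off])))
        scores, valid = _scan_encoded(rc, LO)
        for k in np.nonzero(valid & (scores >= threshold_bits))[0]:
            per_element.append(MotifHit(eid, int(n - L - k), "-", float(scores[k])))
        per_element.sort(key=lambda h: (h.offset, h.strand))
        hits.extend(per_element)
    return hits


# ---------------------------------------------------------------------------
# enrichment and ternary projection
# ---------------------------------------------------------------------------

def motif_state_enrichment(
    hits: Iterable[MotifHit],
    foreground: Iterable[str],
    background: Iterable[str],
    motif: str,
    population: str,
    state: str,
) -> MotifEnrichmentResult:
    """One-sided Fisher test: elements with >= 1 hit, foreground vs background."""
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValidationError("foreground and background must be non-empty")
    if fg & bg:
        raise ValidationError("foreground and background element sets must be disjoint")
    hit_elements = {h.element_id for h in hits}
    a = len(fg & hit_elements)
    b = len(fg - hit_elements)
    c = len(bg & hit_elements)
    d = len(bg - hit_elements)
    # table margins: rows = has-hit / no-hit, columns = foreground / background
    table = ContingencyTable(a, b, c, d)
    return MotifEnrichmentResult(
        motif=motif,
        population=population,
        state=state,
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_p(table, alternative="greater"),
    )


def ternary_projection(results: Sequence[MotifEnrichmentResult]) -> TernaryCoordinates:
    """Barycentric weights of one motif/state across exactly three populations.

    (u, v, w) are the per-population -log10 p values divided by their sum;
    when all three p-values are 1 the projection falls back to the centroid.
    """
    if len(results) != 3:
        raise ValidationError(f"need exactly 3 populations, got {len(results)}")
    motifs = {r.motif for r in results}
    states = {r.state for r in results}
    if len(motifs) != 1 or len(states) != 1:
        raise ValidationError("results must share one motif and one state category")
    pops = tuple(r.population for r in results)
    if len(set(pops)) != 3:
        raise ValidationError("results must come from three distinct populations")
    v = np.array([r.neg_log10_p for r in results])
    s = v.sum()
    weights = tuple(v / s) if s > 0 else (1 / 3, 1 / 3, 1 / 3)
    return TernaryCoordinates(
        motif=motifs.pop(), state=states.pop(), populations=pops,
        weights=tuple(float(w) for w in weights),
    )


def plot_ternary(coords: Sequence[TernaryCoordinates], ax=None, highlight: set[str] | None = None):
    """Simple matplotlib ternary scatter of barycentric motif-enrichment weights."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    tri = np.vstack([corners, corners[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", linewidth=1)
    for c in coords:
        xy = np.asarray(c.weights) @ corners
        emphasized = highlight is not None and c.motif in highlight
        ax.scatter(*xy, c="#c0392b" if emphasized else "#aaaaaa", s=40 if emphasized else 15,
                   zorder=3 if emphasized else 2)
    if coords:
        for corner, pop in zip(corners, coords[0].populations):
            ax.annotate(pop, corner, ha="center", va="bottom" if corner[1] > 0 else "top")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
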
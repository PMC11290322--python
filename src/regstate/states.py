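"""Combinatorial chromatin-state classification of enhancers and promoters.

The element universe is shared across cell populations: the union of all
populations' consensus peaks for the classifying marks, minus annotated
promoter windows, so that a state exists for every (element, population) pair
and statements like "primed in one population, active in another" are
well-posed.

Enhancer states (H3K4me1 / H3K27ac / H3K27me3 / H3K9me3):

* active    - H3K4me1 together with H3K27ac
* primed    - H3K4me1 alone
* bivalent  - H3K4me1 together with H3K27me3
* repressed - H3K9me3 (without H3K4me1)

Where marks co-occur the default precedence puts bivalency above activity
(H3K27me3 dominates H3K27ac within H3K4me1+ elements) and evaluates H3K9me3
only on H3K4me1- elements, keeping the four classes mutually exclusive;
``precedence="active"`` checks H3K27ac before H3K27me3 instead.

Promoter states (H3K4me3-based, the default scheme):

* active_promoter    - H3K4me3 and H3K27ac
* poised_promoter    - H3K4me3 alone
* repressed_promoter - H3K27me3 together with H3K9me3 (no H3K4me3)

An alternative H3K4me1-based scheme (active: H3K27ac and H3K4me1; poised:
H3K27me3 only; repressed: H3K27me3 and H3K9me3) is available as
``scheme="s8c_legend"``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusPeakSet
from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    nearest_tss_hit,
    overlap_flags,
    tss_within,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "ENHANCER_MARKS",
    "PROMOTER_MARKS",
    "ENHANCER_STATES",
    "PROMOTER_STATES",
    "MarkPanel",
    "PromoterWindows",
    "RegulatoryElement",
    "ElementStateTable",
    "enhancer_state",
    "promoter_state",
    "define_promoter_windows",
    "build_enhancer_universe",
    "classify_enhancers",
    "classify_promoters",
    "link_elements_to_genes",
    "state_gene_sets",
]

ENHANCER_MARKS = ("H3K4me1", "H3K27ac", "H3K27me3", "H3K9me3")
PROMOTER_MARKS = ("H3K4me3", "H3K27ac", "H3K27me3", "H3K9me3")
ENHANCER_STATES = ("active", "primed", "bivalent", "repressed", "unclassified")
PROMOTER_STATES = ("active_promoter", "poised_promoter", "repressed_promoter", "unclassified")


class ConfigurationError(ValueError):
    """A panel is missing a mark required by the requested classification."""


@dataclass
class MarkPanel:
    """Consensus peak sets per histone mark for one population."""

    population: str
    marks: dict[str, IntervalSet]

    def __post_init__(self) -> None:
        # accept ConsensusPeakSet values for convenience
        self.marks = {
            m: (v.peaks if isinstance(v, ConsensusPeakSet) else v) for m, v in self.marks.items()
        }

    def require(self, names: Iterable[str]) -> None:
        missing = [m for m in names if m not in self.marks]
        if missing:
            raise ConfigurationError(
                f"panel for {self.population!r} is missing marks: {', '.join(missing)}"
            )

    def knockout(self, marks: Iterable[str]) -> "MarkPanel":
        """Copy of the panel with the named marks replaced by empty peak sets."""
        dropped = set(marks)
        return MarkPanel(
            population=self.population,
            marks={
                m: (IntervalSet(label=f"{self.population}/{m}/knockout") if m in dropped else v)
                for m, v in self.marks.items()
            },
        )


@dataclass
class PromoterWindows:
    """Merged strand-aware windows around annotated TSSs."""

    windows: IntervalSet
    upstream: int
    downstream: int
    source: str = ""


@dataclass
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # "enhancer" | "promoter"
    gene_links: list[tuple[str, int]] = field(default_factory=list)


class ElementStateTable:
    """The element universe with one categorical state per (element, population)."""

    def __init__(self, elements: Iterable[RegulatoryElement], element_class: str | None = None):
        self.elements: list[RegulatoryElement] = list(elements)
        if element_class is not None:
            for el in self.elements:
                el.element_class = element_class
        self.element_class = element_class or (
            self.elements[0].element_class if self.elements else "enhancer"
        )
        self._states: dict[str, list[str]] = {}
        self.link_mode: str | None = None

    # -- states --------------------------------------------------------------
    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self._states)

    @property
    def valid_states(self) -> tuple[str, ...]:
        return ENHANCER_STATES if self.element_class == "enhancer" else PROMOTER_STATES

    def set_population(self, population: str, states: Sequence[str]) -> None:
        if len(states) != len(self.elements):
            raise ValidationError(
                f"{len(states)} states for {len(self.elements)} elements ({population})"
            )
        bad = set(states) - set(self.valid_states)
        if bad:
            raise ValidationError(f"invalid states for {self.element_class}: {sorted(bad)}")
        self._states[population] = list(states)

    def states_for(self, population: str) -> list[str]:
        return list(self._states[population])

    def state(self, index: int, population: str) -> str:
        return self._states[population][index]

    def state_counts(self, population: str) -> Counter:
        return Counter(self._states[population])

    def __len__(self) -> int:
        return len(self.elements)

    # -- export ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, el in enumerate(self.elements):
            row: dict = {
                "chrom": el.interval.chrom,
                "start": el.interval.start,
                "end": el.interval.end,
                "element_class": el.element_class,
            }
            for pop in self._states:
                row[f"state:{pop}"] = self._states[pop][i]
            if el.gene_links:
                row["gene_id"] = el.gene_links[0][0]
                row["gene_distance"] = el.gene_links[0][1]
                row["all_gene_links"] = ";".join(f"{g}:{d}" for g, d in el.gene_links)
            else:
                row["gene_id"] = ""
                row["gene_distance"] = -1
                row["all_gene_links"] = ""
            rows.append(row)
        df = pd.DataFrame(rows)
        if self.link_mode:
            df.attrs["link_mode"] = self.link_mode
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            if self.link_mode:
                fh.write(f"# gene_link_mode={self.link_mode}\n")
            df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# decision rules
# ---------------------------------------------------------------------------

def enhancer_state(
    h3k4me1: bool, h3k27ac: bool, h3k27me3: bool, h3k9me3: bool, precedence: str = "bivalent"
) -> str:
    """State of a single enhancer element from its mark-overlap flags."""
    if precedence not in ("bivalent", "active"):
        raise ValidationError(f"precedence must be 'bivalent' or 'active', got {precedence!r}")
    if h3k4me1:
        if precedence == "bivalent":
            if h3k27me3:
                return "bivalent"
            if h3k27ac:
                return "active"
        else:
            if h3k27ac:
                return "active"
            if h3k27me3:
                return "bivalent"
        return "primed"
    if h3k9me3:
        return "repressed"
    return "unclassified"


def promoter_state(
    h3k4me3: bool, h3k27ac: bool, h3k27me3: bool, h3k9me3: bool, h3k4me1: bool = False,
    scheme: str = "h3k4me3",
) -> str:
    """State of one promoter window from its mark-overlap flags."""
    if scheme == "h3k4me3":
        if h3k4me3:
            return "active_promoter" if h3k27ac else "poised_promoter"
        if h3k27me3 and h3k9me3:
            return "repressed_promoter"
        return "unclassified"
    if scheme == "s8c_legend":
        if h3k27ac and h3k4me1:
            return "active_promoter"
        if h3k27me3 and h3k9me3:
            return "repressed_promoter"
        if h3k27me3:
            return "poised_promoter"
        return "unclassified"
    raise ValidationError(f"unknown promoter scheme {scheme!r}")


# ---------------------------------------------------------------------------
# universe construction
# ---------------------------------------------------------------------------

def define_promoter_windows(
    ann: GenomeAnnotation, upstream: int = 2_000, downstream: int = 2_000, source: str = ""
) -> PromoterWindows:
    """Strand-aware promoter windows, merged into one IntervalSet.

    '+' genes get [tss - upstream, tss + downstream); '-' genes the mirrored
    window [tss - downstream + 1, tss + upstream + 1).  Windows are clipped to
    chromosome bounds when sizes are known.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream and downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValidationError("promoter window cannot be empty (upstream = downstream = 0)")
    intervals = []
    for g in ann.genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream + 1, g.tss + upstream + 1
        s = max(0, s)
        if ann.chrom_sizes is not None and g.chrom in ann.chrom_sizes:
            e = min(e, ann.chrom_sizes[g.chrom])
        if e > s:
            intervals.append(GenomicInterval(g.chrom, s, e))
    return PromoterWindows(
        windows=IntervalSet(intervals, label="promoter_windows"),
        upstream=upstream,
        downstream=downstream,
        source=source,
    )


def build_enhancer_universe(
    panels: Sequence[MarkPanel], prom: PromoterWindows, merge_gap: int = 0
) -> list[RegulatoryElement]:
    """Shared enhancer universe: union of all populations' classifying marks
    outside annotated promoter windows."""
    if not panels:
        raise ValidationError("need at least one mark panel")
    union = IntervalSet(label="enhancer_universe")
    for panel in panels:
        panel.require(ENHANCER_MARKS)
        for mark in ENHANCER_MARKS:
            union = union.union(panel.marks[mark])
    if merge_gap > 0:
        union = union.merge(merge_gap)
    universe = union.subtract(prom.windows)
    return [RegulatoryElement(iv, "enhancer") for iv in universe]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _as_table(
    universe: Sequence[RegulatoryElement] | ElementStateTable, element_class: str
) -> ElementStateTable:
    if isinstance(universe, ElementStateTable):
        return universe
    return ElementStateTable(universe, element_class=element_class)


def classify_enhancers(
    universe: Sequence[RegulatoryElement] | ElementStateTable,
    panel: MarkPanel,
    min_bp: int = 1,
    min_frac: float | None = None,
    precedence: str = "bivalent",
) -> ElementStateTable:
    """Assign one enhancer state per element for ``panel``'s population.

    The overlap criterion is >= ``min_bp`` bases (default 1), optionally
    tightened to a fraction of the element length via ``min_frac``.  Pass the
    returned table back in for further populations to accumulate state
    columns over the same shared universe.
    """
    table = _as_table(universe, "enhancer")
    panel.require(ENHANCER_MARKS)
    ivs = [el.interval for el in table.elements]
    flags = {m: overlap_flags(ivs, panel.marks[m], min_bp=min_bp, min_frac=min_frac)
             for m in ENHANCER_MARKS}
    states = [
        enhancer_state(
            bool(flags["H3K4me1"][i]),
            bool(flags["H3K27ac"][i]),
            bool(flags["H3K27me3"][i]),
            bool(flags["H3K9me3"][i]),
            precedence=precedence,
        )
        for i in range(len(ivs))
    ]
    table.set_population(panel.population, states)
    return table


def classify_promoters(
    prom: PromoterWindows | ElementStateTable,
    panel: MarkPanel,
    min_bp: int = 1,
    min_frac: float | None = None,
    scheme: str = "h3k4me3",
) -> ElementStateTable:
    """Assign one promoter state per promoter window for ``panel``'s population."""
    if isinstance(prom, PromoterWindows):
        table = ElementStateTable(
            (RegulatoryElement(iv, "promoter") for iv in prom.windows), element_class="promoter"
        )
    else:
        table = prom
    required = PROMOTER_MARKS if scheme == "h3k4me3" else ("H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3")
    panel.require(required)
    ivs = [el.interval for el in table.elements]
    flags = {m: overlap_flags(ivs, panel.marks[m], min_bp=min_bp, min_frac=min_frac)
             for m in required}
    false = np.zeros(len(ivs), dtype=bool)
    k4me3 = flags.get("H3K4me3", false)
    k4me1 = flags.get("H3K4me1", false)
    states = [
        promoter_state(
            bool(k4me3[i]),
            bool(flags["H3K27ac"][i]),
            bool(flags["H3K27me3"][i]),
            bool(flags["H3K9me3"][i]),
            h3k4me1=bool(k4me1[i]),
            scheme=scheme,
        )
        for i in range(len(ivs))
    ]
    table.set_population(panel.population, states)
    return table


# ---------------------------------------------------------------------------
# gene linking
# ---------------------------------------------------------------------------

def link_elements_to_genes(
    table: ElementStateTable,
    ann: GenomeAnnotation,
    max_dist: int = 20_000,
    mode: str = "nearest",
) -> ElementStateTable:
    """Attach TSS-proximity gene links to every element (in place).

    ``mode="nearest"`` links each element to the single nearest TSS within
    ``max_dist``; ``mode="all"`` links every TSS within the window.  Elements
    with no TSS in range keep empty links and drop out of gene-level
    enrichment.  The mode is recorded on the table for output metadata.
    """
    if mode not in ("nearest", "all"):
        raise ValidationError(f"mode must be 'nearest' or 'all', got {mode!r}")
    for el in table.elements:
        if mode == "nearest":
            hit = nearest_tss_hit(el.interval, ann, max_dist=max_dist)
            el.gene_links = [hit] if hit is not None else []
        else:
            el.gene_links = tss_within(el.interval, ann, max_dist=max_dist)
    table.link_mode = mode
    return table


def state_gene_sets(table: ElementStateTable, population: str) -> dict[str, set[str]]:
    """Per state, the genes linked to >= 1 element in that state.

    A gene may appear under several states when it neighbors multiple
    elements; the mapping is deliberately non-exclusive.
    """
    out: dict[str, set[str]] = {}
    states = table.states_for(population)
    for el, st in zip(table.elements, states):
        if not el.gene_links:
            continue
        bucket = out.setdefault(st, set())
        for gene_id, _dist in el.gene_links:
            bucket.add(gene_id)
    return out
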
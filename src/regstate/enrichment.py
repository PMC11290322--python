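"""Gene-set overlap statistics, occupancy matrices and enhancer-pattern PCA.

The central statistic is the 2x2 odds ratio of joint gene-set membership
within a declared universe U::

                 in B    not in B
    in A          a         b
    not in A      c         d          a + b + c + d = |U|

    OR = (a * d) / (b * c)

with significance from Fisher's exact test (two-sided, via direct summation
of the hypergeometric distribution: the p-value is the sum of the
probabilities of all tables with point probability <= that of the observed
table, the convention shared by R's fisher.test and scipy).  When any cell is
zero the odds ratio uses the Haldane-Anscombe +0.5 correction; the exact
p-value is never corrected.  Grids of such tests are adjusted with
Benjamini-Hochberg across the whole grid.

The choice of universe materially changes odds ratios; it is therefore an
explicit argument everywhere and echoed in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, ValidationError
from .states import MarkPanel, ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "ContingencyTable",
    "EnrichmentResult",
    "OccupancyMatrix",
    "StatePCAResult",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "fisher_overlap",
    "enrichment_grid",
    "venn_partition",
    "occupancy_matrix",
    "state_pattern_pca",
    "odds_ratio",
    "fisher_p",
    "plot_enrichment_grid",
]

_TIE_REL_TOL = 1e-7  # relative tolerance when comparing point probabilities


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # in both sets
    b: int  # in A only
    c: int  # in B only
    d: int  # in neither, within the universe

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    pair: tuple[str, str]
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    p_adjusted: float | None = None
    significant: bool | None = None


def odds_ratio(table: ContingencyTable) -> float:
    """(a*d)/(b*c), Haldane-Anscombe corrected (+0.5 all cells) iff any cell is 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_p(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher exact p by direct hypergeometric summation.

    The margins fix a hypergeometric distribution for cell ``a``; two-sided
    p sums the probabilities of all support points whose point probability is
    <= that of the observed table (with a 1+1e-7 relative tie tolerance);
    'greater' is the over-representation tail P(X >= a).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    K = a + b  # size of set A within the universe
    n = a + c  # size of set B within the universe
    if N == 0:
        raise ValidationError("empty contingency table")
    rv = hypergeom(N, K, n)
    if alternative == "greater":
        return float(min(1.0, rv.sf(a - 1)))
    if alternative == "less":
        return float(min(1.0, rv.cdf(a)))
    if alternative != "two-sided":
        raise ValidationError(f"unknown alternative {alternative!r}")
    lo = max(0, K + n - N)
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    obs = rv.pmf(a)
    p = float(pmf[pmf <= obs * (1 + _TIE_REL_TOL)].sum())
    return min(1.0, p)


def fisher_overlap(
    setA: GeneSet, setB: GeneSet, universe: GeneSet, alternative: str = "two-sided"
) -> EnrichmentResult:
    """Odds ratio and Fisher exact p for the overlap of two gene sets.

    Genes outside the declared universe are dropped (and logged); the
    contingency table is built over the universe.
    """
    U = universe.genes
    if not U:
        raise ValidationError("universe is empty")
    A = setA.genes & U
    B = setB.genes & U
    droppedA = len(setA.genes) - len(A)
    droppedB = len(setB.genes) - len(B)
    if droppedA or droppedB:
        logger.warning(
            "fisher_overlap(%s, %s): dropped %d/%d genes outside universe",
            setA.name, setB.name, droppedA + droppedB, len(setA.genes) + len(setB.genes),
        )
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    table = ContingencyTable(a, b, c, d)
    return EnrichmentResult(
        pair=(setA.name, setB.name),
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_p(table, alternative=alternative),
    )


def enrichment_grid(
    rows: Sequence[GeneSet],
    cols: Sequence[GeneSet],
    universe: GeneSet,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """All pairwise overlaps with BH adjustment computed across the whole grid.

    Results with raw p above ``alpha`` are flagged not significant (the
    conventional 'gray points' of overlap dot-grids).
    """
    results: list[EnrichmentResult] = []
    for r in rows:
        for ccol in cols:
            results.append(fisher_overlap(r, ccol, universe, alternative=alternative))
    pvals = np.array([res.p_value for res in results])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    records = []
    for res, padj in zip(results, p_adj):
        res.p_adjusted = float(padj)
        res.significant = res.p_value <= alpha
        t = res.table
        records.append(
            {
                "row_set": res.pair[0],
                "col_set": res.pair[1],
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "p_adjusted": res.p_adjusted,
                "significant": res.significant,
            }
        )
    df = pd.DataFrame(records)
    df.attrs["universe"] = universe.name
    df.attrs["alpha"] = alpha
    return df


def venn_partition(sets: Sequence[GeneSet]) -> dict[tuple[str, ...], dict[str, float]]:
    """Exact counts and union fractions for every region of a 2- or 3-set Venn.

    Region keys are tuples of the member set names; each value carries the
    exclusive ``count`` and its ``fraction`` of the union.
    """
    if len(sets) < 2:
        raise ValidationError("venn_partition needs at least 2 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError("set names must be unique")
    union: set[str] = set()
    for s in sets:
        union |= s.genes
    total = len(union)
    out: dict[tuple[str, ...], dict[str, float]] = {}
    for k in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), k):
            inside = set(union)
            for i in combo:
                inside &= sets[i].genes
            for i in range(len(sets)):
                if i not in combo:
                    inside -= sets[i].genes
            key = tuple(names[i] for i in combo)
            out[key] = {"count": len(inside), "fraction": len(inside) / total if total else 0.0}
    return out


# ---------------------------------------------------------------------------
# GMT / gene-list I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {lineno}: GMT needs name, description, genes")
            genes = [g for g in fields[2:] if g]
            sets.append(GeneSet.from_iterable(fields[0], genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One-gene-per-line list."""
    path = Path(path)
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet.from_iterable(name or path.stem, genes)


# ---------------------------------------------------------------------------
# occupancy matrices and pattern PCA
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMatrix:
    """log2(1 + peak count) per catalog region x population, optionally row-z-scaled."""

    data: pd.DataFrame  # rows: region ids, columns: populations
    mark: str
    scaling: str  # "none" | "row_z"


def occupancy_matrix(
    catalog: Mapping[str, GenomicInterval] | Sequence[tuple[str, GenomicInterval]],
    panels: Sequence[MarkPanel],
    mark: str,
    scaling: str = "none",
    count_mode: str = "peaks",
) -> OccupancyMatrix:
    """Per catalog region, log2(1 + number of ``mark`` peaks overlapping it) per population.

    ``scaling="row_z"`` standardizes each row to mean 0 / sd 1 (constant rows
    become all zeros), the usual display form of row-scaled peak heatmaps.
    Counts are peak counts by default; ``count_mode="coverage"`` uses
    overlapping base pairs instead.
    """
    if scaling not in ("none", "row_z"):
        raise ValidationError(f"scaling must be 'none' or 'row_z', got {scaling!r}")
    if count_mode not in ("peaks", "coverage"):
        raise ValidationError(f"count_mode must be 'peaks' or 'coverage', got {count_mode!r}")
    items = list(catalog.items()) if isinstance(catalog, Mapping) else list(catalog)
    if not items:
        raise ValidationError("catalog is empty")
    for panel in panels:
        if mark not in panel.marks:
            raise ConfigurationError(f"mark {mark!r} absent from panel {panel.population!r}")
    mat = np.zeros((len(items), len(panels)))
    for j, panel in enumerate(panels):
        peaks = panel.marks[mark]
        for i, (_rid, iv) in enumerate(items):
            n = peaks.count_overlapping(iv) if count_mode == "peaks" else peaks.overlap_bp(iv)
            mat[i, j] = np.log2(1 + n)
    if scaling == "row_z":
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sd > 0, (mat - mean) / sd, 0.0)
    df = pd.DataFrame(mat, index=[rid for rid, _ in items], columns=[p.population for p in panels])
    return OccupancyMatrix(data=df, mark=mark, scaling=scaling)


@dataclass
class StatePCAResult:
    coordinates: dict[str, np.ndarray]  # condition -> (PC1, PC2, ...)
    explained_variance: np.ndarray  # fraction per PC, non-increasing
    region_universe: str = ""


def state_pattern_pca(
    catalog: Mapping[str, GenomicInterval] | Sequence[tuple[str, GenomicInterval]],
    condition_peaks: Mapping[str, IntervalSet],
    n_components: int = 2,
    region_universe: str = "",
) -> StatePCAResult:
    """PCA of binary region-occupancy patterns across conditions.

    Rows are conditions, columns catalog regions, entries 1 where the
    condition's peaks overlap the region.  The matrix is column-centered and
    decomposed; nested condition peak sets order monotonically along PC1.
    """
    items = list(catalog.items()) if isinstance(catalog, Mapping) else list(catalog)
    if len(items) < 2:
        raise ValidationError("catalog needs >= 2 regions")
    conditions = list(condition_peaks)
    if len(conditions) < max(3, n_components):
        raise ValidationError(
            f"need >= {max(3, n_components)} conditions, got {len(conditions)}"
        )
    M = np.zeros((len(conditions), len(items)))
    for i, cond in enumerate(conditions):
        peaks = condition_peaks[cond]
        for j, (_rid, iv) in enumerate(items):
            M[i, j] = 1.0 if peaks.overlaps_any(iv) else 0.0
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(M)
    return StatePCAResult(
        coordinates={c: coords[i] for i, c in enumerate(conditions)},
        explained_variance=pca.explained_variance_ratio_,
        region_universe=region_universe,
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_enrichment_grid(grid: pd.DataFrame, ax=None, alpha: float = 0.05):
    """Dot-grid of an enrichment grid: dot size ~ odds ratio, gray when p > alpha."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + grid["col_set"].nunique(), 1 + grid["row_set"].nunique()))
    rows = list(dict.fromkeys(grid["row_set"]))
    cols = list(dict.fromkeys(grid["col_set"]))
    for _, rec in grid.iterrows():
        x = cols.index(rec["col_set"])
        y = rows.index(rec["row_set"])
        size = 30 + 40 * np.log2(1 + rec["odds_ratio"])
        color = "#cccccc" if rec["p_value"] > alpha else "#c0392b"
        ax.scatter([x], [y], s=size, c=color, edgecolors="black", linewidths=0.5)
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
    ax.set_yticks(range(len(rows)), rows)
    ax.set_xlim(-0.5, len(cols) - 0.5)
    ax.set_ylim(len(rows) - 0.5, -0.5)
    return ax
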
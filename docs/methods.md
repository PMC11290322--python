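# Methods

## Problem setting

Multi-population profiling of histone post-translational modifications (e.g.
CUT&Tag with peaks called per biological replicate) yields, for each cell
population, one peak set per mark per replicate.  The analysis implemented
here turns those peak sets into a comparable *state landscape*: one
categorical chromatin state per regulatory element per population, linked to
genes and tested for association with lineage-specific gene sets and
transcription-factor motifs.  The scientific question it serves is whether an
uncommitted population holds the enhancers of alternative lineages in primed
or bivalent — rather than active or repressed — configurations.

## Coordinate conventions and interval algebra

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on load, and the TSS of a minus-strand gene is its annotated
transcript end (the 0-based last base).  Interval sets are kept in a strict
normal form — sorted, with overlapping *and abutting* intervals unioned — so a
normalized set is exactly the set of maximal covered runs of its per-base
occupancy, and every operation (merge-with-gap, intersection, subtraction,
overlap queries) can be checked against a per-base boolean-array oracle, which
the test suite does on randomized toy chromosomes.  `merge(gap=g)` unions
intervals separated by at most `g` uncovered bases; under half-open semantics
[0,10) and [12,20) are 2 bp apart.  Peaks are unstranded; strand enters only
through TSS derivation and promoter-window orientation.

## Replicate consensus

For one mark and population, replicates are pooled, merged into candidate
regions (merge gap 0 by default), and each candidate's support is the number
of distinct replicates contributing ≥ 1 bp.  Candidates with support ≥
`min_support` are kept.  The default `min_support=2` of 3 replicates reflects
common overlap-based consensus practice; it is a configurable assumption, not
a measured value.  Candidate regions are the merged pooled union rather than
per-base majority regions, which mirrors how overlap-based consensus tools
construct their peak sets; with merge gap 0 the retained regions coincide with
the per-base support oracle, which the tests verify exactly.

## Element universe and state calls

The enhancer universe is shared across populations: the union over all
populations of the four classifying marks' consensus peaks, minus promoter
windows, split wherever a promoter window interrupts a peak.  A shared
universe is what makes cross-population statements ("primed here, active
there") well-posed; per-population universes would not align.

Promoter windows default to TSS ± 2 kb (strand-aware, clipped to chromosome
bounds).  The window size is a conventional choice and shifts the enhancer
universe, so it is an explicit parameter.

Enhancer decision rule, per element and population, with ≥ 1 bp overlap as
the default criterion (`min_bp`/fraction configurable):

1. H3K4me1 present: H3K27me3 → **bivalent**; else H3K27ac → **active**;
   else → **primed**.
2. H3K4me1 absent: H3K9me3 → **repressed**; else → **unclassified**.

Two precedence questions are genuinely open in the underlying scheme and are
resolved as follows: bivalency dominates activity within H3K4me1⁺ elements
(consistent with how bivalent domains are treated in the literature, and
keeping the four classes mutually exclusive), and H3K9me3 is only consulted on
H3K4me1⁻ elements, so a primed call is never overturned by heterochromatin
overlap.  `precedence="active"` switches the first choice.  The complete
16-row mark-combination table is frozen in the test suite.

Promoter windows are classified per population as active (H3K4me3 ∧ H3K27ac),
poised (H3K4me3 alone) or repressed (H3K27me3 ∧ H3K9me3, H3K4me3⁻).  An
alternative H3K4me1-based scheme (active: H3K27ac ∧ H3K4me1; poised: H3K27me3
only; repressed: H3K27me3 ∧ H3K9me3) exists behind `scheme="s8c_legend"`; the
H3K4me3-based rule is the default because it is self-consistent with the
promoter mark panel.

## Gene linking

Each element is annotated to its nearest TSS with distance 0 when the TSS
falls inside the element, otherwise the distance to the nearer edge base, and
dropped from gene-level analyses when no TSS lies within ± 20 kb.  Ties are
broken by distance then lexicographic gene id, making the assignment
deterministic.  `mode="all"` instead links every TSS within the window; the
mode is recorded in the output metadata because the two readings of
"nearest TSS (± 20 kb)" vs. "genes within ± 20 kb" give different gene sets.
Per-state gene sets are deliberately non-exclusive: a gene neighboring both a
primed and a bivalent element appears in both.

## Enrichment statistics

Gene-set overlap uses the 2×2 odds ratio OR = (a·d)/(b·c) over a declared
universe, with Fisher's exact p computed by direct hypergeometric summation.
The two-sided p follows the standard "sum of point probabilities ≤ observed"
rule with the conventional 1 + 1e-7 relative tie tolerance (so the package,
R's `fisher.test` and scipy agree); the test suite checks it against an exact
rational-arithmetic oracle to 1e-10.  When any cell is zero the odds ratio —
and only the odds ratio — receives the Haldane–Anscombe +0.5 correction; the
exact p is never corrected.  Grids are Benjamini–Hochberg adjusted across all
cells, and results with raw p > α (default 0.05) are flagged.

The gene universe materially changes odds ratios and there is no universally
correct choice; it is therefore a mandatory argument (all annotated genes in
the bundled pipeline) and echoed in the grid metadata.

Catalog occupancy is log₂(1 + number of overlapping peaks) per region and
population — peak counts, reading "peaks overlapping" literally, with
base-pair coverage behind a flag — optionally row-z-scaled (constant rows set
to 0).  The cross-condition pattern PCA builds a binary condition × region
overlap matrix, column-centers it and decomposes it (scikit-learn); nested
condition peak sets order monotonically along PC1.

## Motif enrichment

Known PWMs (JASPAR matrix text, parsed with Biopython) are converted to
probabilities with a pseudocount and scored as log₂(p/background) sums in
bits, uniform background by default.  Both strands are scanned; windows
containing N are skipped; sequences shorter than the matrix are skipped with
a log entry.  The default hit threshold is 80% of each matrix's maximum
achievable score — a per-matrix relative threshold in the spirit of common
known-motif scanners whose per-motif cutoffs are rarely reported.  Enrichment
per (population, state) is a one-sided Fisher test of elements-with-≥ 1-hit
against a background of the same population's unclassified elements
(dinucleotide-shuffled backgrounds being the main alternative; the choice is
logged).  For three populations the −log₁₀ p values are normalized to
barycentric weights (centroid when all p = 1), the coordinates of ternary
plots; p is floored at 1e-300.  De novo motif discovery is out of scope.

## The simulator

`simdata.simulate` emits a complete, self-consistent input set plus truth
tables.  Design choices:

* **Geometry.**  Elements occupy fixed, evenly spaced slots (default 1,000
  elements on one 10 Mb chromosome; widths uniform 400–800 bp).  A subset of
  slots (default 300) carries a gene whose TSS sits 3 kb beyond the element,
  so each gene's nearest element is the one in its own slot, promoter windows
  (± 2 kb) never touch enhancer elements, and adjacent slots stay well clear
  of each other under jitter.  Promoter peaks span TSS ± 500 bp, inside the
  window.
* **States.**  Per population, element states are drawn i.i.d. (default
  active 0.25, primed 0.25, bivalent 0.15, repressed 0.15, unclassified 0.20;
  promoters 0.40/0.30/0.20/0.10), and each state emits exactly the marks of
  its decision rule.  Lineage gene sets are wired to the planted states of
  the uncommitted "DP" population: active → endoderm, primed → epiblast,
  bivalent → trophectoderm, emulating a population whose primed/bivalent
  enhancers flank the genes of lineages it can still enter.
* **Noise.**  Default jitter sd 20 bp on both peak ends per replicate,
  dropout 0.1 per replicate-peak (also settable per mark, e.g. a total
  H3K27ac knockout), spurious peaks at 2/Mb per replicate per mark with
  uniform positions and 200–800 bp widths.  These rates leave ~97% of state
  calls recoverable at 2-of-3 consensus: losing a consensus peak requires
  dropout in ≥ 2 of 3 replicates (~2.8% per mark), and spurious peaks rarely
  replicate.
* **Motifs.**  Element sequences are uniform-random ACGT; three synthetic
  consensus-based matrices (STAT3-, GATA3-, TFAP2C-like, 0.85 on the
  consensus base per column) are written as JASPAR text.  The STAT3 motif is
  planted (as its consensus, at a random offset) in DP-primed elements with
  probability 0.25 against a 0.05 background — the designed 5× ratio — making
  DP the expected ternary apex for the primed category.
* **Reproducibility.**  One seed feeds named substreams (geometry, one per
  population, sequences, motifs) keyed by CRC32 of the stream name, so output
  is byte-identical per seed and adding a population does not reshuffle
  earlier draws.  File write order is fixed.

What the simulator does **not** emulate: read-level data (fragment sizes, Tn5
insertion bias, depth), realistic peak-width and spacing distributions,
correlated states between neighboring elements, distal (> 20 kb) regulation,
GC-structured sequence backgrounds, or inter-replicate efficiency differences
beyond i.i.d. dropout.  Passing the planted-truth tests therefore shows the
pipeline's logic is correct under its stated assumptions, not that real peak
sets of arbitrary quality will classify this cleanly.

`truth_report` matches planted to observed elements by maximal overlap (an
unmatched planted element counts as observed "unclassified", which is also
the correct call when all its marks dropped out) and reports per-population
confusion matrices and the overall recovery fraction.

## Test-suite problem sizes

Randomized-oracle suites use ≥ 1,000 interval instances on ≤ 100 kb toy
chromosomes, 100 consensus instances, and 20 default-noise simulations for
the end-to-end recovery, enrichment-ranking and motif-apex checks (pass
criterion ≥ 19 of 20 seeds).  Fisher p-values are checked against the exact
rational oracle exhaustively for all tables with universe ≤ 25 and on 500
randomized tables with universe up to 500 — the exhaustive bound keeps the
check to a few seconds while covering every tie-heavy small table, where the
two-sided rule is most delicate.

## Known limitations

* Consensus is overlap-based only; affinity (read-count) consensus and
  differential binding are out of scope, as is peak calling itself.
* State calls are binary-overlap decisions; no signal quantification or
  probabilistic segmentation (ChromHMM-style) is attempted.
* Real published numbers from comparable studies depend on unreported tool
  parameters (consensus thresholds, motif libraries, gene universes) and are
  matched qualitatively, not numerically.
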
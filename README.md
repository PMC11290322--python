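# regstate

Chromatin-state landscapes from multi-population histone-mark peak sets.

`regstate` is for epigenomics analysts who have per-replicate peak calls
(BED) for the classic regulatory histone modifications — H3K27ac, H3K4me1,
H3K27me3, H3K9me3 at enhancers and H3K4me3 at promoters — across several cell
populations, and who want to ask how each population's *combinatorial* state
landscape relates to lineage-specific transcription.  The motivating setting
is lineage plasticity in early extra-embryonic endoderm, where an uncommitted
OCT4⁺/PDGFRA⁺ population keeps epiblast genes behind primed enhancers and
trophectoderm genes behind bivalent enhancers, but the machinery is generic.

## What it computes

1. **Consensus peaks.**  Per mark and population, replicate BEDs are pooled,
   merged into candidate regions, and kept when ≥ *k* of *n* replicates
   contribute ≥ 1 bp of overlap (default 2 of 3).

2. **Element states.**  A single enhancer universe — the union of all
   populations' classifying marks, minus promoter windows (default TSS ± 2 kb)
   — is classified per population:

   | state | rule |
   |---|---|
   | active | H3K4me1 ∧ H3K27ac |
   | primed | H3K4me1 alone |
   | bivalent | H3K4me1 ∧ H3K27me3 (dominates H3K27ac) |
   | repressed | H3K9me3 (on H3K4me1⁻ elements) |

   Promoter windows are analogously classified active (H3K4me3 ∧ H3K27ac),
   poised (H3K4me3 alone) or repressed (H3K27me3 ∧ H3K9me3).

3. **Gene linking and enrichment.**  Elements are annotated to their nearest
   TSS within ± 20 kb; the resulting per-state gene sets are tested against
   lineage gene sets with Fisher's exact test over a declared universe,
   OR = (a·d)/(b·c), Benjamini–Hochberg adjusted across the grid.  Catalog
   occupancy matrices (log₂(1 + peaks), row-z-scaled) and a binary
   region-pattern PCA across conditions are included.

4. **Motif enrichment.**  JASPAR-format PWMs are scanned over element
   sequences (log-odds in bits, both strands, threshold 80% of the maximum
   score); per (population, state) enrichment against background elements
   yields −log₁₀ p values projected barycentrically across three populations
   (ternary plots).

5. **Synthetic data.**  `regstate.simdata` plants per-population element
   states, state-wired lineage gene sets and motif instances, emits all input
   files with realistic replicate noise (positional jitter, dropout, spurious
   peaks), and scores recovery against the planted truth.

## Worked example

```python
from regstate.simdata import SimulationConfig, simulate, truth_report
from regstate.pipeline import run_state_pipeline
from regstate.states import state_gene_sets
from regstate.enrichment import GeneSet, enrichment_grid

truth = simulate(SimulationConfig(seed=1), "sim")
result = run_state_pipeline("sim", min_support=2)
print("DP enhancer states:", dict(result.enhancers.state_counts("DP")))
print(f"planted-state recovery: {truth_report(truth, result.enhancers).recovery:.1%}")

gs = state_gene_sets(result.enhancers, "DP")
rows = [GeneSet.from_iterable(f"DP_{s}", gs[s]) for s in ("active", "primed", "bivalent")]
cols = [GeneSet.from_iterable(n, g) for n, g in sorted(truth.gene_sets.items())]
universe = GeneSet.from_iterable("all_genes", truth.promoters["gene_id"])
print(enrichment_grid(rows, cols, universe)
      [["row_set", "col_set", "odds_ratio", "p_adjusted"]].round(3).to_string(index=False))
```

prints

```
DP enhancer states: {'bivalent': 131, 'unclassified': 195, 'active': 234, 'primed': 260, 'repressed': 171}
planted-state recovery: 97.4%
    row_set       col_set  odds_ratio  p_adjusted
  DP_active      endoderm      43.097       0.000
  DP_active      epiblast       0.432       0.004
  DP_active trophectoderm       0.196       0.000
  DP_primed      endoderm       0.414       0.002
  DP_primed      epiblast     152.733       0.000
  DP_primed trophectoderm       0.746       0.452
DP_bivalent      endoderm       0.545       0.081
DP_bivalent      epiblast       0.830       0.572
DP_bivalent trophectoderm      47.049       0.000
```

97.4% of the 3,000 planted (element, population) states survive the default
replicate noise, and the three planted state→lineage pairings (active→
endoderm, primed→epiblast, bivalent→trophectoderm in the DP population) are
the only cells with odds ratios above 1 — the designed signal that primed and
bivalent enhancers in the uncommitted population mark the genes of the
lineages it can still enter.

A `regstate` console command exposes the same steps
(`regstate simulate | consensus | classify | enrich | motif | intervals …`).

## Documentation

`docs/methods.md` describes the model, the decision rules and their
precedence, the simulator's noise model and what it does and does not emulate,
and the numerical choices (tie-breaking, zero-cell correction, thresholds).
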
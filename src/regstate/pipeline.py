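"""End-to-end glue: replicate BEDs -> consensus -> shared universe -> states.

Works from an explicit ``{population: {mark: [replicate BEDs]}}`` mapping or
directly from a directory written by :func:`regstate.simdata.simulate` (which
carries a ``manifest.yaml`` describing the layout).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .consensus import ConsensusPeakSet, ReplicatePeakCollection, build_consensus
from .intervals import GenomeAnnotation, IntervalSet, load_annotation, read_chrom_sizes
from .states import (
    ElementStateTable,
    MarkPanel,
    PromoterWindows,
    build_enhancer_universe,
    classify_enhancers,
    classify_promoters,
    define_promoter_windows,
    link_elements_to_genes,
)

__all__ = ["PipelineResult", "build_panels", "run_state_pipeline", "panels_from_sim_dir"]


@dataclass
class PipelineResult:
    enhancers: ElementStateTable
    promoters: ElementStateTable
    panels: dict[str, MarkPanel]
    annotation: GenomeAnnotation
    promoter_windows: PromoterWindows


def build_panels(
    peak_files: Mapping[str, Mapping[str, Sequence[str | Path]]],
    min_support: int = 2,
    merge_gap: int = 0,
    knockout: Sequence[str] = (),
) -> dict[str, MarkPanel]:
    """Consensus panels per population from replicate BED paths.

    ``knockout`` names marks whose peak files are replaced by empty sets,
    emulating removal of that mark's data.
    """
    panels: dict[str, MarkPanel] = {}
    for population, marks in peak_files.items():
        consensus: dict[str, IntervalSet] = {}
        for mark, paths in marks.items():
            if mark in knockout:
                consensus[mark] = IntervalSet(label=f"{population}/{mark}/knockout")
                continue
            coll = ReplicatePeakCollection.from_bed_files(mark, population, paths)
            consensus[mark] = build_consensus(coll, min_support=min_support,
                                              merge_gap=merge_gap).peaks
        panels[population] = MarkPanel(population=population, marks=consensus)
    return panels


def panels_from_sim_dir(
    simdir: str | Path,
    min_support: int = 2,
    merge_gap: int = 0,
    knockout: Sequence[str] = (),
) -> tuple[dict[str, MarkPanel], GenomeAnnotation]:
    simdir = Path(simdir)
    with open(simdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    peaks_dir = simdir / manifest["peaks_dir"]
    peak_files = {
        pop: {
            mark: [
                peaks_dir / f"{pop}_{mark}_rep{r + 1}.bed"
                for r in range(manifest["replicates"])
            ]
            for mark in manifest["marks"]
        }
        for pop in manifest["populations"]
    }
    panels = build_panels(peak_files, min_support=min_support, merge_gap=merge_gap,
                          knockout=knockout)
    sizes = read_chrom_sizes(simdir / manifest["chrom_sizes"])
    ann = load_annotation(simdir / manifest["annotation"], format="tss_bed", chrom_sizes=sizes)
    return panels, ann


def run_state_pipeline(
    source: str | Path | Mapping[str, Mapping[str, Sequence[str | Path]]],
    annotation: GenomeAnnotation | None = None,
    min_support: int = 2,
    merge_gap: int = 0,
    promoter_upstream: int = 2_000,
    promoter_downstream: int = 2_000,
    max_dist: int = 20_000,
    min_bp: int = 1,
    link_mode: str = "nearest",
    knockout: Sequence[str] = (),
) -> PipelineResult:
    """Full classification pipeline over all populations.

    ``source`` is either a simulate() output directory or a nested mapping of
    replicate BED paths (then ``annotation`` is required).
    """
    if isinstance(source, (str, Path)):
        panels, ann = panels_from_sim_dir(source, min_support=min_support,
                                          merge_gap=merge_gap, knockout=knockout)
    else:
        if annotation is None:
            raise ValueError("annotation is required when passing explicit peak files")
        panels = build_panels(source, min_support=min_support, merge_gap=merge_gap,
                              knockout=knockout)
        ann = annotation
    prom = define_promoter_windows(ann, upstream=promoter_upstream,
                                   downstream=promoter_downstream)
    universe = build_enhancer_universe(list(panels.values()), prom, merge_gap=merge_gap)
    enhancers: ElementStateTable | None = None
    promoters: ElementStateTable | None = None
    for panel in panels.values():
        enhancers = classify_enhancers(enhancers if enhancers is not None else universe,
                                       panel, min_bp=min_bp)
        promoters = classify_promoters(promoters if promoters is not None else prom,
                                       panel, min_bp=min_bp)
    link_elements_to_genes(enhancers, ann, max_dist=max_dist, mode=link_mode)
    link_elements_to_genes(promoters, ann, max_dist=max_dist, mode=link_mode)
    return PipelineResult(
        enhancers=enhancers,
        promoters=promoters,
        panels=panels,
        annotation=ann,
        promoter_windows=prom,
    )
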
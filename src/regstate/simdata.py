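"""Synthetic multi-population histone-peak datasets with planted ground truth.

The generator emulates the inputs of a multi-population CUT&Tag-style study:
for each cell population it plants one chromatin state per regulatory element
and emits the per-replicate peak BED files those states imply (active ->
H3K4me1 + H3K27ac; primed -> H3K4me1; bivalent -> H3K4me1 + H3K27me3;
repressed -> H3K9me3; promoter states analogously through H3K4me3), together
with a TSS annotation, lineage gene sets wired to planted states, element
sequences with planted motif instances, and truth tables for scoring.

Noise model per replicate: independent positional jitter of both peak ends
(Normal(0, jitter_sd), rounded, truncated so intervals stay positive and
inside the chromosome), per-peak dropout, and uniformly placed spurious peaks
at a fixed rate per megabase.  All randomness flows from one seed through
named substreams (keyed by CRC32 of the stream name), so the same seed gives
byte-identical output files and adding populations does not reshuffle earlier
draws.

The default scale -- one 10 Mb chromosome, 300 genes, 1,000 elements, three
populations, three replicates -- runs the full pipeline in seconds.  Elements
sit in fixed evenly spaced slots with the gene TSS 3 kb beyond the element, so
promoter windows (+/- 2 kb) never touch enhancer elements and each gene's
nearest element is the one in its own slot.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSet, write_gmt
from .intervals import GenomicInterval, IntervalSet, ValidationError
from .motifs import PositionWeightMatrix, write_fasta, write_jaspar
from .states import ENHANCER_STATES, PROMOTER_STATES, ElementStateTable

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "PlantedTruth", "TruthReport", "simulate", "truth_report",
           "default_pwms"]

# marks implied by each planted state
STATE_MARKS: dict[str, tuple[str, ...]] = {
    "active": ("H3K4me1", "H3K27ac"),
    "primed": ("H3K4me1",),
    "bivalent": ("H3K4me1", "H3K27me3"),
    "repressed": ("H3K9me3",),
    "unclassified": (),
}
PROMOTER_STATE_MARKS: dict[str, tuple[str, ...]] = {
    "active_promoter": ("H3K4me3", "H3K27ac"),
    "poised_promoter": ("H3K4me3",),
    "repressed_promoter": ("H3K27me3", "H3K9me3"),
    "unclassified": (),
}
ALL_MARKS = ("H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3", "H3K4me3")

DEFAULT_POPULATIONS = ("Oct4", "DP", "Pdgfra")
DEFAULT_STATE_FREQS = {
    "active": 0.25, "primed": 0.25, "bivalent": 0.15, "repressed": 0.15, "unclassified": 0.20,
}
DEFAULT_PROMOTER_FREQS = {
    "active_promoter": 0.40, "poised_promoter": 0.30, "repressed_promoter": 0.20,
    "unclassified": 0.10,
}
# which population/state pairs feed which lineage gene set (uncommitted DP states
# predict the three lineages)
DEFAULT_GENE_LINK_DESIGN = {
    ("DP", "active"): "endoderm",
    ("DP", "primed"): "epiblast",
    ("DP", "bivalent"): "trophectoderm",
}
DEFAULT_MOTIF_PLANT = {("STAT3", "DP", "primed"): 0.25}


def default_pwms() -> list[PositionWeightMatrix]:
    """Idealized consensus-based matrices used for planting (synthetic, not
    database downloads); 0.85 weight on the consensus base per column."""

    def sharp(name: str, consensus: str) -> PositionWeightMatrix:
        probs = np.full((4, len(consensus)), 0.05)
        for j, base in enumerate(consensus):
            probs["ACGT".index(base), j] = 0.85
        return PositionWeightMatrix(name=name, probs=probs)

    return [
        sharp("STAT3", "TTCCCGGAA"),
        sharp("GATA3", "AGATAAGA"),
        sharp("TFAP2C", "GCCTGAGGC"),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 300
    n_elements: int = 1_000
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    replicates: int = 3
    element_min_width: int = 400
    element_max_width: int = 800
    tss_offset: int = 3_000  # TSS placed this far beyond the element end
    promoter_peak_halfwidth: int = 500
    state_design: dict[str, dict[str, float]] | None = None  # population -> state freq
    promoter_design: dict[str, dict[str, float]] | None = None
    gene_link_design: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LINK_DESIGN)
    )
    jitter_sd: float = 20.0
    dropout_prob: float | dict[str, float] = 0.1  # scalar, or per-mark mapping
    spurious_rate: float = 2.0  # spurious peaks per Mb per replicate per mark
    spurious_min_width: int = 200
    spurious_max_width: int = 800
    motif_plant: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PLANT)
    )
    motif_background_rate: float = 0.05
    with_sequences: bool = True

    def resolved_state_design(self) -> dict[str, dict[str, float]]:
        return self.state_design or {p: dict(DEFAULT_STATE_FREQS) for p in self.populations}

    def resolved_promoter_design(self) -> dict[str, dict[str, float]]:
        return self.promoter_design or {p: dict(DEFAULT_PROMOTER_FREQS) for p in self.populations}

    def dropout_for(self, mark: str) -> float:
        if isinstance(self.dropout_prob, Mapping):
            return float(self.dropout_prob.get(mark, 0.0))
        return float(self.dropout_prob)

    def validate(self) -> None:
        if self.n_chroms < 1 or self.n_elements < 1 or self.n_genes < 1:
            raise ValidationError("n_chroms, n_elements and n_genes must be positive")
        if self.n_genes > self.n_elements:
            raise ValidationError("n_genes must be <= n_elements (one slot per gene)")
        if not (0 < self.element_min_width <= self.element_max_width):
            raise ValidationError("element widths must satisfy 0 < min <= max")
        for design, states in (
            (self.resolved_state_design(), ENHANCER_STATES),
            (self.resolved_promoter_design(), PROMOTER_STATES),
        ):
            for pop, freqs in design.items():
                if set(freqs) - set(states):
                    raise ValidationError(f"unknown states in design for {pop}: {freqs}")
                if abs(sum(freqs.values()) - 1.0) > 1e-9:
                    raise ValidationError(f"state frequencies for {pop} must sum to 1")
        probs = [self.motif_background_rate, *self.motif_plant.values()]
        if isinstance(self.dropout_prob, Mapping):
            probs.extend(self.dropout_prob.values())
        else:
            probs.append(self.dropout_prob)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        # element-density guarantee: slots must fit element + TSS + promoter window
        slots_per_chrom = -(-self.n_elements // self.n_chroms)
        slot = self.chrom_length // slots_per_chrom
        needed = 1_000 + self.element_max_width + self.tss_offset + 2_500
        if slot < needed:
            raise ValidationError(
                f"element density too high: slot width {slot} bp < required {needed} bp"
            )


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: adding streams never reshuffles existing ones."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class TruthReport:
    confusion: dict[str, pd.DataFrame]  # population -> planted x observed counts
    recovery: float  # overall fraction of (element, population) calls recovered
    per_population: dict[str, float]


@dataclass
class PlantedTruth:
    """Ground truth emitted by :func:`simulate`, re-derivable from its files."""

    config: SimulationConfig
    elements: pd.DataFrame  # element_id, chrom, start, end, gene_id, state:<pop>...
    promoters: pd.DataFrame  # gene_id, chrom, tss, strand, state:<pop>...
    gene_sets: dict[str, set[str]]  # lineage name -> gene ids
    motif_placements: pd.DataFrame  # motif, element_id, offset
    outdir: Path | None = None

    def element_intervals(self) -> dict[str, GenomicInterval]:
        return {
            row.element_id: GenomicInterval(row.chrom, int(row.start), int(row.end))
            for row in self.elements.itertuples()
        }

    def states_for(self, population: str) -> dict[str, str]:
        col = f"state:{population}"
        return dict(zip(self.elements["element_id"], self.elements[col]))

    def state_elements(self, population: str, state: str) -> set[str]:
        col = f"state:{population}"
        return set(self.elements.loc[self.elements[col] == state, "element_id"])


def _plan_geometry(config: SimulationConfig, rng: np.random.Generator):
    """Fixed element slots, element intervals, gene slots and strands."""
    slots_per_chrom = -(-config.n_elements // config.n_chroms)
    slot_width = config.chrom_length // slots_per_chrom
    records = []
    for i in range(config.n_elements):
        chrom_idx = i // slots_per_chrom
        slot_idx = i % slots_per_chrom
        width = int(rng.integers(config.element_min_width, config.element_max_width + 1))
        start = slot_idx * slot_width + 1_000
        records.append(
            {
                "element_id": f"element_{i:05d}",
                "chrom": f"chr{chrom_idx + 1}",
                "start": start,
                "end": start + width,
            }
        )
    elements = pd.DataFrame(records)
    gene_slots = np.sort(rng.choice(config.n_elements, size=config.n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_genes)
    return elements, gene_slots, strands


def _jittered(rng: np.random.Generator, start: int, end: int, sd: float, chrom_len: int):
    ds = int(np.round(rng.normal(0.0, sd))) if sd > 0 else 0
    de = int(np.round(rng.normal(0.0, sd))) if sd > 0 else 0
    s = max(0, start + ds)
    e = min(chrom_len, end + de)
    if e <= s:  # truncation keeps intervals positive-length
        s = max(0, min(start, chrom_len - 1))
        e = s + 1
    return s, e


def simulate(config: SimulationConfig, outdir: str | Path) -> PlantedTruth:
    """Generate the full synthetic dataset under ``outdir`` and return the truth.

    Deterministic for a fixed config: the same seed produces byte-identical
    files.  Emits per population x mark x replicate BEDs under ``peaks/``, a
    TSS BED + chrom.sizes annotation, a lineage GMT, element FASTA + JASPAR
    matrices, truth TSVs and a ``manifest.yaml`` describing the layout.
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)

    geometry_rng = _stream(config.seed, "geometry")
    elements, gene_slots, strands = _plan_geometry(config, geometry_rng)
    n_el = len(elements)
    chrom_names = sorted(elements["chrom"].unique(), key=lambda c: int(c[3:]))
    chrom_sizes = {c: config.chrom_length for c in chrom_names}

    # genes: TSS a fixed offset beyond their slot's element
    gene_ids = [f"gene_{k:04d}" for k in range(config.n_genes)]
    gene_rows = []
    element_gene = [""] * n_el
    for k, (slot, strand) in enumerate(zip(gene_slots, strands)):
        el = elements.iloc[int(slot)]
        gene_rows.append(
            {
                "gene_id": gene_ids[k],
                "chrom": el["chrom"],
                "tss": int(el["end"]) + config.tss_offset,
                "strand": str(strand),
                "element_id": el["element_id"],
            }
        )
        element_gene[int(slot)] = gene_ids[k]
    genes = pd.DataFrame(gene_rows)
    elements["gene_id"] = element_gene

    # planted states per population
    state_design = config.resolved_state_design()
    promoter_design = config.resolved_promoter_design()
    pop_rngs = {p: _stream(config.seed, f"population:{p}") for p in config.populations}
    for pop in config.populations:
        freqs = state_design[pop]
        names = [s for s in ENHANCER_STATES if s in freqs]
        p = np.array([freqs[s] for s in names])
        elements[f"state:{pop}"] = pop_rngs[pop].choice(names, size=n_el, p=p / p.sum())
        pfreqs = promoter_design[pop]
        pnames = [s for s in PROMOTER_STATES if s in pfreqs]
        pp = np.array([pfreqs[s] for s in pnames])
        genes[f"state:{pop}"] = pop_rngs[pop].choice(pnames, size=len(genes), p=pp / pp.sum())

    # lineage gene sets wired to planted states of each gene's own element
    gene_sets: dict[str, set[str]] = {}
    for (pop, state), lineage in config.gene_link_design.items():
        col = f"state:{pop}"
        linked = genes.loc[
            genes["element_id"].map(dict(zip(elements["element_id"], elements[col]))) == state,
            "gene_id",
        ]
        gene_sets.setdefault(lineage, set()).update(linked)

    # per-replicate peak files
    halfw = config.promoter_peak_halfwidth
    for pop in config.populations:
        rng = pop_rngs[pop]
        for mark in ALL_MARKS:
            dropout = config.dropout_for(mark)
            for rep in range(config.replicates):
                peaks: list[tuple[str, int, int]] = []
                for row in elements.itertuples():
                    if mark not in STATE_MARKS[elements.at[row.Index, f"state:{pop}"]]:
                        continue
                    u = rng.random()
                    s, e = _jittered(rng, int(row.start), int(row.end), config.jitter_sd,
                                     chrom_sizes[row.chrom])
                    if u < dropout:
                        continue
                    peaks.append((row.chrom, s, e))
                for row in genes.itertuples():
                    if mark not in PROMOTER_STATE_MARKS[genes.at[row.Index, f"state:{pop}"]]:
                        continue
                    u = rng.random()
                    s, e = _jittered(rng, int(row.tss) - halfw, int(row.tss) + halfw,
                                     config.jitter_sd, chrom_sizes[row.chrom])
                    if u < dropout:
                        continue
                    peaks.append((row.chrom, s, e))
                total_mb = config.n_chroms * config.chrom_length / 1e6
                n_spurious = int(rng.poisson(config.spurious_rate * total_mb))
                for _ in range(n_spurious):
                    chrom = chrom_names[int(rng.integers(config.n_chroms))]
                    width = int(rng.integers(config.spurious_min_width,
                                             config.spurious_max_width + 1))
                    start = int(rng.integers(0, chrom_sizes[chrom] - width))
                    peaks.append((chrom, start, start + width))
                peaks.sort()
                path = outdir / "peaks" / f"{pop}_{mark}_rep{rep + 1}.bed"
                with open(path, "w") as fh:
                    for chrom, s, e in peaks:
                        fh.write(f"{chrom}\t{s}\t{e}\n")

    # sequences with planted motif instances
    pwms = default_pwms()
    placements: list[dict] = []
    if config.with_sequences:
        seq_rng = _stream(config.seed, "sequences")
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences: dict[str, str] = {}
        widths = (elements["end"] - elements["start"]).to_numpy()
        for row, width in zip(elements.itertuples(), widths):
            codes = seq_rng.integers(0, 4, size=int(width))
            sequences[row.element_id] = bytes(base_bytes[codes]).decode("ascii")
        motif_rng = _stream(config.seed, "motifs")
        for pwm in pwms:
            cons = pwm.consensus
            for row in elements.itertuples():
                prob = config.motif_background_rate
                for (motif, pop, state), plant_prob in config.motif_plant.items():
                    if motif == pwm.name and elements.at[row.Index, f"state:{pop}"] == state:
                        prob = plant_prob
                if motif_rng.random() >= prob:
                    continue
                seq = sequences[row.element_id]
                if len(seq) < len(cons):
                    continue
                offset = int(motif_rng.integers(0, len(seq) - len(cons) + 1))
                sequences[row.element_id] = seq[:offset] + cons + seq[offset + len(cons):]
                placements.append(
                    {"motif": pwm.name, "element_id": row.element_id, "offset": offset}
                )
        write_fasta(sequences, outdir / "elements.fa")
    write_jaspar(pwms, outdir / "motifs.jaspar")

    # annotation + gene sets + truth tables
    with open(outdir / "genes.tss.bed", "w") as fh:
        for row in genes.itertuples():
            fh.write(f"{row.chrom}\t{row.tss}\t{row.tss + 1}\t{row.gene_id}\t0\t{row.strand}\n")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in chrom_names:
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")
    lineages = sorted(gene_sets)
    write_gmt(
        [GeneSet.from_iterable(name, gene_sets[name]) for name in lineages if gene_sets[name]],
        outdir / "genesets.gmt",
        description="planted",
    )
    placements_df = pd.DataFrame(placements, columns=["motif", "element_id", "offset"])
    elements.to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "truth_promoters.tsv", sep="\t", index=False)
    placements_df.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)

    manifest = {
        "populations": list(config.populations),
        "marks": list(ALL_MARKS),
        "replicates": config.replicates,
        "peaks_dir": "peaks",
        "annotation": "genes.tss.bed",
        "chrom_sizes": "chrom.sizes",
        "gene_sets": "genesets.gmt",
        "sequences": "elements.fa" if config.with_sequences else None,
        "pwms": "motifs.jaspar",
        "seed": config.seed,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    promoters = genes.rename(columns={"element_id": "linked_element"})
    return PlantedTruth(
        config=config,
        elements=elements,
        promoters=promoters,
        gene_sets=gene_sets,
        motif_placements=placements_df,
        outdir=outdir,
    )


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def _observed_state_lookup(observed: ElementStateTable, population: str):
    """Per chromosome: (starts, ends, states) arrays for max-overlap matching."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    states = observed.states_for(population)
    buckets: dict[str, list[tuple[int, int, str]]] = {}
    for el, st in zip(observed.elements, states):
        buckets.setdefault(el.interval.chrom, []).append((el.interval.start, el.interval.end, st))
    for chrom, rows in buckets.items():
        rows.sort()
        by_chrom[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            [r[2] for r in rows],
        )
    return by_chrom


def truth_report(
    truth: PlantedTruth,
    observed: ElementStateTable,
    populations: Sequence[str] | None = None,
) -> TruthReport:
    """Confusion matrices and recovery fraction of planted element states.

    Planted elements are matched to observed elements by maximal overlap; a
    planted element with no overlapping observed element counts as observed
    'unclassified' (its marks produced no surviving peaks).  Raises when the
    two universes share no overlap at all despite both being non-empty.
    """
    pops = list(populations or truth.config.populations)
    missing = [p for p in pops if p not in observed.populations]
    if missing:
        raise ValidationError(f"observed table lacks populations: {missing}")
    confusion: dict[str, pd.DataFrame] = {}
    states_order = list(observed.valid_states)
    total = 0
    agree = 0
    any_overlap = False
    for pop in pops:
        lookup = _observed_state_lookup(observed, pop)
        mat = pd.DataFrame(0, index=states_order, columns=states_order, dtype=int)
        planted_states = truth.elements[f"state:{pop}"]
        for row, planted in zip(truth.elements.itertuples(), planted_states):
            entry = lookup.get(row.chrom)
            obs_state = "unclassified"
            if entry is not None:
                starts, ends, obs_states = entry
                lo = int(np.searchsorted(ends, row.start, side="right"))
                hi = int(np.searchsorted(starts, row.end, side="left"))
                best_ov = 0
                for j in range(lo, hi):
                    ov = min(ends[j], row.end) - max(starts[j], row.start)
                    if ov > best_ov:
                        best_ov = int(ov)
                        obs_state = obs_states[j]
                if best_ov > 0:
                    any_overlap = True
            mat.loc[planted, obs_state] += 1
        confusion[pop] = mat
        total += len(truth.elements)
        agree += int(np.diag(mat.to_numpy()).sum())
    if not any_overlap and len(observed.elements) > 0:
        raise ValidationError("planted and observed element universes are disjoint")
    per_pop = {
        pop: float(np.diag(confusion[pop].to_numpy()).sum()) / len(truth.elements)
        for pop in pops
    }
    return TruthReport(confusion=confusion, recovery=agree / total, per_population=per_pop)
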
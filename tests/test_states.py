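"""Enhancer/promoter state calls, the shared universe and gene linking."""

import itertools

import numpy as np
import pytest

import oracles
from regstate.intervals import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    IntervalSet,
    ValidationError,
)
from regstate.states import (
    ConfigurationError,
    ElementStateTable,
    MarkPanel,
    RegulatoryElement,
    build_enhancer_universe,
    classify_enhancers,
    classify_promoters,
    define_promoter_windows,
    link_elements_to_genes,
    state_gene_sets,
    PromoterWindows,
)

CHROM = "chr1"

# The full decision table for the four enhancer marks, fixed by hand:
# (H3K4me1, H3K27ac, H3K27me3, H3K9me3) -> state under the default precedence
# (bivalency over activity; H3K9me3 only consulted on H3K4me1- elements).
ENHANCER_TRUTH_TABLE = {
    (0, 0, 0, 0): "unclassified",
    (0, 0, 0, 1): "repressed",
    (0, 0, 1, 0): "unclassified",
    (0, 0, 1, 1): "repressed",
    (0, 1, 0, 0): "unclassified",
    (0, 1, 0, 1): "repressed",
    (0, 1, 1, 0): "unclassified",
    (0, 1, 1, 1): "repressed",
    (1, 0, 0, 0): "primed",
    (1, 0, 0, 1): "primed",
    (1, 0, 1, 0): "bivalent",
    (1, 0, 1, 1): "bivalent",
    (1, 1, 0, 0): "active",
    (1, 1, 0, 1): "active",
    (1, 1, 1, 0): "bivalent",
    (1, 1, 1, 1): "bivalent",
}

# (H3K4me3, H3K27ac, H3K27me3, H3K9me3) -> promoter state, default scheme.
PROMOTER_TRUTH_TABLE = {
    (0, 0, 0, 0): "unclassified",
    (0, 0, 0, 1): "unclassified",
    (0, 0, 1, 0): "unclassified",
    (0, 0, 1, 1): "repressed_promoter",
    (0, 1, 0, 0): "unclassified",
    (0, 1, 0, 1): "unclassified",
    (0, 1, 1, 0): "unclassified",
    (0, 1, 1, 1): "repressed_promoter",
    (1, 0, 0, 0): "poised_promoter",
    (1, 0, 0, 1): "poised_promoter",
    (1, 0, 1, 0): "poised_promoter",
    (1, 0, 1, 1): "poised_promoter",
    (1, 1, 0, 0): "active_promoter",
    (1, 1, 0, 1): "active_promoter",
    (1, 1, 1, 0): "active_promoter",
    (1, 1, 1, 1): "active_promoter",
}

ENHANCER_ORDER = ("H3K4me1", "H3K27ac", "H3K27me3", "H3K9me3")
PROMOTER_ORDER = ("H3K4me3", "H3K27ac", "H3K27me3", "H3K9me3")


def combo_panel(order, population="DP", extra_marks=()):
    """One element per 4-bit mark combination, each on its own chromosome."""
    elements = []
    marks = {m: [] for m in set(order) | set(extra_marks)}
    for bits in itertools.product((0, 1), repeat=4):
        chrom = "combo" + "".join(map(str, bits))
        elements.append(RegulatoryElement(GenomicInterval(chrom, 100, 600), "enhancer"))
        for present, mark in zip(bits, order):
            if present:
                marks[mark].append(GenomicInterval(chrom, 200, 400))
    panel = MarkPanel(population, {m: IntervalSet(ivs) for m, ivs in marks.items()})
    return elements, panel


class TestEnhancerClassification:
    def test_sixteen_row_truth_table(self):
        elements, panel = combo_panel(ENHANCER_ORDER)
        table = classify_enhancers(elements, panel)
        states = table.states_for("DP")
        for bits, state in zip(itertools.product((0, 1), repeat=4), states):
            assert state == ENHANCER_TRUTH_TABLE[bits], bits

    def test_active_precedence_variant(self):
        elements, panel = combo_panel(ENHANCER_ORDER)
        table = classify_enhancers(elements, panel, precedence="active")
        states = dict(zip(itertools.product((0, 1), repeat=4), table.states_for("DP")))
        assert states[(1, 1, 1, 0)] == "active"  # K27ac wins over K27me3
        assert states[(1, 0, 1, 0)] == "bivalent"

    def test_min_frac_requires_fractional_coverage(self):
        # one element [100,600), a 50 bp H3K4me1 peak: 10% of the element
        el = [RegulatoryElement(GenomicInterval(CHROM, 100, 600), "enhancer")]
        empty = IntervalSet()
        panel = MarkPanel(
            "P",
            {"H3K4me1": IntervalSet.from_tuples([(CHROM, 200, 250)]),
             "H3K27ac": empty, "H3K27me3": empty, "H3K9me3": empty},
        )
        assert classify_enhancers(list(el), panel).states_for("P") == ["primed"]
        assert classify_enhancers(list(el), panel, min_frac=0.05).states_for("P") == ["primed"]
        assert classify_enhancers(list(el), panel, min_frac=0.2).states_for("P") == ["unclassified"]

    def test_missing_mark_is_configuration_error(self):
        elements, panel = combo_panel(ENHANCER_ORDER)
        del panel.marks["H3K9me3"]
        with pytest.raises(ConfigurationError, match="H3K9me3"):
            classify_enhancers(elements, panel)

    def test_dropping_h3k27me3_turns_bivalent_into_active_or_primed(self):
        elements, panel = combo_panel(ENHANCER_ORDER)
        full = classify_enhancers(list(elements), panel).states_for("DP")
        ko = classify_enhancers(list(elements), panel.knockout(["H3K27me3"])).states_for("DP")
        changed = [(a, b) for a, b in zip(full, ko) if a == "bivalent"]
        assert changed and all(b in ("active", "primed") for _, b in changed)

    def test_partition_on_random_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            elements = [
                RegulatoryElement(GenomicInterval(CHROM, int(s), int(s) + 200), "enhancer")
                for s in range(0, 20_000, 1_000)
            ]
            panel = MarkPanel(
                "P",
                {
                    m: IntervalSet.from_tuples(
                        (CHROM, s, e) for s, e in oracles.random_pairs(rng, 20_000, 15)
                    )
                    for m in ENHANCER_ORDER
                },
            )
            table = classify_enhancers(elements, panel)
            counts = table.state_counts("P")
            assert sum(counts.values()) == len(elements)
            assert set(counts) <= {"active", "primed", "bivalent", "repressed", "unclassified"}


class TestPromoterClassification:
    def test_sixteen_row_truth_table(self):
        elements, panel = combo_panel(PROMOTER_ORDER)
        windows = PromoterWindows(IntervalSet(el.interval for el in elements), 2000, 2000)
        table = classify_promoters(windows, panel)
        for bits, state in zip(itertools.product((0, 1), repeat=4), table.states_for("DP")):
            assert state == PROMOTER_TRUTH_TABLE[bits], bits

    def test_legend_scheme_variant(self):
        elements, panel = combo_panel(PROMOTER_ORDER, extra_marks=("H3K4me1",))
        # give every element H3K4me1 so "H3K27ac and H3K4me1" can fire
        panel.marks["H3K4me1"] = IntervalSet(
            GenomicInterval(el.interval.chrom, 200, 400) for el in elements
        )
        windows = PromoterWindows(IntervalSet(el.interval for el in elements), 2000, 2000)
        states = dict(
            zip(
                itertools.product((0, 1), repeat=4),
                classify_promoters(windows, panel, scheme="s8c_legend").states_for("DP"),
            )
        )
        assert states[(0, 1, 0, 0)] == "active_promoter"  # K27ac + K4me1
        assert states[(0, 0, 1, 0)] == "poised_promoter"  # K27me3 only
        assert states[(0, 0, 1, 1)] == "repressed_promoter"
        assert states[(0, 0, 0, 0)] == "unclassified"


class TestPromoterWindows:
    def make_ann(self, strand, tss, size=1_000_000):
        return GenomeAnnotation([GeneModel("g", "g", CHROM, strand, tss)], {CHROM: size})

    def test_plus_strand_window(self):
        w = define_promoter_windows(self.make_ann("+", 10_000), 2_000, 2_000)
        assert [(iv.start, iv.end) for iv in w.windows] == [(8_000, 12_000)]

    def test_minus_strand_mirrored_window(self):
        w = define_promoter_windows(self.make_ann("-", 10_000), 2_000, 2_000)
        assert [(iv.start, iv.end) for iv in w.windows] == [(8_001, 12_001)]

    def test_clipped_at_chromosome_start(self):
        w = define_promoter_windows(self.make_ann("+", 500), 2_000, 2_000)
        assert [(iv.start, iv.end) for iv in w.windows] == [(0, 2_500)]

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            define_promoter_windows(self.make_ann("+", 500), 0, 0)


class TestEnhancerUniverse:
    def make_panel(self, k4me1_pairs):
        empty = IntervalSet()
        return MarkPanel(
            "DP",
            {
                "H3K4me1": IntervalSet.from_tuples((CHROM, s, e) for s, e in k4me1_pairs),
                "H3K27ac": empty,
                "H3K27me3": empty,
                "H3K9me3": empty,
            },
        )

    def test_peak_inside_promoter_yields_empty_universe(self):
        prom = PromoterWindows(IntervalSet.from_tuples([(CHROM, 0, 2_000)]), 1000, 1000)
        assert build_enhancer_universe([self.make_panel([(500, 1_500)])], prom) == []

    def test_promoter_splits_peak_into_two_elements(self):
        prom = PromoterWindows(IntervalSet.from_tuples([(CHROM, 500, 800)]), 1000, 1000)
        universe = build_enhancer_universe([self.make_panel([(0, 1_000)])], prom)
        assert [(el.interval.start, el.interval.end) for el in universe] == [(0, 500), (800, 1_000)]

    def test_random_instance_matches_union_minus_promoter_oracle(self):
        rng = np.random.default_rng(1)
        L = 50_000
        mark_pairs = {m: oracles.random_pairs(rng, L, 20) for m in ENHANCER_ORDER}
        prom_pairs = oracles.random_pairs(rng, L, 10)
        panel = MarkPanel(
            "DP",
            {m: IntervalSet.from_tuples((CHROM, s, e) for s, e in p)
             for m, p in mark_pairs.items()},
        )
        prom = PromoterWindows(
            IntervalSet.from_tuples((CHROM, s, e) for s, e in prom_pairs), 1000, 1000
        )
        universe = build_enhancer_universe([panel], prom)
        mask = np.zeros(L, dtype=bool)
        for pairs in mark_pairs.values():
            mask |= oracles.to_mask(pairs, L)
        mask &= ~oracles.to_mask(prom_pairs, L)
        assert [(el.interval.start, el.interval.end) for el in universe] == oracles.runs(mask)

    def test_enhancers_never_overlap_promoter_windows(self, noiseless_result):
        _, result = noiseless_result
        prom = result.promoter_windows.windows
        for el in result.enhancers.elements:
            assert prom.overlap_bp(el.interval) == 0


class TestGeneLinking:
    @pytest.fixture
    def ann(self):
        return GenomeAnnotation(
            [
                GeneModel("gNear", "gNear", CHROM, "+", 5_099),
                GeneModel("gFar", "gFar", CHROM, "+", 90_000),
            ],
            {CHROM: 200_000},
        )

    def table(self, *pairs):
        return ElementStateTable(
            [RegulatoryElement(GenomicInterval(CHROM, s, e), "enhancer") for s, e in pairs]
        )

    def test_element_links_to_nearest_tss_with_distance(self, ann):
        t = link_elements_to_genes(self.table((0, 100)), ann)
        assert t.elements[0].gene_links == [("gNear", 5_000)]
        assert t.link_mode == "nearest"

    def test_element_beyond_cutoff_has_no_link(self, ann):
        t = link_elements_to_genes(self.table((120_000, 120_500)), ann, max_dist=20_000)
        assert t.elements[0].gene_links == []

    def test_all_mode_links_every_tss_in_window(self):
        ann = GenomeAnnotation(
            [GeneModel(f"g{i}", f"g{i}", CHROM, "+", 1_000 * i) for i in range(1, 6)],
            {CHROM: 100_000},
        )
        t = link_elements_to_genes(self.table((2_500, 2_600)), ann, max_dist=2_000, mode="all")
        # distances: g3 -> 401, g2 -> 500, g4 -> 1401, g1 -> 1500; g5 out of range
        assert t.elements[0].gene_links == [("g3", 401), ("g2", 500), ("g4", 1401), ("g1", 1500)]

    def test_state_gene_sets_non_exclusive(self, ann):
        t = self.table((0, 100), (4_000, 4_200))
        t.set_population("DP", ["primed", "bivalent"])
        link_elements_to_genes(t, ann)
        sets = state_gene_sets(t, "DP")
        assert sets == {"primed": {"gNear"}, "bivalent": {"gNear"}}

    def test_noiseless_links_match_planted_genes(self, noiseless_result):
        """At zero noise every element with a gene in its slot links to exactly
        that gene, and the state->gene map equals the planted one."""
        truth, result = noiseless_result
        planted = dict(zip(truth.elements["element_id"], truth.elements["gene_id"]))
        intervals = truth.element_intervals()
        by_pos = {
            (iv.chrom, iv.start, iv.end): eid for eid, iv in intervals.items()
        }
        for el in result.enhancers.elements:
            key = (el.interval.chrom, el.interval.start, el.interval.end)
            if key not in by_pos:
                continue
            gene = planted[by_pos[key]]
            if gene:
                assert el.gene_links and el.gene_links[0][0] == gene
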
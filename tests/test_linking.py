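import pytest
from hypothesis import given, settings, strategies as st

from tadresponse.core import DifferentialRegion, Gene, GenomicInterval, Interaction
from tadresponse.linking import (
    LinkConfig,
    build_regulatory_domains,
    link_regions_to_genes,
    links_per_gene,
    signal_expression_correlation,
)

CFG = LinkConfig()
SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def region(region_id, start, end, chrom="chr1", lfc=1.0):
    return DifferentialRegion(region_id, GenomicInterval(chrom, start, end), lfc, 0.01)


class TestRegulatoryDomains:
    def test_isolated_plus_gene(self):
        (d,) = build_regulatory_domains([Gene("g", "chr1", 100_000, "+")], SIZES, CFG)
        # basal [95k, 101k), extended 10 kb each way
        assert (d.interval.start, d.interval.end) == (85_000, 111_000)

    def test_isolated_minus_gene_mirrored(self):
        (d,) = build_regulatory_domains([Gene("g", "chr1", 100_000, "-")], SIZES, CFG)
        # basal [99k, 105k)
        assert (d.interval.start, d.interval.end) == (89_000, 115_000)

    def test_left_clip_at_chromosome_start(self):
        (d,) = build_regulatory_domains([Gene("g", "chr1", 3_000, "+")], SIZES, CFG)
        assert (d.interval.start, d.interval.end) == (0, 14_000)

    def test_overlapping_neighbor_basal_never_shrinks(self):
        # B's basal starts at 99,000, inside A's basal [95,000, 101,000):
        # A's right edge must stay at its basal edge 101,000.
        genes = [Gene("A", "chr1", 100_000, "+"), Gene("B", "chr1", 104_000, "+")]
        domains = {d.gene_id: d for d in build_regulatory_domains(genes, SIZES, CFG)}
        assert domains["A"].interval.end == 101_000
        assert domains["B"].interval.start == 99_000  # symmetric never-shrink

    def test_extension_stops_at_neighbor_basal_edge(self):
        genes = [Gene("A", "chr1", 100_000, "+"), Gene("B", "chr1", 120_000, "+")]
        domains = {d.gene_id: d for d in build_regulatory_domains(genes, SIZES, CFG)}
        # B's basal starts at 115,000, inside A's 10 kb extension window
        assert domains["A"].interval.end == 111_000  # capped before reaching B
        genes = [Gene("A", "chr1", 100_000, "+"), Gene("B", "chr1", 108_000, "+")]
        domains = {d.gene_id: d for d in build_regulatory_domains(genes, SIZES, CFG)}
        assert domains["A"].interval.end == 103_000  # stops at B's basal start

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            build_regulatory_domains([Gene("g", "chr9", 10, "+")], SIZES, CFG)
        with pytest.raises(ValueError, match="outside chromosome"):
            build_regulatory_domains([Gene("g", "chr1", 2_000_000, "+")], SIZES, CFG)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 900_000), st.sampled_from(["+", "-"])
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_domain_contains_basal_and_respects_bounds(self, gene_specs):
        from tadresponse.linking import basal_domain

        genes = [
            Gene(f"g{i}", "chr1", tss, strand) for i, (tss, strand) in enumerate(gene_specs)
        ]
        for gene, dom in zip(genes, build_regulatory_domains(genes, SIZES, CFG)):
            b_start, b_end = basal_domain(gene, CFG)
            assert dom.interval.start <= max(0, b_start)
            assert dom.interval.end >= min(SIZES["chr1"], b_end)
            assert dom.interval.start >= 0
            assert dom.interval.end <= SIZES["chr1"]


class TestLinking:
    def setup_method(self):
        self.genes = [Gene("gA", "chr1", 100_000, "+"), Gene("gB", "chr2", 500_000, "+")]
        self.domains = build_regulatory_domains(self.genes, SIZES, CFG)

    def test_linear_link_on_overlap(self):
        links = link_regions_to_genes(
            [region("r1", 100_500, 100_600)], self.domains, [], self.genes, CFG
        )
        assert [(l.region_id, l.gene_id, l.evidence) for l in links] == [
            ("r1", "gA", "linear")
        ]

    def test_no_link_across_chromosomes(self):
        links = link_regions_to_genes(
            [region("r1", 100_500, 100_600, chrom="chr2")],
            [d for d in self.domains if d.interval.chrom == "chr1"],
            [],
            self.genes,
            CFG,
        )
        assert links == []

    def test_interaction_link(self):
        reg = region("r1", 700_000, 700_500)  # far from gA's domain
        ia = Interaction(
            GenomicInterval("chr1", 699_000, 701_000),
            GenomicInterval("chr1", 99_000, 101_000),  # covers TSS +/- 2.5 kb window
            0.001,
        )
        links = link_regions_to_genes([reg], self.domains, [ia], self.genes, CFG)
        assert [(l.region_id, l.gene_id, l.evidence) for l in links] == [
            ("r1", "gA", "interaction")
        ]
        # anchors are symmetric: swapping them gives the same link
        ia_swapped = Interaction(ia.anchor2, ia.anchor1, 0.001)
        assert link_regions_to_genes([reg], self.domains, [ia_swapped], self.genes, CFG) == links

    def test_both_evidences_kept_and_counted_once(self):
        reg = region("r1", 100_500, 100_600)  # inside gA's domain
        ia = Interaction(
            GenomicInterval("chr1", 100_400, 100_700),
            GenomicInterval("chr1", 99_000, 101_000),
            0.001,
        )
        links = link_regions_to_genes([reg], self.domains, [ia], self.genes, CFG)
        assert {(l.evidence) for l in links} == {"linear", "interaction"}
        per_gene = links_per_gene(links)
        assert per_gene["gA"]["n_regions"] == 1  # distinct regions, not evidences
        assert per_gene["gA"]["stratum"] == "1"

    def test_decomposability_without_interactions(self):
        regs = [region("r1", 100_500, 100_600), region("r2", 200_000, 200_100)]
        ia = Interaction(
            GenomicInterval("chr1", 199_900, 200_200),
            GenomicInterval("chr1", 99_000, 101_000),
            0.01,
        )
        with_ia = link_regions_to_genes(regs, self.domains, [ia], self.genes, CFG)
        without = link_regions_to_genes(regs, self.domains, [], self.genes, CFG)
        assert without == [l for l in with_ia if l.evidence == "linear"]

    def test_order_invariance(self):
        regs = [region("r1", 100_500, 100_600), region("r2", 95_500, 95_600)]
        a = link_regions_to_genes(regs, self.domains, [], self.genes, CFG)
        b = link_regions_to_genes(regs[::-1], self.domains[::-1], [], self.genes, CFG)
        assert a == b

    def test_shrinking_extension_only_removes_links(self):
        regs = [region(f"r{i}", s, s + 200) for i, s in enumerate(range(85_000, 115_000, 2_000))]
        links_of = {}
        for ext in (0, 5_000, 10_000):
            cfg = LinkConfig(max_extension=ext)
            domains = build_regulatory_domains(self.genes, SIZES, cfg)
            links_of[ext] = set(
                (l.region_id, l.gene_id)
                for l in link_regions_to_genes(regs, domains, [], self.genes, cfg)
            )
        assert links_of[0] <= links_of[5_000] <= links_of[10_000]


class TestCorrelation:
    def test_perfect_line(self):
        r, p, n = signal_expression_correlation([(0, 0), (1, 2), (2, 4), (3, 6)])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_known_value(self):
        # x=[0,1,2], y=[0,1,4]: r = 2 / sqrt(1 * 13/3) / sqrt(2)... = 0.9608
        r, p, n = signal_expression_correlation([(0, 0), (1, 1), (2, 4)])
        assert r == pytest.approx(0.9608, abs=1e-3)

    @pytest.mark.parametrize(
        "pairs",
        [
            [(0, 1), (1, 2)],  # n < 3
            [(1, 0), (1, 1), (1, 2)],  # constant x
            [(0, 5), (1, 5), (2, 5)],  # constant y
        ],
    )
    def test_undefined_cases_raise(self, pairs):
        with pytest.raises(ValueError):
            signal_expression_correlation(pairs)
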
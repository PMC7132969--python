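"""Splice-graph construction and guided variant reconstruction."""

import numpy as np
import pytest

from _oracles import brute_maximal_novel_paths

from exonscout.exon_discovery import SpliceJunction, TranscribedIsland, call_novel_exons
from exonscout.genomic_io import GeneModel, GenomicInterval
from exonscout.transcript_assembly import (
    AmbiguityError,
    build_splice_graph,
    reconstruct_variants,
)


def make_gene(n_exons, transcripts, chrom="chr1", exon_len=50, gap=100):
    exons = [
        GenomicInterval(chrom, i * (exon_len + gap), i * (exon_len + gap) + exon_len, "+")
        for i in range(n_exons)
    ]
    return GeneModel("g", "+", exons, transcripts)


def novel_call(gene, start, end, junctions=(), tolerance=0):
    island = TranscribedIsland(GenomicInterval(gene.chrom, start, end), 5.0, 6)
    (call,) = call_novel_exons([island], gene, list(junctions), tolerance)
    return call


class TestBuildSpliceGraph:
    def test_guide_only_graph(self):
        gene = make_gene(3, {"t1": [0, 1, 2]})
        graph = build_splice_graph(gene, [], [])
        assert len(graph.nodes) == 3
        assert set(graph.edges) == {(0, 1), (1, 2)}
        assert all(e.guide and e.support == 0 for e in graph.edges.values())

    def test_novel_node_and_junction_edge(self):
        gene = make_gene(3, {"t1": [0, 1, 2]})
        # novel island in the intron between exons 2 and 3, spliced to exon 3
        j = SpliceJunction(gene.chrom, 260, 300, support=4)
        call = novel_call(gene, 210, 260, [j])
        graph = build_splice_graph(gene, [call], [j])
        assert len(graph.nodes) == 4
        assert len(graph.edges) == 3
        novel_index = next(i for i, n in enumerate(graph.nodes) if n.origin == "novel")
        exon3_index = next(
            i for i, n in enumerate(graph.nodes) if n.interval.start == 300
        )
        assert graph.edges[(novel_index, exon3_index)].support == 4

    def test_junction_support_recorded_on_known_edges(self):
        gene = make_gene(2, {"t1": [0, 1]})
        j = SpliceJunction(gene.chrom, 50, 150, support=7)
        graph = build_splice_graph(gene, [], [j])
        assert graph.edges[(0, 1)].support == 7 and graph.edges[(0, 1)].guide

    def test_unmatched_junction_ignored(self):
        gene = make_gene(2, {"t1": [0, 1]})
        j = SpliceJunction(gene.chrom, 999, 1500, support=3)
        graph = build_splice_graph(gene, [], [j])
        assert set(graph.edges) == {(0, 1)}

    def test_ambiguous_boundary_raises(self):
        gene = make_gene(3, {"t1": [0, 1, 2]})
        # two nodes whose starts are within tolerance of the acceptor
        island = TranscribedIsland(GenomicInterval(gene.chrom, 145, 150), 5.0, 6)
        (call,) = call_novel_exons([island], gene, [], 5)
        j = SpliceJunction(gene.chrom, 50, 150, support=2)
        with pytest.raises(AmbiguityError):
            build_splice_graph(gene, [call], [j], boundary_tolerance=5)

    def test_counts_match_independent_construction(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            gene = make_gene(n, {"t1": list(range(n))})
            junctions = []
            for i in range(n - 1):
                if rng.random() < 0.5:
                    junctions.append(
                        SpliceJunction(
                            gene.chrom,
                            gene.exons[i].end,
                            gene.exons[i + 1].start,
                            support=int(rng.integers(1, 9)),
                        )
                    )
            graph = build_splice_graph(gene, [], junctions)
            # independent expectation: guide edges for consecutive exon
            # pairs; junction support added onto matching pairs
            assert len(graph.nodes) == n
            assert set(graph.edges) == {(i, i + 1) for i in range(n - 1)}
            expected_support = {
                (i, i + 1): sum(
                    j.support
                    for j in junctions
                    if j.donor_end == gene.exons[i].end
                    and j.acceptor_start == gene.exons[i + 1].start
                )
                for i in range(n - 1)
            }
            assert {k: e.support for k, e in graph.edges.items()} == expected_support


class TestReconstructVariants:
    def test_guide_plus_novel_first_exon(self):
        gene = make_gene(3, {"t1": [0, 1, 2]})
        j = SpliceJunction(gene.chrom, 260, 300, support=4)
        call = novel_call(gene, 210, 260, [j])
        graph = build_splice_graph(gene, [call], [j])
        result = reconstruct_variants(graph)
        chains = {v.labels for v in result.variants}
        assert chains == {("E1", "E2", "E3"), ("N1", "E3")}

    def test_no_novel_nodes_returns_guides_only(self):
        gene = make_gene(4, {"a": [0, 1, 3], "b": [0, 2, 3]})
        result = reconstruct_variants(build_splice_graph(gene, [], []))
        assert {v.labels for v in result.variants} == {
            ("E1", "E2", "E4"),
            ("E1", "E3", "E4"),
        }
        assert not any(v.novelty for v in result.variants)

    def test_novel_transcript_adopts_guide_structure_downstream(self):
        """A novel first exon spliced onto exon 5 of a 7-exon guide yields
        the chain novel-5-6-7, mirroring guided reconstruction."""
        gene = make_gene(7, {"t1": list(range(7))})
        intron_start = gene.exons[3].end
        j = SpliceJunction(gene.chrom, intron_start + 80, gene.exons[4].start, support=9)
        call = novel_call(gene, intron_start + 30, intron_start + 80, [j])
        graph = build_splice_graph(gene, [call], [j])
        result = reconstruct_variants(graph)
        novel = [v for v in result.variants if v.novelty]
        assert [v.labels for v in novel] == [("N1", "E5", "E6", "E7")]
        assert novel[0].support == 9

    def test_unlinked_novel_node_reported(self):
        gene = make_gene(3, {"t1": [0, 1, 2]})
        call = novel_call(gene, 210, 260)
        result = reconstruct_variants(build_splice_graph(gene, [call], []))
        assert {v.labels for v in result.variants} == {("E1", "E2", "E3")}
        assert [n.label for n in result.unlinked] == ["N1"]

    def test_guide_preservation_under_novel_additions(self):
        """Adding novel nodes never removes or alters a guide variant."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            gene = make_gene(n, {"t1": list(range(n))})
            baseline = reconstruct_variants(build_splice_graph(gene, [], []))
            guide_chains = {v.labels for v in baseline.variants}
            intron = int(rng.integers(0, n - 1))
            s = gene.exons[intron].end + 20
            e = s + 30
            junctions = [SpliceJunction(gene.chrom, e, gene.exons[intron + 1].start)]
            if rng.random() < 0.5:
                junctions.append(SpliceJunction(gene.chrom, gene.exons[intron].end, s))
            call = novel_call(gene, s, e, junctions)
            result = reconstruct_variants(build_splice_graph(gene, [call], junctions))
            assert guide_chains <= {v.labels for v in result.variants}

    def test_chains_are_valid_paths(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            graph = _random_graph(rng)
            result = reconstruct_variants(graph)
            for v in result.variants:
                index = {id(n): i for i, n in enumerate(graph.nodes)}
                chain = [index[id(n)] for n in v.chain]
                for u, w in zip(chain, chain[1:]):
                    assert (u, w) in graph.edges
                starts = [n.interval.start for n in v.chain]
                assert starts == sorted(starts) and len(set(starts)) == len(starts)

    def test_novel_chains_match_maximal_path_enumeration(self):
        """Novel variant chains equal the brute-force enumeration of
        maximal DAG paths through novel nodes (graphs up to 12 nodes)."""
        rng = np.random.default_rng(19)
        for _ in range(300):
            graph = _random_graph(rng, max_nodes=12)
            result = reconstruct_variants(graph)
            index = {id(n): i for i, n in enumerate(graph.nodes)}
            got = {
                tuple(index[id(n)] for n in v.chain)
                for v in result.variants
                if v.novelty
            }
            expected = brute_maximal_novel_paths(graph)
            # nodes with no edges at all are reported unlinked, not as paths
            expected = {p for p in expected if len(p) > 1}
            got = {p for p in got if len(p) > 1}
            assert got == expected


class TestExports:
    def test_variants_gtf_round_trips_novel_chain(self, tmp_path):
        from exonscout.genomic_io import read_gene_annotation
        from exonscout.transcript_assembly import write_variants_gtf

        gene = make_gene(3, {"t1": [0, 1, 2]})
        j = SpliceJunction(gene.chrom, 260, 300, support=4)
        call = novel_call(gene, 210, 260, [j])
        result = reconstruct_variants(build_splice_graph(gene, [call], [j]))
        path = tmp_path / "variants.gtf"
        write_variants_gtf(result.variants, gene.gene_id, gene.strand, path)
        text = path.read_text()
        assert "exonscout_novel" in text
        (reparsed,) = read_gene_annotation(path)
        novel_tx = [tx for tx in reparsed.transcripts if tx.endswith("_novel")]
        assert len(novel_tx) == 1
        chain = reparsed.transcript_exons(novel_tx[0])
        assert [(e.start, e.end) for e in chain] == [(210, 260), (300, 350)]

    def test_calls_bed_is_readable_zero_based(self, tmp_path):
        from exonscout.exon_discovery import write_calls_bed
        from exonscout.genomic_io import read_scored_bed

        gene = make_gene(3, {"t1": [0, 1, 2]})
        j = SpliceJunction(gene.chrom, 260, 300, support=4)
        call = novel_call(gene, 210, 260, [j])
        path = tmp_path / "calls.bed"
        write_calls_bed([call], path)
        (rec,) = read_scored_bed(path)
        assert (rec.interval.start, rec.interval.end) == (210, 260)
        assert "first_exon" in path.read_text()


def _random_graph(rng, max_nodes=10):
    """Random splice graph over a chain of known exons with extra novel
    nodes and random (always left-to-right) junction edges."""
    n_known = int(rng.integers(2, max(3, max_nodes - 2)))
    gene = make_gene(n_known, {"t1": list(range(n_known))})
    calls = []
    junctions = []
    n_novel = int(rng.integers(0, min(3, max_nodes - n_known) + 1))
    placed = 0
    for intron in rng.permutation(n_known - 1)[:n_novel]:
        intron = int(intron)
        s = gene.exons[intron].end + 10 + placed
        e = s + 20
        local = []
        if rng.random() < 0.8:
            local.append(SpliceJunction(gene.chrom, e, gene.exons[intron + 1].start))
        if rng.random() < 0.4:
            local.append(SpliceJunction(gene.chrom, gene.exons[intron].end, s))
        island = TranscribedIsland(GenomicInterval(gene.chrom, s, e), 5.0, 6)
        got = call_novel_exons([island], gene, local, 0)
        if got:
            calls.append(got[0])
            junctions.extend(local)
            placed += 1
    # extra exon-skipping junctions between known exons
    for i in range(n_known - 1):
        for j in range(i + 1, n_known):
            if rng.random() < 0.15:
                junctions.append(
                    SpliceJunction(gene.chrom, gene.exons[i].end, gene.exons[j].start)
                )
    return build_splice_graph(gene, calls, junctions)
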
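"""Format readers/writers and the shared coordinate model."""

import random

import pytest

from conftest import write_sam
from _oracles import brute_cigar_blocks, rf_distance

from exonscout.genomic_io import (
    GenomicInterval,
    ParseError,
    ValidationError,
    cigar_blocks,
    read_alignments,
    read_gene_annotation,
    read_scored_bed,
    sam_library_size,
    write_gene_annotation,
    write_newick,
)
from exonscout.evo_epigenetics import PhyloTree, TreeNode


# ---------------------------------------------------------------------------
# intervals


class TestGenomicInterval:
    def test_length_and_conversion(self):
        iv = GenomicInterval.from_1based("chr7", 144238708, 144239093)
        assert (iv.start, iv.end) == (144238707, 144239093)
        assert iv.length() == 386
        assert iv.to_1based() == (144238708, 144239093)
        assert str(iv) == "chr7:144238708-144239093"

    @pytest.mark.parametrize("start,end", [(10, 10), (10, 5), (-1, 5)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end)

    def test_overlap_is_half_open(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 5, 6))


# ---------------------------------------------------------------------------
# GTF


GTF_LINE = 'chr1\tsrc\texon\t{start}\t{end}\t.\t+\t.\tgene_id "g1"; transcript_id "{tx}";\n'


class TestGeneAnnotation:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            GTF_LINE.format(start=101, end=150, tx="t1")
            + GTF_LINE.format(start=501, end=560, tx="t1")
        )
        (gene,) = read_gene_annotation(path)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 150), (500, 560)]
        assert gene.transcripts == {"t1": [0, 1]}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gene_annotation(path) == []

    def test_shuffled_lines_give_identical_model(self, tmp_path):
        lines = [
            GTF_LINE.format(start=s, end=e, tx=tx)
            for tx, pairs in (("t1", [(101, 150), (501, 560), (901, 980)]),
                              ("t2", [(501, 560), (901, 980)]))
            for s, e in pairs
        ]
        sorted_path = tmp_path / "sorted.gtf"
        sorted_path.write_text("".join(lines))
        shuffled = lines[:]
        random.Random(0).shuffle(shuffled)
        shuffled_path = tmp_path / "shuffled.gtf"
        shuffled_path.write_text("".join(shuffled))
        assert read_gene_annotation(sorted_path) == read_gene_annotation(shuffled_path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(GTF_LINE.format(start=101, end=150, tx="t1") + "not\ta\tgtf\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gene_annotation(path)

    def test_overlapping_exons_rejected(self, tmp_path):
        path = tmp_path / "ovl.gtf"
        path.write_text(
            GTF_LINE.format(start=101, end=150, tx="t1")
            + GTF_LINE.format(start=140, end=200, tx="t1")
        )
        with pytest.raises(ValidationError, match="t1"):
            read_gene_annotation(path)

    def test_round_trip_preserves_coordinates(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            GTF_LINE.format(start=101, end=150, tx="t1")
            + GTF_LINE.format(start=501, end=560, tx="t1")
        )
        genes = read_gene_annotation(path)
        out = tmp_path / "out.gtf"
        write_gene_annotation(genes, out)
        assert read_gene_annotation(out) == genes


# ---------------------------------------------------------------------------
# SAM / CIGAR


def parse_cigar(text):
    out = []
    num = ""
    codes = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((codes[ch], int(num)))
            num = ""
    return out


class TestCigarBlocks:
    @pytest.mark.parametrize(
        "pos1,cigar,expected",
        [
            (101, "50M200N50M", [(100, 150), (350, 400)]),
            (101, "100M", [(100, 200)]),
            (101, "10M5I10M20N10M", [(100, 120), (140, 150)]),
            (101, "5S20M3D10M", [(100, 133)]),
        ],
    )
    def test_known_cigars(self, pos1, cigar, expected):
        assert cigar_blocks(pos1 - 1, parse_cigar(cigar)) == expected

    def test_matches_per_base_walk_on_random_cigars(self):
        """Block extraction equals a brute-force per-base reference walk."""
        rng = random.Random(42)
        ops_ref = [(0, "M"), (2, "D"), (7, "="), (8, "X")]
        for _ in range(1000):
            cig = [(4, rng.randint(1, 10))] if rng.random() < 0.3 else []
            cig.append((0, rng.randint(1, 30)))
            for _ in range(rng.randint(0, 6)):
                kind = rng.random()
                if kind < 0.4:
                    cig.append((3, rng.randint(1, 500)))  # N
                elif kind < 0.6:
                    cig.append((1, rng.randint(1, 5)))  # I
                else:
                    cig.append(rng.choice(ops_ref)[:1] + (rng.randint(1, 40),))
                cig.append((0, rng.randint(1, 30)))
            start = rng.randint(0, 10_000)
            assert cigar_blocks(start, cig) == brute_cigar_blocks(start, cig)

    def test_invalid_operation_rejected(self):
        with pytest.raises(ParseError):
            cigar_blocks(0, [(11, 10)])


class TestReadAlignments:
    def test_spliced_read_blocks(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 101, 60, "50M200N50M")])
        (read,) = read_alignments(sam)
        assert [(b.start, b.end) for b in read.blocks] == [(100, 150), (350, 400)]
        assert read.junctions() == [(150, 350)]

    def test_unique_filter_by_mapq_and_flags(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                ("ok", 0, 101, 60, "50M"),
                ("lowq", 0, 101, 5, "50M"),
                ("secondary", 256, 101, 60, "50M"),
                ("supplementary", 2048, 101, 60, "50M"),
            ],
        )
        stats = {}
        reads = list(read_alignments(sam, unique_only=True, min_mapq=30, stats=stats))
        assert [r.read_id for r in reads] == ["ok"]
        assert stats["skipped_non_unique"] == 3
        everyone = list(read_alignments(sam, unique_only=False))
        assert {r.read_id: r.unique for r in everyone}["lowq"] is False

    def test_missing_cigar_skipped_with_count(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 101, 60, "*"), ("r2", 0, 101, 60, "50M")])
        stats = {}
        reads = list(read_alignments(sam, stats=stats))
        assert len(reads) == 1 and stats["skipped_no_cigar"] == 1

    def test_library_size_from_header_comment(self, tmp_path):
        path = tmp_path / "a.sam"
        text = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n@CO\tlibrary_size:123456\n"
        path.write_text(text + "r1\t0\tchr1\t1\t60\t10M\t*\t0\t0\t*\t*\n")
        assert sam_library_size(path) == 123456

    def test_library_size_falls_back_to_read_count(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 101, 60, "50M"), ("r2", 0, 201, 60, "50M")])
        assert sam_library_size(sam) == 2


# ---------------------------------------------------------------------------
# BED


class TestScoredBed:
    def test_bed5_line(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr7\t100\t200\t.\t0.15\n")
        (rec,) = read_scored_bed(path)
        assert (rec.interval.start, rec.interval.end, rec.score) == (100, 200, 0.15)
        assert not rec.score_missing

    def test_scoreless_record_defaults_and_flags(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr7\t100\t200\n")
        (rec,) = read_scored_bed(path)
        assert rec.score == 0.0 and rec.score_missing

    def test_unsorted_input_sorted_output(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr7\t500\t600\t.\t0.5\nchr7\t100\t200\t.\t0.1\n")
        recs = read_scored_bed(path)
        assert [r.interval.start for r in recs] == [100, 500]

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr7\t200\t100\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_scored_bed(path)


# ---------------------------------------------------------------------------
# Newick


class TestWriteNewick:
    def test_two_leaves_even_split(self):
        root = TreeNode(children=[(TreeNode("A"), 2.5), (TreeNode("B"), 2.5)])
        tree = PhyloTree(root, ("A", "B"))
        assert write_newick(tree) == "(A:2.5,B:2.5);"

    def test_single_leaf(self):
        tree = PhyloTree(TreeNode("A"), ("A",))
        assert write_newick(tree) == "A;"

    def test_round_trip_is_isomorphic(self):
        """A 4-taxon tree re-parses to the same topology and path lengths."""
        import dendropy

        from exonscout.evo_epigenetics import DistanceMatrix, build_nj_tree
        import numpy as np

        d = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float),
        )
        tree = build_nj_tree(d)
        nwk = write_newick(tree)
        assert rf_distance(nwk, nwk) == 0
        reparsed = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = reparsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in pdm.taxon_iter()}
        for i, a in enumerate(d.taxa):
            for j, b in enumerate(d.taxa):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d.matrix[i, j])

    def test_cycle_rejected(self):
        a = TreeNode("A")
        a.children.append((a, 1.0))
        with pytest.raises(ValidationError):
            write_newick(PhyloTree(a, ("A",)))
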
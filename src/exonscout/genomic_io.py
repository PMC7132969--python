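"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals, the
native convention of BED and SAM.  GTF input (1-based inclusive) is
converted on the way in; user-facing reports convert back to 1-based
inclusive strings so that printed coordinates can be compared directly
with genome-browser style positions such as ``chr7:144238708-144239093``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils.feature
import pysam

__all__ = [
    "GenomicIOError",
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "GeneModel",
    "AlignedRead",
    "ScoredInterval",
    "read_gene_annotation",
    "read_alignments",
    "read_scored_bed",
    "write_scored_bed",
    "sam_library_size",
    "cigar_blocks",
    "write_newick",
]

logger = logging.getLogger(__name__)


class GenomicIOError(Exception):
    """Base class for I/O and validation failures in this package."""


class ParseError(GenomicIOError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GenomicIOError):
    """Parsed content violates an invariant of the data model."""


_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unknown/unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @classmethod
    def from_1based(cls, chrom: str, first: int, last: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GTF / browser style)."""
        return cls(chrom, first - 1, last, strand)

    def to_1based(self) -> tuple[int, int]:
        """Return (first, last) in 1-based inclusive convention."""
        return self.start + 1, self.end

    def __str__(self) -> str:  # 1-based inclusive, browser style
        first, last = self.to_1based()
        return f"{self.chrom}:{first}-{last}"


@dataclass
class GeneModel:
    """A gene as a sorted union of exons plus named transcripts.

    ``exons`` is the union of exon intervals across all transcripts,
    sorted by start and pairwise disjoint.  ``transcripts`` maps a
    transcript id to strictly increasing indices into ``exons``.
    """

    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    transcripts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene without exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(f"{self.gene_id}: exons on multiple chromosomes {chroms}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.gene_id}: overlapping or unsorted exons {a} and {b}"
                )
        n = len(self.exons)
        for name, idx in self.transcripts.items():
            if any(j <= i for i, j in zip(idx, idx[1:])):
                raise ValidationError(f"{self.gene_id}/{name}: exon indices not increasing")
            if idx and (idx[0] < 0 or idx[-1] >= n):
                raise ValidationError(f"{self.gene_id}/{name}: exon index out of range")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def introns(self, transcript: Optional[str] = None) -> list[GenomicInterval]:
        """Gaps between consecutive exons (of one transcript, or of the union)."""
        if transcript is None:
            chain = self.exons
        else:
            chain = [self.exons[i] for i in self.transcripts[transcript]]
        out = []
        for a, b in zip(chain, chain[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def transcript_exons(self, transcript: str) -> list[GenomicInterval]:
        return [self.exons[i] for i in self.transcripts[transcript]]


@dataclass(frozen=True)
class AlignedRead:
    """A spliced alignment as ordered gapless reference blocks.

    Gaps between consecutive blocks are splice skips (CIGAR ``N``).
    """

    read_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    unique: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"{self.read_id}: read without aligned blocks")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValidationError(f"{self.read_id}: blocks overlap or are unsorted")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.blocks[0].start, self.blocks[-1].end)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) pairs for each spliced gap."""
        return [
            (a.end, b.start)
            for a, b in zip(self.blocks, self.blocks[1:])
            if b.start > a.end
        ]

    def overlaps(self, region: GenomicInterval) -> bool:
        """True when at least one aligned block intersects ``region``."""
        return any(b.overlaps(region) for b in self.blocks)


@dataclass(frozen=True)
class ScoredInterval:
    """A BED interval with a numeric score (methylation level in [0, 1]).

    ``score_missing`` flags records whose input carried no score column;
    such records default to 0.0 and are rejected by methylation analyses.
    """

    interval: GenomicInterval
    score: float = 0.0
    score_missing: bool = False


# ---------------------------------------------------------------------------
# GTF

def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read exon features of a GTF file into :class:`GeneModel` objects.

    GTF 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.  Exons are grouped per transcript per
    gene; the union exon list of every gene is sorted by start.  Exons of
    different transcripts must be either identical or disjoint.
    """
    path = Path(path)
    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: exon record missing {exc} attribute"
                ) from exc
            iv = GenomicInterval.from_1based(feat.seqid, feat.start, feat.end, feat.strand or ".")
            per_gene.setdefault(gene_id, {}).setdefault(tx_id, []).append(iv)
            strands[gene_id] = feat.strand or "."

    genes = []
    for gene_id in sorted(per_gene):
        tx_exons = per_gene[gene_id]
        union: set[GenomicInterval] = set()
        for tx_id, ivs in tx_exons.items():
            ivs.sort(key=lambda e: (e.start, e.end))
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"{gene_id}/{tx_id}: overlapping exons {a} and {b}"
                    )
            union.update(ivs)
        exons = sorted(union, key=lambda e: (e.start, e.end))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{gene_id}: exons {a} and {b} overlap across transcripts"
                )
        index = {e: i for i, e in enumerate(exons)}
        transcripts = {
            tx_id: [index[e] for e in ivs] for tx_id, ivs in sorted(tx_exons.items())
        }
        genes.append(GeneModel(gene_id, strands[gene_id], exons, transcripts))
    genes.sort(key=lambda g: (g.chrom, g.span.start))
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path, source: str = "exonscout") -> None:
    """Write exon features of the given gene models as GTF."""
    with open(path, "w") as out:
        for gene in genes:
            for tx_id, idx in gene.transcripts.items():
                for k, i in enumerate(idx, 1):
                    e = gene.exons[i]
                    first, last = e.to_1based()
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}"; '
                        f'exon_number "{k}";'
                    )
                    out.write(
                        f"{e.chrom}\t{source}\texon\t{first}\t{last}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# SAM

# CIGAR operations that consume reference within a block: M, D, =, X.
# N (3) opens a new block; I, S, H, P consume no reference.
_REF_EXTEND = frozenset({0, 2, 7, 8})
_NO_REF = frozenset({1, 4, 5, 6})


def cigar_blocks(start: int, cigartuples: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Convert a CIGAR into gapless reference blocks.

    M/=/X/D extend the current block; N closes it and skips; I/S/H/P do
    not consume reference.  ``start`` is the 0-based leftmost reference
    position of the alignment.
    """
    blocks: list[tuple[int, int]] = []
    block_start = cursor = start
    for op, length in cigartuples:
        if op in _REF_EXTEND:
            cursor += length
        elif op == 3:  # N: splice skip
            if cursor > block_start:
                blocks.append((block_start, cursor))
            cursor += length
            block_start = cursor
        elif op in _NO_REF:
            continue
        else:
            raise ParseError(f"unsupported CIGAR operation code {op}")
    if cursor > block_start:
        blocks.append((block_start, cursor))
    return blocks


def read_alignments(
    path: str | Path,
    unique_only: bool = True,
    min_mapq: int = 30,
    stats: Optional[dict] = None,
) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from a headered SAM file.

    A read is "uniquely mapped" when its mapping quality is at least
    ``min_mapq`` and it carries neither the secondary nor the
    supplementary flag.  With ``unique_only`` (the default, matching the
    use of uniquely mapped reads for reconstruction) non-unique reads are
    dropped.  Unmapped records and records without a CIGAR are skipped
    and counted in ``stats``.
    """
    counters = stats if stats is not None else {}
    for key in ("yielded", "skipped_unmapped", "skipped_no_cigar", "skipped_non_unique"):
        counters.setdefault(key, 0)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            # htslib downgrades mapped records lacking a CIGAR to unmapped,
            # so the no-CIGAR counter covers both cases.
            if rec.cigartuples is None:
                counters["skipped_no_cigar"] += 1
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            if rec.is_unmapped:
                counters["skipped_unmapped"] += 1
                continue
            unique = (
                rec.mapping_quality >= min_mapq
                and not rec.is_secondary
                and not rec.is_supplementary
            )
            if unique_only and not unique:
                counters["skipped_non_unique"] += 1
                continue
            blocks = tuple(
                GenomicInterval(rec.reference_name, s, e)
                for s, e in cigar_blocks(rec.reference_start, rec.cigartuples)
            )
            counters["yielded"] += 1
            yield AlignedRead(rec.query_name, rec.reference_name, blocks, unique)


def sam_library_size(path: str | Path) -> int:
    """Total uniquely mapped reads of a library.

    Prefers an explicit ``library_size:N`` comment in the SAM header
    (written by the read simulator, standing in for the genome-wide
    library size of which a single locus is a negligible part); falls
    back to counting unique records in the file.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for comment in sam.header.to_dict().get("CO", []):
            if comment.startswith("library_size:"):
                return int(comment.split(":", 1)[1])
    stats: dict = {}
    count = sum(1 for _ in read_alignments(path, unique_only=True, stats=stats))
    return count


# ---------------------------------------------------------------------------
# BED

def read_scored_bed(path: str | Path) -> list[ScoredInterval]:
    """Read a BED3/BED5 file into sorted :class:`ScoredInterval` records.

    BED's native 0-based half-open coordinates are kept as-is.  The
    score is taken from column 5 (BED5) or from a numeric column 4;
    scoreless records get score 0.0 with ``score_missing=True``.
    """
    path = Path(path)
    out: list[ScoredInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if (
                not stripped.strip()
                or stripped.startswith("#")
                or stripped.startswith(("track", "browser"))
            ):
                continue
            cols = stripped.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            score, missing = 0.0, True
            if len(cols) >= 5:
                score, missing = float(cols[4]), False
            elif len(cols) == 4:
                try:
                    score, missing = float(cols[3]), False
                except ValueError:
                    pass
            out.append(ScoredInterval(GenomicInterval(chrom, start, end), score, missing))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return out


def write_scored_bed(records: Iterable[ScoredInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            iv = rec.interval
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{rec.score:g}\n")


# ---------------------------------------------------------------------------
# Newick

def _format_length(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree) -> str:
    """Serialize a :class:`~exonscout.evo_epigenetics.PhyloTree` to Newick.

    Branch lengths are included; the string is terminated by ``;``.  A
    cyclic structure raises :class:`ValidationError`.
    """
    root = getattr(tree, "root", tree)
    seen: set[int] = set()

    def render(node) -> str:
        if id(node) in seen:
            raise ValidationError("cyclic tree structure")
        seen.add(id(node))
        if not node.children:
            return node.name or ""
        parts = [
            f"{render(child)}:{_format_length(length)}"
            for child, length in node.children
        ]
        label = node.name or ""
        return f"({','.join(parts)}){label}"

    return render(root) + ";"
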
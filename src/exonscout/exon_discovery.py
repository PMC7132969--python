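"""Detection of unannotated exons from spliced RNA-seq alignments.

The core inference: per-base read coverage over a gene locus is scanned
for transcribed islands; islands falling entirely within annotated
introns are candidate novel exons; splice junctions extracted from
N-gapped reads link candidates to annotated exons and classify them as
first, internal or terminal exons of a (novel) transcript.  A candidate
linked only to a downstream exon is the first exon of its transcript —
the situation of an intronic exon spliced onto the downstream annotated
exon but never reached from upstream ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    ValidationError,
)

__all__ = [
    "CoverageTrack",
    "SpliceJunction",
    "TranscribedIsland",
    "NovelExonCall",
    "compute_coverage",
    "extract_junctions",
    "call_islands",
    "call_novel_exons",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MIN_LENGTH",
    "DEFAULT_MERGE_GAP",
    "DEFAULT_MIN_SUPPORT",
    "DEFAULT_BOUNDARY_TOLERANCE",
]

# Defaults tuned to suppress single-read noise while detecting a
# few-hundred-bp exon at modest sequencing depth.
DEFAULT_MIN_DEPTH = 2
DEFAULT_MIN_LENGTH = 50
DEFAULT_MERGE_GAP = 10
DEFAULT_MIN_SUPPORT = 2
DEFAULT_BOUNDARY_TOLERANCE = 5


@dataclass
class CoverageTrack:
    """Per-base read depth over a window."""

    window: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (self.window.length(),):
            raise ValidationError("depth length does not match window length")
        if (self.depth < 0).any():
            raise ValidationError("negative depth")


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """A donor/acceptor coordinate pair with read support.

    ``donor_end`` is the (exclusive) end of the upstream aligned block,
    ``acceptor_start`` the start of the downstream one, both 0-based.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    support: int = 1

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ValidationError(
                f"junction acceptor {self.acceptor_start} <= donor {self.donor_end}"
            )
        if self.support < 1:
            raise ValidationError("junction support must be >= 1")


@dataclass(frozen=True)
class TranscribedIsland:
    """A maximal run of above-threshold coverage."""

    interval: GenomicInterval
    mean_depth: float
    max_depth: int


#: Classification of a novel exon by its junction links.
EXON_CLASSES = ("first_exon", "internal", "terminal", "unlinked")


@dataclass
class NovelExonCall:
    """A transcribed intronic island with its junction links.

    ``upstream_links`` / ``downstream_links`` are ``(exon_index,
    junction)`` pairs in transcript orientation (for a ``-`` strand gene,
    upstream is genomically to the right).  ``exon_class`` follows the
    link-presence truth table: downstream-only = first_exon,
    upstream-only = terminal, both = internal, neither = unlinked.
    """

    island: TranscribedIsland
    upstream_links: list[tuple[int, SpliceJunction]]
    downstream_links: list[tuple[int, SpliceJunction]]
    exon_class: str
    outside_gene_span: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return self.island.interval

    def __post_init__(self) -> None:
        if self.exon_class not in EXON_CLASSES:
            raise ValidationError(f"unknown exon class {self.exon_class!r}")


def write_calls_bed(calls: Iterable["NovelExonCall"], path) -> None:
    """Export novel exon calls as BED6 (0-based, score = mean depth)."""
    with open(path, "w") as out:
        for k, call in enumerate(calls, 1):
            iv = call.interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"novel_exon_{k}_{call.exon_class}\t"
                f"{call.island.mean_depth:g}\t{iv.strand if iv.strand != '.' else '+'}\n"
            )


def classify_links(has_upstream: bool, has_downstream: bool) -> str:
    """Truth table mapping link presence to an exon class."""
    if has_upstream and has_downstream:
        return "internal"
    if has_downstream:
        return "first_exon"
    if has_upstream:
        return "terminal"
    return "unlinked"


def compute_coverage(
    reads: Iterable[AlignedRead],
    window: GenomicInterval,
    stats: Optional[dict] = None,
) -> CoverageTrack:
    """Per-base depth of aligned blocks over ``window``.

    ``depth[i]`` counts read blocks overlapping ``window.start + i``;
    splice-skip gaps contribute nothing.  Reads on other chromosomes are
    skipped (counted in ``stats``).
    """
    counters = stats if stats is not None else {}
    counters.setdefault("skipped_other_chrom", 0)
    depth = np.zeros(window.length(), dtype=np.int64)
    for read in reads:
        if read.chrom != window.chrom:
            counters["skipped_other_chrom"] += 1
            continue
        for block in read.blocks:
            lo = max(block.start, window.start) - window.start
            hi = min(block.end, window.end) - window.start
            if hi > lo:
                depth[lo:hi] += 1
    return CoverageTrack(window, depth)


def extract_junctions(
    reads: Iterable[AlignedRead],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[SpliceJunction]:
    """Distinct (donor_end, acceptor_start) pairs across spliced reads.

    Support counts the number of distinct reads containing the junction;
    junctions below ``min_support`` are dropped.  Output is sorted by
    donor then acceptor coordinate.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    counts: Counter[tuple[str, int, int]] = Counter()
    for read in reads:
        counts.update({(read.chrom, d, a) for d, a in read.junctions()})
    return sorted(
        SpliceJunction(chrom, d, a, support)
        for (chrom, d, a), support in counts.items()
        if support >= min_support
    )


def call_islands(
    cov: CoverageTrack,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_length: int = DEFAULT_MIN_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[TranscribedIsland]:
    """Maximal runs of depth >= ``min_depth``.

    Runs separated by at most ``merge_gap`` sub-threshold bases are
    merged (mean depth is then taken over the whole merged span, gap
    included); merged islands shorter than ``min_length`` are discarded.
    """
    if min_depth < 1 or min_length < 1 or merge_gap < 0:
        raise ValidationError("invalid island-calling parameters")
    above = np.flatnonzero(cov.depth >= min_depth)
    if above.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(above) > 1)
    starts = np.concatenate(([above[0]], above[breaks + 1]))
    ends = np.concatenate((above[breaks] + 1, [above[-1] + 1]))
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    islands = []
    base = cov.window.start
    for s, e in merged:
        if e - s < min_length:
            continue
        segment = cov.depth[s:e]
        islands.append(
            TranscribedIsland(
                GenomicInterval(cov.window.chrom, base + s, base + e, cov.window.strand),
                mean_depth=float(segment.mean()),
                max_depth=int(segment.max()),
            )
        )
    return islands


def _snap_boundaries(
    island: TranscribedIsland,
    left_links: list[tuple[int, SpliceJunction]],
    right_links: list[tuple[int, SpliceJunction]],
) -> TranscribedIsland:
    """Snap island edges to linking junction coordinates.

    Splice sites are base-precise while coverage edges decay gradually,
    so junction evidence outranks the coverage boundary.  Among several
    links the best-supported (then nearest) junction wins.
    """
    interval = island.interval
    start, end = interval.start, interval.end
    if left_links:
        best = max(
            left_links,
            key=lambda l: (l[1].support, -abs(l[1].acceptor_start - start)),
        )
        start = best[1].acceptor_start
    if right_links:
        best = max(
            right_links,
            key=lambda l: (l[1].support, -abs(l[1].donor_end - end)),
        )
        end = best[1].donor_end
    if (start, end) == (interval.start, interval.end):
        return island
    return replace(
        island, interval=GenomicInterval(interval.chrom, start, end, interval.strand)
    )


def call_novel_exons(
    islands: Iterable[TranscribedIsland],
    gene: GeneModel,
    junctions: Iterable[SpliceJunction],
    boundary_tolerance: int = DEFAULT_BOUNDARY_TOLERANCE,
) -> list[NovelExonCall]:
    """Call novel exons: intronic islands linked to annotated exons.

    Islands overlapping *any* annotated exon (the union across all known
    isoforms) are discarded — "novel" means unannotated in every known
    transcript.  A junction is a genomically-right link of an island when
    its donor lies within ``boundary_tolerance`` of the island end and
    its acceptor within tolerance of the start of an annotated exon to
    the right; left links are the mirror case.  Link direction is then
    translated into transcript orientation using the gene strand and the
    exon class assigned from the link truth table.  Island boundaries are
    snapped to linking junction coordinates.
    """
    if boundary_tolerance < 0:
        raise ValidationError("boundary_tolerance must be >= 0")
    junctions = [j for j in junctions if j.chrom == gene.chrom]
    exon_tree = IntervalTree()
    for i, exon in enumerate(gene.exons):
        exon_tree.addi(exon.start, exon.end, i)
    span = gene.span
    calls = []
    for island in islands:
        iv = island.interval
        if iv.chrom != gene.chrom or exon_tree.overlap(iv.start, iv.end):
            continue
        left_links: list[tuple[int, SpliceJunction]] = []
        right_links: list[tuple[int, SpliceJunction]] = []
        for j in junctions:
            # island ... -> exon (junction leaves the island's right edge)
            if abs(j.donor_end - iv.end) <= boundary_tolerance:
                for i, exon in enumerate(gene.exons):
                    if (
                        abs(j.acceptor_start - exon.start) <= boundary_tolerance
                        and exon.start >= iv.end - boundary_tolerance
                    ):
                        right_links.append((i, j))
            # exon -> ... island (junction enters the island's left edge)
            if abs(j.acceptor_start - iv.start) <= boundary_tolerance:
                for i, exon in enumerate(gene.exons):
                    if (
                        abs(j.donor_end - exon.end) <= boundary_tolerance
                        and exon.end <= iv.start + boundary_tolerance
                    ):
                        left_links.append((i, j))
        snapped = _snap_boundaries(island, left_links, right_links)
        if gene.strand == "-":
            upstream, downstream = right_links, left_links
        else:
            upstream, downstream = left_links, right_links
        calls.append(
            NovelExonCall(
                island=snapped,
                upstream_links=sorted(upstream),
                downstream_links=sorted(downstream),
                exon_class=classify_links(bool(upstream), bool(downstream)),
                outside_gene_span=not (
                    span.start <= snapped.interval.start
                    and snapped.interval.end <= span.end
                ),
            )
        )
    return calls
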
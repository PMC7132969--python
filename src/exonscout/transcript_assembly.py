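"""Guided reconstruction of transcript variants over a splice graph.

Annotated exons and novel exon calls become nodes; splice junctions
whose endpoints match node boundaries become read-supported edges, and
consecutive exons of every known (guide) transcript contribute guide
edges.  Variants are the guide transcripts themselves plus, for every
novel node, the maximal paths through the graph that pass through it —
so an intronic first exon spliced onto exon 5 yields a novel transcript
that adopts the known exon structure from exon 5 onward.

All edges run from lower to higher genomic coordinate; minus-strand
genes are handled by interpreting that order as 3'→5'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .exon_discovery import NovelExonCall, SpliceJunction
from .genomic_io import GeneModel, GenomicInterval, ValidationError

__all__ = [
    "AmbiguityError",
    "ExonNode",
    "SpliceEdge",
    "SpliceGraph",
    "TranscriptVariant",
    "ReconstructionResult",
    "build_splice_graph",
    "reconstruct_variants",
]


class AmbiguityError(ValidationError):
    """A junction boundary matches more than one graph node."""


@dataclass(frozen=True)
class ExonNode:
    label: str
    interval: GenomicInterval
    origin: str  # "known" | "novel"

    def __post_init__(self) -> None:
        if self.origin not in ("known", "novel"):
            raise ValidationError(f"unknown node origin {self.origin!r}")


@dataclass
class SpliceEdge:
    """Directed (left-to-right in genomic coordinates) splice link.

    ``support`` is the read count of the matched junction(s); ``guide``
    marks edges implied by a known transcript's exon chain (guide edges
    exist even without read evidence, with support 0).
    """

    support: int = 0
    guide: bool = False


@dataclass
class SpliceGraph:
    """Acyclic by construction: edges only run left to right."""

    nodes: list[ExonNode]
    edges: dict[tuple[int, int], SpliceEdge]
    guides: dict[str, list[int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for (u, v) in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValidationError(f"edge ({u},{v}) endpoint is not a node")
            if self.nodes[u].interval.start >= self.nodes[v].interval.start:
                raise ValidationError(f"edge ({u},{v}) does not run left to right")

    def successors(self, u: int) -> list[int]:
        return sorted(v for (a, v) in self.edges if a == u)

    def predecessors(self, v: int) -> list[int]:
        return sorted(u for (u, b) in self.edges if b == v)


@dataclass
class TranscriptVariant:
    """An ordered exon chain; ``support`` is the minimum read support
    over read-supported edges of the chain (0 when the chain rests on
    guide edges alone)."""

    chain: list[ExonNode]
    novelty: bool
    support: int = 0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(node.label for node in self.chain)

    def __post_init__(self) -> None:
        for a, b in zip(self.chain, self.chain[1:]):
            if b.interval.start <= a.interval.start:
                raise ValidationError("variant chain is not coordinate-monotone")


@dataclass
class ReconstructionResult:
    variants: list[TranscriptVariant]
    unlinked: list[ExonNode] = field(default_factory=list)


def write_variants_gtf(
    variants: Iterable[TranscriptVariant],
    gene_id: str,
    strand: str,
    path,
) -> None:
    """Export variants as GTF exon features.

    Novel variants get generated transcript ids under the
    ``exonscout_novel`` source tag; guide-only variants use ``exonscout``.
    """
    with open(path, "w") as out:
        for t, variant in enumerate(variants, 1):
            source = "exonscout_novel" if variant.novelty else "exonscout"
            tx_id = f"{gene_id}.variant{t}" + ("_novel" if variant.novelty else "")
            for k, node in enumerate(variant.chain, 1):
                first, last = node.interval.to_1based()
                attrs = (
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                    f'exon_number "{k}"; exon_origin "{node.origin}";'
                )
                out.write(
                    f"{node.interval.chrom}\t{source}\texon\t{first}\t{last}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )


def _match_node(
    candidates: list[int],
    nodes: list[ExonNode],
    junction: SpliceJunction,
    side: str,
) -> Optional[int]:
    if len(candidates) > 1:
        labels = ", ".join(nodes[i].label for i in candidates)
        raise AmbiguityError(
            f"junction {junction.donor_end}-{junction.acceptor_start} {side} boundary "
            f"matches multiple nodes: {labels}"
        )
    return candidates[0] if candidates else None


def build_splice_graph(
    gene: GeneModel,
    novel: Iterable[NovelExonCall],
    junctions: Iterable[SpliceJunction],
    boundary_tolerance: int = 5,
) -> SpliceGraph:
    """Assemble the splice graph of known exons plus novel calls.

    A junction becomes an edge when its donor matches a node end and its
    acceptor a node start, each within ``boundary_tolerance``; a
    junction matching more than one node on the same side raises
    :class:`AmbiguityError`.  Junctions matching no node pair are
    ignored.  Guide edges join consecutive exons of each known
    transcript and are always present.
    """
    if boundary_tolerance < 0:
        raise ValidationError("boundary_tolerance must be >= 0")
    nodes: list[ExonNode] = [
        ExonNode(f"E{i + 1}", exon, "known") for i, exon in enumerate(gene.exons)
    ]
    known_index = {i: i for i in range(len(gene.exons))}
    for k, call in enumerate(novel, 1):
        nodes.append(ExonNode(f"N{k}", call.interval, "novel"))
    order = sorted(range(len(nodes)), key=lambda i: (nodes[i].interval.start, nodes[i].interval.end))
    nodes = [nodes[i] for i in order]
    relabel = {old: new for new, old in enumerate(order)}
    known_index = {i: relabel[i] for i in known_index}

    edges: dict[tuple[int, int], SpliceEdge] = {}
    guides: dict[str, list[int]] = {}
    for tx_id, idx in gene.transcripts.items():
        chain = [known_index[i] for i in idx]
        guides[tx_id] = chain
        for u, v in zip(chain, chain[1:]):
            edge = edges.setdefault((u, v), SpliceEdge())
            edge.guide = True

    for j in junctions:
        if j.chrom != gene.chrom:
            continue
        left = [
            i for i, node in enumerate(nodes)
            if abs(node.interval.end - j.donor_end) <= boundary_tolerance
        ]
        right = [
            i for i, node in enumerate(nodes)
            if abs(node.interval.start - j.acceptor_start) <= boundary_tolerance
        ]
        u = _match_node(left, nodes, j, "donor")
        v = _match_node(right, nodes, j, "acceptor")
        if u is None or v is None or u == v:
            continue
        if nodes[u].interval.start >= nodes[v].interval.start:
            continue
        edge = edges.setdefault((u, v), SpliceEdge())
        edge.support += j.support

    return SpliceGraph(nodes, edges, guides, gene.strand)


def _extend(graph: SpliceGraph, start: int, forward: bool) -> list[list[int]]:
    """All maximal paths from ``start`` (exclusive) in one direction."""
    step = graph.successors if forward else graph.predecessors
    paths: list[list[int]] = []

    def dfs(node: int, acc: list[int]) -> None:
        nxt = step(node)
        if not nxt:
            paths.append(list(acc))
            return
        for other in nxt:
            acc.append(other)
            dfs(other, acc)
            acc.pop()

    dfs(start, [])
    return paths


def _chain_support(graph: SpliceGraph, chain: list[int]) -> int:
    supports = [
        graph.edges[(u, v)].support
        for u, v in zip(chain, chain[1:])
        if graph.edges[(u, v)].support > 0
    ]
    return min(supports) if supports else 0


def _is_subchain(short: tuple[int, ...], long: tuple[int, ...]) -> bool:
    if len(short) >= len(long):
        return False
    for i in range(len(long) - len(short) + 1):
        if long[i : i + len(short)] == short:
            return True
    return False


def reconstruct_variants(graph: SpliceGraph) -> ReconstructionResult:
    """Enumerate transcript variants from the splice graph.

    Returns every guide transcript as a (non-novel) variant, plus for
    each novel node all maximal paths through the graph containing it,
    built by extending along read-supported or guide edges in both
    directions.  Novel chains that are contiguous sub-paths of other
    novel chains are suppressed; a novel node with no edges at all
    yields no variant and is reported in ``unlinked``.
    """
    variants: list[TranscriptVariant] = []
    seen: set[tuple[int, ...]] = set()
    for tx_id, chain in graph.guides.items():
        if tuple(chain) in seen:
            continue
        seen.add(tuple(chain))
        variants.append(
            TranscriptVariant(
                [graph.nodes[i] for i in chain],
                novelty=False,
                support=_chain_support(graph, chain),
            )
        )

    novel_chains: set[tuple[int, ...]] = set()
    unlinked: list[ExonNode] = []
    for i, node in enumerate(graph.nodes):
        if node.origin != "novel":
            continue
        if not graph.successors(i) and not graph.predecessors(i):
            unlinked.append(node)
            continue
        backward = _extend(graph, i, forward=False)
        forward = _extend(graph, i, forward=True)
        for back in backward:
            for fwd in forward:
                novel_chains.add(tuple(back[::-1] + [i] + fwd))

    kept = [
        chain
        for chain in novel_chains
        if not any(_is_subchain(chain, other) for other in novel_chains)
    ]
    for chain in sorted(kept):
        if chain in seen:
            continue
        seen.add(chain)
        variants.append(
            TranscriptVariant(
                [graph.nodes[j] for j in chain],
                novelty=True,
                support=_chain_support(graph, list(chain)),
            )
        )
    return ReconstructionResult(variants, unlinked)
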
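"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a result by the most literal method available
(per-base walks, position-set membership, exhaustive enumeration) so
that the optimized implementations can be checked against them.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import numpy as np

from exonscout.evo_epigenetics import PhyloTree, TreeNode
from exonscout.genomic_io import GenomicInterval

_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X


def brute_cigar_blocks(start: int, cigartuples) -> list[tuple[int, int]]:
    """Per-base reference walk: mark each consumed position, merge runs."""
    covered = []
    cursor = start
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            covered.extend(range(cursor, cursor + length))
            cursor += length
        elif op == 3:  # N skips reference without covering it
            cursor += length
        # I/S/H/P consume no reference
    blocks = []
    for pos in covered:
        if blocks and pos == blocks[-1][1]:
            blocks[-1][1] = pos + 1
        else:
            blocks.append([pos, pos + 1])
    return [tuple(b) for b in blocks]


def brute_coverage(reads, window: GenomicInterval) -> np.ndarray:
    """Per-base membership count over all read blocks."""
    depth = np.zeros(window.length(), dtype=int)
    for i, pos in enumerate(range(window.start, window.end)):
        for read in reads:
            if read.chrom != window.chrom:
                continue
            depth[i] += sum(1 for b in read.blocks if b.start <= pos < b.end)
    return depth


def brute_junctions(reads, min_support: int) -> list[tuple[str, int, int, int]]:
    counts: Counter = Counter()
    for read in reads:
        seen = set()
        for a, b in zip(read.blocks, read.blocks[1:]):
            if b.start > a.end:
                seen.add((read.chrom, a.end, b.start))
        counts.update(seen)
    return sorted(
        (c, d, a, n) for (c, d, a), n in counts.items() if n >= min_support
    )


def brute_islands(
    depth: np.ndarray, min_depth: int, min_length: int, merge_gap: int
) -> list[tuple[int, int]]:
    """Literal threshold scan with gap merging, as offsets into the track."""
    runs = []
    i = 0
    n = len(depth)
    while i < n:
        if depth[i] >= min_depth:
            j = i
            while j < n and depth[j] >= min_depth:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(s, e) for s, e in merged if e - s >= min_length]


def brute_union_overlap(query: GenomicInterval, intervals) -> int:
    """Position-set union of interval coverage inside the query."""
    positions = set()
    for iv in intervals:
        if iv.chrom != query.chrom:
            continue
        positions.update(range(max(iv.start, query.start), min(iv.end, query.end)))
    return len(positions)


def brute_maximal_novel_paths(graph) -> set[tuple[int, ...]]:
    """All maximal DAG paths containing at least one novel node."""
    g = nx.DiGraph()
    g.add_nodes_from(range(len(graph.nodes)))
    g.add_edges_from(graph.edges)
    sources = [v for v in g.nodes if g.in_degree(v) == 0]
    sinks = [v for v in g.nodes if g.out_degree(v) == 0]
    novel = {i for i, node in enumerate(graph.nodes) if node.origin == "novel"}
    paths = set()
    for s in sources:
        for t in sinks:
            if s == t:
                if s in novel and not g.degree(s) == 0:
                    continue
                continue
            for path in nx.all_simple_paths(g, s, t):
                if novel & set(path):
                    paths.add(tuple(path))
    return paths


def random_binary_phylo(rng: np.random.Generator, n_taxa: int) -> PhyloTree:
    """A random unrooted binary tree with positive branch lengths."""
    def bl() -> float:
        return float(rng.uniform(0.1, 1.0))

    nodes: list[TreeNode] = [TreeNode(f"t{i}") for i in range(n_taxa)]
    if n_taxa == 2:
        root = TreeNode(children=[(nodes[0], bl()), (nodes[1], bl())])
        return PhyloTree(root, tuple(f"t{i}" for i in range(n_taxa)))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(TreeNode(children=[(a, bl()), (b, bl())]))
    root = TreeNode(children=[(x, bl()) for x in nodes])
    return PhyloTree(root, tuple(f"t{i}" for i in range(n_taxa)))


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds (symmetric bipartition difference) via dendropy."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)
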
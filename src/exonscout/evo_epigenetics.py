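"""Evolutionary and epigenetic characterization of a genomic region.

Three independent analyses over supplied inputs:

* windowed mean pairwise identity across a multi-species alignment, with
  conserved blocks called as runs of high-identity windows (an
  identity-based stand-in for browser conservation tracks);
* pairwise distances (p-distance or Jukes-Cantor 1969) and a
  neighbor-joining phylogeny (Saitou & Nei), serialized as Newick;
* overlap between a query region and hypomethylated intervals of
  tissue methylation tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import AlignIO

from .genomic_io import GenomicInterval, ScoredInterval, ValidationError

__all__ = [
    "Msa",
    "ConservationProfile",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "read_msa",
    "conserved_blocks",
    "pairwise_distances",
    "build_nj_tree",
    "methylation_overlap",
    "MethylationOverlap",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "DEFAULT_IDENTITY_THRESHOLD",
    "DEFAULT_HYPO_THRESHOLD",
    "DEFAULT_UPSTREAM_CONTEXT",
]

# Conservation windowing defaults: 20-column windows every 10 columns,
# a block being windows with mean pairwise identity >= 0.8.
DEFAULT_WINDOW = 20
DEFAULT_STEP = 10
DEFAULT_IDENTITY_THRESHOLD = 0.8
#: Methylation level at or below which an interval counts as hypomethylated.
DEFAULT_HYPO_THRESHOLD = 0.3
#: Upstream context (bp) included ahead of an exon for conservation work,
#: wide enough to cover a promoter-proximal conserved block.
DEFAULT_UPSTREAM_CONTEXT = 200

_VALID_CHARS = set("ACGTN-")
_BASES = set("ACGT")


@dataclass
class Msa:
    """A gap-aware multiple sequence alignment over {A,C,G,T,N,-}."""

    records: dict[str, str]
    aligned_length: int = 0

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        lengths = {len(seq) for seq in self.records.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal aligned lengths: {sorted(lengths)}")
        self.aligned_length = lengths.pop()
        for name, seq in self.records.items():
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise ValidationError(f"{name}: invalid characters {sorted(bad)}")
            self.records[name] = seq.upper()

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.records)


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file."""
    alignment = AlignIO.read(str(path), "fasta")
    return Msa({rec.id: str(rec.seq) for rec in alignment})


@dataclass
class ConservationProfile:
    """Windowed mean pairwise identity; NaN marks undefined windows
    (all sequence pairs gap-only in the window)."""

    window_size: int
    step: int
    scores: list[tuple[int, float]]


def _pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of matching sites among columns where both are bases."""
    comparable = np.isin(a, _BASE_CODES) & np.isin(b, _BASE_CODES)
    n = int(comparable.sum())
    if n == 0:
        return math.nan
    return float((a[comparable] == b[comparable]).sum() / n)


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(msa: Msa) -> dict[str, np.ndarray]:
    return {
        name: np.frombuffer(seq.encode(), dtype=np.uint8)
        for name, seq in msa.records.items()
    }


def conserved_blocks(
    msa: Msa,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[ConservationProfile, list[tuple[int, int]]]:
    """Sliding-window conservation and high-identity blocks.

    Per window the score is the mean over all sequence pairs of
    (matching non-gap sites / sites where both are non-gap); pairs with
    no comparable site in the window are excluded, and a window where
    every pair is excluded scores NaN and cannot join a block.  Blocks
    are maximal runs of consecutive windows scoring >= ``threshold``,
    merged into alignment-coordinate intervals ``[start, end)``.
    """
    if window_size < 1 or step < 1:
        raise ValidationError("window_size and step must be >= 1")
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    encoded = _encode(msa)
    names = sorted(encoded)  # species-order invariance
    scores: list[tuple[int, float]] = []
    for start in range(0, msa.aligned_length, step):
        end = min(start + window_size, msa.aligned_length)
        pair_scores = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                s = _pairwise_identity(
                    encoded[names[i]][start:end], encoded[names[j]][start:end]
                )
                if not math.isnan(s):
                    pair_scores.append(s)
        scores.append((start, float(np.mean(pair_scores)) if pair_scores else math.nan))

    blocks: list[tuple[int, int]] = []
    current: Optional[list[int]] = None
    for start, score in scores:
        end = min(start + window_size, msa.aligned_length)
        qualifies = not math.isnan(score) and score >= threshold
        if qualifies:
            if current is None:
                current = [start, end]
            else:
                current[1] = max(current[1], end)
        elif current is not None:
            blocks.append((current[0], current[1]))
            current = None
    if current is not None:
        blocks.append((current[0], current[1]))
    return ConservationProfile(window_size, step, scores), blocks


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValidationError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite distance")
        if np.any(self.matrix < 0):
            raise ValidationError("negative distance")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValidationError("non-zero diagonal")


def pairwise_distances(msa: Msa, model: str = "jc69") -> DistanceMatrix:
    """p-distance or JC69 distances with pairwise deletion.

    p = mismatches / sites where both sequences are bases;
    jc69 = -(3/4) ln(1 - (4/3) p), undefined (saturation error) at
    p >= 0.75.  A pair with zero comparable sites is an error.
    """
    if model not in ("p_distance", "jc69"):
        raise ValidationError(f"unknown distance model {model!r}")
    encoded = _encode(msa)
    taxa = tuple(msa.records)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = encoded[taxa[i]], encoded[taxa[j]]
            comparable = np.isin(a, _BASE_CODES) & np.isin(b, _BASE_CODES)
            sites = int(comparable.sum())
            if sites == 0:
                raise ValidationError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            p = float((a[comparable] != b[comparable]).sum() / sites)
            if model == "p_distance":
                dist = p
            else:
                if p >= 0.75:
                    raise ValidationError(
                        f"JC69 saturated (p={p:.3f}) for pair {taxa[i]}/{taxa[j]}"
                    )
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """An unrooted tree rooted, for storage, at an internal node.

    For >= 3 taxa the storage root has degree 3 (unrooted binary tree);
    for 2 taxa it has degree 2 with the single branch split evenly.
    ``raw_branch_lengths`` records pre-clamping values of any branch
    whose NJ estimate was negative.
    """

    root: TreeNode
    taxa: tuple[str, ...]
    raw_branch_lengths: dict[str, float] = field(default_factory=dict)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the additive metric of the tree)."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        nodes: dict[int, TreeNode] = {}

        def walk(node: TreeNode) -> None:
            nodes[id(node)] = node
            adjacency.setdefault(id(node), [])
            for child, length in node.children:
                adjacency[id(node)].append((id(child), length))
                adjacency.setdefault(id(child), []).append((id(node), length))
                walk(child)

        walk(self.root)
        leaves = {id(n): n.name for n in self.leaves()}
        order = [id(n) for n in self.leaves()]
        n = len(order)
        d = np.zeros((n, n))
        for i, src in enumerate(order):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, length in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + length
                        stack.append(v)
            for j, dst in enumerate(order):
                d[i, j] = dist[dst]
        return DistanceMatrix(tuple(leaves[k] for k in order), d)


def _clamped(raw: float, sibling_raw: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sibling."""
    a, b = raw, sibling_raw
    if a < 0:
        b += a
        a = 0.0
    if b < 0:
        a += b
        b = 0.0
    return max(a, 0.0), max(b, 0.0)


def build_nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k),
    with pendant lengths l_i = d(i,j)/2 + (S_i - S_j)/(2(n-2)) and
    distance update d(u,k) = (d(i,k) + d(j,k) - d(i,j))/2.  Ties on Q
    are broken toward the lowest cluster-index pair, so results are
    deterministic across platforms.  Negative branch-length estimates
    are clamped to zero with the deficit moved to the sibling branch;
    raw values are kept in ``raw_branch_lengths``.  On an additive
    matrix the generating tree is recovered exactly.
    """
    n = len(D.taxa)
    if n < 2:
        raise ValidationError("need at least 2 taxa")
    raw_lengths: dict[str, float] = {}

    def note_raw(node: TreeNode, raw: float, clamped: float) -> None:
        if raw != clamped:
            raw_lengths[node.name or f"node{id(node)}"] = raw

    if n == 2:
        half = D.matrix[0, 1] / 2.0
        root = TreeNode(children=[(TreeNode(D.taxa[0]), half), (TreeNode(D.taxa[1]), half)])
        return PhyloTree(root, D.taxa, raw_lengths)

    clusters: list[TreeNode] = [TreeNode(t) for t in D.taxa]
    d = D.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best: Optional[tuple[float, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li_raw = d[i, j] / 2.0 + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj_raw = d[i, j] - li_raw
        li, lj = _clamped(li_raw, lj_raw)
        new = TreeNode(children=[(clusters[i], li), (clusters[j], lj)])
        note_raw(clusters[i], li_raw, li)
        note_raw(clusters[j], lj_raw, lj)
        # distances from the new cluster; reuse row i for the new node
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
            d[i, k] = d[k, i] = dk
        clusters[i] = new
        active.remove(j)

    i, j, k = active
    li_raw = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj_raw = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk_raw = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    li, lj, lk = (max(x, 0.0) for x in (li_raw, lj_raw, lk_raw))
    root = TreeNode(children=[(clusters[i], li), (clusters[j], lj), (clusters[k], lk)])
    for node, raw, clamped in (
        (clusters[i], li_raw, li),
        (clusters[j], lj_raw, lj),
        (clusters[k], lk_raw, lk),
    ):
        note_raw(node, raw, clamped)
    return PhyloTree(root, D.taxa, raw_lengths)


# ---------------------------------------------------------------------------
# Methylation


@dataclass
class MethylationOverlap:
    """Overlap between a query region and hypomethylated track intervals."""

    query: GenomicInterval
    hypo_threshold: float
    overlapped_bp: int
    fraction: float
    contributing: list[ScoredInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.overlapped_bp <= self.query.length()):
            raise ValidationError("overlapped_bp outside [0, query length]")


def methylation_overlap(
    query: GenomicInterval,
    track: list[ScoredInterval],
    hypo_threshold: float = DEFAULT_HYPO_THRESHOLD,
) -> MethylationOverlap:
    """Base pairs of ``query`` covered by hypomethylated track intervals.

    Hypomethylated intervals are those with score <= ``hypo_threshold``;
    the overlap is taken against their union, so fragmented tracks give
    the same answer as merged ones.  Records with missing scores are
    refused.
    """
    if not (0 <= hypo_threshold <= 1):
        raise ValidationError("hypo_threshold must be in [0, 1]")
    missing = [s for s in track if s.score_missing]
    if missing:
        raise ValidationError(
            f"{len(missing)} track interval(s) have missing methylation scores"
        )
    hypo = [
        s
        for s in track
        if s.score <= hypo_threshold and s.interval.overlaps(query)
    ]
    clipped = sorted(
        (max(s.interval.start, query.start), min(s.interval.end, query.end))
        for s in hypo
    )
    covered = 0
    cursor = query.start
    for start, end in clipped:
        start = max(start, cursor)
        if end > start:
            covered += end - start
            cursor = end
    return MethylationOverlap(
        query=query,
        hypo_threshold=hypo_threshold,
        overlapped_bp=covered,
        fraction=covered / query.length(),
        contributing=hypo,
    )
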
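# Methods

## The problem

Alternative promoters and unannotated internal exons are easy to miss in
standard annotation-driven RNA-seq quantification. The motivating case is a
knockout mouse line in which a transcribed region appears inside an annotated
intron of a synaptic-scaffold gene: spliced reads join the region to the
downstream annotated exon but never to any upstream exon, identifying it as
the first exon of a previously unannotated transcript whose expression is
strongly genotype-dependent. `exonscout` packages that inference — and the
downstream characterization of such a region — as a reusable, tested
pipeline over standard file formats.

## Discovery model

**Coverage islands.** Per-base depth over a gene span is computed from the
aligned blocks of uniquely mapped spliced reads (CIGAR `M/=/X/D` consume
reference into a block; `N` opens a new block; `I/S/H/P` consume none).
Transcribed islands are maximal runs of depth ≥ `min_depth`; runs separated
by at most `merge_gap` sub-threshold bases are merged, and merged islands
shorter than `min_length` are dropped. Defaults `min_depth=2`,
`min_length=50`, `merge_gap=10` suppress single-read noise while keeping a
few-hundred-bp exon detectable at modest depth.

**Junction linkage.** Splice junctions are the distinct
(donor end, acceptor start) pairs between consecutive blocks of any read,
supported by the number of distinct reads containing them; junctions below
`min_support=2` are dropped. An island overlapping *any* annotated exon
(the union over all known isoforms) is not novel and is discarded. A
surviving intronic island is linked downstream when a junction donor sits
within `boundary_tolerance=5` bp of the island end and its acceptor within
tolerance of a downstream annotated exon start (upstream mirror-wise; the
two directions swap on minus-strand genes). Classification follows the link
truth table: downstream-only → first exon, upstream-only → terminal, both →
internal, neither → unlinked. Where a linking junction exists, the island
edge is snapped to the junction coordinate: splice sites are base-precise,
coverage decay is not. The 5′ edge of a first exon has no junction and is
therefore only as precise as the coverage edge — real libraries can move it
by a few bases between samples, which the tool reports per sample without
reconciling.

**Guided reconstruction.** Annotated exons plus novel calls form the nodes
of a splice graph; junction-matched edges carry read support and each known
transcript contributes guide edges between its consecutive exons. Variants
are (a) every guide transcript and (b), for each novel node, the maximal
paths through the graph containing it, extended along read-supported or
guide edges in both directions; so a novel first exon spliced onto exon 5
adopts the known structure from exon 5 onward, one variant per compatible
guide. Sub-paths and duplicates are suppressed; an edge-less novel node is
reported as unlinked rather than emitted as a single-exon transcript.
Whether such a novel transcript ends like the short or the long known
isoform is not decidable from junction evidence near its first exon, so one
variant per compatible guide is emitted and the choice left to the user.

## Quantification

**Read density.** A region's expression in a sample is the RPKM-style
density `count / (kb × millions of mapped reads)`, counting a read when at
least one aligned block overlaps the region by ≥ 1 bp (a read whose splice
skip spans the region does not count). The genotype fold change is the
ratio of group mean densities, with an optional pseudocount; a zero control
mean with pseudocount 0 is an explicit error rather than an infinite fold.

**2^-ΔΔCt.** For qPCR tables, ΔCt = target Ct − reference Ct per biological
sample, with technical replicates averaged per sample before group
statistics (the standard Livak formulation: group aggregation is
mean-of-ΔCt, not mean-of-folds). ΔΔCt is the case mean minus the control
mean and the estimate 2^(−ΔΔCt); per-sample folds relative to the control
mean are reported as the dispersion summary. No significance test is
attached to either estimator.

## Evolutionary and epigenetic characterization

**Conservation.** Over a supplied gapless-or-gapped multi-species
alignment, each window of 20 alignment columns (step 10) scores the mean
over sequence pairs of matching sites / sites where both are `ACGT`
(pairwise deletion; a window where every pair lacks comparable sites is
flagged undefined and excluded). Conserved blocks are maximal runs of
windows scoring ≥ 0.8, merged to alignment coordinates. This windowed
identity is a deliberately simple stand-in for browser conservation tracks;
it is not a phastCons/phyloP-style statistical model.

**Phylogeny.** Distances are p-distance or its Jukes–Cantor correction
−(3/4)·ln(1 − 4p/3) (default `jc69`; saturation p ≥ 0.75 is an error naming
the pair). The tree is classic Saitou–Nei neighbor joining: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), pendant lengths
l_i = d(i,j)/2 + (S_i−S_j)/(2(n−2)), distance update
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties on Q break toward the lowest
cluster-index pair, making results platform-deterministic. Negative branch
estimates are clamped to 0 with the deficit moved to the sibling branch
(the common MEGA-compatible convention); raw values are retained in a
diagnostic field. On any additive matrix the generating tree's topology and
branch lengths are recovered exactly — this is property-tested, and the
worked 4-taxon example in the test suite resolves to pendants (2,3,4,4)
with internal branch 3. The 2-taxon tree splits its single branch evenly
for serialization.

**Methylation.** Hypomethylated intervals are track records with score ≤
`hypo_threshold` (default 0.3). Overlap with a query region is computed
against the *union* of hypomethylated intervals, so the answer is invariant
to how the track is fragmented. Records whose BED input carried no score
are flagged on read and refused by this analysis. No branch-length
rate-change statistic is computed; branch lengths are reported and
rate-change inference is left to the user.

## The synthetic locus

The generator emulates the study conditions end to end with known ground
truth. The default locus is a 7-exon plus-strand gene (long isoform = all
exons, short = exons 3–7) with a 386 bp novel exon planted 300 bp into the
intron between exons 4 and 5 — 386 bp being the size of the novel region
the pipeline is designed around. The novel transcript is the planted exon
followed by exons 5–7; it appears only in the ground truth, never in the
GTF.

Reads are emitted pre-aligned (SAM with correct coordinates and N-gapped
CIGARs) because alignment is out of scope; noise enters through sampling,
not mis-mapping. Two placement modes: `random` draws Poisson read counts
with uniform, edge-clamped starts (flat expected coverage equal to
weight × depth); `tiling` lays staggered deterministic passes for exactly
uniform, noise-free coverage — used when base-exact boundary recovery is
the property under test. Genotype presets weight the novel transcript at
0.02 (WT), 8× that (e67KO-like) and 1.71× that (e7KO-like) against weight
1.0 for each annotated isoform; at 50× depth the WT baseline stays below
the island-calling threshold, mirroring a transcript detectable in
knockout but not wild-type libraries. The SAM header records
`library_size = emitted + 1,000,000`, modeling the genome-wide library of
which one locus is a negligible fraction; this keeps per-million
normalization comparable across genotypes. In tiling mode the whole-read
overlap counter has a small phase-quantization bias (a single-pass control
sees 4 or 5 tiles over a 386 bp region depending on phase), so fold-change
calibration is assessed in random mode, where the estimator is unbiased.

qPCR tables draw a per-sample biological ΔCt (sd = `ct_sd`) around a
baseline, shift case samples by −log2(true fold), and add technical noise
per replicate (triplicates, five samples per group by default). The
alignment generator covers the novel exon plus 200 bp of upstream context
across eight vertebrate species (mouse = reference genome row), with two
planted high-identity blocks — one upstream "promoter-like", one flush with
the exon 3′ end — placed on the conservation window grid so default-setting
recovery is exact; per-column identity is 0.98 in blocks vs 0.55 elsewhere,
i.e. window scores ≈ 0.96 vs ≈ 0.42 around the 0.8 threshold. Methylation
tracks tile the locus in 200 bp bins: brain tissues score ≤ 0.16 over the
exon and its upstream context, everything else ≥ 0.75. All outputs are
byte-deterministic under fixed seeds.

What the simulation does **not** model: sequencing errors, PCR duplicates,
multi-mapping, indels in the alignment, non-uniform (fragmentation- or
GC-driven) coverage, and expression overdispersion beyond Poisson. Passing
tests therefore demonstrate correctness of the inference machinery under
idealized evidence, not robustness to every artifact of real libraries.

## Numerical and interface choices

Coordinates are 0-based half-open internally (BED/SAM native); every
printed report coordinate is 1-based inclusive, browser style. "Uniquely
mapped" = MAPQ ≥ 30 and neither secondary nor supplementary flag
(configurable; upstream aligners differ). Reads are treated as unstranded
and inherit orientation from the gene under analysis. Scoreless BED records
default to 0.0 but are flagged, and methylation analysis refuses them. A
junction matching more than one graph-node boundary on the same side within
tolerance is an ambiguity error listing the candidates rather than a silent
choice. All randomness across the package flows through explicit integer
seeds.

## Problem sizes used by the verification scripts

The recovery studies run on the default locus (~10.5 kb, ~1,200 reads per
sample at 50×): 30 seeded replicates per planted density ratio with 3
samples per group, 100 seeded qPCR tables at sd 0.3, 100 random additive
matrices of 4–11 taxa for the neighbor-joining property, and ≥ 1,000 random
instances per brute-force oracle comparison.
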
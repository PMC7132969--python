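"""Synthetic test locus with a planted novel exon and all pipeline inputs.

Generates, with known ground truth and full seed determinism:

* a multi-exon gene annotation (GTF) plus random genome (FASTA) in which
  one unannotated exon sits inside an intron — annotated transcripts
  only; the planted exon exists solely in the ground truth;
* spliced pre-aligned reads (SAM) per genotype, sampled along each
  transcript proportional to genotype expression weights, with N-gapped
  CIGARs across splice sites.  Genotype presets mirror a knockout study
  in which the intronic exon is induced ~8-fold in one KO line and
  ~1.71-fold in another relative to wild type;
* replicate qPCR Ct tables with Gaussian noise around a planted fold;
* an 8-species alignment with two planted conserved blocks (one in the
  200 bp upstream "promoter-like" context, one at the exon's 3' end)
  and per-tissue methylation tracks hypomethylated over the exon in
  brain tissues.

Reads are emitted pre-aligned because alignment is outside the scope of
the pipeline; simulation noise enters through sampling, not mis-mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .genomic_io import GeneModel, GenomicInterval, ValidationError, write_gene_annotation
from .quantification import QpcrTable

__all__ = [
    "LocusSpec",
    "GroundTruth",
    "SimulatedLocus",
    "ReadSimResult",
    "EvoTracks",
    "simulate_locus",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_evo_tracks",
    "GENOTYPES",
    "SPECIES",
    "BRAIN_TISSUES",
    "OTHER_TISSUES",
]

#: The eight vertebrate species of the default alignment.
SPECIES = ("human", "rhesus", "mouse", "rat", "dog", "cow", "chicken", "frog")
REFERENCE_SPECIES = "mouse"

BRAIN_TISSUES = ("brain_hippocampus", "brain_frontal_cortex")
OTHER_TISSUES = ("liver", "heart")

#: Genotype presets: expression weight of the novel transcript relative
#: to the annotated transcripts (each weighted 1.0).  The knockout
#: presets carry 8x and 1.71x the wild-type novel weight, the two
#: induction magnitudes the pipeline is meant to recover; the wild-type
#: baseline is low enough that the exon stays below default island
#: thresholds at 50x depth, emulating a transcript detectable in KO but
#: not WT libraries.
WT_NOVEL_WEIGHT = 0.02
GENOTYPES: dict[str, float] = {
    "WT": 1.0,
    "e67KO": 8.0,
    "e7KO": 1.71,
}

_UPSTREAM_CONTEXT = 200
# Planted conserved blocks, as offsets in the [upstream+exon] alignment:
# an 80-column block inside the upstream context and a 96-column block
# flush with the exon's 3' end.  Both lie on the default conservation
# window grid so that window-based calling can recover them exactly.
_UPSTREAM_BLOCK = (60, 140)
_END_BLOCK_LEN = 96

_METH_BIN = 200


@dataclass
class LocusSpec:
    """Layout of the synthetic locus.

    The default plants a 386 bp novel exon (the size of the novel region
    the pipeline is designed around) in the intron between exons 4 and 5
    of a 7-exon gene carrying a long (all exons) and a short (exons 3-7)
    annotated isoform.
    """

    chrom: str = "chrS"
    gene_id: str = "GeneA"
    strand: str = "+"
    exon_lengths: tuple[int, ...] = (180, 150, 160, 140, 150, 170, 200)
    intron_lengths: tuple[int, ...] = (700, 650, 900, 800, 600, 650)
    novel_intron_index: int = 3  # 0-based: the intron between exons 4 and 5
    novel_offset: int = 300
    novel_length: int = 386
    flank: int = 500
    transcripts: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "tx_long": tuple(range(7)),
            "tx_short": (2, 3, 4, 5, 6),
        }
    )
    seed: int = 17

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValidationError("need exactly one intron length per exon gap")
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise ValidationError("exon and intron lengths must be > 0")
        if self.novel_length <= 0:
            raise ValidationError("novel exon length must be > 0")
        if not (0 <= self.novel_intron_index < len(self.intron_lengths)):
            raise ValidationError("novel_intron_index out of range")
        intron = self.intron_lengths[self.novel_intron_index]
        if not (0 < self.novel_offset and self.novel_offset + self.novel_length < intron):
            raise ValidationError(
                "novel exon does not fit strictly inside its intron "
                f"(offset {self.novel_offset} + length {self.novel_length} vs intron {intron})"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    novel_exon: GenomicInterval
    junction: tuple[int, int]  # (novel exon end, downstream exon start)
    downstream_exon_index: int
    genotype_weights: dict[str, dict[str, float]]
    true_fold: dict[str, float]
    msa_region: GenomicInterval
    conserved_blocks: list[GenomicInterval]
    hypomethylated: dict[str, list[GenomicInterval]]

    def to_json(self, path: str | Path) -> None:
        def iv(x: GenomicInterval) -> dict:
            return {"chrom": x.chrom, "start": x.start, "end": x.end, "strand": x.strand}

        payload = {
            "novel_exon": iv(self.novel_exon),
            "junction": list(self.junction),
            "downstream_exon_index": self.downstream_exon_index,
            "genotype_weights": self.genotype_weights,
            "true_fold": self.true_fold,
            "msa_region": iv(self.msa_region),
            "conserved_blocks": [iv(b) for b in self.conserved_blocks],
            "hypomethylated": {
                tissue: [iv(b) for b in blocks]
                for tissue, blocks in self.hypomethylated.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class SimulatedLocus:
    spec: LocusSpec
    gene: GeneModel
    genome: str
    truth: GroundTruth

    @property
    def chrom(self) -> str:
        return self.spec.chrom

    def transcript_chains(self) -> dict[str, list[GenomicInterval]]:
        """Genomic exon chains of all transcripts, including the novel one.

        The novel transcript starts at the planted exon and continues
        with the annotated exons downstream of it.
        """
        chains = {
            name: self.gene.transcript_exons(name) for name in self.gene.transcripts
        }
        downstream = self.gene.exons[self.truth.downstream_exon_index :]
        chains["novel"] = [self.truth.novel_exon, *downstream]
        return chains

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.gtf",
            "genome": outdir / "genome.fa",
            "truth": outdir / "truth.json",
        }
        write_gene_annotation([self.gene], paths["annotation"])
        with open(paths["genome"], "w") as fa:
            fa.write(f">{self.chrom}\n")
            for i in range(0, len(self.genome), 60):
                fa.write(self.genome[i : i + 60] + "\n")
        self.truth.to_json(paths["truth"])
        return paths


def simulate_locus(spec: Optional[LocusSpec] = None) -> SimulatedLocus:
    """Build the synthetic locus: annotation, genome and ground truth.

    The annotation contains the known transcripts only; the novel exon
    appears nowhere in the GTF and only in the ground truth.
    """
    spec = spec or LocusSpec()
    rng = np.random.default_rng(spec.seed)

    exons: list[GenomicInterval] = []
    cursor = spec.flank
    for i, length in enumerate(spec.exon_lengths):
        exons.append(GenomicInterval(spec.chrom, cursor, cursor + length, spec.strand))
        cursor += length
        if i < len(spec.intron_lengths):
            cursor += spec.intron_lengths[i]
    genome_length = cursor + spec.flank
    genome = "".join(rng.choice(list("ACGT"), size=genome_length))

    gene = GeneModel(
        spec.gene_id,
        spec.strand,
        exons,
        {name: list(idx) for name, idx in spec.transcripts.items()},
    )

    intron_start = exons[spec.novel_intron_index].end
    novel = GenomicInterval(
        spec.chrom,
        intron_start + spec.novel_offset,
        intron_start + spec.novel_offset + spec.novel_length,
        spec.strand,
    )
    downstream_index = spec.novel_intron_index + 1

    weights = {
        genotype: {
            **{name: 1.0 for name in spec.transcripts},
            "novel": WT_NOVEL_WEIGHT * ratio,
        }
        for genotype, ratio in GENOTYPES.items()
    }
    true_fold = {g: r for g, r in GENOTYPES.items() if g != "WT"}

    msa_region = GenomicInterval(
        spec.chrom, novel.start - _UPSTREAM_CONTEXT, novel.end, spec.strand
    )
    conserved = [
        GenomicInterval(
            spec.chrom,
            msa_region.start + _UPSTREAM_BLOCK[0],
            msa_region.start + _UPSTREAM_BLOCK[1],
            spec.strand,
        ),
        GenomicInterval(spec.chrom, novel.end - _END_BLOCK_LEN, novel.end, spec.strand),
    ]
    hypo_span = GenomicInterval(spec.chrom, msa_region.start, novel.end, spec.strand)
    hypomethylated = {tissue: [hypo_span] for tissue in BRAIN_TISSUES}

    truth = GroundTruth(
        novel_exon=novel,
        junction=(novel.end, exons[downstream_index].start),
        downstream_exon_index=downstream_index,
        genotype_weights=weights,
        true_fold=true_fold,
        msa_region=msa_region,
        conserved_blocks=conserved,
        hypomethylated=hypomethylated,
    )
    return SimulatedLocus(spec, gene, genome, truth)


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadSimResult:
    path: Path
    n_reads: int
    library_size: int


def _to_genomic_blocks(
    chain: list[GenomicInterval], t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate segment onto genomic exon blocks."""
    blocks = []
    offset = 0
    for exon in chain:
        exon_len = exon.length()
        lo = max(t_start - offset, 0)
        hi = min(t_end - offset, exon_len)
        if hi > lo:
            blocks.append((exon.start + lo, exon.start + hi))
        offset += exon_len
    return blocks


def _segment_starts_tiling(length: int, read_length: int, copies: int) -> list[tuple[int, int]]:
    """Deterministic uniform-coverage tiling: ``copies`` staggered passes,
    each covering every transcript base exactly once."""
    segments = []
    for k in range(copies):
        offset = (k * read_length) // copies if copies > 1 else 0
        j = -offset
        while j < length:
            lo, hi = max(j, 0), min(j + read_length, length)
            if hi > lo:
                segments.append((lo, hi))
            j += read_length
    return segments


def simulate_reads(
    locus: SimulatedLocus,
    genotype: str,
    out_sam: str | Path,
    depth: float = 50.0,
    read_length: int = 100,
    seed: int = 0,
    mode: str = "random",
    weights: Optional[dict[str, float]] = None,
    background_library: int = 1_000_000,
) -> ReadSimResult:
    """Write a SAM file of spliced reads for one genotype.

    Reads are sampled uniformly along each transcript with expected
    per-base coverage ``weight x depth``; reads spanning splice sites
    get N-gapped CIGARs.  ``mode="random"`` draws Poisson read counts
    with uniform start positions (edge-clamped, so expected coverage is
    flat out to the transcript ends); ``mode="tiling"`` lays reads
    deterministically for exactly uniform, noise-free coverage.  All
    reads are flagged uniquely mapped (MAPQ 60).  The library size
    written to the header comment adds ``background_library`` reads,
    representing the genome-wide remainder of a sequencing library of
    which this locus is a negligible fraction.
    """
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    if read_length < 20:
        raise ValidationError("read_length must be >= 20")
    if mode not in ("random", "tiling"):
        raise ValidationError(f"unknown mode {mode!r}")
    chains = locus.transcript_chains()
    if weights is None:
        try:
            weights = locus.truth.genotype_weights[genotype]
        except KeyError:
            known = ", ".join(sorted(locus.truth.genotype_weights))
            raise ValidationError(
                f"unknown genotype {genotype!r}; known genotypes: {known}"
            ) from None
    rng = np.random.default_rng(seed)

    reads = []  # (start, name, blocks)
    serial = 0
    for name in sorted(chains):
        weight = float(weights.get(name, 0.0))
        if weight <= 0:
            continue
        chain = chains[name]
        length = sum(e.length() for e in chain)
        if mode == "tiling":
            copies = int(round(weight * depth))
            segments = _segment_starts_tiling(length, read_length, copies)
        else:
            expected = weight * depth * (length + read_length - 1) / read_length
            n = int(rng.poisson(expected))
            starts = rng.integers(-(read_length - 1), length, size=n)
            segments = [
                (max(int(s), 0), min(int(s) + read_length, length)) for s in starts
            ]
        for t_start, t_end in segments:
            blocks = _to_genomic_blocks(chain, t_start, t_end)
            serial += 1
            reads.append((blocks[0][0], f"{genotype}_{name}_{serial}", blocks))

    reads.sort(key=lambda r: (r[0], r[1]))
    library_size = background_library + len(reads)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": locus.chrom, "LN": len(locus.genome)}],
        "CO": [f"library_size:{library_size}", f"genotype:{genotype}"],
    }
    out_sam = Path(out_sam)
    out_sam.parent.mkdir(parents=True, exist_ok=True)
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for start, name, blocks in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            cigar = []
            seq_parts = []
            for k, (bs, be) in enumerate(blocks):
                if k > 0:
                    cigar.append((3, bs - blocks[k - 1][1]))  # N
                cigar.append((0, be - bs))  # M
                seq_parts.append(locus.genome[bs:be])
            a.cigartuples = cigar
            a.query_sequence = "".join(seq_parts)
            out.write(a)
    return ReadSimResult(out_sam, len(reads), library_size)


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_fold: float,
    n_per_group: int = 5,
    ct_sd: float = 0.3,
    seed: int = 0,
    n_technical: int = 3,
    baseline_dct: float = 6.0,
    reference_ct: float = 18.0,
) -> QpcrTable:
    """Simulate a replicate Ct table with a planted fold change.

    Control samples have ΔCt around ``baseline_dct``; case samples are
    shifted by −log2(true_fold).  Biological scatter (per sample) and
    technical scatter (per replicate) are both Gaussian with sd
    ``ct_sd``.  The defaults emulate five biological samples per group
    measured in technical triplicates.
    """
    if true_fold <= 0:
        raise ValidationError("true_fold must be > 0")
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if ct_sd < 0:
        raise ValidationError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, shift in (("control", 0.0), ("case", -np.log2(true_fold))):
        for s in range(1, n_per_group + 1):
            sample_dct = baseline_dct + shift + rng.normal(0.0, ct_sd)
            for _ in range(n_technical):
                ref = reference_ct + rng.normal(0.0, ct_sd)
                target = ref + sample_dct + rng.normal(0.0, ct_sd)
                rows.append(
                    {
                        "sample": f"{group}_{s}",
                        "group": group,
                        "target_ct": target,
                        "reference_ct": ref,
                    }
                )
    return QpcrTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Conservation and methylation tracks


@dataclass
class EvoTracks:
    msa_path: Path
    methylation_paths: dict[str, Path]


def simulate_evo_tracks(
    locus: SimulatedLocus,
    outdir: str | Path,
    n_species: int = 8,
    conserved_identity: float = 0.98,
    background_identity: float = 0.55,
    seed: int = 0,
) -> EvoTracks:
    """Write the multi-species alignment and per-tissue methylation BEDs.

    The alignment covers the novel exon plus its 200 bp upstream
    context, gapless, with the mouse row equal to the reference genome.
    Within the two planted conserved blocks every non-reference species
    matches the reference per column with probability
    ``conserved_identity``; elsewhere with ``background_identity``.
    Methylation tracks tile the locus in 200 bp bins; brain-tissue bins
    overlapping the exon and its upstream context are hypomethylated
    (score <= 0.2), all other bins score >= 0.7.
    """
    if not (0 <= background_identity < conserved_identity <= 1):
        raise ValidationError("need 0 <= background_identity < conserved_identity <= 1")
    if n_species < 2:
        raise ValidationError("n_species must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    region = locus.truth.msa_region
    ref = np.frombuffer(
        locus.genome[region.start : region.end].encode(), dtype=np.uint8
    ).copy()
    length = region.length()

    conserved_mask = np.zeros(length, dtype=bool)
    for block in locus.truth.conserved_blocks:
        conserved_mask[block.start - region.start : block.end - region.start] = True
    identity = np.where(conserved_mask, conserved_identity, background_identity)

    if n_species <= len(SPECIES):
        names = list(SPECIES[:n_species])
        if REFERENCE_SPECIES not in names:
            names[-1] = REFERENCE_SPECIES
    else:
        names = list(SPECIES) + [f"species{k}" for k in range(len(SPECIES) + 1, n_species + 1)]

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows: dict[str, np.ndarray] = {}
    for name in names:
        if name == REFERENCE_SPECIES:
            rows[name] = ref
            continue
        seq = ref.copy()
        mutate = rng.random(length) > identity
        if mutate.any():
            originals = seq[mutate]
            shifts = rng.integers(1, 4, size=int(mutate.sum()))
            indices = (np.searchsorted(bases, originals) + shifts) % 4
            seq[mutate] = bases[indices]
        rows[name] = seq

    msa_path = outdir / "alignment.fa"
    with open(msa_path, "w") as fa:
        for name in names:
            fa.write(f">{name}\n")
            seq = rows[name].tobytes().decode()
            for i in range(0, length, 60):
                fa.write(seq[i : i + 60] + "\n")

    hypo_span = locus.truth.hypomethylated[BRAIN_TISSUES[0]][0]
    meth_paths: dict[str, Path] = {}
    for tissue in (*BRAIN_TISSUES, *OTHER_TISSUES):
        path = outdir / f"methylation_{tissue}.bed"
        with open(path, "w") as bed:
            for start in range(0, len(locus.genome), _METH_BIN):
                end = min(start + _METH_BIN, len(locus.genome))
                is_hypo = (
                    tissue in BRAIN_TISSUES
                    and start < hypo_span.end
                    and end > hypo_span.start
                )
                if is_hypo:
                    score = 0.06 + 0.08 * rng.random()
                else:
                    score = 0.75 + 0.2 * rng.random()
                bed.write(f"{locus.chrom}\t{start}\t{end}\t{tissue}\t{score:.3f}\n")
        meth_paths[tissue] = path
    return EvoTracks(msa_path, meth_paths)
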
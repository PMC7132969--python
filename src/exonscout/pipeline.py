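"""End-to-end orchestration: discovery and characterization runs.

``run_discovery`` takes annotation plus per-sample spliced alignments,
calls transcribed intronic islands, links them through splice junctions,
reconstructs transcript variants and compares novel-region read density
across genotypes.  ``run_characterization`` handles the downstream
analyses (conservation, phylogeny, methylation overlap, qPCR folds) for
whichever inputs the configuration provides.

All report coordinates are printed 1-based inclusive; raw 0-based
half-open coordinates are included alongside under ``start0``/``end0``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import evo_epigenetics as evo
from . import exon_discovery as disc
from .genomic_io import (
    GenomicInterval,
    ValidationError,
    read_alignments,
    read_gene_annotation,
    read_scored_bed,
    sam_library_size,
    write_newick,
)
from .quantification import QpcrTable, ddct_fold_change, density_fold_change, region_density
from .transcript_assembly import build_splice_graph, reconstruct_variants, write_variants_gtf

logger = logging.getLogger(__name__)

__all__ = ["SampleSpec", "RunConfig", "run_discovery", "run_characterization"]


@dataclass
class SampleSpec:
    sample_id: str
    genotype: str
    sam: Path


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Every stage parameter has the package default; all randomness (none
    in discovery itself, but downstream consumers may use it) is behind
    the single ``seed``.
    """

    annotation: Path
    outdir: Path
    samples: list[SampleSpec] = field(default_factory=list)
    control_genotype: str = "WT"
    seed: int = 0
    # discovery
    min_mapq: int = 30
    min_depth: int = disc.DEFAULT_MIN_DEPTH
    min_length: int = disc.DEFAULT_MIN_LENGTH
    merge_gap: int = disc.DEFAULT_MERGE_GAP
    min_support: int = disc.DEFAULT_MIN_SUPPORT
    boundary_tolerance: int = disc.DEFAULT_BOUNDARY_TOLERANCE
    # quantification
    pseudocount: float = 0.0
    # characterization inputs (optional)
    msa: Optional[Path] = None
    methylation_tracks: dict[str, Path] = field(default_factory=dict)
    qpcr: Optional[Path] = None
    query_region: Optional[str] = None  # 1-based "chrom:first-last"
    window_size: int = evo.DEFAULT_WINDOW
    step: int = evo.DEFAULT_STEP
    identity_threshold: float = evo.DEFAULT_IDENTITY_THRESHOLD
    distance_model: str = "jc69"
    hypo_threshold: float = evo.DEFAULT_HYPO_THRESHOLD

    @classmethod
    def from_dict(cls, raw: dict, base: Optional[Path] = None) -> "RunConfig":
        base = Path(base) if base else Path(".")

        def path_of(value) -> Path:
            p = Path(value)
            return p if p.is_absolute() else base / p

        kwargs: dict = {
            "annotation": path_of(raw["annotation"]),
            "outdir": path_of(raw.get("outdir", "exonscout_out")),
        }
        kwargs["samples"] = [
            SampleSpec(s["sample_id"], s["genotype"], path_of(s["sam"]))
            for s in raw.get("samples", [])
        ]
        for key in (
            "control_genotype", "seed", "min_mapq", "min_depth", "min_length",
            "merge_gap", "min_support", "boundary_tolerance", "pseudocount",
            "query_region", "window_size", "step", "identity_threshold",
            "distance_model", "hypo_threshold",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if raw.get("msa"):
            kwargs["msa"] = path_of(raw["msa"])
        if raw.get("qpcr"):
            kwargs["qpcr"] = path_of(raw["qpcr"])
        kwargs["methylation_tracks"] = {
            tissue: path_of(p) for tissue, p in (raw.get("methylation_tracks") or {}).items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=path.parent)

    def validate_paths(self, discovery: bool = True, characterization: bool = False) -> None:
        missing = []
        if discovery:
            if not self.annotation.exists():
                missing.append(self.annotation)
            missing += [s.sam for s in self.samples if not s.sam.exists()]
        if characterization:
            for p in (self.msa, self.qpcr, *self.methylation_tracks.values()):
                if p is not None and not Path(p).exists():
                    missing.append(p)
        if missing:
            raise ValidationError(
                "missing input file(s): " + ", ".join(str(p) for p in missing)
            )


def _iv_record(iv: GenomicInterval) -> dict:
    first, last = iv.to_1based()
    return {
        "printed": str(iv),
        "chrom": iv.chrom,
        "first_1based": first,
        "last_1based": last,
        "start0": iv.start,
        "end0": iv.end,
    }


def _parse_region(text: str) -> GenomicInterval:
    chrom, _, rest = text.partition(":")
    first, _, last = rest.partition("-")
    return GenomicInterval.from_1based(chrom, int(first.replace(",", "")), int(last.replace(",", "")))


def _merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[list] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1][0] == iv.chrom and iv.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], iv.end)
        else:
            merged.append([iv.chrom, iv.start, iv.end])
    return [GenomicInterval(c, s, e) for c, s, e in merged]


def run_discovery(config: RunConfig) -> dict:
    """Run coverage → islands → junction linkage → variants → fold change.

    Returns the report as a dict and writes ``discovery.json`` plus TSV
    tables (calls, variants, fold changes, per-sample coverage) under
    ``config.outdir``.
    """
    config.validate_paths(discovery=True)
    if not config.samples:
        raise ValidationError("discovery needs at least one sample")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_gene_annotation(config.annotation)
    params = {
        "min_mapq": config.min_mapq,
        "min_depth": config.min_depth,
        "min_length": config.min_length,
        "merge_gap": config.merge_gap,
        "min_support": config.min_support,
        "boundary_tolerance": config.boundary_tolerance,
        "pseudocount": config.pseudocount,
        "control_genotype": config.control_genotype,
        "seed": config.seed,
    }
    for key, value in params.items():
        logger.info("discovery parameter %s = %r", key, value)

    sample_reads: dict[str, list] = {}
    sample_library: dict[str, int] = {}
    report_samples: dict[str, dict] = {}
    call_rows = []
    variant_rows = []
    novel_by_gene: dict[str, list[GenomicInterval]] = {}

    for sample in config.samples:
        stats: dict = {}
        reads = list(
            read_alignments(sample.sam, unique_only=True, min_mapq=config.min_mapq, stats=stats)
        )
        sample_reads[sample.sample_id] = reads
        sample_library[sample.sample_id] = sam_library_size(sample.sam)
        entry: dict = {
            "genotype": sample.genotype,
            "library_size": sample_library[sample.sample_id],
            "read_stats": stats,
            "genes": {},
        }
        for gene in genes:
            window = gene.span
            cov = disc.compute_coverage(reads, window)
            junctions = disc.extract_junctions(reads, min_support=config.min_support)
            islands = disc.call_islands(
                cov,
                min_depth=config.min_depth,
                min_length=config.min_length,
                merge_gap=config.merge_gap,
            )
            calls = disc.call_novel_exons(
                islands, gene, junctions, boundary_tolerance=config.boundary_tolerance
            )
            graph = build_splice_graph(
                gene, calls, junctions, boundary_tolerance=config.boundary_tolerance
            )
            recon = reconstruct_variants(graph)
            entry["genes"][gene.gene_id] = {
                "junctions": [
                    {
                        "donor_end_1based": j.donor_end,
                        "acceptor_start_1based": j.acceptor_start + 1,
                        "support": j.support,
                    }
                    for j in junctions
                ],
                "islands": [
                    {**_iv_record(isl.interval), "mean_depth": isl.mean_depth,
                     "max_depth": isl.max_depth}
                    for isl in islands
                ],
                "novel_exon_calls": [
                    {
                        **_iv_record(call.interval),
                        "exon_class": call.exon_class,
                        "upstream_links": [f"E{i + 1}" for i, _ in call.upstream_links],
                        "downstream_links": [f"E{i + 1}" for i, _ in call.downstream_links],
                        "outside_gene_span": call.outside_gene_span,
                    }
                    for call in calls
                ],
                "variants": [
                    {
                        "exon_chain": list(v.labels),
                        "novel": v.novelty,
                        "support": v.support,
                    }
                    for v in recon.variants
                ],
                "unlinked_novel_nodes": [n.label for n in recon.unlinked],
            }
            for call in calls:
                novel_by_gene.setdefault(gene.gene_id, []).append(call.interval)
                first, last = call.interval.to_1based()
                call_rows.append(
                    {
                        "sample": sample.sample_id,
                        "gene": gene.gene_id,
                        "region": str(call.interval),
                        "first_1based": first,
                        "last_1based": last,
                        "exon_class": call.exon_class,
                        "n_upstream_links": len(call.upstream_links),
                        "n_downstream_links": len(call.downstream_links),
                        "mean_depth": call.island.mean_depth,
                    }
                )
            for v in recon.variants:
                variant_rows.append(
                    {
                        "sample": sample.sample_id,
                        "gene": gene.gene_id,
                        "exon_chain": "-".join(v.labels),
                        "novel": v.novelty,
                        "support": v.support,
                    }
                )
            if calls:
                disc.write_calls_bed(
                    calls, outdir / f"novel_exons_{sample.sample_id}_{gene.gene_id}.bed"
                )
            write_variants_gtf(
                recon.variants,
                gene.gene_id,
                gene.strand,
                outdir / f"variants_{sample.sample_id}_{gene.gene_id}.gtf",
            )
            track = pd.DataFrame(
                {
                    "pos_1based": range(window.start + 1, window.end + 1),
                    "depth": cov.depth,
                }
            )
            track.to_csv(outdir / f"coverage_{sample.sample_id}.tsv", sep="\t", index=False)
        report_samples[sample.sample_id] = entry

    fold_rows = []
    fold_report: dict[str, list] = {}
    genotypes = {s.genotype for s in config.samples}
    for gene_id, regions in novel_by_gene.items():
        for region in _merge_intervals(regions):
            expressions = {
                s.sample_id: region_density(
                    sample_reads[s.sample_id],
                    region,
                    sample_library[s.sample_id],
                    sample_id=s.sample_id,
                )
                for s in config.samples
            }
            control = [
                expressions[s.sample_id]
                for s in config.samples
                if s.genotype == config.control_genotype
            ]
            for genotype in sorted(genotypes - {config.control_genotype}):
                case = [
                    expressions[s.sample_id]
                    for s in config.samples
                    if s.genotype == genotype
                ]
                if not case or not control:
                    continue
                try:
                    result = density_fold_change(case, control, pseudocount=config.pseudocount)
                    estimate, note = result.estimate, ""
                except ValidationError as exc:
                    estimate, note = None, str(exc)
                record = {
                    "gene": gene_id,
                    "region": str(region),
                    "genotype": genotype,
                    "vs": config.control_genotype,
                    "fold_change": estimate,
                    "n_case": len(case),
                    "n_control": len(control),
                    "note": note,
                }
                fold_rows.append(record)
                fold_report.setdefault(gene_id, []).append(record)

    n_calls = len(call_rows)
    report = {
        "parameters": params,
        "samples": report_samples,
        "novel_regions": {
            gene_id: [_iv_record(r) for r in _merge_intervals(regions)]
            for gene_id, regions in novel_by_gene.items()
        },
        "fold_changes": fold_report,
        "message": (
            "no novel transcribed regions detected" if n_calls == 0 else f"{n_calls} novel exon call(s)"
        ),
    }
    (outdir / "discovery.json").write_text(json.dumps(report, indent=2) + "\n")
    pd.DataFrame(
        call_rows,
        columns=[
            "sample", "gene", "region", "first_1based", "last_1based", "exon_class",
            "n_upstream_links", "n_downstream_links", "mean_depth",
        ],
    ).to_csv(outdir / "novel_exon_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        variant_rows, columns=["sample", "gene", "exon_chain", "novel", "support"]
    ).to_csv(outdir / "transcript_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        fold_rows,
        columns=["gene", "region", "genotype", "vs", "fold_change", "n_case", "n_control", "note"],
    ).to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    if n_calls == 0:
        logger.info("no novel transcribed regions detected")
    return report


def run_characterization(config: RunConfig) -> dict:
    """Conservation, phylogeny, methylation and qPCR analyses.

    Each section is produced only when its input is present in the
    configuration; the report cleanly omits the rest.
    """
    config.validate_paths(discovery=False, characterization=True)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if config.msa is not None:
        msa = evo.read_msa(config.msa)
        profile, blocks = evo.conserved_blocks(
            msa,
            window_size=config.window_size,
            step=config.step,
            threshold=config.identity_threshold,
        )
        distances = evo.pairwise_distances(msa, model=config.distance_model)
        tree = evo.build_nj_tree(distances)
        newick = write_newick(tree)
        (outdir / "tree.nwk").write_text(newick + "\n")
        pd.DataFrame(
            profile.scores, columns=["window_start", "mean_pairwise_identity"]
        ).to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
        pd.DataFrame(blocks, columns=["block_start", "block_end"]).to_csv(
            outdir / "conserved_blocks.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            distances.matrix, index=list(distances.taxa), columns=list(distances.taxa)
        ).to_csv(outdir / "distances.tsv", sep="\t")
        report["conservation"] = {
            "n_species": len(msa.records),
            "aligned_length": msa.aligned_length,
            "window_size": config.window_size,
            "step": config.step,
            "threshold": config.identity_threshold,
            "blocks": [{"start": s, "end": e} for s, e in blocks],
        }
        report["phylogeny"] = {
            "model": config.distance_model,
            "newick": newick,
            "n_leaves": len(tree.leaves()),
            "clamped_branches": tree.raw_branch_lengths,
        }

    if config.methylation_tracks:
        if not config.query_region:
            raise ValidationError("methylation analysis needs query_region in the config")
        query = _parse_region(config.query_region)
        rows = []
        for tissue, path in sorted(config.methylation_tracks.items()):
            track = read_scored_bed(path)
            overlap = evo.methylation_overlap(query, track, hypo_threshold=config.hypo_threshold)
            rows.append(
                {
                    "tissue": tissue,
                    "query": str(query),
                    "hypo_threshold": config.hypo_threshold,
                    "overlapped_bp": overlap.overlapped_bp,
                    "fraction": overlap.fraction,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "methylation_overlap.tsv", sep="\t", index=False)
        report["methylation"] = rows

    if config.qpcr is not None:
        table = QpcrTable.from_tsv(config.qpcr)
        result = ddct_fold_change(table)
        report["qpcr"] = {
            "fold_change": result.estimate,
            "method": result.method,
            "n_case": result.n_case,
            "n_control": result.n_control,
            "per_replicate_folds": result.per_replicate_folds,
            "spread": result.spread,
        }
        pd.DataFrame(
            [
                {"sample": sample, "fold_vs_control_mean": fold}
                for sample, fold in result.per_replicate_folds.items()
            ]
        ).to_csv(outdir / "qpcr_folds.tsv", sep="\t", index=False)

    (outdir / "characterization.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
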
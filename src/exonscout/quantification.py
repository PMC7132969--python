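"""Abundance of a genomic region per sample and fold changes.

Two complementary routes: an RPKM-style read density computed from the
alignments (reads per kilobase of region per million mapped reads),
compared between genotypes as a ratio of group means; and the Livak
2^-ΔΔCt method for qPCR tables with a reference gene (e.g. GAPDH), with
technical replicates averaged per biological sample before group
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genomic_io import AlignedRead, GenomicInterval, ValidationError

__all__ = [
    "RegionExpression",
    "QpcrTable",
    "FoldChangeResult",
    "region_density",
    "density_fold_change",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class RegionExpression:
    """Read count and RPKM-style density of a region in one sample."""

    region: GenomicInterval
    sample_id: str
    read_count: int
    library_size: int
    density: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValidationError("negative density")


@dataclass
class FoldChangeResult:
    """A case/control fold-change estimate.

    ``per_replicate_folds`` holds the per-sample folds relative to the
    control group mean (the dispersion summary); ``spread`` is their
    standard deviation.
    """

    estimate: float
    method: str  # "density_ratio" | "ddct"
    n_case: int
    n_control: int
    per_replicate_folds: dict[str, float] = field(default_factory=dict)
    spread: Optional[float] = None

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise ValidationError("fold-change estimate must be > 0")
        if self.method not in ("density_ratio", "ddct"):
            raise ValidationError(f"unknown method {self.method!r}")


class QpcrTable:
    """Replicate-resolved Ct table.

    Columns: ``sample`` (biological sample id), ``group`` (``case`` or
    ``control``), ``target_ct``, ``reference_ct``.  Multiple rows per
    sample are technical replicates.
    """

    COLUMNS = ("sample", "group", "target_ct", "reference_ct")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        bad_group = set(frame["group"].unique()) - {"case", "control"}
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        for col in ("target_ct", "reference_ct"):
            for sample, value in zip(frame["sample"], frame[col]):
                if pd.isna(value):
                    raise ValidationError(f"sample {sample!r}: missing {col}")
                if value <= 0:
                    raise ValidationError(f"sample {sample!r}: non-positive {col}")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QpcrTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def delta_ct(self) -> pd.DataFrame:
        """Per-sample ΔCt (target − reference), technical replicates averaged."""
        frame = self.frame.assign(dct=self.frame["target_ct"] - self.frame["reference_ct"])
        return (
            frame.groupby(["group", "sample"], sort=True)["dct"]
            .mean()
            .reset_index()
        )


def region_density(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    library_size: int,
    sample_id: str = "",
) -> RegionExpression:
    """Whole-read overlap count and RPKM-style density for a region.

    A read counts when at least one aligned block overlaps the region by
    >= 1 bp; a spliced read whose skip spans the region does not count.
    density = count / (region length in kb x library size in millions).
    """
    if library_size < 1:
        raise ValidationError("library_size must be >= 1")
    count = sum(1 for read in reads if read.overlaps(region))
    density = count / ((region.length() / 1e3) * (library_size / 1e6))
    return RegionExpression(region, sample_id, count, library_size, density)


def density_fold_change(
    case: list[RegionExpression],
    control: list[RegionExpression],
    pseudocount: float = 0.0,
) -> FoldChangeResult:
    """Ratio of mean densities, case over control.

    ``estimate = (mean case density + pseudocount) / (mean control
    density + pseudocount)``.  With the default pseudocount of 0 a zero
    control mean is an error rather than an infinite fold.
    """
    if not case or not control:
        raise ValidationError("both groups must be non-empty")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    case_mean = float(np.mean([r.density for r in case]))
    control_mean = float(np.mean([r.density for r in control]))
    if control_mean + pseudocount == 0:
        raise ValidationError(
            "control mean density is 0 with pseudocount 0; supply a pseudocount"
        )
    folds = {
        r.sample_id or f"case_{i}": (r.density + pseudocount) / (control_mean + pseudocount)
        for i, r in enumerate(case)
    }
    return FoldChangeResult(
        estimate=(case_mean + pseudocount) / (control_mean + pseudocount),
        method="density_ratio",
        n_case=len(case),
        n_control=len(control),
        per_replicate_folds=folds,
        spread=float(np.std(list(folds.values()))) if len(folds) > 1 else None,
    )


def ddct_fold_change(table: QpcrTable) -> FoldChangeResult:
    """Livak 2^-ΔΔCt relative quantification.

    ΔCt = target Ct − reference Ct per sample (technical replicates
    averaged), ΔΔCt = mean ΔCt(case) − mean ΔCt(control), estimate =
    2^(−ΔΔCt).  Per-replicate folds 2^(−(ΔCt_i − mean ΔCt(control)))
    are reported as the dispersion summary.  Group aggregation is
    mean-of-ΔCt, the standard Livak formulation.
    """
    dct = table.delta_ct()
    case = dct[dct["group"] == "case"]
    control = dct[dct["group"] == "control"]
    if case.empty or control.empty:
        raise ValidationError("need at least one case and one control sample")
    control_mean = float(control["dct"].mean())
    ddct = float(case["dct"].mean()) - control_mean
    folds = {
        str(row["sample"]): 2.0 ** -(float(row["dct"]) - control_mean)
        for _, row in dct.iterrows()
    }
    case_folds = [
        2.0 ** -(float(row["dct"]) - control_mean) for _, row in case.iterrows()
    ]
    return FoldChangeResult(
        estimate=2.0 ** (-ddct),
        method="ddct",
        n_case=len(case),
        n_control=len(control),
        per_replicate_folds=folds,
        spread=float(np.std(case_folds)) if len(case_folds) > 1 else None,
    )
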
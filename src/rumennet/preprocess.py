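"""Family-level aggregation and the four-step pre-processing chain.

Order is fixed: aggregate -> minimum-gene filter -> sample-sum scaling ->
inter-quartile-range (IQR) variable filter -> regularized log.  Each
:class:`FamilyMatrix` carries a stage tag and the chain rejects out-of-order
stages.

Notes on conventions:

* "genes expressed" for the 10-gene floor means genes with at least one read
  in at least one retained sample;
* sample-sum scaling divides each column by its sum and multiplies by the
  median of all column sums, so every column sum equals that median afterwards;
* the IQR filter (default) removes families whose IQR across samples falls
  strictly below the 25th percentile (type-7 linear interpolation) of all
  family IQRs; an alternative reading — removing families whose *total*
  expression falls below the 25th percentile of totals — is available via
  ``mode="total"``;
* the regularized log is implemented as ``log2(x + pseudocount)`` on the
  scaled values.  The only downstream consumer is a rank-based correlation,
  for which any strictly monotone transform yields identical edges, so the
  shrinkage behaviour of reference implementations is not re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_tables import ExpressionTable, SampleDesign

STAGES = ("raw_sum", "scaled", "filtered", "rlog")


class StageError(ValueError):
    """A pre-processing stage was applied out of order."""


@dataclass(frozen=True)
class FamilyMatrix:
    """Family x sample matrix with a processing-stage tag.

    ``gene_counts`` records, per family, the number of expressed genes used by
    the minimum-gene filter.
    """

    values: pd.DataFrame
    stage: str
    gene_counts: pd.Series

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("family matrix contains negative values")

    def _require(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r}, matrix is at {self.stage!r}"
            )

    @property
    def families(self) -> list[str]:
        return list(self.values.index)


def aggregate_by_family(
    table: ExpressionTable,
    design: SampleDesign,
    exclude_baseline: bool = True,
) -> FamilyMatrix:
    """Sum counts of all genes per taxonomic family per sample.

    Baseline (0 h) samples are dropped by default before aggregation; they are
    not part of the temporal analysis.
    """
    table.validate_against(design)
    samples = design.non_baseline_samples() if exclude_baseline else design.sample_ids
    counts = table.counts[samples]
    fam = table.gene_meta["family"]
    sums = counts.groupby(fam).sum()
    sums.index.name = "family"
    expressed = (counts > 0).any(axis=1)
    gene_counts = expressed.groupby(fam).sum().reindex(sums.index).astype(int)
    return FamilyMatrix(values=sums, stage="raw_sum", gene_counts=gene_counts)


def filter_min_genes(fm: FamilyMatrix, min_genes: int = 10) -> FamilyMatrix:
    """Drop families with fewer than ``min_genes`` expressed genes."""
    fm._require("raw_sum")
    keep = fm.gene_counts >= min_genes
    return replace(
        fm,
        values=fm.values.loc[keep[keep].index],
        gene_counts=fm.gene_counts[keep],
    )


def scale_by_sample_sum(fm: FamilyMatrix) -> FamilyMatrix:
    """Divide each column by its sum and multiply by the median column sum."""
    fm._require("raw_sum")
    col_sums = fm.values.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    med = float(np.median(col_sums.to_numpy()))
    scaled = fm.values / col_sums * med
    return replace(fm, values=scaled, stage="scaled")


def iqr_filter(
    fm: FamilyMatrix,
    quantile_cut: float = 0.25,
    mode: str = "iqr",
) -> FamilyMatrix:
    """Variable filter on the scaled matrix.

    ``mode="iqr"`` (default): remove families whose inter-quartile range
    across samples is strictly below the ``quantile_cut`` quantile (type-7
    interpolation) of all family IQRs.  ``mode="total"``: same rule applied to
    family total expression instead.
    """
    fm._require("scaled")
    if fm.values.shape[1] < 2:
        raise ValueError("IQR filter requires at least 2 samples")
    if mode == "iqr":
        stat = pd.Series(
            np.percentile(fm.values.to_numpy(), 75, axis=1)
            - np.percentile(fm.values.to_numpy(), 25, axis=1),
            index=fm.values.index,
        )
    elif mode == "total":
        stat = fm.values.sum(axis=1)
    else:
        raise ValueError(f"unknown iqr_filter mode {mode!r}")
    cut = float(np.quantile(stat.to_numpy(), quantile_cut))  # type-7 default
    keep = stat >= cut
    return replace(
        fm,
        values=fm.values.loc[keep[keep].index],
        gene_counts=fm.gene_counts[keep.reindex(fm.gene_counts.index, fill_value=False)],
        stage="filtered",
    )


def regularized_log(fm: FamilyMatrix, pseudocount: float = 1.0) -> FamilyMatrix:
    """``log2(x + pseudocount)`` on the filtered scaled values (monotone)."""
    fm._require("filtered")
    if (fm.values.to_numpy() < 0).any():
        raise ValueError("regularized log requires non-negative input")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return replace(fm, values=np.log2(fm.values + pseudocount), stage="rlog")


def preprocess_counts(
    table: ExpressionTable,
    design: SampleDesign,
    min_genes: int = 10,
    iqr_quantile: float = 0.25,
    iqr_mode: str = "iqr",
    pseudocount: float = 1.0,
    exclude_baseline: bool = True,
) -> dict[str, FamilyMatrix]:
    """Run the full chain; returns every intermediate stage keyed by name."""
    raw = aggregate_by_family(table, design, exclude_baseline=exclude_baseline)
    filtered_genes = filter_min_genes(raw, min_genes=min_genes)
    scaled = scale_by_sample_sum(filtered_genes)
    filtered = iqr_filter(scaled, quantile_cut=iqr_quantile, mode=iqr_mode)
    rlog = regularized_log(filtered, pseudocount=pseudocount)
    return {
        "raw_sum": raw,
        "min_genes": filtered_genes,
        "scaled": scaled,
        "filtered": filtered,
        "rlog": rlog,
    }
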
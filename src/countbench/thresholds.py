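"""Empirical low-expression thresholding and the three filtering workflows.

The detection threshold is derived from intergenic regions: genic and
intergenic rows are normalized jointly, and the chosen percentile (default
95th) of the pooled intergenic values on the log2(normalized + 1) scale is
taken as the limit below which a count cannot be distinguished from
background.  A gene is removed only if it falls below the threshold in
*every* sample.

Workflow 1 normalizes first and filters afterwards; Workflow 2 filters first
and re-normalizes the remaining genes (with library sizes frozen from the
unfiltered matrix); Workflow 3 never filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AnalysisConfig,
    CountMatrix,
    FeatureTable,
    SampleDesign,
    ValidationError,
)
from .normalization import NormalizedMatrix, normalize

__all__ = [
    "ThresholdResult",
    "empirical_threshold",
    "filter_low_expression",
    "filter_noncoding",
    "apply_workflow",
    "WorkflowResult",
]


@dataclass
class ThresholdResult:
    method: str
    threshold: float  # on log2(normalized + 1)
    percentile: float
    n_intergenic: int

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("threshold must be non-negative")


def _log2p1(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


def empirical_threshold(
    genic: CountMatrix,
    intergenic: CountMatrix,
    method: str,
    percentile: float = 95.0,
    features: FeatureTable | None = None,
    read_length: int = 76,
) -> ThresholdResult:
    """Percentile of jointly-normalized intergenic values, log2(x+1) scale.

    Intergenic features shorter than the read length are excluded when a
    feature table is given (they cannot carry uniquely mapped reads).
    """
    inter_counts = intergenic.counts
    if features is not None:
        valid = features.intergenic_ids(valid_only=True).intersection(
            inter_counts.index
        )
        inter_counts = inter_counts.loc[valid]
    if inter_counts.shape[0] == 0:
        raise ValidationError("no (valid) intergenic features for thresholding")
    if not genic.sample_ids.equals(inter_counts.columns):
        raise ValidationError("genic and intergenic matrices must share samples")
    pooled = CountMatrix(
        pd.concat([genic.counts, inter_counts]), genic.library_sizes
    )
    if method == "RPKM":
        norm = normalize(pooled, method, features=features)
    else:
        norm = normalize(pooled, method)
    inter_norm = norm.values.loc[inter_counts.index]
    logvals = _log2p1(inter_norm).to_numpy().ravel()
    thr = float(np.percentile(logvals, percentile))
    return ThresholdResult(method, max(thr, 0.0), percentile, inter_counts.shape[0])


def filter_low_expression(
    matrix: NormalizedMatrix, threshold: ThresholdResult
) -> tuple[NormalizedMatrix, pd.Index]:
    """Keep genes exceeding the threshold in at least one sample.

    Returns the filtered matrix and the index of removed genes.  The matrix
    must be on the same normalization scale as the threshold.
    """
    if matrix.method != threshold.method:
        raise ValidationError(
            f"scale mismatch: threshold derived under {threshold.method!r}, "
            f"matrix normalized with {matrix.method!r}"
        )
    log_max = _log2p1(matrix.values).max(axis=1)
    keep = log_max >= threshold.threshold
    removed = matrix.values.index[~keep]
    filtered = NormalizedMatrix(
        matrix.values.loc[keep], matrix.method, matrix.scaling
    )
    return filtered, removed


def filter_noncoding(
    matrix: pd.DataFrame, features: FeatureTable
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop non-protein-coding rows; returns (matrix, removed ids)."""
    coding = features.coding_ids()
    keep = matrix.index.intersection(coding)
    removed = matrix.index.difference(coding)
    return matrix.loc[keep], removed


@dataclass
class WorkflowResult:
    matrix: NormalizedMatrix  # analysis-ready genic matrix
    threshold: ThresholdResult | None
    removed_genes: pd.Index
    workflow: int
    #: matrix on which distribution parameters are estimated; in Workflow 1
    #: estimation precedes filtering, so this is the unfiltered matrix
    estimation_matrix: NormalizedMatrix | None = None


def apply_workflow(
    counts: CountMatrix,
    features: FeatureTable,
    design: SampleDesign,
    config: AnalysisConfig,
) -> WorkflowResult:
    """Produce the analysis-ready normalized genic matrix for a workflow.

    The input matrix may contain both genic and intergenic rows; intergenic
    rows participate only in threshold derivation.  Library sizes are frozen
    from the input matrix so Workflow 2's re-normalization sees the same N_k.
    """
    design.check_samples(counts.sample_ids)
    method = config.normalization_method
    genic_ids = features.genic_ids().intersection(counts.gene_ids)
    inter_ids = features.intergenic_ids(valid_only=False).intersection(counts.gene_ids)
    genic = CountMatrix(counts.counts.loc[genic_ids], counts.library_sizes)

    if config.workflow == 3:
        norm = normalize(genic, method, features=features)
        return WorkflowResult(norm, None, pd.Index([]), 3, norm)

    if len(inter_ids) == 0:
        raise ValidationError("workflows 1 and 2 need intergenic features")
    intergenic = CountMatrix(counts.counts.loc[inter_ids], counts.library_sizes)
    thr = empirical_threshold(
        genic, intergenic, method, config.threshold_percentile, features
    )

    if config.workflow == 1:
        norm = normalize(genic, method, features=features)
        filtered, removed = filter_low_expression(norm, thr)
        return WorkflowResult(filtered, thr, removed, 1, norm)

    # Workflow 2: identify low genes on the normalized scale, drop them from
    # the raw counts, then re-normalize the remaining genic counts.
    norm = normalize(genic, method, features=features)
    _, removed = filter_low_expression(norm, thr)
    kept = genic.gene_ids.difference(removed, sort=False)
    reduced = CountMatrix(genic.counts.loc[kept], counts.library_sizes)
    renorm = normalize(reduced, method, features=features)
    return WorkflowResult(renorm, thr, removed, 2, renorm)
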
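"""Sample-identity quality control and technical-replicate assessment.

Genotype is verified against a reference SNP table for each candidate inbred
line: r_ij = D_ij / M_ij is the mismatch-to-match ratio of sample i against
line j over sites where both have calls, rescaled per sample to
R_ij = 1 - (r_ij - min) / (max - min) so the best-matching line has R = 1.
Sex is verified by rank correlation against per-sex median expression
standards.  Technical variation between duplicate libraries of the same
individual is quantified with an NB-GLM containing only the individual
(fly) factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, SampleDesign, ValidationError
from .diffexpr import make_de_table
from .nbglm import fit_nb_glm, lrt
from .normalization import NormalizedMatrix

__all__ = [
    "GenotypeQCResult",
    "genotype_verify",
    "SexQCResult",
    "sex_verify",
    "min_reads_filter",
    "TechRepResult",
    "technical_replicate_test",
]

MISSING = "N"


@dataclass
class GenotypeQCResult:
    r: pd.DataFrame  # samples x lines mismatch ratios
    R: pd.DataFrame  # samples x lines rescaled similarity in [0, 1]
    D: pd.DataFrame  # mismatch counts
    M: pd.DataFrame  # match counts
    assigned: pd.Series  # best line per sample
    passed: pd.Series  # r to assigned line <= threshold
    tied: pd.Series  # multiple lines share the minimum r
    threshold: float


def genotype_verify(
    calls: pd.DataFrame, line_table: pd.DataFrame, r_threshold: float = 0.10
) -> GenotypeQCResult:
    """Assign each sample to the candidate line minimizing the mismatch ratio.

    ``calls``: sites x samples base calls (A/C/G/T or 'N' for missing);
    ``line_table``: sites x lines reference calls.  Sites missing in either
    member of a (sample, line) pair are excluded pairwise, so r stays a
    ratio over comparable sites.  Pairs with no comparable site are flagged
    incomparable (NaN) and excluded from the per-sample min/max rescale.
    """
    if line_table.shape[1] < 2:
        raise ValidationError("need at least two candidate lines")
    shared = calls.index.intersection(line_table.index)
    if len(shared) == 0:
        raise ValidationError("no shared SNP sites between calls and line table")
    C = calls.loc[shared].to_numpy(dtype="U1")
    L = line_table.loc[shared].to_numpy(dtype="U1")
    ok = (C[:, :, None] != MISSING) & (L[:, None, :] != MISSING)
    eq = (C[:, :, None] == L[:, None, :]) & ok
    M = eq.sum(axis=0)
    D = (ok & ~eq).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(M > 0, D / np.where(M > 0, M, 1), np.nan)
    samples, lines = calls.columns, line_table.columns
    r_df = pd.DataFrame(r, index=samples, columns=lines)
    rmin = np.nanmin(r, axis=1)
    rmax = np.nanmax(r, axis=1)
    span = rmax - rmin
    with np.errstate(divide="ignore", invalid="ignore"):
        R = 1.0 - (r - rmin[:, None]) / np.where(span > 0, span, np.nan)[:, None]
    # degenerate: all comparable lines equally distant -> all R = 1, tie
    R = np.where(np.isnan(R) & ~np.isnan(r), 1.0, R)
    R_df = pd.DataFrame(R, index=samples, columns=lines)
    n_best = (r_df.eq(rmin, axis=0)).sum(axis=1)
    if np.isnan(rmin).any():
        bad = samples[np.isnan(rmin)]
        raise ValidationError(f"samples with no comparable line: {list(bad)[:5]}")
    assigned = r_df.idxmin(axis=1)
    passed = pd.Series(rmin <= r_threshold, index=samples)
    tied = n_best > 1
    return GenotypeQCResult(
        r_df,
        R_df,
        pd.DataFrame(D, index=samples, columns=lines),
        pd.DataFrame(M, index=samples, columns=lines),
        assigned,
        passed,
        tied,
        r_threshold,
    )


@dataclass
class SexQCResult:
    male_standard: pd.Series
    female_standard: pd.Series
    correlations: pd.DataFrame  # samples x {male, female}
    same_sex_correlation: pd.Series
    passed: pd.Series
    threshold: float


def sex_verify(
    norm: NormalizedMatrix | pd.DataFrame,
    design: SampleDesign,
    correlation_threshold: float = 0.795,
    leave_one_out: bool = True,
) -> SexQCResult:
    """Spearman correlation of each sample with per-sex median standards.

    The standard for a sample's own labelled sex is computed leaving that
    sample out (switchable), so a sample never correlates with a profile it
    contributed to; ties get average ranks.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    t = design.table.loc[values.columns]
    sexes = sorted(t["sex"].unique())
    if len(sexes) != 2:
        raise ValidationError(f"need exactly two sexes, got {sexes}")
    groups = {s: values.columns[t["sex"] == s] for s in sexes}
    for s, cols in groups.items():
        if len(cols) == 0:
            raise ValidationError(f"no samples labelled sex {s!r}")
    standards = {s: values[cols].median(axis=1) for s, cols in groups.items()}

    corr = pd.DataFrame(index=values.columns, columns=sexes, dtype=float)
    for sample in values.columns:
        own = t.loc[sample, "sex"]
        for s in sexes:
            if leave_one_out and s == own and len(groups[s]) > 1:
                std = values[groups[s].drop(sample)].median(axis=1)
            else:
                std = standards[s]
            corr.loc[sample, s] = stats.spearmanr(values[sample], std).statistic
    same = pd.Series(
        [corr.loc[k, t.loc[k, "sex"]] for k in values.columns], index=values.columns
    )
    passed = same >= correlation_threshold
    # conventional labels when present, else positional
    male_key = "M" if "M" in standards else sexes[0]
    female_key = "F" if "F" in standards else sexes[-1]
    return SexQCResult(
        standards[male_key],
        standards[female_key],
        corr,
        same,
        passed,
        correlation_threshold,
    )


def min_reads_filter(cm: CountMatrix, min_mapped: int = 2_500_000) -> pd.Index:
    """Samples with at least ``min_mapped`` mapped reads (inclusive)."""
    keep = cm.library_sizes >= min_mapped
    return cm.sample_ids[keep.to_numpy()]


@dataclass
class TechRepResult:
    de_table: pd.DataFrame  # fly-factor LRT per gene
    spikein_table: pd.DataFrame
    n_spikein_significant: int
    library_abs_diff: pd.DataFrame  # genes x individuals |lib1 - lib2|


def technical_replicate_test(
    counts: CountMatrix,
    design: SampleDesign,
    spikein_ids=(),
    fdr_level: float = 0.05,
    size_factors: pd.Series | None = None,
) -> TechRepResult:
    """Biological-vs-technical test on duplicate libraries.

    Restricting to individuals with two libraries, fits log(mu) = b0 + F
    (F = individual fly) against the intercept-only model per gene.  Genes
    driven by biology differ between flies; spike-ins, which carry only
    technical noise, should be significant at no more than the FDR level.
    Also reports per-individual absolute raw count differences between the
    duplicate libraries.
    """
    t = design.table.loc[counts.sample_ids]
    dup_counts = t.groupby("individual").size()
    dup_ids = dup_counts.index[dup_counts >= 2]
    if len(dup_ids) < 2:
        raise ValidationError("need at least two individuals with duplicate libraries")
    cols = t.index[t["individual"].isin(dup_ids)]
    sub = counts.subset_samples(cols)
    tt = t.loc[cols]

    Y = sub.counts.to_numpy(float)
    # dispersion from replicate libraries within individuals
    cells = tt.groupby("individual").indices
    ss = np.zeros(Y.shape[0])
    dfr = 0
    for idx in cells.values():
        block = Y[:, list(idx)]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dfr += len(idx) - 1
    mean = Y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (ss / max(dfr, 1) - mean) / mean**2, 0.0)
    phi = np.clip(raw, 0.0, None)

    # fly-factor design
    flies = sorted(dup_ids)
    Xf = np.column_stack(
        [np.ones(len(cols))]
        + [(tt["individual"] == f).to_numpy(float) for f in flies[1:]]
    )
    X0 = np.ones((len(cols), 1))
    offsets = (
        np.log(size_factors.reindex(cols).to_numpy(float))
        if size_factors is not None
        else None
    )
    fit_full = fit_nb_glm(Y, Xf, phi, offset=offsets)
    fit_red = fit_nb_glm(Y, X0, phi, offset=offsets)
    stat, pvals = lrt(fit_full.deviance, fit_red.deviance, Xf.shape[1] - 1)
    zero = Y.sum(axis=1) == 0
    pvals = np.where(zero, 1.0, pvals)
    table = make_de_table(
        sub.gene_ids, stat, Xf.shape[1] - 1, pvals, fdr_level, "F", "techrep"
    )
    spike_idx = sub.gene_ids.intersection(pd.Index(spikein_ids))
    spike_table = table.loc[spike_idx]

    diffs = {}
    for f in flies:
        libs = tt.index[tt["individual"] == f][:2]
        diffs[f] = (sub.counts[libs[0]] - sub.counts[libs[1]]).abs()
    diff_df = pd.DataFrame(diffs)
    return TechRepResult(
        table, spike_table, int(spike_table["significant"].sum()), diff_df
    )
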
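"""Count normalization methods.

Seven methods plus the raw-count identity:

* TC — divide each sample by its library size over the mean library size.
* UQ / Med — same ratio structure built from the per-sample upper quartile /
  median of counts, computed after dropping genes that are zero in every
  sample.
* TMM — trimmed mean of M-values against a reference sample (the one whose
  upper quartile is closest to the mean upper quartile); genes with extreme
  log-ratios (M) or extreme abundance (A) are trimmed before taking a
  precision-weighted mean of M-values.
* DESeq — median of per-gene ratios to a geometric-mean pseudo-reference.
* Q — full quantile normalization (rank-wise averaging across samples).
* RPKM — reads per kilobase of gene model per million mapped reads.
* RUVg — k technical factors extracted from negative-control (spike-in)
  genes, for use as covariates rather than as a rescaling.

Quantiles use linear interpolation between order statistics (type 7)
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, FeatureTable, ValidationError

__all__ = [
    "ScalingFactors",
    "NormalizedMatrix",
    "TMMIntermediate",
    "normalize_tc",
    "normalize_uq",
    "normalize_med",
    "tmm_reference",
    "normalize_tmm",
    "deseq_size_factors",
    "normalize_deseq",
    "normalize_quantile",
    "normalize_rpkm",
    "ruvg_factors",
    "normalize",
    "SCALE_FACTOR_METHODS",
]

#: methods whose output is raw counts divided by a single per-sample factor,
#: hence representable as a GLM offset
SCALE_FACTOR_METHODS = ("TC", "UQ", "Med", "TMM", "DESeq", "RC")


@dataclass
class ScalingFactors:
    """Per-sample divisors and their provenance."""

    method: str
    factors: pd.Series | None
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if self.factors is not None and (self.factors <= 0).any():
            raise ValidationError(f"{self.method}: non-positive scaling factor")


@dataclass
class TMMIntermediate:
    """Per-sample TMM diagnostics: M/A values, weights and the trimmed set."""

    m_values: dict[str, pd.Series]
    a_values: dict[str, pd.Series]
    weights: dict[str, pd.Series]
    trimmed_gene_sets: dict[str, pd.Index]
    trim_m: float
    trim_a: float


@dataclass
class NormalizedMatrix:
    """Normalized values plus the factors that produced them."""

    values: pd.DataFrame
    method: str
    scaling: ScalingFactors | None = None

    @property
    def rounded_view(self) -> pd.DataFrame:
        """Integer view (round half to even) for count-based engines."""
        return pd.DataFrame(
            np.rint(self.values.to_numpy()).astype(np.int64),
            index=self.values.index,
            columns=self.values.columns,
        )

    def log_offsets(self) -> pd.Series:
        """Natural-log per-sample offsets such that values = counts / exp(offset)."""
        if self.scaling is None or self.scaling.factors is None:
            raise ValidationError(
                f"method {self.method!r} has no per-sample scaling factor; "
                "offset mode unavailable"
            )
        return np.log(self.scaling.factors)


def _ratio_normalize(cm: CountMatrix, per_sample: pd.Series, method: str):
    ratios = per_sample / per_sample.mean()
    values = cm.counts / ratios
    return (
        NormalizedMatrix(values, method, ScalingFactors(method, ratios)),
        ScalingFactors(method, ratios),
    )


def normalize_tc(cm: CountMatrix):
    """Total-count scaling: divide by library size over mean library size."""
    if (cm.library_sizes <= 0).any():
        raise ValidationError("zero library size")
    return _ratio_normalize(cm, cm.library_sizes.astype(float), "TC")


def _nonzero_rows(cm: CountMatrix) -> pd.DataFrame:
    keep = cm.counts.sum(axis=1) > 0
    if not keep.any():
        raise ValidationError("all genes are zero in every sample")
    return cm.counts.loc[keep]


def _upper_quartiles(cm: CountMatrix) -> pd.Series:
    sub = _nonzero_rows(cm)
    return sub.quantile(0.75, axis=0, interpolation="linear")


def normalize_uq(cm: CountMatrix):
    """Upper-quartile scaling (all-zero genes excluded from the quartile)."""
    uq = _upper_quartiles(cm)
    zero = uq[uq == 0]
    if len(zero):
        raise ValidationError(f"upper quartile is zero for samples {list(zero.index)}")
    return _ratio_normalize(cm, uq, "UQ")


def normalize_med(cm: CountMatrix):
    """Median scaling (all-zero genes excluded from the median)."""
    med = _nonzero_rows(cm).median(axis=0)
    zero = med[med == 0]
    if len(zero):
        raise ValidationError(f"median is zero for samples {list(zero.index)}")
    return _ratio_normalize(cm, med, "Med")


def tmm_reference(cm: CountMatrix) -> str:
    """Reference sample: upper quartile closest to the mean upper quartile.

    Ties broken by lowest sample index.
    """
    if cm.n_samples < 2:
        raise ValidationError("TMM reference requires at least two samples")
    uq = _upper_quartiles(cm)
    dist = (uq - uq.mean()).abs().to_numpy()
    return cm.sample_ids[int(np.argmin(dist))]


def _middle_mask(x: np.ndarray, keep: float) -> np.ndarray:
    """Mask of values inside the central ``keep`` fraction (quantile trim)."""
    lo, hi = np.quantile(x, [(1 - keep) / 2, 1 - (1 - keep) / 2])
    return (x >= lo) & (x <= hi)


def normalize_tmm(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.10,
    reference: str | None = None,
    center_factors: bool = True,
):
    """Trimmed mean of M-values.

    ``trim_m`` / ``trim_a`` are total trimmed fractions: the default keeps the
    middle 40 % of M-values and the middle 90 % of A-values, intersected, as
    the gene set G*.  The per-sample factor is 2**(weighted mean of M over G*),
    optionally recentred so the factors have geometric mean 1.  Normalized
    values are counts divided by factor*N, rescaled by the mean normalized
    library size to stay on a count-like scale.
    """
    ref = reference if reference is not None else tmm_reference(cm)
    if ref not in cm.sample_ids:
        raise ValidationError(f"reference sample {ref!r} not in matrix")
    x = cm.counts.to_numpy(dtype=float)
    N = cm.library_sizes.to_numpy(dtype=float)
    ridx = cm.sample_ids.get_loc(ref)
    xr, Nr = x[:, ridx], N[ridx]

    factors = pd.Series(1.0, index=cm.sample_ids)
    mvals, avals, wvals, gstars = {}, {}, {}, {}
    for k, sid in enumerate(cm.sample_ids):
        if k == ridx:
            continue
        ok = (x[:, k] > 0) & (xr > 0)
        if not ok.any():
            raise ValidationError(f"no genes shared between {sid} and reference")
        xk = x[ok, k]
        xrk = xr[ok]
        m = np.log2((xk / N[k]) / (xrk / Nr))
        a = 0.5 * (np.log2(xk / N[k]) + np.log2(xrk / Nr))
        var = (N[k] - xk) / (N[k] * xk) + (Nr - xrk) / (Nr * xrk)
        genes = cm.gene_ids[ok]
        keep = _middle_mask(m, 1 - trim_m) & _middle_mask(a, 1 - trim_a)
        if not keep.any():
            raise ValidationError(
                f"TMM trimmed gene set empty for sample {sid}; reduce trims"
            )
        # weight = inverse approximate asymptotic variance of M
        pos = var[keep] > 0
        if not pos.any():
            raise ValidationError(f"TMM weights all degenerate for sample {sid}")
        wk = 1.0 / var[keep][pos]
        mk = m[keep][pos]
        factors[sid] = 2.0 ** (np.sum(wk * mk) / np.sum(wk))
        mvals[sid] = pd.Series(m, index=genes)
        avals[sid] = pd.Series(a, index=genes)
        with np.errstate(divide="ignore"):
            wvals[sid] = pd.Series(np.where(var > 0, 1.0 / var, np.inf), index=genes)
        gstars[sid] = genes[keep]
    if center_factors:
        factors = factors / np.exp(np.log(factors).mean())
    eff_lib = factors * cm.library_sizes
    values = cm.counts / eff_lib * eff_lib.mean()
    scaling = ScalingFactors("TMM", eff_lib / eff_lib.mean(), reference_sample=ref)
    inter = TMMIntermediate(mvals, avals, wvals, gstars, trim_m, trim_a)
    return NormalizedMatrix(values, "TMM", scaling), scaling, inter


def deseq_size_factors(cm: CountMatrix) -> ScalingFactors:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    The geometric mean is taken only over genes positive in all samples.
    """
    x = cm.counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError("no gene has positive counts in all samples")
    ref = np.exp(np.log(x[allpos]).mean(axis=1))
    s = np.median(x[allpos] / ref[:, None], axis=0)
    return ScalingFactors("DESeq", pd.Series(s, index=cm.sample_ids))


def normalize_deseq(cm: CountMatrix):
    sf = deseq_size_factors(cm)
    values = cm.counts / sf.factors
    return NormalizedMatrix(values, "DESeq", sf), sf


def normalize_quantile(cm: CountMatrix) -> NormalizedMatrix:
    """Full quantile normalization.

    Every sample's sorted profile is replaced by the mean sorted profile;
    tied counts within a sample get the mean of the target values their
    positions span, so the result is order-independent and deterministic.
    """
    x = cm.counts.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for k in range(x.shape[1]):
        assigned = np.empty(n)
        assigned[order[:, k]] = target
        # average assigned values over ties within the sample
        col = pd.Series(assigned)
        out[:, k] = col.groupby(pd.Series(x[:, k])).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=cm.gene_ids, columns=cm.sample_ids)
    return NormalizedMatrix(values, "Q", None)


def normalize_rpkm(cm: CountMatrix, features: FeatureTable) -> NormalizedMatrix:
    """Reads per kilobase per million mapped reads."""
    lengths = features.lengths(cm.gene_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"missing gene lengths for {missing[:10]}")
    values = (
        cm.counts
        * 1e9
        / np.outer(lengths.to_numpy(float), cm.library_sizes.to_numpy(float))
    )
    return NormalizedMatrix(values, "RPKM", None)


def ruvg_factors(cm: CountMatrix, control_gene_ids, k: int = 1) -> pd.DataFrame:
    """Technical-variation factors from negative-control genes.

    Left as covariates for the DE model: W holds the first ``k`` sample-wise
    singular factors of the row-centred log(x+1) control submatrix.
    """
    controls = pd.Index(control_gene_ids)
    missing = controls.difference(cm.gene_ids)
    if len(missing):
        raise ValidationError(f"control genes absent from matrix: {list(missing)[:5]}")
    if k >= len(controls):
        raise ValidationError(f"k={k} must be < number of controls ({len(controls)})")
    z = np.log(cm.counts.loc[controls].to_numpy(float) + 1.0)
    z = z - z.mean(axis=1, keepdims=True)
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    W = (vt[:k] * s[:k, None]).T  # samples x k, scaled by singular values
    return pd.DataFrame(
        W, index=cm.sample_ids, columns=[f"W{j + 1}" for j in range(k)]
    )


def normalize(
    cm: CountMatrix, method: str, features: FeatureTable | None = None, **kwargs
) -> NormalizedMatrix:
    """Dispatch to a normalization method; ``RC`` is the identity."""
    if method == "RC":
        return NormalizedMatrix(
            cm.counts.astype(float),
            "RC",
            ScalingFactors("RC", pd.Series(1.0, index=cm.sample_ids)),
        )
    if method == "TC":
        return normalize_tc(cm)[0]
    if method == "UQ":
        return normalize_uq(cm)[0]
    if method == "Med":
        return normalize_med(cm)[0]
    if method == "TMM":
        return normalize_tmm(cm, **kwargs)[0]
    if method == "DESeq":
        return normalize_deseq(cm)[0]
    if method == "Q":
        return normalize_quantile(cm)
    if method == "RPKM":
        if features is None:
            raise ValidationError("RPKM requires a feature table with gene lengths")
        return normalize_rpkm(cm, features)
    raise ValidationError(f"unknown normalization method {method!r}")
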
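"""Differential-expression testing over the factorial model ladder.

For each gene the NB-GLM engine compares nested log-linear models in the
three crossed factors sex (S), genotype (G) and environment (E):

    Model 1:    b0 + S + G + E
    Model 2(a): b0 + S + G + E + G:E
    Model 2(b): b0 + S + G + E + G:E + G:S
    Model 2:    b0 + S + G + E + G:E + G:S + E:S
    Full:       Model 2 + G:E:S

Main effects are tested by removing each in turn from Model 1.  First-order
interactions can be tested three ways: ``sequential`` walks the ladder
(2(a) vs 1, 2(b) vs 2(a), 2 vs 2(b)); ``add_one`` adds each interaction
alone to Model 1; ``drop_one`` removes each from Model 2.  The three-way
interaction always compares the full model to Model 2.  On a balanced
design ``sequential`` and ``drop_one`` agree; ``sequential`` and ``add_one``
share the first rung (G:E) and ``sequential``/``drop_one`` share the last
(E:S) by construction.

The alternative engine ln-transforms normalized counts and runs a per-gene
fixed-effects ANOVA with partial (Type III) sums of squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleDesign, ValidationError
from .nbglm import (
    DispersionEstimates,
    cell_codes,
    design_matrix,
    estimate_dispersions,
    fit_nb_glm,
    fit_nb_glm_cells,
    lrt,
)

__all__ = [
    "MAIN_TERMS",
    "FIRST_ORDER_TERMS",
    "ALL_TERMS",
    "term_model_pairs",
    "test_terms",
    "ln_anova",
    "bh_adjust",
    "make_de_table",
]

MAIN_TERMS = ("G", "E", "S")
FIRST_ORDER_TERMS = ("G:E", "G:S", "E:S")
THREE_WAY = "G:E:S"
ALL_TERMS = MAIN_TERMS + FIRST_ORDER_TERMS + (THREE_WAY,)

MODEL1 = ("S", "G", "E")
MODEL2A = MODEL1 + ("G:E",)
MODEL2B = MODEL2A + ("G:S",)
MODEL2 = MODEL2B + ("E:S",)
FULL = MODEL2 + (THREE_WAY,)


def term_model_pairs(approach: str) -> dict[str, tuple[tuple, tuple]]:
    """(full, reduced) term sets per tested term for a given approach."""
    pairs: dict[str, tuple[tuple, tuple]] = {}
    for t in MAIN_TERMS:
        pairs[t] = (MODEL1, tuple(x for x in MODEL1 if x != t))
    if approach == "sequential":
        pairs["G:E"] = (MODEL2A, MODEL1)
        pairs["G:S"] = (MODEL2B, MODEL2A)
        pairs["E:S"] = (MODEL2, MODEL2B)
    elif approach == "add_one":
        for t in FIRST_ORDER_TERMS:
            pairs[t] = (MODEL1 + (t,), MODEL1)
    elif approach == "drop_one":
        for t in FIRST_ORDER_TERMS:
            pairs[t] = (MODEL2, tuple(x for x in MODEL2 if x != t))
    else:
        raise ValidationError(f"unknown interaction approach {approach!r}")
    pairs[THREE_WAY] = (FULL, MODEL2)
    return pairs


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN propagated)."""
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    if ((ps < 0) | (ps > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def make_de_table(
    gene_ids, stat, df, pvalues, fdr_level: float = 0.05, term: str = "", approach: str = ""
) -> pd.DataFrame:
    q = bh_adjust(pvalues)
    return pd.DataFrame(
        {
            "statistic": stat,
            "df": df,
            "pvalue": pvalues,
            "qvalue": q,
            "significant": q < fdr_level,
            "term": term,
            "approach": approach,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def test_terms(
    matrix: pd.DataFrame,
    design: SampleDesign,
    approach: str = "sequential",
    dispersions: DispersionEstimates | None = None,
    dispersion_mode: str = "trend_max",
    offsets: np.ndarray | None = None,
    fdr_level: float = 0.05,
    terms: tuple[str, ...] | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-term NB-GLM likelihood-ratio tests with BH correction within term.

    ``matrix`` is a genes x samples integer matrix (rounded normalized counts,
    or raw counts when per-sample log ``offsets`` carry the scaling).
    Dispersions are estimated once (on the input matrix) and reused for every
    nested comparison of a gene.
    """
    design = design.subset(matrix.columns)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, design, mode=dispersion_mode)
    phi = dispersions.phi.reindex(matrix.index).to_numpy()
    Y = matrix.to_numpy(float)
    zero_genes = Y.sum(axis=1) == 0
    wanted = tuple(terms) if terms is not None else ALL_TERMS
    pairs = term_model_pairs(approach)

    cache: dict[tuple, tuple[np.ndarray, int]] = {}
    # purely factorial models without offsets/covariates have cell-constant
    # means: fit on per-cell count sums (exact, and independent of n per cell)
    use_cells = offsets is None and extra_covariates is None
    if use_cells:
        codes, n_cells, reps = cell_codes(design)
        onehot = np.zeros((Y.shape[1], n_cells))
        onehot[np.arange(Y.shape[1]), codes] = 1.0
        S = Y @ onehot
        n_c = onehot.sum(axis=0)

    def fit(term_set: tuple) -> tuple[np.ndarray, int]:
        key = tuple(sorted(term_set))
        if key not in cache:
            X, _names = design_matrix(design, term_set, extra_covariates)
            if use_cells:
                _mu, dev, _conv = fit_nb_glm_cells(S, n_c, X[reps], phi)
                cache[key] = (dev, X.shape[1])
            else:
                res = fit_nb_glm(Y, X, phi, offset=offsets)
                cache[key] = (res.deviance, res.n_params)
        return cache[key]

    out: dict[str, pd.DataFrame] = {}
    for term in wanted:
        full_terms, red_terms = pairs[term]
        dev_f, p_f = fit(full_terms)
        dev_r, p_r = fit(red_terms)
        df = p_f - p_r
        if df < 1:
            out[term] = make_de_table(
                matrix.index,
                np.zeros(len(matrix)),
                0,
                np.full(len(matrix), np.nan),
                fdr_level,
                term,
                approach,
            )
            continue
        stat, pvals = lrt(dev_f, dev_r, df)
        stat = np.where(zero_genes, 0.0, stat)
        pvals = np.where(zero_genes, 1.0, pvals)
        out[term] = make_de_table(
            matrix.index, stat, df, pvals, fdr_level, term, approach
        )
    return out


# ---------------------------------------------------------------------------
# ln & ANOVA engine


def _sum_coded(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values))
    last = levels[-1]
    cols, names = [], []
    for lv in levels[:-1]:
        col = (values == lv).astype(float) - (values == last).astype(float)
        cols.append(col.to_numpy())
        names.append(f"{prefix}[{lv}]")
    return np.column_stack(cols) if cols else np.empty((len(values), 0)), names


def _anova_design(design: SampleDesign) -> dict[str, np.ndarray]:
    t = design.table
    base = {
        "G": _sum_coded(t["genotype"], "G")[0],
        "E": _sum_coded(t["environment"], "E")[0],
        "S": _sum_coded(t["sex"], "S")[0],
    }
    blocks: dict[str, np.ndarray] = {}
    for term in ALL_TERMS:
        mats = [base[f] for f in term.split(":")]
        block = mats[0]
        for mat in mats[1:]:
            block = np.einsum("ni,nj->nij", block, mat).reshape(len(t), -1)
        blocks[term] = block
    return blocks


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    resid = Y - (Y @ q) @ q.T
    return np.einsum("ij,ij->i", resid, resid)


def ln_anova(
    values: pd.DataFrame,
    design: SampleDesign,
    fdr_level: float = 0.05,
    offset: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Per-gene fixed-effects ANOVA of ln(normalized count + 1).

    Factors are sum-to-zero coded and each term is tested by partial
    (Type III) sums of squares, which coincide with sequential sums of
    squares when the design is balanced.  Genes with no residual variation
    report p = 1 by contract.
    """
    design = design.subset(values.columns)
    Y = np.log(values.to_numpy(float) + offset)
    blocks = _anova_design(design)
    n = Y.shape[1]
    Xfull = np.column_stack([np.ones((n, 1))] + [blocks[t] for t in ALL_TERMS])
    p_full = Xfull.shape[1]
    if np.linalg.matrix_rank(Xfull) < p_full:
        raise ValidationError("ANOVA design is rank-deficient (empty cells)")
    df_error = n - p_full
    if df_error < 1:
        raise ValidationError("no residual degrees of freedom for the full model")
    rss_full = _rss(Y, Xfull)
    degenerate = rss_full <= 1e-12 * np.maximum(1.0, (Y**2).sum(axis=1))
    out: dict[str, pd.DataFrame] = {}
    for term in ALL_TERMS:
        others = [np.ones((n, 1))] + [blocks[t] for t in ALL_TERMS if t != term]
        rss_red = _rss(Y, np.column_stack(others))
        df_t = blocks[term].shape[1]
        ss = np.clip(rss_red - rss_full, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_t) / (rss_full / df_error)
        pvals = stats.f.sf(F, df_t, df_error)
        F = np.where(degenerate, 0.0, F)
        pvals = np.where(degenerate, 1.0, pvals)
        out[term] = make_de_table(
            values.index, F, df_t, pvals, fdr_level, term, "lnanova"
        )
    return out
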
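"""Negative-binomial GLM engine with fixed per-gene dispersion.

Counts are modeled as x ~ NB(mu, sigma^2) with the quadratic mean-variance
law sigma^2 = mu + mu^2 * phi and a log link on the mean.  The dispersion
phi is estimated once per gene (method-of-moments within design cells, with
a fitted mean-dispersion trend) and then held fixed while nested models are
compared by likelihood ratio, i.e. by differences of deviances.

Fitting is iteratively reweighted least squares, vectorized across genes in
blocks: every gene shares the design matrix but carries its own working
weights, so the normal equations are solved as batched matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import SampleDesign, ValidationError

__all__ = [
    "design_matrix",
    "DispersionEstimates",
    "estimate_dispersions",
    "NBFitResult",
    "fit_nb_glm",
    "nb_deviance",
    "lrt",
]

FACTOR_COLUMNS = {"G": "genotype", "E": "environment", "S": "sex"}

#: numerical floor for fitted means
MU_FLOOR = 1e-8
#: dispersions below this are treated as Poisson
PHI_FLOOR = 1e-12


def _dummies(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values))
    cols = [(values == lv).to_numpy(float) for lv in levels[1:]]
    names = [f"{values.name}[{lv}]" for lv in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0)), names


def design_matrix(
    design: SampleDesign,
    terms: tuple[str, ...],
    extra_covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Full-rank treatment-coded design matrix for a set of factorial terms.

    ``terms`` uses the shorthand G/E/S with ':' for interactions, e.g.
    ``("S", "G", "E", "G:E")``.  Aliased columns (from empty cells) are
    dropped by pivoted QR so the returned matrix has full column rank.
    """
    t = design.table
    n = len(t)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    base = {}
    for key, col in FACTOR_COLUMNS.items():
        series = t[col].copy()
        series.name = key
        base[key] = _dummies(series)
    covariate_block = None
    for term in terms:
        factors = term.split(":")
        bad = [f for f in factors if f not in base]
        if bad:
            raise ValidationError(f"unknown factors {bad} in term {term!r}")
        mats = [base[f][0] for f in factors]
        nms = [base[f][1] for f in factors]
        block = mats[0]
        blocknames = nms[0]
        for mat, nm in zip(mats[1:], nms[1:]):
            block = np.einsum("ni,nj->nij", block, mat).reshape(n, -1)
            blocknames = [f"{a}:{b}" for a in blocknames for b in nm]
        blocks.append(block)
        names.extend(blocknames)
    if extra_covariates is not None:
        covariate_block = extra_covariates.loc[t.index].to_numpy(float)
        blocks.append(covariate_block)
        names.extend(list(extra_covariates.columns))
    X = np.column_stack(blocks)
    # drop aliased columns via pivoted QR
    from scipy.linalg import qr

    _q, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionEstimates:
    """Per-gene dispersion with the fitted mean trend.

    ``raw`` is the method-of-moments estimate from within-cell replicate
    variation; ``fitted`` evaluates the trend phi(mu) = a0 + a1/mu at the
    gene's mean; ``phi`` is the final value: the max of the two in
    ``trend_max`` mode, or a precision-weighted shrink of raw toward the
    trend in ``eb_shrink`` mode.
    """

    raw: pd.Series
    fitted: pd.Series
    phi: pd.Series
    mode: str
    trend_coef: tuple[float, float]
    mean: pd.Series


def estimate_dispersions(
    matrix: pd.DataFrame,
    design: SampleDesign,
    mode: str = "trend_max",
    prior_weight: float = 10.0,
    trend_min_mean: float = 5.0,
) -> DispersionEstimates:
    """Method-of-moments dispersions with a robust 1/mu trend.

    Within each genotype x environment x sex cell the replicate variance is
    pooled; phi_raw = max(0, (pooled variance - mean) / mean^2).  The trend
    a0 + a1/mu is fitted by robust (Huber) regression over genes with a
    positive raw estimate and mean at least ``trend_min_mean``: near-zero
    means give 1/mu enormous leverage and would let a handful of barely
    expressed genes steer the trend for every gene.
    """
    t = design.table.loc[matrix.columns]
    y = matrix.to_numpy(float)
    cells = t.groupby(["genotype", "environment", "sex"]).indices
    ss = np.zeros(y.shape[0])
    df_resid = 0
    for idx in cells.values():
        if len(idx) < 2:
            continue
        sub = y[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df_resid += len(idx) - 1
    if df_resid == 0:
        raise ValidationError(
            "no design cell has replication; dispersion unidentifiable"
        )
    pooled_var = ss / df_resid
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (pooled_var - mean) / mean**2, 0.0)
    raw = np.clip(raw, 0.0, None)

    ok = (raw > 0) & (mean >= trend_min_mean)
    if ok.sum() < 10:  # too few adequately expressed genes: relax the floor
        ok = (raw > 0) & (mean > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        rlm = sm.RLM(raw[ok], X, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = float(rlm.params[0]), float(rlm.params[1])
    else:  # too few informative genes: flat trend at the median raw value
        a0, a1 = float(np.median(raw[ok])) if ok.any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        fitted = np.where(mean > 0, a0 + a1 / mean, 0.0)
    fitted = np.clip(fitted, 0.0, None)

    if mode == "trend_max":
        phi = np.maximum(raw, fitted)
    elif mode == "eb_shrink":
        w = prior_weight / (prior_weight + df_resid)
        phi = w * fitted + (1.0 - w) * raw
    else:
        raise ValidationError(f"unknown dispersion mode {mode!r}")
    idx = matrix.index
    return DispersionEstimates(
        raw=pd.Series(raw, index=idx),
        fitted=pd.Series(fitted, index=idx),
        phi=pd.Series(phi, index=idx),
        mode=mode,
        trend_coef=(a0, a1),
        mean=pd.Series(mean, index=idx),
    )


# ---------------------------------------------------------------------------
# batched IRLS


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Residual deviance (saturated minus model, times two) per gene.

    ``y``/``mu`` are (genes, samples); ``phi`` is (genes,).  Genes with phi
    below the Poisson floor use the Poisson deviance, the phi -> 0 limit.
    """
    y = np.asarray(y, float)
    mu = np.maximum(mu, MU_FLOOR)
    phi = np.asarray(phi, float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    pois = 2.0 * (term1 - (y - mu))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(phi > PHI_FLOOR, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        nb = 2.0 * (term1 - (y + inv) * np.log((y + inv) / (mu + inv)))
    dev = np.where(phi > PHI_FLOOR, nb, pois)
    return dev.sum(axis=1)


@dataclass
class NBFitResult:
    beta: np.ndarray  # genes x p
    mu: np.ndarray  # genes x samples
    deviance: np.ndarray  # genes
    converged: np.ndarray  # genes, bool
    n_params: int
    column_names: list[str]


def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    phi: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    block_size: int = 256,
) -> NBFitResult:
    """Fit one NB GLM per gene (rows of ``Y``) at fixed dispersion.

    ``X`` (samples x p) is shared across genes; ``offset`` is an optional
    per-sample natural-log offset.  Returns coefficients, fitted means and
    residual deviances.  A small ridge (1e-10) stabilizes the normal
    equations; genes that fail to converge are flagged, not dropped.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    g, n = Y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, float), (g,)).copy()
    off = np.zeros(n) if offset is None else np.asarray(offset, float)
    beta = np.zeros((g, p))
    mu_all = np.zeros((g, n))
    dev_all = np.zeros(g)
    conv = np.zeros(g, bool)
    ridge = 1e-10 * np.eye(p)

    for s in range(0, g, block_size):
        sl = slice(s, min(s + block_size, g))
        yb = Y[sl]
        pb = phi[sl][:, None]
        m = yb.shape[0]
        mu = np.maximum(yb + 0.5, MU_FLOOR)
        eta = np.log(mu)
        b = np.zeros((m, p))
        dev = nb_deviance(yb, mu, phi[sl])
        done = np.zeros(m, bool)
        for _ in range(max_iter):
            act = ~done
            if not act.any():
                break
            W = mu[act] / (1.0 + pb[act] * mu[act])
            z = (eta[act] - off) + (yb[act] - mu[act]) / mu[act]
            Xw = X[None, :, :] * W[:, :, None]  # (m_act, n, p)
            A = np.matmul(Xw.transpose(0, 2, 1), X[None, :, :]) + ridge
            rhs = np.matmul(Xw.transpose(0, 2, 1), (z * 1.0)[:, :, None])[..., 0]
            try:
                b_new = np.linalg.solve(A, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                b_new = np.linalg.lstsq(
                    A.reshape(-1, p), rhs.reshape(-1), rcond=None
                )[0].reshape(-1, p)
            eta_new = b_new @ X.T + off
            eta_new = np.clip(eta_new, np.log(MU_FLOOR), 50.0)
            mu_new = np.exp(eta_new)
            dev_new = nb_deviance(yb[act], mu_new, phi[sl][act])
            # step-halving where deviance worsened appreciably
            worse = dev_new > dev[act] + 1e-8
            if worse.any():
                b_half = 0.5 * (b_new[worse] + b[act][worse])
                eta_half = np.clip(b_half @ X.T + off, np.log(MU_FLOOR), 50.0)
                b_new[worse] = b_half
                eta_new[worse] = eta_half
                mu_new[worse] = np.exp(eta_half)
                dev_new[worse] = nb_deviance(
                    yb[act][worse], mu_new[worse], phi[sl][act][worse]
                )
            moved = np.abs(dev_new - dev[act]) > tol * (np.abs(dev_new) + 1.0)
            idx = np.flatnonzero(act)
            b[idx] = b_new
            eta[idx] = eta_new
            mu[idx] = mu_new
            dev[idx] = dev_new
            done[idx[~moved]] = True
        beta[sl] = b
        mu_all[sl] = mu
        dev_all[sl] = dev
        conv[sl] = done
    return NBFitResult(beta, mu_all, dev_all, conv, p, [])


def cell_codes(design: SampleDesign) -> tuple[np.ndarray, int, np.ndarray]:
    """Factor-cell code per sample, number of cells, one representative row.

    For purely factorial models without offsets the fitted mean is constant
    within each genotype x environment x sex cell, so fitting can operate on
    per-cell count sums.
    """
    t = design.table
    key = (
        t["genotype"].astype(str)
        + "\x00"
        + t["environment"].astype(str)
        + "\x00"
        + t["sex"].astype(str)
    )
    codes, uniques = pd.factorize(key, sort=True)
    reps = np.array([np.flatnonzero(codes == c)[0] for c in range(len(uniques))])
    return codes, len(uniques), reps


def deviance_constant(Y: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene model-independent part of the NB deviance."""
    Y = np.asarray(Y, float)
    phi = np.asarray(phi, float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0)), 0.0)
        inv = 1.0 / np.where(phi > PHI_FLOOR, phi, 1.0)
        nb_const = 2.0 * (ylogy - (Y + inv) * np.log(Y + inv))
    pois_const = 2.0 * (ylogy - Y)
    return np.where(phi > PHI_FLOOR, nb_const, pois_const).sum(axis=1)


def _dev_part_cells(
    S: np.ndarray, n_c: np.ndarray, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Model-dependent deviance part from cell sums S and cell means mu."""
    phi = np.asarray(phi, float)[:, None]
    mu = np.maximum(mu, MU_FLOOR)
    logmu = np.log(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / np.where(phi > PHI_FLOOR, phi, 1.0)
        nb = 2.0 * (-S * logmu + (S + n_c[None, :] * inv) * np.log(mu + inv))
    pois = 2.0 * (-S * logmu + n_c[None, :] * mu)
    return np.where(phi > PHI_FLOOR, nb, pois).sum(axis=1)


def fit_nb_glm_cells(
    S: np.ndarray,
    n_c: np.ndarray,
    Xc: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    block_size: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS on per-cell sufficient aggregates (exact for factorial designs).

    ``S`` is genes x cells count sums, ``n_c`` the per-cell sample counts and
    ``Xc`` the design matrix evaluated at one sample per cell.  Returns
    (cell means mu, model-dependent deviance part, converged).  When ``Xc``
    spans the full cell space the MLE is the cell mean and no iteration runs.
    """
    S = np.atleast_2d(np.asarray(S, float))
    g, ncell = S.shape
    p = Xc.shape[1]
    phi = np.broadcast_to(np.asarray(phi, float), (g,)).copy()
    if p == ncell:  # cell-saturated model: NB score solves to the cell mean
        mu = np.maximum(S / n_c[None, :], MU_FLOOR)
        return mu, _dev_part_cells(S, n_c, mu, phi), np.ones(g, bool)
    mu_all = np.zeros((g, ncell))
    dev_all = np.zeros(g)
    conv = np.zeros(g, bool)
    ridge = 1e-10 * np.eye(p)
    Q, _ = np.linalg.qr(Xc)  # projection init: log cell means onto the model
    for s0 in range(0, g, block_size):
        sl = slice(s0, min(s0 + block_size, g))
        Sb = S[sl]
        pb = phi[sl][:, None]
        m = Sb.shape[0]
        ybar = Sb / n_c[None, :]
        eta = np.clip(
            (np.log(np.maximum(ybar, 0.5)) @ Q) @ Q.T, np.log(MU_FLOOR), 50.0
        )
        mu = np.exp(eta)
        b = np.zeros((m, p))
        dev = _dev_part_cells(Sb, n_c, mu, phi[sl])
        done = np.zeros(m, bool)
        for _ in range(max_iter):
            act = ~done
            if not act.any():
                break
            W = n_c[None, :] * mu[act] / (1.0 + pb[act] * mu[act])
            z = eta[act] + (ybar[act] - mu[act]) / mu[act]
            Xw = Xc[None, :, :] * W[:, :, None]
            A = np.matmul(Xw.transpose(0, 2, 1), Xc[None, :, :]) + ridge
            rhs = np.matmul(Xw.transpose(0, 2, 1), z[:, :, None])[..., 0]
            b_new = np.linalg.solve(A, rhs[..., None])[..., 0]
            eta_new = np.clip(b_new @ Xc.T, np.log(MU_FLOOR), 50.0)
            mu_new = np.exp(eta_new)
            dev_new = _dev_part_cells(Sb[act], n_c, mu_new, phi[sl][act])
            worse = dev_new > dev[act] + 1e-8
            if worse.any():
                b_half = 0.5 * (b_new[worse] + b[act][worse])
                eta_half = np.clip(b_half @ Xc.T, np.log(MU_FLOOR), 50.0)
                b_new[worse] = b_half
                eta_new[worse] = eta_half
                mu_new[worse] = np.exp(eta_half)
                dev_new[worse] = _dev_part_cells(
                    Sb[act][worse], n_c, mu_new[worse], phi[sl][act][worse]
                )
            moved = np.abs(dev_new - dev[act]) > tol * (np.abs(dev_new) + 1.0)
            idx = np.flatnonzero(act)
            b[idx] = b_new
            eta[idx] = eta_new
            mu[idx] = mu_new
            dev[idx] = dev_new
            done[idx[~moved]] = True
        mu_all[sl] = mu
        dev_all[sl] = dev
        conv[sl] = done
    return mu_all, dev_all, conv


def lrt(
    dev_full: np.ndarray,
    dev_reduced: np.ndarray,
    df: int,
    neg_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio statistics and chi-square p-values for nested fits.

    The statistic is the deviance difference (identical whether deviance is
    measured against the saturated model or as -2 log-likelihood).  Small
    negative differences from finite convergence are clipped to zero; larger
    ones indicate a fitting failure and raise.
    """
    stat = np.asarray(dev_reduced, float) - np.asarray(dev_full, float)
    if (stat < -neg_tol).any():
        worst = float(stat.min())
        raise ValidationError(
            f"negative LRT statistic ({worst:.3g}): full model fits worse "
            "than reduced; fitting failure"
        )
    stat = np.clip(stat, 0.0, None)
    if df < 1:
        raise ValidationError("LRT needs at least one parameter difference")
    pvals = stats.chi2.sf(stat, df)
    return stat, pvals


def fit_single_gene_statsmodels(y, X, phi, offset=None):
    """Reference per-gene fit via statsmodels (oracle for tests)."""
    fam = (
        sm.families.Poisson()
        if phi <= PHI_FLOOR
        else sm.families.NegativeBinomial(alpha=phi)
    )
    model = sm.GLM(y, X, family=fam, offset=offset)
    res = model.fit(maxiter=200, tol=1e-10)
    return res


def all_model_terms() -> list[str]:
    out = ["G", "E", "S"]
    for r in (2, 3):
        out += [":".join(c) for c in combinations(("G", "E", "S"), r)]
    return out
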
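"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the defining formulas, with plain
loops and no shared code with the package, so agreement between the two
routes is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tc_normalize(counts: pd.DataFrame, lib_sizes: pd.Series) -> pd.DataFrame:
    mean_n = lib_sizes.mean()
    out = counts.astype(float).copy()
    for k in counts.columns:
        out[k] = counts[k] / (lib_sizes[k] / mean_n)
    return out


def _nonzero(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.loc[counts.sum(axis=1) > 0]


def uq_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    sub = _nonzero(counts)
    uqs = {k: np.percentile(sub[k], 75) for k in counts.columns}
    mean_uq = np.mean(list(uqs.values()))
    out = counts.astype(float).copy()
    for k in counts.columns:
        out[k] = counts[k] / (uqs[k] / mean_uq)
    return out


def med_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    sub = _nonzero(counts)
    meds = {k: np.median(sub[k]) for k in counts.columns}
    mean_med = np.mean(list(meds.values()))
    out = counts.astype(float).copy()
    for k in counts.columns:
        out[k] = counts[k] / (meds[k] / mean_med)
    return out


def deseq_factors(counts: pd.DataFrame) -> pd.Series:
    x = counts.to_numpy(float)
    keep = (x > 0).all(axis=1)
    ref = np.exp(np.log(x[keep]).mean(axis=1))
    s = {}
    for j, k in enumerate(counts.columns):
        s[k] = float(np.median(x[keep, j] / ref))
    return pd.Series(s)


def quantile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    x = counts.to_numpy(float)
    target = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for k in range(x.shape[1]):
        col = x[:, k]
        # value for each row: mean of target over the positions its ties span
        order = np.argsort(col, kind="stable")
        pos_value = np.empty_like(col)
        pos_value[order] = target
        for v in np.unique(col):
            mask = col == v
            pos_value[mask] = pos_value[mask].mean()
        out[:, k] = pos_value
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def rpkm_normalize(
    counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series
) -> pd.DataFrame:
    out = counts.astype(float).copy()
    for k in counts.columns:
        for g in counts.index:
            out.loc[g, k] = counts.loc[g, k] * 1e9 / (lib_sizes[k] * lengths[g])
    return out


def tmm_factor(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    sample: str,
    ref: str,
    trim_m: float = 0.30,
    trim_a: float = 0.10,
) -> float:
    """Weighted trimmed mean of M-values, directly from the definitions."""
    xk = counts[sample].to_numpy(float)
    xr = counts[ref].to_numpy(float)
    Nk, Nr = float(lib_sizes[sample]), float(lib_sizes[ref])
    ok = (xk > 0) & (xr > 0)
    xk, xr = xk[ok], xr[ok]
    M = np.log2((xk / Nk) / (xr / Nr))
    A = 0.5 * (np.log2(xk / Nk) + np.log2(xr / Nr))
    m_lo, m_hi = np.quantile(M, [trim_m / 2, 1 - trim_m / 2])
    a_lo, a_hi = np.quantile(A, [trim_a / 2, 1 - trim_a / 2])
    keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
    var = (Nk - xk) / (Nk * xk) + (Nr - xr) / (Nr * xr)
    w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), 0.0)
    w, M = w[keep], M[keep]
    return float(2.0 ** (np.sum(w * M) / np.sum(w)))


def bh(pvalues) -> np.ndarray:
    """Definitional step-up: q_(i) = min_{j >= i} (m/j) p_(j), capped at 1."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        vals = [p[order[j]] * m / (j + 1) for j in range(rank_i, m)]
        q[order[rank_i]] = min(1.0, min(vals))
    return q


def spearman(x, y) -> float:
    """Rank (average ties) then Pearson."""

    def rank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        for u in np.unique(v):
            mask = v == u
            r[mask] = r[mask].mean()
        return r

    rx, ry = rank(x), rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def jaccard_pct(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 100.0
    inter = 0
    for item in a:
        if item in b:
            inter += 1
    return 100.0 * inter / len(a | b)


def r_mismatch(sample_calls, line_calls, missing="N") -> float:
    D = M = 0
    for s, l in zip(sample_calls, line_calls):
        if s == missing or l == missing:
            continue
        if s == l:
            M += 1
        else:
            D += 1
    return D / M if M else float("nan")
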
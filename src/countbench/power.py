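"""Factorial power analysis for the three-factor ANOVA model.

For a balanced a x b x c design with n replicates per cell and error
variance sigma^2 on the ln scale, the F test of the three-way interaction
has noncentrality

    lambda = n * sum_ijk (abc_effect_ijk)^2 / sigma^2

With the standardized range d = D / sigma, where D = max(mu_ijk) -
min(mu_ijk) is the ln-scale fold-change, the minimum noncentrality over all
effect patterns with that range is n d^2 / 2 (attained by two cells at
+/- D/2).  Using lambda_min therefore yields a conservative power estimate
and a conservative detectable fold-change at a target power.

An empirical counterpart subsamples flies per cell, reruns the NB-GLM
analysis, and reports the fraction of the full data set's significant genes
recovered at each FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CountMatrix, SampleDesign, ValidationError

__all__ = [
    "PowerSpec",
    "noncentrality",
    "lambda_min",
    "power_f",
    "detectable_fold_change",
    "power_curve",
    "empirical_subsample_power",
]


@dataclass
class PowerSpec:
    """Design dimensions and test parameters for the factorial F test."""

    a: int = 16
    b: int = 3
    c: int = 2
    alpha: float = 0.05
    term: str = "three_way"  # or "first_order" (the a x b interaction)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 2:
            raise ValidationError("each factor needs at least two levels")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.term not in ("three_way", "first_order"):
            raise ValidationError("term must be 'three_way' or 'first_order'")

    @property
    def df1(self) -> int:
        if self.term == "three_way":
            return (self.a - 1) * (self.b - 1) * (self.c - 1)
        return (self.a - 1) * (self.b - 1)

    def df2(self, n: int) -> int:
        return self.a * self.b * self.c * (n - 1)

    def replication_per_cell(self, n: int) -> int:
        """Effective replication of one cell of the tested interaction."""
        return n if self.term == "three_way" else self.c * n


def _check_interaction_effects(effects: np.ndarray, tol: float = 1e-8) -> None:
    """Pure three-way interaction effects sum to zero over every axis."""
    for ax in range(3):
        margins = effects.sum(axis=ax)
        if np.abs(margins).max() > tol * max(1.0, np.abs(effects).max()):
            raise ValidationError(
                "effects are not a pure interaction pattern (nonzero margins)"
            )


def noncentrality(effects, sigma2: float, n: int) -> tuple[float, float]:
    """Noncentrality lambda and its phi^2 form for the three-way F test.

    ``effects`` is the a x b x c array of interaction deviations
    (abc_effect_ijk); lambda = n * sum(effects^2) / sigma^2.
    """
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    eff = np.asarray(effects, float)
    if eff.ndim != 3:
        raise ValidationError("effects must be a 3-d (a, b, c) array")
    _check_interaction_effects(eff)
    a, b, c = eff.shape
    lam = n * float((eff**2).sum()) / sigma2
    phi2 = lam / ((a - 1) * (b - 1) * (c - 1) + 1)
    return lam, phi2


def lambda_min(n: int, d: float) -> float:
    """Minimum noncentrality over effect patterns with standardized range d."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if d < 0:
        raise ValidationError("d must be >= 0")
    return n * d * d / 2.0


def power_f(lam: float, df1: int, df2: int, alpha: float = 0.05) -> float:
    """Power of the F test at noncentrality ``lam``; lam = 0 gives alpha."""
    if df1 < 1 or df2 < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    if lam < 0:
        raise ValidationError("noncentrality must be >= 0")
    crit = stats.f.isf(alpha, df1, df2)
    if lam == 0:
        return float(alpha)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def detectable_fold_change(
    n: int,
    target_power: float = 0.80,
    sigma2: float = 1.0,
    spec: PowerSpec | None = None,
    tol: float = 1e-8,
) -> float:
    """Smallest ln-scale fold-change D detectable at the target power.

    Conservative: uses lambda_min, i.e. the least favourable effect pattern
    with range D.  Solved by bracketed root finding on D.
    """
    spec = spec or PowerSpec()
    if not spec.alpha < target_power < 1:
        raise ValidationError("target_power must be in (alpha, 1)")
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    df2 = spec.df2(n)
    if df2 < 1:
        raise ValidationError(f"n={n} leaves no error degrees of freedom")
    reps = spec.replication_per_cell(n)

    def gap(D: float) -> float:
        lam = lambda_min(reps, D / np.sqrt(sigma2))
        return power_f(lam, spec.df1, df2, spec.alpha) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("no detectable fold-change bracket found")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=tol))


def power_curve(
    n_values=range(2, 9),
    target_power: float = 0.80,
    sigma2: float = 1.0,
    spec: PowerSpec | None = None,
) -> pd.DataFrame:
    """Detectable ln fold-change (and its exp) versus replicates per cell."""
    spec = spec or PowerSpec()
    rows = []
    for n in n_values:
        D = detectable_fold_change(n, target_power, sigma2, spec)
        rows.append({"n": n, "detectable_D_ln": D, "detectable_fold": float(np.exp(D))})
    return pd.DataFrame(rows).set_index("n")


def empirical_subsample_power(
    full_tables: dict[str, pd.DataFrame],
    counts: CountMatrix,
    design: SampleDesign,
    de_runner,
    n_sub=(2, 3, 5),
    fdr_grid=(0.0001, 0.001, 0.01, 0.05),
    seed: int = 0,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Overlap of subsampled analyses with the full data set's DE genes.

    ``de_runner(counts, design) -> {term: DETable}`` re-runs the chosen
    analysis on the subsample.  For each term and FDR threshold the table
    reports the percentage of the full data set's significant genes that the
    subsample recovers, averaged over ``n_repeats`` seeded draws per cell
    (sampling without replacement within genotype x environment x sex cells).
    """
    t = design.table.loc[counts.sample_ids]
    cell_sizes = t.groupby(["genotype", "environment", "sex"]).size()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    rows = []
    for ns in n_sub:
        if ns > cell_sizes.min():
            raise ValidationError(
                f"n_sub={ns} exceeds smallest cell size {cell_sizes.min()}"
            )
        for rep in range(n_repeats):
            chosen = []
            for _, grp in t.groupby(["genotype", "environment", "sex"]):
                idx = rng.choice(len(grp), size=ns, replace=False)
                chosen.extend(grp.index[np.sort(idx)])
            sub_counts = counts.subset_samples(chosen)
            sub_tables = de_runner(sub_counts, design.subset(chosen))
            for term, full_tab in full_tables.items():
                if term not in sub_tables:
                    continue
                sub_tab = sub_tables[term]
                for fdr in fdr_grid:
                    full_set = set(full_tab.index[full_tab["qvalue"] < fdr])
                    sub_set = set(sub_tab.index[sub_tab["qvalue"] < fdr])
                    pct = (
                        100.0 * len(full_set & sub_set) / len(full_set)
                        if full_set
                        else np.nan
                    )
                    rows.append(
                        {
                            "term": term,
                            "n_sub": ns,
                            "repeat": rep,
                            "fdr": fdr,
                            "overlap_pct": pct,
                            "n_full": len(full_set),
                            "n_sub_sig": len(sub_set),
                        }
                    )
    return pd.DataFrame(rows)
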
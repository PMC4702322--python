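"""Agreement metrics between DE gene sets and a PCA diagnostic.

"Agreement" between two significant-gene sets is reported three ways: the
Jaccard percentage 100*|A&B|/|A|B| union, and both directed recalls.  Two
empty sets agree perfectly by convention (two null results).  A grid helper
tabulates agreement across analysis conditions (workflow pairs, engine
pairs, approach pairs) per model term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import SampleDesign, ValidationError
from .normalization import NormalizedMatrix

__all__ = [
    "AgreementResult",
    "agreement",
    "overlap_across_conditions",
    "comparison_grid",
    "PCADiagnostic",
    "pca_diagnostic",
]


@dataclass
class AgreementResult:
    jaccard: float  # percentage
    recall_a: float
    recall_b: float
    n_a: int
    n_b: int
    n_intersection: int

    @property
    def headline(self) -> float:
        return self.jaccard


def agreement(set_a, set_b) -> AgreementResult:
    """Percentage agreement between two gene sets (empty/empty -> 100)."""
    A, B = set(set_a), set(set_b)
    inter = len(A & B)
    union = len(A | B)
    if union == 0:
        return AgreementResult(100.0, 100.0, 100.0, 0, 0, 0)
    jac = 100.0 * inter / union
    ra = 100.0 * inter / len(A) if A else 100.0
    rb = 100.0 * inter / len(B) if B else 100.0
    return AgreementResult(jac, ra, rb, len(A), len(B), inter)


def overlap_across_conditions(
    sets: dict, exclude: str | None = None
) -> dict:
    """Common intersection size across conditions, with/without one excluded."""
    if len(sets) < 2:
        raise ValidationError("need at least two sets")
    all_inter = set.intersection(*(set(s) for s in sets.values()))
    out = {
        "n_common": len(all_inter),
        "sizes": {k: len(set(v)) for k, v in sets.items()},
    }
    if exclude is not None and exclude in sets:
        rest = [set(v) for k, v in sets.items() if k != exclude]
        out["n_common_excluding"] = len(set.intersection(*rest))
        out["excluded"] = exclude
    return out


def comparison_grid(runs: dict, metric: str = "jaccard") -> pd.DataFrame:
    """Agreement matrix over (term x condition-pair).

    ``runs`` maps condition label -> {term: significant gene set}.  All runs
    must share the same term keys.  Rows are terms, columns are unordered
    condition pairs.
    """
    labels = list(runs)
    if len(labels) < 2:
        raise ValidationError("need at least two runs to compare")
    terms = list(runs[labels[0]])
    for lab in labels[1:]:
        if list(runs[lab]) != terms:
            raise ValidationError("runs have mismatched term definitions")
    cols = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            vals = []
            for term in terms:
                res = agreement(runs[la][term], runs[lb][term])
                vals.append(getattr(res, {"jaccard": "jaccard",
                                          "recall_a": "recall_a",
                                          "recall_b": "recall_b"}[metric]))
            cols[f"{la} vs {lb}"] = vals
    return pd.DataFrame(cols, index=pd.Index(terms, name="term"))


@dataclass
class PCADiagnostic:
    scores: pd.DataFrame  # samples x [PC1, PC2]
    variance_pct: np.ndarray
    sex_silhouette_pc1: float | None


def pca_diagnostic(
    norm: NormalizedMatrix | pd.DataFrame, design: SampleDesign | None = None
) -> PCADiagnostic:
    """First two principal components of centred log2(normalized + 1).

    When a design is given, reports the silhouette of the two sexes along
    PC1 as a separation score.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if values.shape[1] < 3:
        raise ValidationError("PCA diagnostic needs at least three samples")
    Z = np.log2(values.to_numpy(float).T + 1.0)  # samples x genes
    if np.allclose(Z.std(axis=0).sum(), 0):
        raise ValidationError("constant matrix has no principal components")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z - Z.mean(axis=0, keepdims=True))
    var_pct = 100.0 * pca.explained_variance_ratio_
    score_df = pd.DataFrame(scores, index=values.columns, columns=["PC1", "PC2"])
    sil = None
    if design is not None:
        sex = design.table.loc[values.columns, "sex"]
        if sex.nunique() == 2:
            sil = float(
                silhouette_score(scores[:, [0]], sex.to_numpy())
            )
    return PCADiagnostic(score_df, var_pct, sil)
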
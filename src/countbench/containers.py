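"""Core domain containers for the count-analysis pipeline.

The central objects are a gene-by-sample integer count matrix with per-sample
library sizes, a feature annotation table distinguishing genic from intergenic
regions, and a sample design table carrying the three crossed experimental
factors (genotype, environment, sex) plus replicate/library structure.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountMatrix",
    "FeatureTable",
    "SampleDesign",
    "AnalysisConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object violates its contract."""


def _check_unique(ids: Iterable, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``library_sizes`` holds the per-sample total of mapped reads (N_k).  When
    not supplied it defaults to the column sums of the matrix and is then
    *frozen*: downstream filtering steps must not recompute it, so that
    total-count scaling sees the same N_k before and after gene removal.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        vals = self.counts.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if vals.size:
            if np.isnan(vals.astype(float)).any():
                raise ValidationError("counts contain NaN")
            if (vals < 0).any():
                raise ValidationError("counts contain negative entries")
            if not np.allclose(vals, np.round(vals.astype(float))):
                bad = np.argwhere(vals != np.round(vals.astype(float)))
                raise ValidationError(
                    f"counts contain non-integer entries, first at {bad[0].tolist()}"
                )
            self.counts = self.counts.astype(np.int64)
        _check_unique(self.counts.index, "gene_ids")
        _check_unique(self.counts.columns, "sample_ids")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()]
                raise ValidationError(f"library_sizes missing for {list(missing)}")
            if (self.library_sizes <= 0).any():
                raise ValidationError("library_sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        """Row subset keeping the frozen library sizes."""
        return CountMatrix(self.counts.loc[gene_ids], self.library_sizes)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.library_sizes[list(sample_ids)]
        )


GENIC = "genic"
INTERGENIC = "intergenic"
PROTEIN_CODING = "protein_coding"
NON_CODING = "non_coding"


@dataclass
class FeatureTable:
    """Feature annotation: coordinates, length, genic/intergenic and coding class.

    Coordinates are stored 0-based half-open; lengths are ``end - start``.
    Intergenic features shorter than the read length cannot receive uniquely
    mapped reads and are flagged invalid for threshold derivation.
    """

    table: pd.DataFrame
    read_length: int = 76

    REQUIRED = ("chrom", "start", "end", "strand", "region_class", "coding_class")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        _check_unique(t.index, "feature_ids")
        if (t["end"] <= t["start"]).any():
            bad = t.index[t["end"] <= t["start"]].tolist()
            raise ValidationError(f"features with end <= start: {bad[:10]}")
        bad_strand = ~t["strand"].isin(["+", "-", "."])
        if bad_strand.any():
            raise ValidationError(
                f"unknown strand symbols: {t['strand'][bad_strand].unique().tolist()}"
            )
        bad_region = ~t["region_class"].isin([GENIC, INTERGENIC])
        if bad_region.any():
            raise ValidationError("region_class must be genic or intergenic")
        t = t.copy()
        t["length"] = (t["end"] - t["start"]).astype(np.int64)
        t["intergenic_valid"] = (t["region_class"] == INTERGENIC) & (
            t["length"] >= self.read_length
        )
        self.table = t

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index

    def lengths(self, feature_ids=None) -> pd.Series:
        s = self.table["length"]
        return s if feature_ids is None else s.reindex(feature_ids)

    def genic_ids(self) -> pd.Index:
        return self.table.index[self.table["region_class"] == GENIC]

    def intergenic_ids(self, valid_only: bool = True) -> pd.Index:
        mask = self.table["region_class"] == INTERGENIC
        if valid_only:
            mask &= self.table["intergenic_valid"]
        return self.table.index[mask]

    def coding_ids(self) -> pd.Index:
        return self.table.index[self.table["coding_class"] == PROTEIN_CODING]


@dataclass
class SampleDesign:
    """Sample-to-condition mapping for the genotype x environment x sex design."""

    table: pd.DataFrame

    REQUIRED = ("genotype", "environment", "sex")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"design table missing columns {missing}")
        _check_unique(t.index, "sample_ids")
        t = t.copy()
        if "replicate" not in t.columns:
            t["replicate"] = (
                t.groupby(["genotype", "environment", "sex"]).cumcount() + 1
            )
        if "individual" not in t.columns:
            t["individual"] = t.index
        if "library_id" not in t.columns:
            t["library_id"] = t.index
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def levels(self, factor: str) -> list:
        return sorted(self.table[factor].unique().tolist())

    @property
    def n_levels(self) -> tuple[int, int, int]:
        return (
            len(self.levels("genotype")),
            len(self.levels("environment")),
            len(self.levels("sex")),
        )

    def cell_sizes(self) -> pd.Series:
        return self.table.groupby(["genotype", "environment", "sex"]).size()

    def is_balanced(self) -> bool:
        sizes = self.cell_sizes()
        a, b, c = self.n_levels
        return len(sizes) == a * b * c and sizes.nunique() == 1

    def subset(self, sample_ids) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_ids)])

    def primary_libraries(self) -> pd.Index:
        """One library per individual (the first), for biological analyses."""
        first = self.table.groupby("individual", sort=False).head(1)
        return pd.Index(first.index)

    def duplicate_individuals(self) -> pd.Index:
        """Individuals represented by more than one library."""
        counts = self.table.groupby("individual").size()
        return pd.Index(counts.index[counts >= 2])

    def check_samples(self, sample_ids) -> None:
        missing = pd.Index(sample_ids).difference(self.table.index)
        if len(missing):
            raise ValidationError(
                f"samples present in counts but absent from design: {list(missing)[:10]}"
            )


NORMALIZATION_METHODS = ("TC", "UQ", "Med", "TMM", "DESeq", "Q", "RPKM", "RC")
WORKFLOWS = (1, 2, 3)
DISPERSION_MODES = ("trend_max", "eb_shrink")
INTERACTION_APPROACHES = ("sequential", "add_one", "drop_one")
COUNT_INPUT_MODES = ("rounded", "offset")


@dataclass
class AnalysisConfig:
    """Validated knobs for one end-to-end analysis run."""

    normalization_method: str = "DESeq"
    workflow: int = 1
    threshold_percentile: float = 95.0
    fdr_level: float = 0.05
    dispersion_mode: str = "trend_max"
    interaction_approach: str = "sequential"
    rng_seed: int = 0
    count_input_mode: str = "rounded"

    def __post_init__(self) -> None:
        if self.normalization_method not in NORMALIZATION_METHODS:
            raise ValidationError(
                f"unknown normalization method {self.normalization_method!r}; "
                f"choose from {NORMALIZATION_METHODS}"
            )
        if self.workflow not in WORKFLOWS:
            raise ValidationError(f"workflow must be one of {WORKFLOWS}")
        if not 0 < self.threshold_percentile <= 100:
            raise ValidationError("threshold_percentile must be in (0, 100]")
        if not 0 < self.fdr_level < 1:
            raise ValidationError("fdr_level must be in (0, 1)")
        if self.dispersion_mode not in DISPERSION_MODES:
            raise ValidationError(f"dispersion_mode must be one of {DISPERSION_MODES}")
        if self.interaction_approach not in INTERACTION_APPROACHES:
            raise ValidationError(
                f"interaction_approach must be one of {INTERACTION_APPROACHES}"
            )
        if self.count_input_mode not in COUNT_INPUT_MODES:
            raise ValidationError(
                f"count_input_mode must be one of {COUNT_INPUT_MODES}"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
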
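"""Empirical detection threshold and the three filtering workflows."""

import numpy as np
import pandas as pd
import pytest

from countbench import AnalysisConfig, CountMatrix, ValidationError
from countbench.containers import FeatureTable
from countbench.normalization import deseq_size_factors
from countbench.thresholds import (
    ThresholdResult,
    apply_workflow,
    empirical_threshold,
    filter_low_expression,
    filter_noncoding,
)


def _mini_matrices(inter_counts, genic_counts=None):
    if genic_counts is None:
        genic_counts = [10, 100, 1000]
    genic = CountMatrix(
        pd.DataFrame({"s1": genic_counts},
                     index=[f"g{i}" for i in range(len(genic_counts))])
    )
    inter = CountMatrix(
        pd.DataFrame({"s1": inter_counts},
                     index=[f"i{i}" for i in range(len(inter_counts))]),
        genic.library_sizes,
    )
    return genic, inter


class TestEmpiricalThreshold:
    def test_order_statistic_interpolation(self):
        # intergenic log2(x+1) values exactly 1..20 -> type-7 95th pct = 19.05
        counts = (2.0 ** np.arange(1, 21) - 1).astype(int)
        genic, inter = _mini_matrices(counts)
        res = empirical_threshold(genic, inter, "RC", 95)
        assert res.threshold == pytest.approx(19.05, abs=1e-12)

    def test_all_zero_intergenic_gives_zero(self):
        genic, inter = _mini_matrices([0, 0, 0, 0])
        res = empirical_threshold(genic, inter, "RC", 95)
        assert res.threshold == 0.0

    def test_monotone_in_percentile(self, rng):
        counts = rng.integers(0, 50, 30)
        genic, inter = _mini_matrices(counts)
        thr = [
            empirical_threshold(genic, inter, "RC", p).threshold
            for p in (50, 75, 90, 95, 99)
        ]
        assert all(b >= a for a, b in zip(thr, thr[1:]))

    def test_sample_permutation_invariant(self, small_study):
        _, cm, features, _, _ = small_study
        genic = CountMatrix(
            cm.counts.loc[features.genic_ids().intersection(cm.gene_ids)],
            cm.library_sizes,
        )
        inter = CountMatrix(
            cm.counts.loc[features.intergenic_ids(False).intersection(cm.gene_ids)],
            cm.library_sizes,
        )
        t1 = empirical_threshold(genic, inter, "TC", 95, features).threshold
        perm = list(cm.sample_ids[::-1])
        genic_p = genic.subset_samples(perm)
        inter_p = inter.subset_samples(perm)
        t2 = empirical_threshold(genic_p, inter_p, "TC", 95, features).threshold
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_short_intergenic_features_excluded(self, small_study):
        _, cm, features, _, _ = small_study
        short = features.table[
            (features.table["region_class"] == "intergenic")
            & (~features.table["intergenic_valid"])
        ]
        assert len(short) > 0  # the generator produces sub-read-length regions
        genic = CountMatrix(
            cm.counts.loc[features.genic_ids().intersection(cm.gene_ids)],
            cm.library_sizes,
        )
        inter = CountMatrix(
            cm.counts.loc[features.intergenic_ids(False).intersection(cm.gene_ids)],
            cm.library_sizes,
        )
        res = empirical_threshold(genic, inter, "RC", 95, features)
        assert res.n_intergenic == len(features.intergenic_ids(valid_only=True))

    def test_no_intergenic_rejected(self):
        genic, inter = _mini_matrices([1])
        empty = CountMatrix(inter.counts.iloc[:0], genic.library_sizes)
        with pytest.raises(ValidationError):
            empirical_threshold(genic, empty, "RC", 95)


class TestFilter:
    def _norm(self, values):
        df = pd.DataFrame(values, dtype=float)
        df.index = [f"g{i}" for i in range(len(df))]
        from countbench.normalization import NormalizedMatrix

        return NormalizedMatrix(df, "RC", None)

    def test_single_high_sample_retains_gene(self):
        norm = self._norm({"s1": [0.0] * 2, "s2": [100.0, 0.0]})
        thr = ThresholdResult("RC", 3.0, 95, 10)
        kept, removed = filter_low_expression(norm, thr)
        assert "g0" in kept.values.index  # above threshold in one sample only
        assert "g1" in removed

    def test_zero_threshold_removes_nothing(self):
        norm = self._norm({"s1": [0.0, 5.0]})
        thr = ThresholdResult("RC", 0.0, 95, 10)
        kept, removed = filter_low_expression(norm, thr)
        assert len(removed) == 0 and len(kept.values) == 2

    def test_idempotent(self, small_study):
        _, cm, features, design, _ = small_study
        cfg = AnalysisConfig(normalization_method="TC", workflow=1)
        wf = apply_workflow(cm, features, design, cfg)
        again, removed2 = filter_low_expression(wf.matrix, wf.threshold)
        assert len(removed2) == 0
        assert again.values.shape == wf.matrix.values.shape

    def test_scale_mismatch_rejected(self):
        norm = self._norm({"s1": [1.0]})
        thr = ThresholdResult("DESeq", 1.0, 95, 5)
        with pytest.raises(ValidationError, match="scale mismatch"):
            filter_low_expression(norm, thr)


class TestFilterNoncoding:
    def test_removes_noncoding_rows(self, small_study):
        _, cm, features, _, truth = small_study
        mat = cm.counts.loc[features.genic_ids().intersection(cm.gene_ids)]
        kept, removed = filter_noncoding(mat, features)
        assert set(removed) == set(mat.index.difference(features.coding_ids()))
        assert truth.spikein_ids[0] in removed

    def test_all_coding_is_identity(self):
        ft = FeatureTable(
            pd.DataFrame(
                {
                    "chrom": "c", "start": [0, 100], "end": [50, 200],
                    "strand": "+", "region_class": "genic",
                    "coding_class": "protein_coding",
                },
                index=["a", "b"],
            )
        )
        mat = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        kept, removed = filter_noncoding(mat, ft)
        assert len(removed) == 0 and kept.equals(mat)

    def test_refit_size_factors_change_after_removal(self, small_study):
        _, cm, features, _, _ = small_study
        genic = CountMatrix(
            cm.counts.loc[features.genic_ids().intersection(cm.gene_ids)],
            cm.library_sizes,
        )
        s_full = deseq_size_factors(genic).factors
        kept, _ = filter_noncoding(genic.counts, features)
        s_red = deseq_size_factors(CountMatrix(kept, cm.library_sizes)).factors
        assert not np.allclose(s_full, s_red)


class TestWorkflows:
    def test_workflow3_keeps_all_genes(self, small_study):
        _, cm, features, design, _ = small_study
        cfg = AnalysisConfig(normalization_method="DESeq", workflow=3)
        wf = apply_workflow(cm, features, design, cfg)
        assert len(wf.matrix.values) == len(
            features.genic_ids().intersection(cm.gene_ids)
        )
        assert wf.threshold is None

    def test_filter_noop_makes_workflows_agree(self):
        # genic counts far above the background: nothing is removed and the
        # three workflows deliver the same DE input (TC factors frozen)
        rng = np.random.default_rng(8)
        genic = rng.integers(500, 2000, size=(30, 6))
        inter = rng.integers(0, 2, size=(10, 6))
        ids = [f"g{i}" for i in range(30)] + [f"i{i}" for i in range(10)]
        counts = CountMatrix(
            pd.DataFrame(
                np.vstack([genic, inter]), index=ids,
                columns=[f"s{j}" for j in range(6)],
            )
        )
        feats = FeatureTable(
            pd.DataFrame(
                {
                    "chrom": "c",
                    "start": np.arange(40) * 1000,
                    "end": np.arange(40) * 1000 + 500,
                    "strand": "+",
                    "region_class": ["genic"] * 30 + ["intergenic"] * 10,
                    "coding_class": "protein_coding",
                },
                index=ids,
            )
        )
        import countbench

        design = countbench.SampleDesign(
            pd.DataFrame(
                {
                    "genotype": ["a", "a", "a", "b", "b", "b"],
                    "environment": ["x"] * 6,
                    "sex": ["M", "F"] * 3,
                },
                index=[f"s{j}" for j in range(6)],
            )
        )
        outs = {}
        for w in (1, 2, 3):
            cfg = AnalysisConfig(normalization_method="TC", workflow=w)
            outs[w] = apply_workflow(counts, feats, design, cfg).matrix.values
        pd.testing.assert_frame_equal(outs[1], outs[2])
        pd.testing.assert_frame_equal(outs[1], outs[3])

    def test_med_workflows_differ_tc_identical(self, small_study):
        """Removal changes median factors but not frozen total-count factors."""
        _, cm, features, design, _ = small_study
        mats = {}
        for method in ("TC", "Med"):
            for w in (1, 2):
                cfg = AnalysisConfig(normalization_method=method, workflow=w)
                wf = apply_workflow(cm, features, design, cfg)
                mats[(method, w)] = wf.matrix.values
        assert len(mats[("Med", 1)]) == len(mats[("Med", 2)])
        pd.testing.assert_frame_equal(mats[("TC", 1)], mats[("TC", 2)])
        assert not np.allclose(mats[("Med", 1)], mats[("Med", 2)])

    def test_workflow1_estimation_matrix_is_unfiltered(self, small_study):
        _, cm, features, design, _ = small_study
        cfg = AnalysisConfig(normalization_method="DESeq", workflow=1)
        wf = apply_workflow(cm, features, design, cfg)
        assert len(wf.estimation_matrix.values) > len(wf.matrix.values)
        assert len(wf.removed_genes) > 0
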
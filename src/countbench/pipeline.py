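"""End-to-end pipeline: workflow -> dispersion -> DE per term -> reports."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .containers import (
    AnalysisConfig,
    CountMatrix,
    FeatureTable,
    SampleDesign,
    ValidationError,
)
from .diffexpr import test_terms
from .nbglm import estimate_dispersions
from .thresholds import apply_workflow

logger = logging.getLogger("countbench")

__all__ = ["run_de_for_config", "run_pipeline"]


def _write_power_report(wf, design, config, out) -> None:
    """Detectable fold-change curve at the data's own ln-scale error variance."""
    from .power import PowerSpec, power_curve

    values = wf.matrix.values
    t = design.table.loc[values.columns]
    Y = np.log(values.to_numpy(float) + 1.0)
    ss = np.zeros(Y.shape[0])
    df = 0
    for idx in t.groupby(["genotype", "environment", "sex"]).indices.values():
        block = Y[:, list(idx)]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    if df == 0:
        return
    expressed = values.mean(axis=1).to_numpy() >= 10
    if not expressed.any():
        expressed = np.ones(len(ss), bool)
    sigma2 = float(np.median(ss[expressed] / df))
    a, b, c = design.subset(values.columns).n_levels
    try:
        spec = PowerSpec(a=a, b=b, c=c, alpha=config.fdr_level)
        curve = power_curve(range(2, 9), 0.8, sigma2, spec)
    except Exception:  # degenerate designs have no power curve
        return
    curve.insert(0, "sigma2", sigma2)
    curve.to_csv(out / "power_curve.tsv", sep="\t")


def run_de_for_config(
    counts: CountMatrix,
    features: FeatureTable,
    design: SampleDesign,
    config: AnalysisConfig,
    terms=None,
):
    """Workflow + dispersion + per-term NB-GLM tests for one configuration.

    Returns (WorkflowResult, DispersionEstimates, {term: DETable}).  In
    ``rounded`` mode the engine sees normalized counts rounded half-to-even;
    in ``offset`` mode it sees raw counts with ln scaling-factor offsets
    (only for methods that reduce to a per-sample factor).
    """
    wf = apply_workflow(counts, features, design, config)
    design_sub = design.subset(wf.matrix.values.columns)
    est = wf.estimation_matrix if wf.estimation_matrix is not None else wf.matrix
    if config.count_input_mode == "rounded":
        matrix = wf.matrix.rounded_view
        disp = estimate_dispersions(
            est.rounded_view, design_sub, mode=config.dispersion_mode
        )
        offsets = None
    else:
        offsets = wf.matrix.log_offsets().to_numpy()
        matrix = counts.counts.loc[wf.matrix.values.index, wf.matrix.values.columns]
        # dispersion from scale-adjusted values so library-size spread does
        # not masquerade as biological overdispersion
        disp = estimate_dispersions(
            est.values, design_sub, mode=config.dispersion_mode
        )
    tables = test_terms(
        matrix,
        design_sub,
        approach=config.interaction_approach,
        dispersions=disp,
        offsets=offsets,
        fdr_level=config.fdr_level,
        terms=terms,
    )
    return wf, disp, tables


def run_pipeline(
    config: AnalysisConfig,
    counts: CountMatrix,
    features: FeatureTable,
    design: SampleDesign,
    out_dir,
) -> dict:
    """Run the full analysis and write results under ``out_dir``.

    Writes the normalized matrix, a threshold report, one DE table per model
    term and a JSON manifest recording the configuration.  Any stage failure
    aborts with the stage name in the error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        design.check_samples(counts.sample_ids)
        stage = "workflow"
        wf, disp, tables = run_de_for_config(counts, features, design, config)
        stage = "write"
        cio.write_table(wf.matrix.values, out / "normalized.tsv")
        thr_rows = {
            "method": config.normalization_method,
            "workflow": config.workflow,
            "threshold_log2": wf.threshold.threshold if wf.threshold else np.nan,
            "percentile": wf.threshold.percentile if wf.threshold else np.nan,
            "n_intergenic": wf.threshold.n_intergenic if wf.threshold else 0,
            "n_genes_removed": len(wf.removed_genes),
        }
        pd.DataFrame([thr_rows]).to_csv(out / "threshold.tsv", sep="\t", index=False)
        disp_df = pd.DataFrame(
            {"raw": disp.raw, "fitted": disp.fitted, "phi": disp.phi, "mean": disp.mean}
        )
        cio.write_table(disp_df, out / "dispersions.tsv")
        for term, tab in tables.items():
            cio.write_table(tab, out / f"de_{term.replace(':', 'x')}.tsv")
        stage = "power"
        _write_power_report(wf, design, config, out)
        cio.write_manifest(
            out / "manifest.json",
            config.to_dict(),
            {
                "n_genes_input": int(counts.n_genes),
                "n_genes_tested": int(len(wf.matrix.values)),
                "n_samples": int(counts.n_samples),
                "terms": list(tables),
            },
        )
    except Exception as exc:
        raise ValidationError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete: %s", out)
    return {"workflow": wf, "dispersions": disp, "tables": tables, "out_dir": out}
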
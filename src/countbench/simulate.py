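"""Synthetic data generator emulating a large multi-factor fly RNA-seq study.

The generator produces everything the pipeline consumes without any external
download: overdispersed NB counts under a genotype x environment x sex
factorial design with known differentially expressed gene sets per model
term, a heavy-tailed baseline expression distribution (a small set of genes
carries a large share of reads, as in real fly libraries), low-rate
intergenic background features for threshold derivation, spike-in control
rows whose means are independent of the biology, duplicate libraries for a
subset of individuals sharing biological but not technical noise, and an
informative-SNP base-call matrix for genotype verification.

Counts are drawn as a gamma-Poisson mixture: each fly's biological intensity
t ~ Gamma(1/phi, mu*phi) and its library's counts ~ Poisson(s_k * t), which
realizes the NB mean-variance law sigma^2 = mu + mu^2 * phi and lets
duplicate libraries of the same fly share t while resampling only the
Poisson (technical) layer.

One global seed feeds independent per-component streams (counts, SNPs,
effect assignment) so stages are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GENIC,
    INTERGENIC,
    NON_CODING,
    PROTEIN_CODING,
    CountMatrix,
    FeatureTable,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_snp_data",
]

TERMS = ("G", "E", "S", "G:E", "G:S", "E:S", "G:E:S")


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the emulated design: 16 genotypes x 3 environments x
    2 sexes with up to 8 flies per cell, 32 spike-in controls, 76 bp reads,
    log-normal baseline expression with a heavy right tail, log-normal
    per-gene dispersions, and modest library-size spread.  Effect sizes are
    ln-scale ranges (max minus min over the term's levels).
    """

    n_genes: int = 2000
    n_intergenic: int = 400
    a: int = 16  # genotypes
    b: int = 3  # environments
    c: int = 2  # sexes
    n_per_cell: int = 8
    baseline_log_mean: float = 3.0  # ln scale
    baseline_log_sd: float = 1.8  # heavy tail: a few genes dominate reads
    low_expression_fraction: float = 0.2  # genes expressed near background
    low_log_mean: float = 0.0
    low_log_sd: float = 1.0
    dispersion_meanlog: float = float(np.log(0.15))
    dispersion_sdlog: float = 0.6
    de_fractions: dict = field(
        default_factory=lambda: {
            "G": 0.20,
            "E": 0.15,
            "S": 0.30,
            "G:E": 0.05,
            "G:S": 0.05,
            "E:S": 0.05,
            "G:E:S": 0.05,
        }
    )
    effect_sizes: dict = field(
        default_factory=lambda: {
            "G": 1.0,
            "E": 1.0,
            "S": 2.0,
            "G:E": 1.0,
            "G:S": 1.0,
            "E:S": 1.0,
            "G:E:S": 1.0,
        }
    )
    libsize_sdlog: float = 0.25
    n_spikeins: int = 32
    duplicate_library_fraction: float = 0.05
    noncoding_fraction: float = 0.05
    intergenic_rate_scale: float = 1.0
    read_length: int = 76
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_cell < 1:
            raise ValidationError("degenerate config: need genes and replicates")
        if min(self.a, self.b, self.c) < 2:
            raise ValidationError("each factor needs at least 2 levels")
        for t, f in self.de_fractions.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"DE fraction for {t} outside [0, 1]")
        for t, e in self.effect_sizes.items():
            if not np.isfinite(e):
                raise ValidationError(f"effect size for {t} not finite")


@dataclass
class SyntheticTruth:
    de_genes: dict[str, pd.Index]
    size_factors: pd.Series
    dispersions: pd.Series
    cell_means: np.ndarray  # genes x a x b x c, ln scale
    identities: pd.DataFrame  # per-sample true genotype / sex
    spikein_ids: pd.Index
    effects: dict[str, np.ndarray]  # per-term per-gene effect arrays


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _project_interaction(arr: np.ndarray) -> np.ndarray:
    """Remove all lower-order margins, leaving a pure interaction pattern."""
    out = arr.copy()
    ndim = out.ndim
    if ndim == 1:
        return out - out.mean()
    # iterative double/triple centering: subtract means over each axis
    for _ in range(50):
        before = out.copy()
        for ax in range(ndim):
            out = out - out.mean(axis=ax, keepdims=True)
        if np.abs(out - before).max() < 1e-14:
            break
    return out


def _term_effect(term: str, size: float, a: int, b: int, c: int, rng) -> np.ndarray:
    """Random ln-scale effect pattern for one term, range max-min = size.

    Half the levels (or cells) get +size/2 and half -size/2, centred and,
    for interactions, projected onto the pure-interaction subspace, then
    rescaled so the realized range equals the requested effect size.
    """
    dims = {"G": a, "E": b, "S": c}
    shape = tuple(dims[f] for f in term.split(":"))
    if size == 0:
        return np.zeros(shape)
    n = int(np.prod(shape))
    signs = np.full(n, -0.5)
    signs[rng.permutation(n)[: n // 2]] = 0.5
    eff = _project_interaction(signs.reshape(shape) * size)
    span = eff.max() - eff.min()
    if span <= 1e-12 * size:
        # degenerate draw (pattern was purely additive): use a tensor-product
        # contrast, which is a pure interaction with nonzero range
        vecs = []
        for dim in shape:
            v = np.zeros(dim)
            v[0], v[1] = 0.5, -0.5
            vecs.append(v)
        eff = vecs[0]
        for v in vecs[1:]:
            eff = np.multiply.outer(eff, v)
        span = eff.max() - eff.min()
    return eff * (size / span)


def _expand(term: str, eff: np.ndarray, a: int, b: int, c: int) -> np.ndarray:
    """Broadcast a term's effect array to the full (a, b, c) grid."""
    axes = {"G": 0, "E": 1, "S": 2}
    idx = [None, None, None]
    for axn, f in enumerate(term.split(":")):
        idx[axes[f]] = axn
    # build einsum-like expansion
    full = np.zeros((a, b, c))
    it = np.ndindex(a, b, c)
    sub_axes = [axes[f] for f in term.split(":")]
    for pos in it:
        key = tuple(pos[ax] for ax in sub_axes)
        full[pos] = eff[key]
    return full


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, FeatureTable, SampleDesign, SyntheticTruth]:
    """Generate counts, annotation, design and ground truth for one study."""
    cfg = config
    rngs = _streams(cfg.rng_seed, ("effects", "counts", "library", "features"))
    a, b, c, n = cfg.a, cfg.b, cfg.c, cfg.n_per_cell
    genotypes = [f"G{i + 1:02d}" for i in range(a)]
    envs = [f"E{j + 1}" for j in range(b)]
    sexes = ["F", "M"][:c] if c == 2 else [f"S{k + 1}" for k in range(c)]

    # --- design ----------------------------------------------------------
    rows = []
    for g in genotypes:
        for e in envs:
            for s in sexes:
                for r in range(1, n + 1):
                    sid = f"{g}_{e}_{s}_r{r}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "genotype": g,
                            "environment": e,
                            "sex": s,
                            "replicate": r,
                            "individual": sid,
                            "library_id": sid + "_L1",
                        }
                    )
    base_design = pd.DataFrame(rows).set_index("sample_id")

    # --- gene-level parameters -------------------------------------------
    er = rngs["effects"]
    gene_ids = pd.Index([f"gene{i + 1:05d}" for i in range(cfg.n_genes)])
    beta0 = er.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    n_low = int(round(cfg.low_expression_fraction * cfg.n_genes))
    if n_low:
        low_idx = er.permutation(cfg.n_genes)[:n_low]
        beta0[low_idx] = er.normal(cfg.low_log_mean, cfg.low_log_sd, n_low)
    phi = np.exp(er.normal(cfg.dispersion_meanlog, cfg.dispersion_sdlog, cfg.n_genes))

    cell_means = np.tile(beta0[:, None, None, None], (1, a, b, c))
    de_sets: dict[str, pd.Index] = {}
    effects: dict[str, np.ndarray] = {}
    for term in TERMS:
        frac = cfg.de_fractions.get(term, 0.0)
        size = cfg.effect_sizes.get(term, 0.0)
        n_de = int(round(frac * cfg.n_genes))
        chosen = er.permutation(cfg.n_genes)[:n_de]
        de_sets[term] = gene_ids[np.sort(chosen)]
        term_eff = np.zeros((cfg.n_genes,) + tuple(
            {"G": a, "E": b, "S": c}[f] for f in term.split(":")
        ))
        for gi in chosen:
            eff = _term_effect(term, size, a, b, c, er)
            term_eff[gi] = eff
            cell_means[gi] += _expand(term, eff, a, b, c)
        effects[term] = term_eff

    # --- library factors and biological intensities ----------------------
    lr = rngs["library"]
    size_factors = pd.Series(
        np.exp(lr.normal(0.0, cfg.libsize_sdlog, len(base_design))),
        index=base_design.index,
    )

    cr = rngs["counts"]
    gidx = {g: i for i, g in enumerate(genotypes)}
    eidx = {e: j for j, e in enumerate(envs)}
    sidx = {s: k for k, s in enumerate(sexes)}
    mu = np.empty((cfg.n_genes, len(base_design)))
    for col, (sid, row) in enumerate(base_design.iterrows()):
        mu[:, col] = np.exp(
            cell_means[:, gidx[row["genotype"]], eidx[row["environment"]], sidx[row["sex"]]]
        )
    # biological intensity per fly: Gamma(1/phi, mu*phi); Poisson floor at phi=0
    shape = 1.0 / phi
    intensity = np.where(
        phi[:, None] > 0,
        cr.gamma(np.broadcast_to(shape[:, None], mu.shape), mu * phi[:, None]),
        mu,
    )

    # spike-ins: biology-independent means
    spike_ids = pd.Index([f"ERCC-{i + 1:04d}" for i in range(cfg.n_spikeins)])
    spike_mean = np.exp(er.normal(3.0, 1.0, cfg.n_spikeins))
    spike_intensity = np.tile(spike_mean[:, None], (1, len(base_design)))

    # intergenic background: per-kb Poisson rate, reads accrue with length
    fr = rngs["features"]
    inter_ids = pd.Index([f"intergenic{i + 1:05d}" for i in range(cfg.n_intergenic)])
    inter_len = np.maximum(20, fr.exponential(500.0, cfg.n_intergenic).astype(int))
    inter_per_kb = fr.exponential(cfg.intergenic_rate_scale, cfg.n_intergenic)
    inter_rate = inter_per_kb * inter_len / 1000.0
    inter_intensity = np.tile(inter_rate[:, None], (1, len(base_design)))

    all_ids = gene_ids.append(spike_ids).append(inter_ids)
    lam = (
        np.vstack([intensity, spike_intensity, inter_intensity])
        * size_factors.to_numpy()[None, :]
    )
    counts = cr.poisson(lam)

    # duplicate libraries: same biological intensity, fresh Poisson draw
    n_dup = int(round(cfg.duplicate_library_fraction * len(base_design)))
    dup_samples = (
        base_design.index[np.sort(lr.permutation(len(base_design))[:n_dup])]
        if n_dup
        else pd.Index([])
    )
    dup_cols, dup_rows = [], []
    for sid in dup_samples:
        col = base_design.index.get_loc(sid)
        s2 = float(np.exp(lr.normal(0.0, cfg.libsize_sdlog)))
        lam2 = (
            np.concatenate(
                [intensity[:, col], spike_intensity[:, col], inter_intensity[:, col]]
            )
            * s2
        )
        dup_cols.append(cr.poisson(lam2))
        row = base_design.loc[sid].copy()
        row["library_id"] = sid + "_L2"
        row.name = sid + "_dup"
        dup_rows.append(row)
        size_factors[sid + "_dup"] = s2
    if dup_rows:
        design_df = pd.concat([base_design, pd.DataFrame(dup_rows)])
        counts = np.column_stack([counts] + dup_cols)
    else:
        design_df = base_design

    count_df = pd.DataFrame(counts, index=all_ids, columns=design_df.index)
    # library sizes frozen as genic column sums (total mapped genic reads)
    lib_sizes = count_df.loc[gene_ids.append(spike_ids)].sum(axis=0)
    lib_sizes = lib_sizes.clip(lower=1)
    cm = CountMatrix(count_df, lib_sizes)

    # --- annotation -------------------------------------------------------
    n_nc = int(round(cfg.noncoding_fraction * cfg.n_genes))
    nc_mask = np.zeros(cfg.n_genes, bool)
    nc_mask[fr.permutation(cfg.n_genes)[:n_nc]] = True
    gene_len = np.maximum(
        200, np.exp(fr.normal(7.3, 0.6, cfg.n_genes)).astype(int)
    )
    spike_len = np.full(cfg.n_spikeins, 1000)

    feats = []
    pos = 0
    for fid, ln, region, coding in (
        list(zip(gene_ids, gene_len, [GENIC] * cfg.n_genes,
                 np.where(nc_mask, NON_CODING, PROTEIN_CODING)))
        + list(zip(spike_ids, spike_len, [GENIC] * cfg.n_spikeins,
                   [NON_CODING] * cfg.n_spikeins))
        + list(zip(inter_ids, inter_len, [INTERGENIC] * cfg.n_intergenic,
                   [NON_CODING] * cfg.n_intergenic))
    ):
        feats.append(
            {
                "feature_id": fid,
                "chrom": "chr2L",
                "start": pos,
                "end": pos + int(ln),
                "strand": "+",
                "region_class": region,
                "coding_class": coding,
            }
        )
        pos += int(ln) + 100
    features = FeatureTable(
        pd.DataFrame(feats).set_index("feature_id"), read_length=cfg.read_length
    )

    identities = design_df[["genotype", "sex"]].copy()
    truth = SyntheticTruth(
        de_genes=de_sets,
        size_factors=size_factors.reindex(design_df.index),
        dispersions=pd.Series(phi, index=gene_ids),
        cell_means=cell_means,
        identities=identities,
        spikein_ids=spike_ids,
        effects=effects,
    )
    return cm, features, SampleDesign(design_df), truth


def simulate_snp_data(
    a_lines: int = 16,
    n_sites: int = 1000,
    n_samples: int = 100,
    error_rate: float = 0.05,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Informative-SNP base calls for samples of known line origin.

    Each sample's calls equal its true line's alleles with independent flips
    (to a different base) at ``error_rate`` and dropouts at ``missing_rate``.
    Returns (calls sites x samples, line table sites x lines, true lines).
    """
    if a_lines < 2:
        raise ValidationError("need at least two lines")
    if not 0 <= error_rate < 0.5:
        raise ValidationError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    bases = np.array(list("ACGT"))
    sites = pd.Index([f"site{i + 1:06d}" for i in range(n_sites)])
    lines = pd.Index([f"L{j + 1:02d}" for j in range(a_lines)])
    # informative sites: ensure not all lines share one allele
    alleles = bases[rng.integers(0, 4, size=(n_sites, a_lines))]
    uniform = (alleles == alleles[:, [0]]).all(axis=1)
    for i in np.flatnonzero(uniform):
        j = rng.integers(1, a_lines)
        cur = alleles[i, j]
        alleles[i, j] = bases[(np.flatnonzero(bases == cur)[0] + 1) % 4]
    line_table = pd.DataFrame(alleles, index=sites, columns=lines)

    true_line = pd.Series(
        lines[rng.integers(0, a_lines, n_samples)],
        index=[f"sample{i + 1:04d}" for i in range(n_samples)],
    )
    calls = np.empty((n_sites, n_samples), dtype="U1")
    for k, (sid, lj) in enumerate(true_line.items()):
        truth_alleles = line_table[lj].to_numpy()
        out = truth_alleles.copy()
        flips = rng.random(n_sites) < error_rate
        if flips.any():
            shift = rng.integers(1, 4, flips.sum())
            cur_idx = np.searchsorted(bases, out[flips])
            out[flips] = bases[(cur_idx + shift) % 4]
        out[rng.random(n_sites) < missing_rate] = "N"
        calls[:, k] = out
    calls_df = pd.DataFrame(calls, index=sites, columns=true_line.index)
    return calls_df, line_table, true_line
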
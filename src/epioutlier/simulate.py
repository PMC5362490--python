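"""Synthetic tumor/normal cohorts with planted epigenetically silenced genes.

The generator emulates the data model of a paired expression + promoter
methylation case/control study of a heterogeneous carcinoma: 44 tumors and
25 normal tissues by default, log2 expression with gene-specific baselines
and noise, promoter beta values near a low baseline, and two kinds of
planted alterations that affect only a random subset of tumors per gene:

* silenced genes — expression loss coupled with promoter hypermethylation
  in the same affected tumors, through a shared per-sample latent intensity
  (so expression and beta are negatively correlated by construction);
* up-outlier genes — expression gain with methylation untouched
  (methylation-independent alterations).

Matching probe-level tables, M/U intensities, bisulfite chromatogram
traces, triplicate qPCR Ct values and clinical covariates are generated so
every pipeline stage can be exercised against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, MethylationMatrix, ProbeTable,
                 SampleAnnotation, TUMOR, NORMAL)
from .validation import BisulfiteTrace, QpcrMeasurement

N_CPG_SITES = 5
QPCR_REFERENCE_CT = 20.0   # housekeeping gene mean Ct
QPCR_TARGET_OFFSET = 40.0  # Ct = offset - log2 expression (one cycle per log2 unit)


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    Defaults mirror the discovery-study design: 44 tumors / 25 normals,
    5,000 genes with 1-4 probes each, 50 silenced and 50 upregulated
    planted genes each altered in 30% of tumors, a 2.0 log2-unit expression
    effect, promoter betas near 0.10 rising by ~0.5 when silenced, and
    gene-specific Gaussian noise with sd drawn from 0.2-0.6.
    """

    n_tumor: int = 44
    n_normal: int = 25
    n_genes: int = 5000
    probes_per_gene: tuple[int, int] = (1, 4)
    n_silenced: int = 50
    n_up_outlier: int = 50
    affected_fraction: float = 0.3
    expr_effect: float = 2.0
    beta_base: float = 0.10
    beta_effect: float = 0.5
    noise_sd: tuple[float, float] = (0.2, 0.6)
    n_pathway: int = 0                # genes co-shifted in the lead gene's affected tumors
    pathway_effect: float = 1.0       # log2 shift of the planted pathway set
    noise_dist: str = "gaussian"      # or "t5" (heavy-tailed, 5 df)
    coupling_sd: float = 0.15         # spread of the shared latent intensity
    meth_coverage: float = 0.7        # fraction of background genes with promoter probes
    covariate_odds_ratio: float = 1.0 # hpv association with the lead gene's affected set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_silenced + self.n_up_outlier + self.n_pathway > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if not (0 < self.affected_fraction <= 1):
            raise ValueError("affected_fraction must be in (0, 1]")
        if self.n_normal < 2 or self.n_tumor < 1:
            raise ValueError("need >= 1 tumor and >= 2 normals")
        if self.noise_dist not in ("gaussian", "t5"):
            raise ValueError(f"unknown noise_dist {self.noise_dist!r}")
        if not (0 <= self.meth_coverage <= 1):
            raise ValueError("meth_coverage must be in [0, 1]")


@dataclass
class GroundTruth:
    silenced_genes: list[str]
    up_outlier_genes: list[str]
    affected_samples: dict[str, list[str]]
    effects: dict[str, tuple[float, float]]  # gene -> (delta_expr, delta_beta)
    pathway_genes: list[str] = field(default_factory=list)
    pathway_samples: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    expression_probes: ProbeTable
    methylation: MethylationMatrix
    methylation_probes: ProbeTable          # intensities carry M/U
    annotation: SampleAnnotation
    truth: GroundTruth
    config: SimConfig


def _noise(rng: np.random.Generator, sd, shape, dist: str) -> np.ndarray:
    if dist == "t5":
        raw = rng.standard_t(5, size=shape) / np.sqrt(5.0 / 3.0)  # unit variance
    else:
        raw = rng.standard_normal(shape)
    return raw * sd


def simulate_cohort(cfg: SimConfig = SimConfig()) -> SyntheticCohort:
    """Generate a cohort; deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_tumor + cfg.n_normal
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = ([f"T{i:03d}" for i in range(cfg.n_tumor)] +
                  [f"N{i:03d}" for i in range(cfg.n_normal)])
    classes = pd.Series([TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal,
                        index=sample_ids, name="class")

    planted = rng.choice(cfg.n_genes,
                         cfg.n_silenced + cfg.n_up_outlier + cfg.n_pathway,
                         replace=False)
    silenced_idx = planted[:cfg.n_silenced]
    up_idx = planted[cfg.n_silenced:cfg.n_silenced + cfg.n_up_outlier]
    pathway_idx = planted[cfg.n_silenced + cfg.n_up_outlier:]
    silenced = [gene_ids[i] for i in silenced_idx]
    up_outlier = [gene_ids[i] for i in up_idx]
    pathway_genes = [gene_ids[i] for i in pathway_idx]

    # expression: gene baseline + gene-specific noise
    mu = rng.uniform(4.0, 12.0, cfg.n_genes)
    sd = rng.uniform(cfg.noise_sd[0], cfg.noise_sd[1], cfg.n_genes)
    X = mu[:, None] + _noise(rng, sd[:, None], (cfg.n_genes, n_samples), cfg.noise_dist)

    # promoter betas: low baseline everywhere (silenced genes get lifted below)
    beta = np.clip(rng.normal(cfg.beta_base, 0.04, (cfg.n_genes, n_samples)), 0.005, 0.995)

    n_aff = max(1, round(cfg.affected_fraction * cfg.n_tumor))
    affected: dict[str, list[str]] = {}
    effects: dict[str, tuple[float, float]] = {}

    for gi in silenced_idx:
        aff = np.sort(rng.choice(cfg.n_tumor, n_aff, replace=False))
        latent = np.clip(rng.normal(1.0, cfg.coupling_sd, n_aff), 0.3, None)
        X[gi, aff] -= cfg.expr_effect * latent
        b = cfg.beta_base + cfg.beta_effect * latent + rng.normal(0, 0.05, n_aff)
        beta[gi, aff] = np.clip(b, 0.005, 0.995)
        gene = gene_ids[gi]
        affected[gene] = [sample_ids[s] for s in aff]
        effects[gene] = (-cfg.expr_effect, cfg.beta_effect)

    for gi in up_idx:
        aff = np.sort(rng.choice(cfg.n_tumor, n_aff, replace=False))
        latent = np.clip(rng.normal(1.0, cfg.coupling_sd, n_aff), 0.3, None)
        X[gi, aff] += cfg.expr_effect * latent
        gene = gene_ids[gi]
        affected[gene] = [sample_ids[s] for s in aff]
        effects[gene] = (cfg.expr_effect, 0.0)

    # planted pathway: genes co-shifted in the lead silenced gene's affected
    # tumors (or a fresh random tumor subset if nothing is silenced), so a
    # marker split on the lead gene separates the shifted samples
    pathway_samples: list[str] = []
    if cfg.n_pathway:
        if len(silenced_idx):
            shared_aff = [sample_ids.index(s) for s in affected[silenced[0]]]
        else:
            shared_aff = sorted(rng.choice(cfg.n_tumor, n_aff, replace=False))
        pathway_samples = [sample_ids[s] for s in shared_aff]
        for gi in pathway_idx:
            X[gi, shared_aff] += cfg.pathway_effect
            gene = gene_ids[gi]
            affected[gene] = list(pathway_samples)
            effects[gene] = (cfg.pathway_effect, 0.0)

    expr_df = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    expression = ExpressionMatrix(expr_df, classes)

    expression_probes = _expression_probes(rng, expr_df, cfg)
    methylation, methylation_probes = _methylation_tables(
        rng, beta, gene_ids, sample_ids, set(silenced_idx), cfg)

    annotation = _annotation(rng, classes, silenced, affected, cfg)
    truth = GroundTruth(silenced, up_outlier, affected, effects,
                        pathway_genes, pathway_samples)
    return SyntheticCohort(expression, expression_probes, methylation,
                           methylation_probes, annotation, truth, cfg)


def _expression_probes(rng, expr_df: pd.DataFrame, cfg: SimConfig) -> ProbeTable:
    lo, hi = cfg.probes_per_gene
    n_probes = rng.integers(lo, hi + 1, len(expr_df))
    rows, probe_ids, genes = [], [], []
    vals = expr_df.to_numpy()
    for gi, k in enumerate(n_probes):
        offsets = rng.normal(0, 0.3, k)
        for pi in range(k):
            rows.append(vals[gi] + offsets[pi] + rng.normal(0, 0.1, vals.shape[1]))
            probe_ids.append(f"{expr_df.index[gi]}_p{pi}")
            genes.append(expr_df.index[gi])
    values = pd.DataFrame(np.asarray(rows), index=probe_ids, columns=expr_df.columns)
    return ProbeTable(values, pd.Series(genes, index=probe_ids, name="gene_id"))


def _methylation_tables(rng, beta: np.ndarray, gene_ids, sample_ids,
                        silenced_idx: set, cfg: SimConfig):
    """Gene-level betas plus probe-level betas and M/U intensities.

    Each covered gene gets one signal probe carrying the gene's beta and
    0-2 background probes at lower methylation; silenced genes are always
    covered, background genes with probability ``meth_coverage``.
    """
    covered = [gi for gi in range(cfg.n_genes)
               if gi in silenced_idx or rng.random() < cfg.meth_coverage]
    rows, probe_ids, genes = [], [], []
    for gi in covered:
        n_extra = int(rng.integers(0, 3))
        rows.append(beta[gi])
        probe_ids.append(f"{gene_ids[gi]}_cg0")
        genes.append(gene_ids[gi])
        for pi in range(n_extra):
            bg = np.clip(beta[gi] * rng.uniform(0.2, 0.7) +
                         rng.normal(0, 0.02, beta.shape[1]), 0.001, 0.999)
            rows.append(bg)
            probe_ids.append(f"{gene_ids[gi]}_cg{pi + 1}")
            genes.append(gene_ids[gi])
    probe_beta = pd.DataFrame(np.asarray(rows), index=probe_ids, columns=sample_ids)
    total = rng.uniform(1000.0, 3000.0, probe_beta.shape)
    M = pd.DataFrame(probe_beta.to_numpy() * total, index=probe_ids, columns=sample_ids)
    U = pd.DataFrame((1.0 - probe_beta.to_numpy()) * total, index=probe_ids,
                     columns=sample_ids)
    probes = ProbeTable(probe_beta, pd.Series(genes, index=probe_ids, name="gene_id"),
                        intensities=(M, U))
    gene_beta = pd.DataFrame(beta[covered], index=[gene_ids[g] for g in covered],
                             columns=sample_ids)
    return MethylationMatrix(gene_beta), probes


def _annotation(rng, classes: pd.Series, silenced: list[str],
                affected: dict[str, list[str]], cfg: SimConfig) -> SampleAnnotation:
    n = len(classes)
    p_base = 0.30
    hpv_p = np.full(n, p_base)
    if silenced and cfg.covariate_odds_ratio != 1.0:
        lead_aff = set(affected[silenced[0]])
        odds = p_base / (1 - p_base) * cfg.covariate_odds_ratio
        p_assoc = odds / (1 + odds)
        hpv_p = np.where([s in lead_aff for s in classes.index], p_assoc, p_base)
    hpv = np.where(rng.random(n) < hpv_p, "pos", "neg")
    site = rng.choice(["oral_cavity", "oropharynx", "larynx"], size=n,
                      p=[0.40, 0.35, 0.25])
    table = pd.DataFrame({"class": classes, "hpv": hpv, "site": site},
                         index=classes.index)
    return SampleAnnotation(table)


# ---------------------------------------------------------------------------
# validation-arm readouts


def simulate_bisulfite(cohort: SyntheticCohort, genes, noise_sd: float = 0.05,
                       seed: int = 0) -> list[BisulfiteTrace]:
    """Bisulfite chromatogram traces: per sample/gene, 5 CpG sites whose C
    fraction is the gene's beta plus clipped Gaussian noise; peak heights
    scaled to 100."""
    rng = np.random.default_rng(seed)
    beta = cohort.methylation.beta
    traces = []
    for gene in genes:
        if gene not in beta.index:
            raise ValueError(f"unknown gene {gene!r} in methylation matrix")
        for sample in beta.columns:
            frac = np.clip(rng.normal(beta.loc[gene, sample], noise_sd, N_CPG_SITES),
                           0.0, 1.0)
            sites = tuple((float(100 * f), float(100 * (1 - f))) for f in frac)
            traces.append(BisulfiteTrace(sample, gene, sites))
    return traces


def simulate_qpcr(cohort: SyntheticCohort, genes, ct_noise: float = 0.2,
                  seed: int = 0) -> list[QpcrMeasurement]:
    """Triplicate qPCR Ct values: reference ~ Normal(20, noise) independent
    of class; target Ct = 40 - log2 expression + noise, so one log2
    expression unit corresponds to one cycle."""
    rng = np.random.default_rng(seed)
    expr = cohort.expression.values
    out = []
    for gene in genes:
        if gene not in expr.index:
            raise ValueError(f"unknown gene {gene!r} in expression matrix")
        for sample in expr.columns:
            ref = QPCR_REFERENCE_CT + _noise(rng, ct_noise, 3, "gaussian")
            tgt = (QPCR_TARGET_OFFSET - expr.loc[gene, sample]
                   + _noise(rng, ct_noise, 3, "gaussian"))
            out.append(QpcrMeasurement(sample, gene,
                                       tuple(float(v) for v in tgt),
                                       tuple(float(v) for v in ref)))
    return out


# ---------------------------------------------------------------------------
# on-disk fixture writing


def write_cohort(cohort: SyntheticCohort, out_dir,
                 bisulfite_genes=None, qpcr_genes=None,
                 bisulfite_noise: float = 0.05, ct_noise: float = 0.2) -> dict:
    """Write the cohort as plain TSV/JSON fixtures; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, df, index_label):
        p = out / name
        df.to_csv(p, sep="\t", index_label=index_label)
        paths[name] = str(p)

    save("expr.tsv", cohort.expression.values, "gene_id")
    probe_expr = cohort.expression_probes.values.copy()
    probe_expr.insert(0, "gene_id", cohort.expression_probes.gene_map)
    save("expr_probes.tsv", probe_expr, "probe_id")
    save("meth.tsv", cohort.methylation.beta, "gene_id")

    M, U = cohort.methylation_probes.intensities
    mu = pd.concat([M.add_suffix(".M"), U.add_suffix(".U")], axis=1)
    mu = mu[[c for s in M.columns for c in (f"{s}.M", f"{s}.U")]]
    mu.insert(0, "gene_id", cohort.methylation_probes.gene_map)
    save("mu.tsv", mu, "probe_id")

    save("samples.tsv", cohort.annotation.table, "sample_id")

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(asdict(cohort.truth), indent=1))
    paths["truth.json"] = str(truth_path)

    seed = cohort.config.seed
    if bisulfite_genes:
        traces = simulate_bisulfite(cohort, bisulfite_genes, bisulfite_noise, seed)
        rows = [{"sample_id": t.sample_id, "gene_id": t.gene_id, "site": i,
                 "c_height": c, "t_height": h}
                for t in traces for i, (c, h) in enumerate(t.cpg_sites)]
        p = out / "bisulfite.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths["bisulfite.tsv"] = str(p)
    if qpcr_genes:
        ms = simulate_qpcr(cohort, qpcr_genes, ct_noise, seed)
        rows = [{"sample_id": m.sample_id, "gene_id": m.gene_id,
                 **{f"ct_target_{i+1}": v for i, v in enumerate(m.ct_target)},
                 **{f"ct_ref_{i+1}": v for i, v in enumerate(m.ct_reference)}}
                for m in ms]
        p = out / "qpcr.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths["qpcr.tsv"] = str(p)
    return paths
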
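"""Stage orchestration: discovery -> integration, validation, pathway.

Each stage reads and writes plain delimited tables, so stages are
independently runnable and re-entrant (a validation-only cohort works
without the discovery inputs).  Every run emits a JSON :class:`RunReport`
whose counts are recomputed from the tables it wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from . import validation as val
from .integration import integrate_methylation, INTEGRATED_COLUMNS
from .outlier import OutlierParams, rank_outlier_candidates
from .pathway import bh_adjust, fit_moderated_t, gene_set_test, split_by_marker_gene

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    stage: str
    parameters: dict
    input_checksums: dict
    counts: dict
    outputs: dict
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _checksum(path) -> str:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:16]


def _checksums(paths: dict) -> dict:
    return {k: _checksum(v) for k, v in paths.items() if v and Path(v).exists()}


# ---------------------------------------------------------------------------
# discovery + integration


def run_discovery(expr_path, annot_path, out_dir, meth_path=None,
                  params: OutlierParams = OutlierParams(),
                  integration_samples: str = "all") -> RunReport:
    """Score genes, select candidates and (if methylation is available)
    attach expression-methylation correlations.

    Writes ``candidates.tsv`` (all genes, ranked) and ``integrated.tsv``
    (selected candidates with rho) under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annot = eio.read_annotation(annot_path)
    expr = eio.read_matrix(expr_path, layout="gene", kind="expression",
                           sample_class=annot.sample_class)
    results = rank_outlier_candidates(expr, params)
    cand_path = out / "candidates.tsv"
    results.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")
    outputs = {"candidates": str(cand_path)}
    warnings = []
    counts = {
        "genes_in": int(len(results)),
        "selected": int(results["selected"].sum()),
        "selected_up": int((results["selected"] & (results["direction"] == "up")).sum()),
        "selected_down": int((results["selected"] & (results["direction"] == "down")).sum()),
    }

    if meth_path is not None and Path(meth_path).exists():
        meth = eio.read_matrix(meth_path, layout="gene", kind="methylation_beta")
        selected = results[results["selected"]].reset_index(drop=True)
        integrated = integrate_methylation(selected, expr, meth,
                                           samples=integration_samples)
        int_path = out / "integrated.tsv"
        integrated[INTEGRATED_COLUMNS].to_csv(int_path, sep="\t", index=False,
                                              float_format="%.6g")
        outputs["integrated"] = str(int_path)
        counts["with_promoter_probe"] = int(integrated["has_promoter_probe"].sum())
        counts["negatively_correlated"] = int(integrated["selected_negative"].sum())
    else:
        if meth_path is not None:
            warnings.append(f"methylation matrix {meth_path} not found; integration skipped")
        else:
            warnings.append("no methylation matrix provided; integration skipped")
        logger.warning(warnings[-1])

    report = RunReport(
        stage="discovery",
        parameters={"q_low": params.q_low, "q_high": params.q_high,
                    "delta": params.delta, "score_cutoff": params.score_cutoff,
                    "top_k": params.top_k, "integration_samples": integration_samples},
        input_checksums=_checksums({"expr": expr_path, "annot": annot_path,
                                    "meth": meth_path}),
        counts=counts, outputs=outputs, warnings=warnings)
    report.write(out / "discovery_report.json")
    return report


# ---------------------------------------------------------------------------
# validation


def run_validation(annot_path, out_dir, qpcr_path=None, bisulfite_path=None,
                   t_low: float = 0.25, t_high: float = 0.75) -> RunReport:
    """Per-gene validation statistics from qPCR and/or bisulfite tables.

    qPCR: relative quantities by 2^-ddCt calibrated on the normal group's
    mean dCt; tumor-vs-normal Student t-test on log2 RQ.  Bisulfite:
    methylation status calls per sample; Fisher exact comparison of
    methylated-promoter frequency between groups.  Writes
    ``validation_report.tsv`` (per gene) and ``methylation_calls.tsv``.
    """
    if qpcr_path is None and bisulfite_path is None:
        raise ValueError("validation requires a qPCR and/or a bisulfite table")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annot = eio.read_annotation(annot_path)
    cls = annot.sample_class
    warnings = []
    per_gene: dict[str, dict] = {}

    if qpcr_path is not None:
        measurements = val.read_qpcr_table(qpcr_path)
        by_gene: dict[str, list] = {}
        for m in measurements:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene, ms in sorted(by_gene.items()):
            normals = [m for m in ms if cls.get(m.sample_id) == eio.NORMAL]
            tumors = [m for m in ms if cls.get(m.sample_id) == eio.TUMOR]
            row = per_gene.setdefault(gene, {"gene_id": gene})
            if len(normals) < 2 or len(tumors) < 2:
                warnings.append(f"{gene}: not enough samples per class for qPCR t-test")
                continue
            cal = val.mean_delta_ct(normals)
            rq_t = [val.ddct_relative_expression(m, cal) for m in tumors]
            rq_n = [val.ddct_relative_expression(m, cal) for m in normals]
            t, p = val.student_t_test(np.log2(rq_t), np.log2(rq_n))
            row.update({"rq_tumor_mean": float(np.mean(rq_t)),
                        "rq_normal_mean": float(np.mean(rq_n)),
                        "t": t, "t_p": p})

    calls_rows = []
    if bisulfite_path is not None:
        traces = val.read_bisulfite_table(bisulfite_path)
        by_gene_tr: dict[str, list] = {}
        for tr in traces:
            by_gene_tr.setdefault(tr.gene_id, []).append(tr)
        for gene, trs in sorted(by_gene_tr.items()):
            calls = {tr.sample_id: val.call_methylation_status(tr, t_low, t_high)
                     for tr in trs}
            for sid, c in calls.items():
                calls_rows.append({"gene_id": gene, "sample_id": sid,
                                   "status": c.status,
                                   "mean_c_fraction": round(c.mean_c_fraction, 6)})
            ct = [c for s, c in calls.items() if cls.get(s) == eio.TUMOR]
            cn = [c for s, c in calls.items() if cls.get(s) == eio.NORMAL]
            row = per_gene.setdefault(gene, {"gene_id": gene})
            if ct and cn:
                row["fisher_p"] = val.compare_methylation_frequency(ct, cn)
            else:
                warnings.append(f"{gene}: missing a class for the Fisher comparison")

    report_df = pd.DataFrame(sorted(per_gene.values(), key=lambda r: r["gene_id"]))
    if report_df.empty:
        report_df = pd.DataFrame(columns=["gene_id"])
        warnings.append("no genes in validation inputs")
    rep_path = out / "validation_report.tsv"
    report_df.to_csv(rep_path, sep="\t", index=False, float_format="%.6g")
    outputs = {"report": str(rep_path)}
    if calls_rows:
        calls_path = out / "methylation_calls.tsv"
        pd.DataFrame(calls_rows).to_csv(calls_path, sep="\t", index=False)
        outputs["calls"] = str(calls_path)

    report = RunReport(
        stage="validation",
        parameters={"t_low": t_low, "t_high": t_high},
        input_checksums=_checksums({"annot": annot_path, "qpcr": qpcr_path,
                                    "bisulfite": bisulfite_path}),
        counts={"genes": int(len(report_df))},
        outputs=outputs, warnings=warnings)
    report.write(out / "validation_report.json")
    return report


# ---------------------------------------------------------------------------
# pathway


def run_pathway(expr_path, annot_path, marker: str, sets_path, out_dir,
                contrasts=(("marker_low", "marker_high"),
                           ("marker_low", "normal"))) -> RunReport:
    """Marker split, moderated t per contrast, BH-FDR, and set-level tests.

    ``sets_path`` is GMT-compatible: one set per line, tab-separated
    (set name, optional description starting with '#', then gene ids).
    Writes ``pathway_genes.tsv`` and ``pathway_sets.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annot = eio.read_annotation(annot_path)
    expr = eio.read_matrix(expr_path, layout="gene", kind="expression",
                           sample_class=annot.sample_class)
    design = split_by_marker_gene(expr, marker)
    gene_sets = read_gmt(sets_path)
    warnings = []

    gene_rows, set_rows = [], []
    for contrast in contrasts:
        name = f"{contrast[0]}_vs_{contrast[1]}"
        results, prior = fit_moderated_t(expr, design, contrast)
        stats_by_gene = results.set_index("gene_id")["t_mod"]
        for set_name, genes in gene_sets.items():
            present = [g for g in genes if g in stats_by_gene.index]
            missing = set(genes) - set(present)
            if missing:
                warnings.append(f"{set_name}: {len(missing)} genes absent from matrix")
            if not present:
                continue
            # per-gene FDR within the stated family (the gene set)
            fam = results[results["gene_id"].isin(present)].copy()
            fam["fdr"] = bh_adjust(fam["p"].to_numpy())
            fam.insert(0, "set", set_name)
            fam.insert(1, "contrast", name)
            gene_rows.append(fam)
            idx = [results.index[results["gene_id"] == g][0] for g in present]
            row = {"set": set_name, "contrast": name, "n_genes": len(present),
                   "d0": prior.d0, "s0_sq": prior.s0_sq,
                   "n_significant": int((fam["fdr"] < 0.05).sum())}
            for alt in ("up", "down", "either"):
                row[f"p_{alt}"] = gene_set_test(results["t_mod"].to_numpy(), idx, alt)
            set_rows.append(row)

    genes_df = pd.concat(gene_rows, ignore_index=True) if gene_rows else pd.DataFrame()
    sets_df = pd.DataFrame(set_rows)
    genes_path = out / "pathway_genes.tsv"
    sets_path_out = out / "pathway_sets.tsv"
    genes_df.to_csv(genes_path, sep="\t", index=False, float_format="%.6g")
    sets_df.to_csv(sets_path_out, sep="\t", index=False, float_format="%.6g")

    report = RunReport(
        stage="pathway",
        parameters={"marker": marker, "contrasts": [list(c) for c in contrasts]},
        input_checksums=_checksums({"expr": expr_path, "annot": annot_path,
                                    "sets": sets_path}),
        counts={"sets": int(len(sets_df)),
                "significant_sets_either": int((sets_df.get("p_either", pd.Series(dtype=float)) < 0.05).sum())},
        outputs={"genes": str(genes_path), "sets": str(sets_path_out)},
        warnings=warnings)
    report.write(out / "pathway_report.json")
    return report


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets: one per line, tab-separated; a second field starting
    with '#' is treated as a description and skipped."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = [p for p in line.rstrip("\n").split("\t") if p != ""]
        name, rest = parts[0], parts[1:]
        if rest and rest[0].startswith("#"):
            rest = rest[1:]
        if not rest:
            raise ValueError(f"gene set {name!r} is empty")
        sets[name] = rest
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets
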
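"""Expression-methylation integration for outlier candidates.

Candidates whose expression correlates negatively with promoter methylation
across samples are flagged as putatively epigenetically regulated (promoter
hypermethylation co-occurring with expression loss, or hypomethylation with
gain).  The filter is on the sign of the Spearman correlation only — no
significance test — mirroring how such candidate funnels are typically
constructed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, MethylationMatrix, TUMOR

logger = logging.getLogger(__name__)

INTEGRATED_COLUMNS = ["gene_id", "score", "direction", "n_outliers",
                      "spearman_rho", "has_promoter_probe", "selected_negative"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks.

    Requires two equal-length vectors of at least 3 finite values; a
    constant vector has no rank ordering and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def integrate_methylation(candidates: pd.DataFrame, expr: ExpressionMatrix,
                          meth: MethylationMatrix, samples: str = "all",
                          min_shared: int = 3) -> pd.DataFrame:
    """Attach expression-methylation Spearman correlations to candidates.

    Parameters
    ----------
    candidates
        Output of :func:`epioutlier.outlier.rank_outlier_candidates` (or any
        frame with ``gene_id``, ``score``, ``direction``, ``n_outliers``).
    samples
        ``"all"`` correlates over every shared sample (default);
        ``"tumor_only"`` restricts to tumors.

    Genes with no row in the methylation matrix get
    ``has_promoter_probe=False`` and a missing rho.  Samples missing from
    either matrix are dropped pairwise; genes left with fewer than
    ``min_shared`` shared samples (or with a constant vector) also get a
    missing rho.  ``selected_negative`` requires strictly negative rho.
    """
    if samples not in ("all", "tumor_only"):
        raise ValueError(f"unknown sample mode {samples!r}")
    shared = expr.sample_ids.intersection(meth.sample_ids)
    if samples == "tumor_only":
        shared = shared.intersection(expr.tumor_ids)
    if len(shared) == 0:
        raise ValueError("no shared samples between expression and methylation")

    out = candidates.copy()
    rhos, has_probe = [], []
    for gene in out["gene_id"]:
        if gene not in meth.gene_ids or gene not in expr.gene_ids:
            has_probe.append(gene in meth.gene_ids)
            rhos.append(np.nan)
            continue
        has_probe.append(True)
        e = expr.values.loc[gene, shared].to_numpy(dtype=float)
        b = meth.beta.loc[gene, shared].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(b)
        if ok.sum() < min_shared or np.ptp(e[ok]) == 0 or np.ptp(b[ok]) == 0:
            logger.info("gene %s: rho undefined (%d usable samples)", gene, int(ok.sum()))
            rhos.append(np.nan)
            continue
        rhos.append(spearman_rho(e[ok], b[ok]))
    out["spearman_rho"] = rhos
    out["has_promoter_probe"] = has_probe
    out["selected_negative"] = out["has_promoter_probe"] & (out["spearman_rho"] < 0)
    logger.info("%d of %d candidates have promoter probes; %d negatively correlated",
                int(out["has_promoter_probe"].sum()), len(out),
                int(out["selected_negative"].sum()))
    return out
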
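"""Rank-sum outlier scoring of genes against a normal-tissue empirical null.

Heterogeneous tumors alter a given gene in only a subset of samples, which
blunts cohort-level statistics such as the t-test.  The score implemented
here follows the cancer-outlier-profile-analysis (COPA) family: for each
gene the normal samples define an empirical null through their low/high
quantiles (default 10th/90th percentiles), a tumor is called an outlier when
it exceeds the quantile boundary by at least a minimum change ``delta``
(log2 units), and the gene's score is the sum of the outlier tumors' ranks
among all samples, normalized by the total sample count.  Genes altered in
even a few tumors — but altered strongly — therefore score highly, while
sub-threshold changes contribute nothing.

Scores are computed for both tails (down- and upregulation); the reported
score is the larger of the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, NORMAL, TUMOR

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"

RESULT_COLUMNS = ["gene_id", "score", "score_right", "score_left",
                  "direction", "n_outliers", "rank", "selected"]


@dataclass(frozen=True)
class OutlierParams:
    """Scoring parameters.

    q_low, q_high
        Empirical-null quantiles of the normal samples (defaults 0.10/0.90).
    delta
        Minimum change (log2 units) beyond the quantile boundary for a tumor
        to be called an outlier; suppresses biologically meaningless calls.
    score_cutoff
        Selection threshold on the score (default 2.3).
    top_k
        If set, select the top-k genes by score instead of the cutoff.
    """

    q_low: float = 0.10
    q_high: float = 0.90
    delta: float = 0.14
    score_cutoff: float = 2.3
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.q_low < self.q_high < 1.0):
            raise ValueError("require 0 < q_low < q_high < 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class NullQuantiles:
    q_low_value: float
    q_high_value: float
    n_normals: int


@dataclass(frozen=True)
class OutlierResult:
    gene_id: str
    score_right: float
    score_left: float
    score: float
    direction: str
    n_outliers: int
    rank: int | None = None


def empirical_null(normal_values, q_low: float = 0.10, q_high: float = 0.90) -> NullQuantiles:
    """Quantiles of the normal samples defining the per-gene null band.

    Quantiles use linear interpolation between closest order statistics
    (index ``h = (n - 1) q + 1``), so results are reproducible bit-for-bit.
    """
    x = np.asarray(normal_values, dtype=float)
    if x.size < 2:
        raise ValueError("empirical null requires at least 2 normal samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite normal values")
    lo, hi = np.quantile(x, [q_low, q_high])  # method="linear" = (n-1)q + 1
    return NullQuantiles(float(lo), float(hi), int(x.size))


def _score_arrays(values: np.ndarray, is_tumor: np.ndarray, params: OutlierParams,
                  rank_norm: str = "n_total"):
    """Vectorized scoring over a genes x samples array.

    Returns (score_right, score_left, n_out_right, n_out_left).
    """
    n_total = values.shape[1]
    n_tumor = int(is_tumor.sum())
    normals = values[:, ~is_tumor]
    tumors = values[:, is_tumor]
    q_lo, q_hi = np.quantile(normals, [params.q_low, params.q_high], axis=1)

    ranks = rankdata(values, axis=1)          # ascending, average ties
    tumor_ranks = ranks[:, is_tumor]

    out_r = (tumors > q_hi[:, None]) & (tumors - q_hi[:, None] >= params.delta)
    out_l = (tumors < q_lo[:, None]) & (q_lo[:, None] - tumors >= params.delta)

    denom = n_total if rank_norm == "n_total" else n_tumor
    if rank_norm not in ("n_total", "n_tumor"):
        raise ValueError(f"unknown rank normalization {rank_norm!r}")
    score_r = np.where(out_r, tumor_ranks, 0.0).sum(axis=1) / denom
    score_l = np.where(out_l, n_total + 1 - tumor_ranks, 0.0).sum(axis=1) / denom
    return score_r, score_l, out_r.sum(axis=1), out_l.sum(axis=1)


def outlier_score_gene(values, classes, params: OutlierParams = OutlierParams(),
                       gene_id: str = "", rank_norm: str = "n_total") -> OutlierResult:
    """Score a single gene.

    ``values`` covers all samples; ``classes`` is the matching tumor/normal
    label vector.  A right-tail outlier is a tumor above the high quantile
    by at least ``delta``; it contributes its ascending rank (average ranks
    for ties) among all N samples, divided by N.  The left tail is
    symmetric, with descending ranks ``N + 1 - r``.  The gene's score is the
    larger tail; an exact tie goes to "up" (logged).
    """
    x = np.asarray(values, dtype=float)
    cls = np.asarray(classes)
    if x.shape != cls.shape:
        raise ValueError("values and classes must have equal length")
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite values for gene {gene_id!r}")
    is_tumor = cls == TUMOR
    bad = set(cls) - {TUMOR, NORMAL}
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")
    if (~is_tumor).sum() < 2 or is_tumor.sum() < 1:
        raise ValueError("need >= 2 normals and >= 1 tumor")

    sr, sl, nr, nl = _score_arrays(x[None, :], is_tumor, params, rank_norm)
    return _assemble(gene_id, float(sr[0]), float(sl[0]), int(nr[0]), int(nl[0]))


def _assemble(gene_id, score_r, score_l, n_r, n_l) -> OutlierResult:
    if score_r == score_l and score_r > 0:
        logger.info("gene %s: tied left/right scores %.4g; direction set to up",
                    gene_id, score_r)
    if score_r >= score_l:
        direction, score, n_out = UP, score_r, n_r
    else:
        direction, score, n_out = DOWN, score_l, n_l
    return OutlierResult(gene_id, score_r, score_l, score, direction, n_out)


def rank_outlier_candidates(expr: ExpressionMatrix,
                            params: OutlierParams = OutlierParams(),
                            rank_norm: str = "n_total") -> pd.DataFrame:
    """Score every gene and rank by score (descending; ties by gene id).

    Returns a DataFrame with one row per gene (columns per
    ``RESULT_COLUMNS``); ``selected`` marks genes at or above the score
    cutoff, or the top-k genes when ``params.top_k`` is set.
    """
    if expr.values.shape[0] == 0:
        raise ValueError("empty expression matrix")
    is_tumor = (expr.sample_class == TUMOR).to_numpy()
    if is_tumor.all() or (~is_tumor).sum() < 2 or is_tumor.sum() < 1:
        raise ValueError("matrix must contain >= 1 tumor and >= 2 normal samples")

    vals = expr.values.to_numpy()
    sr, sl, nr, nl = _score_arrays(vals, is_tumor, params, rank_norm)
    right_wins = sr >= sl
    score = np.where(right_wins, sr, sl)
    df = pd.DataFrame({
        "gene_id": expr.gene_ids.to_numpy(),
        "score": score,
        "score_right": sr,
        "score_left": sl,
        "direction": np.where(right_wins, UP, DOWN),
        "n_outliers": np.where(right_wins, nr, nl).astype(int),
    })
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="mergesort", ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if params.top_k is not None:
        df["selected"] = df["rank"] <= params.top_k
    else:
        df["selected"] = df["score"] >= params.score_cutoff
    n_up = int((df["selected"] & (df["direction"] == UP)).sum())
    n_down = int((df["selected"] & (df["direction"] == DOWN)).sum())
    logger.info("selected %d candidates (%d up, %d down) of %d genes",
                n_up + n_down, n_up, n_down, len(df))
    return df


def delta_sweep(expr: ExpressionMatrix, deltas,
                params: OutlierParams = OutlierParams(),
                rank_norms=("n_total", "n_tumor")) -> pd.DataFrame:
    """Sensitivity sweep: selected-candidate counts over minimum-change
    values and rank normalizations (by total N or by tumor count)."""
    rows = []
    for norm in rank_norms:
        for d in deltas:
            p = replace(params, delta=float(d))
            res = rank_outlier_candidates(expr, p, rank_norm=norm)
            rows.append({"rank_norm": norm, "delta": float(d),
                         "n_selected": int(res["selected"].sum()),
                         "n_up": int((res["selected"] & (res["direction"] == UP)).sum()),
                         "n_down": int((res["selected"] & (res["direction"] == DOWN)).sum())})
    return pd.DataFrame(rows)
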
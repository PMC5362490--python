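"""Marker-split contrasts, empirical-Bayes moderated t, BH-FDR and a
rank-based gene-set test.

The pathway arm asks whether a gene set (e.g. a signaling pathway) shifts
coherently between tumor subgroups defined by a marker gene's expression.
Tumors are split into marker-low / marker-high halves; per-gene moderated
t-statistics are computed for a contrast by shrinking each gene's sample
variance toward a pooled prior (the empirical-Bayes treatment of gene-wise
variances: s2_g ~ s0^2 * chi^2_{d_g}/d_g scaled-F model, hyperparameters
(d0, s0^2) estimated by closed-form digamma/trigamma moment matching);
p-values are BH-adjusted within the stated gene family; the set-level test
ranks the set's statistics against all remaining genes (Wilcoxon rank-sum,
with an "either" two-sided alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, TUMOR, NORMAL

logger = logging.getLogger(__name__)

MARKER_LOW = "marker_low"
MARKER_HIGH = "marker_high"
GROUP_NORMAL = "normal"


@dataclass(frozen=True)
class GroupDesign:
    """Sample grouping for contrasts: marker_low / marker_high / normal."""

    groups: pd.Series  # sample_id -> group
    marker: str

    def members(self, group: str) -> pd.Index:
        return self.groups.index[(self.groups == group).to_numpy()]


@dataclass(frozen=True)
class EbayesHyperparams:
    """Variance-prior hyperparameters: prior df d0 (may be inf) and prior
    variance s0_sq."""

    d0: float
    s0_sq: float


def split_by_marker_gene(expr: ExpressionMatrix, marker: str) -> GroupDesign:
    """Split tumors into equal low/high halves by a marker gene's expression.

    Tumors are sorted by (marker value, sample id); the lower half goes to
    ``marker_low``.  With an odd tumor count the median sample joins the
    low group (logged).  Normals map to ``normal``.
    """
    if marker not in expr.gene_ids:
        raise ValueError(f"marker gene {marker!r} not in expression matrix")
    tumors = expr.tumor_ids
    if len(tumors) < 2:
        raise ValueError("need at least 2 tumors to split")
    vals = expr.values.loc[marker, tumors]
    # sort by (value, sample_id): stable value-sort after an id-sort
    order = vals.to_frame("v").sort_index(kind="mergesort").sort_values("v", kind="mergesort")
    n_low = (len(tumors) + 1) // 2
    if len(tumors) % 2:
        logger.info("odd tumor count %d: median sample %s assigned to %s",
                    len(tumors), order.index[n_low - 1], MARKER_LOW)
    groups = pd.Series(GROUP_NORMAL, index=expr.sample_ids, name="group")
    groups.loc[order.index[:n_low]] = MARKER_LOW
    groups.loc[order.index[n_low:]] = MARKER_HIGH
    return GroupDesign(groups, marker)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, d_g: int) -> EbayesHyperparams:
    """Moment-match (d0, s0_sq) from gene-wise sample variances.

    Under the scaled-F model, log s2_g has closed-form mean/variance in
    digamma/trigamma terms; matching the observed moments of
    ``log s2_g`` yields d0 (via the trigamma inverse) and s0_sq.  Genes
    with zero residual variance are excluded (flagged via log).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    n_zero = int((~ok).sum())
    if n_zero:
        logger.info("excluding %d zero/invalid-variance genes from prior estimation", n_zero)
    s2 = s2[ok]
    if s2.size < 2:
        raise ValueError("too few positive gene variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return EbayesHyperparams(d0, s0_sq)


def fit_moderated_t(expr: ExpressionMatrix, design: GroupDesign,
                    contrast: tuple[str, str] = (MARKER_LOW, MARKER_HIGH),
                    prior_df: float | None = None,
                    genes=None) -> tuple[pd.DataFrame, EbayesHyperparams]:
    """Moderated t-statistics for a two-group contrast.

    Per gene: log_fc = mean(group1) - mean(group2); residual variance s2_g
    pooled over the two groups with d_g = n1 + n2 - 2 df.  The posterior
    variance shrinks s2_g toward the prior:
    ``s2_post = (d0 s0^2 + d_g s2_g) / (d0 + d_g)``; the moderated t is the
    ordinary t with s2_post in place of s2_g, on d0 + d_g df.

    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t,
    inf fully pools).  ``genes`` restricts the fit to a gene subset (the
    hyperparameters are then estimated within that family).
    """
    g1, g2 = contrast
    s1 = design.members(g1)
    s2_ids = design.members(g2)
    if len(s1) < 2 or len(s2_ids) < 2:
        raise ValueError(f"both contrast groups need >= 2 samples ({g1}: {len(s1)}, "
                         f"{g2}: {len(s2_ids)})")
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    x1 = values[s1].to_numpy(dtype=float)
    x2 = values[s2_ids].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d_g = n1 + n2 - 2

    log_fc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2_g = ss / d_g

    if prior_df is None:
        prior = estimate_variance_prior(s2_g, d_g)
    else:
        s0 = float(np.median(s2_g[s2_g > 0])) if np.isfinite(prior_df) and prior_df > 0 else 1.0
        if np.isinf(prior_df):
            s0 = float(np.exp(np.log(s2_g[s2_g > 0]).mean()))
        prior = EbayesHyperparams(float(prior_df), s0)

    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2_g
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)
        df_total = float(d0 + d_g)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where((se == 0) & (log_fc == 0), 1.0, p)

    res = pd.DataFrame({
        "gene_id": values.index.to_numpy(),
        "log_fc": log_fc,
        "s2_g": s2_g,
        "d_g": d_g,
        "t_mod": t_mod,
        "p": p,
    })
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res, prior


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene-set rank test


def gene_set_test(stats_all, set_index, alternative: str = "either",
                  exact: bool | None = None) -> float:
    """Wilcoxon rank-sum test of a gene set's statistics against the rest.

    ``stats_all`` are per-gene statistics (typically moderated t);
    ``set_index`` selects the set's positions (integer indices or boolean
    mask).  ``alternative="up"`` asks whether set statistics tend larger,
    ``"down"`` smaller; ``"either"`` is two-sided
    (min(1, 2 min(p_up, p_down))).  Small instances (|set| <= 10 and
    n <= 25) are evaluated by exact enumeration over all subsets of the
    observed ranks; otherwise a normal approximation with tie correction
    and continuity correction is used.  ``exact`` forces either mode.
    """
    if alternative not in ("up", "down", "either"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(stats_all, dtype=float)
    n = x.size
    idx = np.asarray(set_index)
    if idx.size == 0:
        raise ValueError("empty gene set")
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    k = int(mask.sum())
    if k == n:
        raise ValueError("gene set contains every gene")
    if not np.isfinite(x).all():
        raise ValueError("non-finite statistics")

    ranks = stats.rankdata(x)
    w = float(ranks[mask].sum())
    use_exact = exact if exact is not None else (k <= 10 and n <= 25)

    if use_exact:
        p_up, p_down = _exact_tail_probs(ranks, k, w)
    else:
        p_up, p_down = _normal_tail_probs(ranks, n, k, w)

    if alternative == "up":
        return min(1.0, p_up)
    if alternative == "down":
        return min(1.0, p_down)
    return min(1.0, 2.0 * min(p_up, p_down))


def _exact_tail_probs(ranks: np.ndarray, k: int, w: float) -> tuple[float, float]:
    total = comb(len(ranks), k)
    eps = 1e-9
    ge = le = 0
    for idx in combinations(range(len(ranks)), k):
        s = ranks[list(idx)].sum()
        if s >= w - eps:
            ge += 1
        if s <= w + eps:
            le += 1
    return ge / total, le / total


def _normal_tail_probs(ranks: np.ndarray, n: int, k: int, w: float) -> tuple[float, float]:
    mean = k * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (n * (n - 1))
    var = (k * (n - k) / 12.0) * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0, 1.0
    sd = np.sqrt(var)
    p_up = float(stats.norm.sf((w - mean - 0.5) / sd))
    p_down = float(stats.norm.cdf((w - mean + 0.5) / sd))
    return p_up, p_down
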
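"""Validation-arm statistics: t-tests, 2^-ddCt qPCR quantification,
bisulfite-trace methylation calling, and two-tailed Fisher exact tests.

These are the confirmatory computations applied to an independent cohort
after discovery: expression differences are tested with the (pooled)
Student t-test on log-scale values, qPCR measurements are converted to
relative quantities against a housekeeping reference and a calibrator
group, bisulfite sequencing chromatogram peak heights are turned into
unmethylated / hemimethylated / methylated promoter calls, and group
frequencies are compared with the Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

UNMETHYLATED = "unmethylated"
HEMIMETHYLATED = "hemimethylated"
METHYLATED = "methylated"


# ---------------------------------------------------------------------------
# t-test


def student_t_test(a, b, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test; returns ``(t, p)``.

    ``variant="student"`` pools variances (default); ``"welch"`` does not.
    Two degenerate-but-equal groups (zero variance in both, equal means)
    return ``(0.0, 1.0)`` by convention.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


# ---------------------------------------------------------------------------
# qPCR relative quantification


@dataclass(frozen=True)
class QpcrMeasurement:
    """Triplicate Ct values for a target and a housekeeping reference gene."""

    sample_id: str
    gene_id: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, cts in (("target", self.ct_target), ("reference", self.ct_reference)):
            arr = np.asarray(cts, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty {name} Ct replicates")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite {name} Ct")
            if (arr <= 0).any() or (arr >= 45).any():
                raise ValueError(f"{name} Ct outside (0, 45)")

    @property
    def delta_ct(self) -> float:
        """Ct(target) - Ct(reference), replicate means."""
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def ddct_relative_expression(m: QpcrMeasurement, calibrator_dct: float) -> float:
    """Relative quantity by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - calibrator dCt; one extra cycle to
    threshold means half the template, so RQ = 2^-ddCt.
    """
    ddct = m.delta_ct - float(calibrator_dct)
    return float(2.0 ** (-ddct))


def mean_delta_ct(measurements) -> float:
    """Mean dCt over a list of measurements (the usual calibrator: the
    normal/control group's mean dCt)."""
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements for calibrator")
    return float(np.mean([m.delta_ct for m in ms]))


# ---------------------------------------------------------------------------
# bisulfite sequencing calls


@dataclass(frozen=True)
class BisulfiteTrace:
    """C/T chromatogram peak heights at CpG sites of one sample's promoter.

    After bisulfite conversion, unmethylated cytosines read as T and
    methylated cytosines stay C, so the relative C peak height at a CpG
    estimates its methylated fraction.
    """

    sample_id: str
    gene_id: str
    cpg_sites: tuple[tuple[float, float], ...]  # (c_height, t_height)

    def __post_init__(self) -> None:
        if len(self.cpg_sites) == 0:
            raise ValueError("trace has no CpG sites")
        for c, t in self.cpg_sites:
            if c < 0 or t < 0:
                raise ValueError("negative peak height")


@dataclass(frozen=True)
class MethylationCall:
    status: str
    mean_c_fraction: float


def call_methylation_status(trace: BisulfiteTrace, t_low: float = 0.25,
                            t_high: float = 0.75) -> MethylationCall:
    """Call a promoter unmethylated / hemimethylated / methylated.

    Per site the methylated fraction is ``c / (c + t)``; the mean over
    usable sites is thresholded at ``t_low`` and ``t_high``.  Sites with
    zero total height are skipped; a trace with no usable site raises.
    """
    if not (0 <= t_low <= t_high <= 1):
        raise ValueError("require 0 <= t_low <= t_high <= 1")
    fracs = [c / (c + t) for c, t in trace.cpg_sites if c + t > 0]
    if not fracs:
        raise ValueError(f"trace {trace.sample_id}/{trace.gene_id}: all sites have zero height")
    mean_frac = float(np.mean(fracs))
    if mean_frac < t_low:
        status = UNMETHYLATED
    elif mean_frac > t_high:
        status = METHYLATED
    else:
        status = HEMIMETHYLATED
    return MethylationCall(status, mean_frac)


# ---------------------------------------------------------------------------
# Fisher exact


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p-value.

    Two-sided by the probability-mass convention: the sum of hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed one (up to a 1 + 1e-7 relative tolerance).
    A zero margin admits only one table: p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        table = ContingencyTable2x2(*arr.ravel().tolist())
    p = stats.fisher_exact(table.as_array(), alternative="two-sided").pvalue
    return float(min(p, 1.0))


def read_qpcr_table(path) -> list[QpcrMeasurement]:
    """Read a qPCR TSV: sample_id, gene_id, ct_target_* and ct_ref_* columns."""
    df = pd.read_csv(path, sep="\t")
    tgt_cols = sorted(c for c in df.columns if c.startswith("ct_target_"))
    ref_cols = sorted(c for c in df.columns if c.startswith("ct_ref_"))
    if not tgt_cols or not ref_cols:
        raise ValueError("qPCR table needs ct_target_* and ct_ref_* columns")
    return [QpcrMeasurement(str(r["sample_id"]), str(r["gene_id"]),
                            tuple(float(r[c]) for c in tgt_cols),
                            tuple(float(r[c]) for c in ref_cols))
            for _, r in df.iterrows()]


def read_bisulfite_table(path) -> list[BisulfiteTrace]:
    """Read a bisulfite TSV: sample_id, gene_id, site, c_height, t_height."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "gene_id", "site", "c_height", "t_height"}
    if not need <= set(df.columns):
        raise ValueError(f"bisulfite table needs columns {sorted(need)}")
    traces = []
    for (sample, gene), grp in df.groupby(["sample_id", "gene_id"], sort=True):
        grp = grp.sort_values("site")
        sites = tuple((float(c), float(t))
                      for c, t in zip(grp["c_height"], grp["t_height"]))
        traces.append(BisulfiteTrace(str(sample), str(gene), sites))
    return traces


def compare_methylation_frequency(calls_tumor, calls_normal) -> float:
    """Fisher exact comparison of methylated-promoter frequency.

    Hemimethylated and methylated calls collapse to "any methylated
    signal"; the 2x2 table is groups x (methylated, unmethylated).
    """
    calls_tumor = list(calls_tumor)
    calls_normal = list(calls_normal)
    if not calls_tumor or not calls_normal:
        raise ValueError("both groups must be non-empty")

    def split(calls):
        m = sum(c.status in (METHYLATED, HEMIMETHYLATED) for c in calls)
        return m, len(calls) - m

    a, b = split(calls_tumor)
    c, d = split(calls_normal)
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
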
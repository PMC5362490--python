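"""Reading, writing and probe-to-gene summarization of omics tables.

Expression values are assumed to be already normalized and on the log2
scale; methylation is carried as beta values (fraction methylated signal,
``beta = M / (M + U)``) in [0, 1].  Files are plain TSV/CSV with one header
row of sample ids and one leading feature-id column; probe-level tables
carry a second ``gene_id`` column mapping each probe to a gene (empty =
unmapped).  Methylated/unmethylated intensity tables use paired columns
named ``<sample>.M`` / ``<sample>.U``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"
SAMPLE_CLASSES = (TUMOR, NORMAL)

GENE_COLUMN = "gene_id"


# ---------------------------------------------------------------------------
# containers


@dataclass
class SampleAnnotation:
    """Per-sample class labels (tumor/normal) plus categorical covariates."""

    table: pd.DataFrame  # index = sample_id; column "class" + covariates

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in annotation: {dupes}")
        if "class" not in self.table.columns:
            raise ValueError("annotation must have a 'class' column")
        bad = set(self.table["class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes {sorted(bad)}; expected {SAMPLE_CLASSES}")

    @property
    def sample_class(self) -> pd.Series:
        return self.table["class"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns=["class"])


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression with tumor/normal sample classes."""

    values: pd.DataFrame        # genes x samples, float
    sample_class: pd.Series     # sample_id -> "tumor" | "normal"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = [s for s in self.values.columns if s not in self.sample_class.index]
        if missing:
            raise ValueError(f"samples without class label: {missing}")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        bad = set(self.sample_class) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_ids(self) -> pd.Index:
        return self.values.columns[(self.sample_class == TUMOR).to_numpy()]

    @property
    def normal_ids(self) -> pd.Index:
        return self.values.columns[(self.sample_class == NORMAL).to_numpy()]


@dataclass
class MethylationMatrix:
    """Gene-by-sample methylation beta values in [0, 1]."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        _check_unique(self.beta.index, "gene ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("methylation matrix contains non-finite values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


@dataclass
class ProbeTable:
    """Probe-level measurements with a probe-to-gene map.

    ``values`` holds one row per probe (log2 expression or beta).  For
    methylation read from M/U intensities the original intensities are kept
    in ``intensities`` and ``values`` holds the derived betas.
    """

    values: pd.DataFrame                     # probes x samples
    gene_map: pd.Series                      # probe_id -> gene_id ("" = unmapped)
    intensities: tuple[pd.DataFrame, pd.DataFrame] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        self.gene_map = self.gene_map.reindex(self.values.index).fillna("")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _check_unique(index: pd.Index, what: str) -> None:
    if not index.is_unique:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes}")


# ---------------------------------------------------------------------------
# beta computation


def compute_beta(M, U):
    """Fraction methylated signal ``beta = M / (M + U)``.

    Accepts scalars or arrays; raises if any intensity is negative or any
    probe has ``M + U == 0`` (beta undefined).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("methylation intensities must be non-negative")
    total = M + U
    if (total == 0).any():
        raise ValueError("beta undefined where M + U == 0")
    beta = M / total
    if beta.ndim == 0:
        return float(beta)
    return beta


# ---------------------------------------------------------------------------
# reading / writing


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def read_annotation(path) -> SampleAnnotation:
    """Read a sample annotation table (sample_id, class, covariates...)."""
    return SampleAnnotation(_read_table(path))


def read_matrix(path, layout: str = "gene", kind: str = "expression",
                sample_class: pd.Series | None = None):
    """Read a delimited omics matrix.

    Parameters
    ----------
    layout
        ``"gene"`` for one row per gene, ``"probe"`` for probe-level tables
        carrying a ``gene_id`` column.
    kind
        ``"expression"`` (log2 values), ``"methylation_beta"`` (betas in
        [0,1]) or ``"methylation_mu"`` (paired ``<sample>.M``/``<sample>.U``
        intensity columns; betas are derived).
    sample_class
        Required for ``kind="expression", layout="gene"``: mapping
        sample_id -> tumor/normal (e.g. ``read_annotation(...).sample_class``).
    """
    if layout not in ("gene", "probe"):
        raise ValueError(f"unknown layout {layout!r}")
    if kind not in ("expression", "methylation_beta", "methylation_mu"):
        raise ValueError(f"unknown kind {kind!r}")

    df = _read_table(path)
    gene_map = None
    if layout == "probe":
        if GENE_COLUMN not in df.columns:
            raise ValueError(f"probe-level table must have a {GENE_COLUMN!r} column")
        gene_map = df[GENE_COLUMN].fillna("").astype(str)
        df = df.drop(columns=[GENE_COLUMN])

    if kind == "methylation_mu":
        m_cols = [c for c in df.columns if c.endswith(".M")]
        u_cols = [c for c in df.columns if c.endswith(".U")]
        samples = [c[:-2] for c in m_cols]
        if samples != [c[:-2] for c in u_cols]:
            raise ValueError("M and U columns do not pair up sample-wise")
        M = df[m_cols].set_axis(samples, axis=1).astype(float)
        U = df[u_cols].set_axis(samples, axis=1).astype(float)
        beta = pd.DataFrame(compute_beta(M.to_numpy(), U.to_numpy()),
                            index=df.index, columns=samples)
        if layout == "probe":
            return ProbeTable(beta, gene_map, intensities=(M, U))
        return MethylationMatrix(beta)

    values = _coerce_numeric(df, path)
    if layout == "probe":
        return ProbeTable(values, gene_map)
    if kind == "methylation_beta":
        return MethylationMatrix(values)
    if sample_class is None:
        raise ValueError("gene-level expression requires a sample_class mapping "
                         "(pass read_annotation(...).sample_class)")
    return ExpressionMatrix(values, sample_class)


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}")
    if out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, "
                         f"column {df.columns[c]!r}")
    return out


def write_matrix(matrix, path) -> None:
    """Write an ExpressionMatrix / MethylationMatrix / DataFrame as TSV/CSV."""
    if isinstance(matrix, ExpressionMatrix):
        df = matrix.values
    elif isinstance(matrix, MethylationMatrix):
        df = matrix.beta
    else:
        df = matrix
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# probe -> gene summarization


def summarize_expression(probes: ProbeTable, method: str = "mean_of_probes",
                         sample_class: pd.Series | None = None):
    """Collapse probe-level expression to one gene-level estimate per gene.

    ``mean_of_probes`` averages all probes of a gene per sample (default);
    ``max_mean_probe`` keeps the single probe with the highest across-sample
    mean (ties broken by lexicographically smallest probe id).  Unmapped
    probes are dropped (count logged).
    """
    if method not in ("mean_of_probes", "max_mean_probe"):
        raise ValueError(f"unknown summarization method {method!r}")
    values = _summarize(probes, mean_of_probes=(method == "mean_of_probes"))
    if sample_class is not None:
        return ExpressionMatrix(values, sample_class)
    return values


def summarize_methylation(probes: ProbeTable, per_sample_max: bool = False) -> MethylationMatrix:
    """Collapse probe-level betas to the gene's highest-methylation estimate.

    By default the single probe with the highest across-sample mean beta
    represents the gene, which keeps one coherent probe per gene and so
    preserves the within-gene sample ordering used downstream for
    expression-methylation correlation.  ``per_sample_max=True`` instead
    takes the per-sample maximum across probes (mixes probes).
    """
    if per_sample_max:
        mapped = probes.gene_map != ""
        _log_unmapped(probes, mapped)
        vals = probes.values.loc[mapped]
        out = vals.groupby(probes.gene_map[mapped]).max()
        out = out.sort_index()
    else:
        out = _summarize(probes, mean_of_probes=False)
    return MethylationMatrix(out)


def _summarize(probes: ProbeTable, mean_of_probes: bool) -> pd.DataFrame:
    mapped = probes.gene_map != ""
    _log_unmapped(probes, mapped)
    if not mapped.any():
        raise ValueError("no probes are mapped to genes")
    vals = probes.values.loc[mapped]
    genes = probes.gene_map[mapped]
    if mean_of_probes:
        return vals.groupby(genes).mean().sort_index()
    # highest across-sample mean; ties -> smallest probe_id
    means = vals.mean(axis=1)
    order = pd.DataFrame({"gene": genes, "mean": means, "probe": vals.index})
    order = order.sort_values(["gene", "mean", "probe"],
                              ascending=[True, False, True], kind="mergesort")
    chosen = order.drop_duplicates("gene")["probe"]
    out = vals.loc[chosen]
    out.index = order.drop_duplicates("gene")["gene"].to_numpy()
    return out.sort_index()


def _log_unmapped(probes: ProbeTable, mapped: pd.Series) -> None:
    n_drop = int((~mapped).sum())
    if n_drop:
        logger.info("dropping %d unmapped probes of %d", n_drop, len(mapped))


# ---------------------------------------------------------------------------
# candidate tables

CANDIDATE_COLUMNS = ["gene_id", "score", "direction", "n_outliers",
                     "spearman_rho", "has_promoter_probe", "selected_negative"]


def write_candidate_table(records: pd.DataFrame, path) -> None:
    """Write an integrated candidate table (sorted by score descending)."""
    df = records.copy()
    for col in CANDIDATE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANDIDATE_COLUMNS].sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort")
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f")


def read_candidate_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
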
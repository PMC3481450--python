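"""Loading and preprocessing of expression data and the modulator catalog.

Expression input is a tab-separated gene x sample matrix of log2-ratio
values over a stimulation time course (header row = sample time labels in
hours).  Probe-level input is supported through an optional probe->gene map
and a per-probe absent-call matrix: probes absent in every sample are
dropped, duplicate probes per gene are averaged, and genes with a small
coefficient of variation across the course are removed before modelling.

Modulators are catalogued by molecular function (kinases, phosphatases,
acetyl-/deacetylases, methyltransferases, transcription factors and
cofactors); their expression is dichotomized at the median to give the
binary M regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: functional classes of candidate modulators (extensible)
MODULATOR_CLASSES = (
    "protein kinase",
    "phosphoprotein phosphatase",
    "acetyltransferase",
    "deacetylase",
    "methyltransferase",
    "transcription factor",
    "transcription cofactor",
)


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad header, non-numeric cells)."""


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-ratio expression values.

    ``data`` is indexed by unique gene identifiers with one column per
    sample (time point, hours).  At least 5 samples are required: the
    interaction model has 4 parameters and needs a residual degree of
    freedom.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.shape[1] < 5:
            raise ValueError(
                f"need at least 5 samples for the 4-parameter interaction model, "
                f"got {self.data.shape[1]}"
            )
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vector(self, gene_id: str) -> np.ndarray:
        """Expression trajectory of one gene (length = n_samples)."""
        return self.data.loc[gene_id].to_numpy(dtype=float)


@dataclass
class ProbeTable:
    """Probe-level expression with a probe->gene map and absent calls.

    ``absent_flags`` is a boolean matrix aligned with ``data`` (same index
    and columns); an entry is True where the platform software called the
    probe absent in that sample.
    """

    data: pd.DataFrame
    probe_to_gene: dict[str, str]
    absent_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe identifiers: {dups}")
        if self.absent_flags is not None:
            if self.absent_flags.shape != self.data.shape:
                raise ValueError(
                    f"absent_flags shape {self.absent_flags.shape} does not match "
                    f"probe matrix shape {self.data.shape}"
                )
            if not self.absent_flags.index.equals(self.data.index):
                raise ValueError("absent_flags probe IDs do not match probe matrix")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ModulatorCatalog:
    """Candidate modulator genes grouped by molecular function."""

    entries: pd.DataFrame  # columns: gene_id, function_class
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.entries["function_class"].str.strip() == "").any():
            raise ValueError("empty function_class label in catalog")

    @property
    def gene_ids(self) -> set[str]:
        """Deduplicated union of modulator genes across all classes."""
        return set(self.entries["gene_id"])

    def class_counts(self) -> pd.Series:
        """Unique-modulator count per functional class."""
        return self.entries.drop_duplicates().groupby("function_class")["gene_id"].nunique()

    def restrict_to(self, universe: set[str]) -> "ModulatorCatalog":
        """Restrict to genes present in an expression matrix.

        Genes absent from the universe are reported (``excluded``) but the
        catalog entries themselves are not rewritten on disk.
        """
        mask = self.entries["gene_id"].isin(universe)
        excluded = sorted(set(self.entries.loc[~mask, "gene_id"]))
        if excluded:
            logger.info("%d catalog genes absent from expression matrix", len(excluded))
        return ModulatorCatalog(self.entries.loc[mask].reset_index(drop=True), excluded)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: first column IDs, header row of sample labels.

    Tolerates CRLF line endings and '#' comment lines; enforces a
    rectangular numeric body.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: header row has no sample labels")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise FormatError(f"{path}: ragged rows (missing cells) at {rows[:5]}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    out[:] = numeric.to_numpy(dtype=float)
    return out.astype(float)


def load_expression(
    path: str | Path,
    probe_map: str | Path | None = None,
    absent_calls: str | Path | None = None,
) -> ExpressionMatrix | ProbeTable:
    """Load an expression TSV, optionally probe-level.

    Without ``probe_map`` the first column is taken as gene IDs and an
    :class:`ExpressionMatrix` is returned (duplicate IDs rejected).  With a
    probe map (2-column TSV probe_id -> gene_id) a :class:`ProbeTable` is
    returned, optionally carrying an absent-call 0/1 matrix of the same
    shape.
    """
    data = _read_tsv_matrix(path)
    if probe_map is None:
        return ExpressionMatrix(data)
    pm = pd.read_csv(probe_map, sep="\t", comment="#", header=None, dtype=str)
    if pm.shape[1] < 2:
        raise FormatError(f"{probe_map}: probe map needs two columns")
    if pm[0].duplicated().any():
        dups = pm.loc[pm[0].duplicated(), 0].tolist()
        raise ValueError(f"probe mapped to more than one gene: {dups}")
    mapping = dict(zip(pm[0], pm[1]))
    flags = None
    if absent_calls is not None:
        fl = _read_tsv_matrix(absent_calls)
        if not set(np.unique(fl.to_numpy())) <= {0.0, 1.0}:
            raise FormatError(f"{absent_calls}: absent-call matrix must be 0/1")
        flags = fl.astype(bool)
    return ProbeTable(data, mapping, flags)


def filter_absent_probes(pt: ProbeTable) -> ProbeTable:
    """Drop probes called absent in every sample; retain all others."""
    if pt.absent_flags is None:
        raise ValueError("probe table carries no absent calls")
    keep = ~pt.absent_flags.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("removed %d probes absent in all samples", n_dropped)
    return ProbeTable(
        pt.data.loc[keep], dict(pt.probe_to_gene), pt.absent_flags.loc[keep]
    )


def collapse_duplicate_probes(pt: ProbeTable) -> ExpressionMatrix:
    """Average duplicate probes per gene into one row per gene.

    Every retained probe must map to a gene; a probe without a mapping is
    an error, a gene whose probes were all filtered simply does not appear.
    """
    unmapped = [p for p in pt.probe_ids if p not in pt.probe_to_gene]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
    genes = pd.Index([pt.probe_to_gene[p] for p in pt.probe_ids], name="gene_id")
    collapsed = pt.data.groupby(genes, sort=True).mean()
    return ExpressionMatrix(collapsed)


def cv_filter(
    em: ExpressionMatrix, threshold: float = 0.15, scale: str = "linear"
) -> tuple[ExpressionMatrix, int]:
    """Remove genes with a small coefficient of variation across samples.

    CV = sample standard deviation / mean, computed per gene on the chosen
    scale:

    - ``linear`` (default): intensities ``2**value``, the usual microarray
      practice for a variation filter on log-ratio data whose log-scale
      mean sits near zero;
    - ``log-abs``: sd / |mean| of the log2 values directly.

    Genes with zero mean on the chosen scale cannot be scored and are
    dropped (logged).  Returns the filtered matrix and the number of genes
    removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if scale == "linear":
        x = np.power(2.0, em.values)
    elif scale == "log-abs":
        x = em.values
    else:
        raise ValueError(f"unknown CV scale {scale!r}")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(sd / mean)
    zero_mean = mean == 0
    if zero_mean.any():
        logger.warning(
            "%d genes have zero mean on %s scale; dropped", int(zero_mean.sum()), scale
        )
    keep = ~zero_mean & (cv >= threshold)
    removed = int((~keep).sum())
    return ExpressionMatrix(em.data.loc[keep]), removed


def dichotomize_modulator(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Binary high/low modulator status split at the median.

    Element = 1 iff the value is strictly above the median, else 0 (ties
    at the median count as low).  A constant vector cannot be split; it is
    returned all-zero with ``degenerate=True`` and the caller must skip
    the triplet.

    Returns ``(binary vector, degenerate flag)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    if np.all(v == v[0]):
        return np.zeros(v.size, dtype=int), True
    med = np.median(v)
    return (v > med).astype(int), False


def load_modulator_catalog(path: str | Path) -> ModulatorCatalog:
    """Load a 2-column TSV catalog (gene_id, function_class)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty modulator catalog")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: catalog needs two columns (gene_id, class)")
    entries = df.iloc[:, :2].copy()
    entries.columns = ["gene_id", "function_class"]
    entries = entries.dropna().drop_duplicates().reset_index(drop=True)
    if entries.empty:
        raise FormatError(f"{path}: no usable catalog rows")
    return ModulatorCatalog(entries)


def write_expression(em: ExpressionMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write an expression matrix in the TSV dialect :func:`load_expression` reads."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        em.data.rename_axis("gene_id").to_csv(fh, sep="\t")
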
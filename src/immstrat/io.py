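"""Tabular I/O and matrix plumbing shared by every pipeline stage.

All expression data is held genes x samples in log2 units.  Every function
that touches a matrix documents its orientation; nothing transposes
silently.  Gene symbols are matched case-sensitively after stripping
whitespace; probe-to-gene annotation and alias mapping are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenePanel",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_panel",
    "read_gene_sets",
    "write_gene_sets",
    "intersect_panel",
    "mean_center",
]


class ImmstratError(ValueError):
    """Base class for user-facing errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix, genes x samples.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene
    symbols and whose columns hold unique sample IDs.  All values must be
    finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index.astype(str).str.strip()
        cols = self.data.columns.astype(str).str.strip()
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ImmstratError(f"duplicate gene symbols: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ImmstratError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ImmstratError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        self.data = pd.DataFrame(values, index=idx.rename(None), columns=cols.rename(None))

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes), :])


@dataclass
class GenePanel:
    """A named set of gene symbols (e.g. an immune profiling panel)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = frozenset(str(g).strip() for g in self.genes)
        if not genes:
            raise ImmstratError(f"gene panel {self.name!r} is empty")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered gene list."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ImmstratError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_matrix(
    path: str,
    orientation: str = "genes_in_rows",
    delimiter: str | None = None,
    duplicate_policy: str = "max",
) -> ExpressionMatrix:
    """Read a delimited expression table into genes x samples orientation.

    Parameters
    ----------
    path
        Delimited text file with one header row and one label column.
    orientation
        ``genes_in_rows`` (default) or ``samples_in_rows``; the returned
        matrix is always genes x samples.
    duplicate_policy
        How duplicate gene rows are collapsed: ``max`` (default, the
        common microarray convention) or ``mean``.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ImmstratError(f"unknown orientation {orientation!r}")
    if duplicate_policy not in ("max", "mean"):
        raise ImmstratError(f"unknown duplicate_policy {duplicate_policy!r}")
    sep = _delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    df = pd.read_csv(path, sep=sep, index_col=0, skiprows=1, header=None)
    labels = [h.strip() for h in header]
    # first header token labels the index column; pandas would otherwise
    # silently mangle duplicated column names
    df.columns = labels[1:] if len(labels) == df.shape[1] + 1 else labels[-df.shape[1]:]
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ImmstratError(
            f"non-numeric value in {path!r} at row {row!r}, column {col!r}"
        )
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ImmstratError(f"duplicate sample IDs in {path!r}: {dups[:5]}")
    if df.index.duplicated().any():
        agg = df.groupby(level=0, sort=False)
        df = agg.max() if duplicate_policy == "max" else agg.mean()
    return ExpressionMatrix(df)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str, delimiter: str | None = None
) -> None:
    """Write genes x samples with gene symbols in the first column."""
    matrix.data.to_csv(path, sep=_delimiter(path, delimiter), index_label="gene")


def read_gene_panel(path: str, name: str | None = None) -> GenePanel:
    """Read a plain-text panel, one gene symbol per line; blanks skipped."""
    with open(path) as fh:
        genes = [line.strip() for line in fh]
    genes = [g for g in genes if g]
    return GenePanel(name=name or os.path.basename(path), genes=frozenset(genes))


def write_gene_panel(panel: GenePanel, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(panel.genes):
            fh.write(g + "\n")


def read_gene_sets(path: str) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``.

    The description field is retained in parsing but unused.  Genes listed
    twice within a set are deduplicated, first occurrence kept.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ImmstratError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise ImmstratError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ImmstratError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(sets=sets)


def write_gene_sets(sets: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def intersect_panel(
    matrix: ExpressionMatrix, panel: GenePanel
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to panel genes, preserving the matrix's gene order.

    Returns the restricted matrix and the sorted list of panel genes not
    found in the matrix.  An empty intersection is an error: no clustering
    is possible without shared genes.
    """
    keep = [g for g in matrix.genes if g in panel.genes]
    missing = sorted(panel.genes - set(matrix.genes))
    if not keep:
        raise ImmstratError(
            f"panel {panel.name!r} shares no genes with the expression matrix"
        )
    return ExpressionMatrix(matrix.data.loc[keep]), missing


def mean_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean zero across samples (classifier convention)."""
    if matrix.shape[1] < 2:
        raise ImmstratError("mean centering needs at least 2 samples")
    centered = matrix.data.sub(matrix.data.mean(axis=1), axis=0)
    return ExpressionMatrix(centered)
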
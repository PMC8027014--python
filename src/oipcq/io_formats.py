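"""Reading and writing expression matrices, gold-standard edge lists and
inferred skeletons in the plain-text dialects used by the DREAM in-silico
network challenges.

Expression files are delimited text with a header of gene names and one
sample per row (genes on columns); the transposed layout (genes on rows,
one gene per line with its values) is also accepted. Gold standards and
predictions are 3-column edge lists ``geneA<TAB>geneB<TAB>flag`` where flag
1 marks a present edge; 2-column lines are treated as flag 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .skeleton import Skeleton

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_gold_standard",
    "write_network",
    "write_expression",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Named genes × samples expression matrix.

    ``values`` has one column per gene (matching ``gene_ids``) and one row
    per sample. Entries are finite reals; at least two samples are required
    so that sample covariance is defined.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            for g in self.gene_ids:
                if list(self.gene_ids).count(g) > 1:
                    raise ValueError(f"duplicate gene id {g!r}")
        if any(not g for g in self.gene_ids):
            raise ValueError("gene ids must be non-empty strings")
        if values.shape[0] < 2:
            raise ValueError("at least 2 samples are required")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at sample {r}, gene {self.gene_ids[c]!r}"
            )
        object.__setattr__(
            self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    def column_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.column_index(gene)]

    def reorder_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Same data with columns permuted to the given gene order."""
        ids = tuple(gene_ids)
        if set(ids) != set(self.gene_ids) or len(ids) != len(self.gene_ids):
            raise ValueError("gene order must be a permutation of the gene ids")
        cols = [self.column_index(g) for g in ids]
        return ExpressionMatrix(ids, self.values[:, cols])

    def subset_samples(self, rows: Iterable[int]) -> "ExpressionMatrix":
        idx = np.asarray(list(rows), dtype=int)
        return ExpressionMatrix(self.gene_ids, self.values[idx, :])

    def zscore(self) -> "ExpressionMatrix":
        """Per-gene standardization (mean 0, sd 1). Off by default in all
        pipelines; exposed for data sets that need it."""
        v = self.values
        sd = v.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(self.gene_ids, (v - v.mean(axis=0)) / sd)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.gene_ids))


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    genes_in: Literal["columns", "rows", "auto"] = "auto",
    normalize: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression file.

    ``genes_in="columns"`` expects a header row of gene names with numeric
    sample rows below; ``"rows"`` expects one gene per line, its id first.
    ``"auto"`` picks columns when the second line is fully numeric, rows
    otherwise. ``normalize=True`` z-scores each gene after reading.
    """
    path = Path(path)
    text = path.read_text()
    sep = delimiter if delimiter is not None else _sniff_delimiter(text)
    rows = [line.split(sep) for line in text.splitlines() if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty expression file")
    rows = [[tok.strip() for tok in r] for r in rows]

    if genes_in == "auto":
        genes_in = (
            "columns"
            if len(rows) > 1 and all(_is_number(t) for t in rows[1])
            else "rows"
        )

    if genes_in == "columns":
        gene_ids = tuple(rows[0])
        data_rows = rows[1:]
        matrix = np.empty((len(data_rows), len(gene_ids)), dtype=float)
        for i, r in enumerate(data_rows):
            if len(r) != len(gene_ids):
                raise ValueError(
                    f"{path}: line {i + 2} has {len(r)} fields, expected {len(gene_ids)}"
                )
            for j, tok in enumerate(r):
                if not _is_number(tok):
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at line {i + 2}, column {j + 1}"
                    )
                matrix[i, j] = float(tok)
    elif genes_in == "rows":
        gene_ids = tuple(r[0] for r in rows)
        n_samples = len(rows[0]) - 1
        matrix = np.empty((n_samples, len(gene_ids)), dtype=float)
        for j, r in enumerate(rows):
            if len(r) - 1 != n_samples:
                raise ValueError(
                    f"{path}: line {j + 1} has {len(r) - 1} values, expected {n_samples}"
                )
            for i, tok in enumerate(r[1:]):
                if not _is_number(tok):
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at line {j + 1}, column {i + 2}"
                    )
                matrix[i, j] = float(tok)
    else:
        raise ValueError(f"genes_in must be 'columns', 'rows' or 'auto', got {genes_in!r}")

    expr = ExpressionMatrix(gene_ids, matrix)
    return expr.zscore() if normalize else expr


def read_gold_standard(path: str | Path, gene_ids: Iterable[str]) -> Skeleton:
    """Read a DREAM-style edge list into an undirected skeleton.

    Lines are ``geneA<sep>geneB<sep>flag`` (tab or whitespace separated);
    flag 0 lines are ignored and a missing flag means 1. Directed duplicates
    (A B and B A) collapse to a single undirected edge. Gene matching is
    case-sensitive and exact.
    """
    path = Path(path)
    ids = tuple(gene_ids)
    known = set(ids)
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) == 2:
            a, b, flag = parts[0], parts[1], "1"
        elif len(parts) == 3:
            a, b, flag = parts
        else:
            raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
        if flag not in {"0", "1"}:
            raise ValueError(
                f"{path}: line {lineno}: flag must be 0 or 1, got {flag!r}"
            )
        if flag == "0":
            continue
        if a == b:
            raise ValueError(f"{path}: line {lineno}: self-edge on {a!r}")
        for g in (a, b):
            if g not in known:
                raise ValueError(
                    f"{path}: line {lineno}: gene {g!r} not in the expression gene set"
                )
        edges.add((a, b) if a < b else (b, a))
    return Skeleton(ids, edges)


def write_network(
    skeleton: Skeleton,
    path: str | Path,
    format: Literal["edgelist", "adjacency", "sif"] = "edgelist",
) -> None:
    """Write a skeleton as a canonical (lexicographically sorted) edge list,
    a symmetric 0/1 adjacency matrix with a gene header, or a SIF file."""
    path = Path(path)
    edges = sorted(skeleton.edges)
    if format == "edgelist":
        path.write_text("".join(f"{a}\t{b}\t1\n" for a, b in edges))
    elif format == "sif":
        path.write_text("".join(f"{a}\tpp\t{b}\n" for a, b in edges))
    elif format == "adjacency":
        ids = sorted(skeleton.gene_ids)
        pos = {g: i for i, g in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)), dtype=int)
        for a, b in edges:
            mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = 1
        lines = ["\t" + "\t".join(ids)]
        for g in ids:
            lines.append(g + "\t" + "\t".join(str(v) for v in mat[pos[g]]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write an expression matrix in the genes-on-columns dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(expr.gene_ids) + "\n")
        for row in expr.values:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")
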
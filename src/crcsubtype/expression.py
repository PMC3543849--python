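"""Expression-matrix container, I/O, and preprocessing conventions.

Expression values are RMA-style log2 intensities, one row per probe set and
one column per sample.  The container is a thin wrapper around a pandas
DataFrame that enforces the invariants the downstream factorization code
relies on: finite values, unique identifiers, and (for NMF input)
nonnegativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_annotation",
    "read_batch_map",
    "mean_center_rows",
    "average_replicates",
    "top_variance_probes",
]


@dataclass
class ExpressionMatrix:
    """Probe-set x sample log2 expression with optional per-sample batch tags.

    Parameters
    ----------
    data
        DataFrame of shape (n_probes, n_samples); index = probe ids,
        columns = sample ids.
    batches
        Optional map sample id -> batch tag, used for per-batch centering.
    """

    data: pd.DataFrame
    batches: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.batches is not None:
            self.batches = dict(self.batches)

    # -- convenience accessors -------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(
        self,
        probes: list[str] | None = None,
        samples: list[str] | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given probes and/or samples (order preserved)."""
        data = self.data
        if probes is not None:
            missing = [p for p in probes if p not in data.index]
            if missing:
                raise KeyError(f"probes not in matrix: {missing[:5]}")
            data = data.loc[probes]
        if samples is not None:
            missing = [s for s in samples if s not in data.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            data = data[samples]
        batches = None
        if self.batches is not None:
            keep = data.columns
            batches = {s: self.batches[s] for s in keep if s in self.batches}
        return ExpressionMatrix(data.copy(), batches)

    def require_nonnegative(self) -> None:
        """Raise if any value is negative (NMF input contract)."""
        if self.data.size and self.data.to_numpy().min() < 0:
            raise ValueError("expression matrix has negative entries; NMF input must be nonnegative")


@dataclass
class ProbeAnnotation:
    """Many-to-one probe set -> gene mapping.

    ``table`` is indexed by probe id with columns ``gene_symbol`` and
    ``gene_id``; each mapped probe maps to exactly one gene entry.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"probe mapped more than once: {dup!r}")
        for col in ("gene_symbol",):
            if col not in self.table.columns:
                raise ValueError(f"annotation table missing column {col!r}")

    def gene_for(self, probe_id: str) -> str | None:
        if probe_id in self.table.index:
            return str(self.table.loc[probe_id, "gene_symbol"])
        return None

    def probes_for(self, gene_symbol: str) -> list[str]:
        mask = self.table["gene_symbol"] == gene_symbol
        return list(self.table.index[mask])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a tab-delimited expression table (probes x samples).

    First column holds probe ids, header row holds sample ids, body is
    numeric.  Duplicated ids, non-numeric cells and empty files raise
    ``ValueError`` naming the offending entry.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header:
        names = header.split("\t")[1:]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise ValueError(f"duplicate sample id in {path}: {sorted(dups)[0]!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression file: {path}") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"expression file has no data rows/columns: {path}")
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate probe id in {path}: {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id in {path}: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at probe {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iloc[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value in {path} at probe {raw.index[r]!r}, sample {raw.columns[c]!r}")
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as a TSV readable by :func:`read_expression_matrix`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe->gene TSV with columns probe_id, gene_symbol[, gene_id]."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(table.columns)
    if "probe_id" not in cols or "gene_symbol" not in cols:
        raise ValueError("annotation file must have columns probe_id and gene_symbol")
    table = table.set_index("probe_id")
    if "gene_id" not in table.columns:
        table["gene_id"] = ""
    return ProbeAnnotation(table)


def read_batch_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, batch) into a dict."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("batch map needs two columns: sample_id, batch")
    sample_col, batch_col = table.columns[:2]
    if table[sample_col].duplicated().any():
        dup = table[sample_col][table[sample_col].duplicated()].iloc[0]
        raise ValueError(f"sample listed twice in batch map: {dup!r}")
    return dict(zip(table[sample_col], table[batch_col]))


# ---------------------------------------------------------------------------
# Preprocessing conventions
# ---------------------------------------------------------------------------

def mean_center_rows(expr: ExpressionMatrix, by_batch: bool = False) -> ExpressionMatrix:
    """Subtract per-probe row means, optionally within each batch.

    Per-batch centering removes dataset-level shifts when several panels are
    analyzed together.  Requires a batch label for every sample when
    ``by_batch`` is set.
    """
    data = expr.data.copy()
    if by_batch:
        if expr.batches is None:
            raise ValueError("by_batch centering requested but no batch labels present")
        missing = [s for s in data.columns if s not in expr.batches]
        if missing:
            raise ValueError(f"samples missing batch labels: {missing[:5]}")
        for batch in sorted(set(expr.batches[s] for s in data.columns)):
            cols = [s for s in data.columns if expr.batches[s] == batch]
            block = data[cols]
            data[cols] = block.sub(block.mean(axis=1), axis=0)
    else:
        data = data.sub(data.mean(axis=1), axis=0)
    return ExpressionMatrix(data, expr.batches)


def average_replicates(expr: ExpressionMatrix, replicate_map: Mapping[str, str]) -> ExpressionMatrix:
    """Average replicate columns into one column per replicate group.

    ``replicate_map`` maps every sample id to a group id; the output has one
    column per group, ordered by first appearance, holding the arithmetic
    mean of member columns.
    """
    missing = [s for s in expr.sample_ids if s not in replicate_map]
    if missing:
        raise ValueError(f"samples missing from replicate map: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        groups.setdefault(replicate_map[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"replicate group {g!r} has no members")
    out = pd.DataFrame(
        {g: expr.data[members].mean(axis=1) for g, members in groups.items()},
        index=expr.data.index,
    )
    return ExpressionMatrix(out)


def top_variance_probes(expr: ExpressionMatrix, n: int) -> list[str]:
    """Ids of the ``n`` probes with largest sample variance, descending.

    Variance is the unbiased (n-1 denominator) sample variance across all
    columns; ties break lexicographically by probe id for determinism.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > expr.shape[0]:
        raise ValueError(f"n={n} exceeds number of probes ({expr.shape[0]})")
    var = expr.data.var(axis=1, ddof=1)
    order = sorted(expr.probe_ids, key=lambda p: (-var[p], p))
    return order[:n]
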
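"""Directional gene-signature scores (EMT and published subtype signatures).

A directional signature is a pair of gene lists — genes up- and
down-regulated in some phenotype (e.g. mesenchymal vs epithelial state).
A sample's score is the mean expression of the up genes minus the mean
expression of the down genes, so a positive EMT score means a more
mesenchymal profile.  Published two-group signatures (e.g. type B vs type A)
fit the same container with one group as "up" and the other as "down".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .expression import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "DirectionalSignature",
    "merge_directional_signatures",
    "signature_difference_score",
    "read_directional_signature",
    "write_directional_signature",
]


@dataclass
class DirectionalSignature:
    """Up/down gene lists with the source each gene came from."""

    up: list[str]
    down: list[str]
    sources: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = list(dict.fromkeys(self.up))
        self.down = list(dict.fromkeys(self.down))
        clash = set(self.up) & set(self.down)
        if clash:
            raise ValueError(f"genes in both up and down lists: {sorted(clash)[:5]}")


def merge_directional_signatures(sigs: Iterable[DirectionalSignature]) -> DirectionalSignature:
    """Union of several directional signatures with conflict removal.

    A gene annotated up in one source and down in another carries no
    consistent direction and is removed entirely.
    """
    sigs = list(sigs)
    if not sigs:
        raise ValueError("need at least one signature to merge")
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for i, sig in enumerate(sigs):
        for g in sig.up:
            up.setdefault(g, []).extend(sig.sources.get(g, (f"source{i + 1}",)))
        for g in sig.down:
            down.setdefault(g, []).extend(sig.sources.get(g, (f"source{i + 1}",)))
    conflicted = set(up) & set(down)
    up_final = [g for g in up if g not in conflicted]
    down_final = [g for g in down if g not in conflicted]
    sources = {g: tuple(dict.fromkeys(up[g])) for g in up_final}
    sources.update({g: tuple(dict.fromkeys(down[g])) for g in down_final})
    return DirectionalSignature(up=up_final, down=down_final, sources=sources)


def _gene_level(expr: ExpressionMatrix, annotation: ProbeAnnotation | None) -> pd.DataFrame:
    """Collapse probe rows to gene rows by averaging probes per gene."""
    if annotation is None:
        return expr.data
    genes = expr.data.join(annotation.table["gene_symbol"], how="inner")
    if genes.empty:
        raise ValueError("no probes of the matrix are covered by the annotation")
    return genes.groupby("gene_symbol").mean()


def signature_difference_score(
    expr: ExpressionMatrix,
    sig: DirectionalSignature,
    annotation: ProbeAnnotation | None = None,
) -> pd.Series:
    """Per-sample score: mean expression over up genes - mean over down genes.

    With an annotation, probe rows are first averaged per gene; otherwise row
    ids are treated as gene ids directly.  Both gene lists must have at least
    one member present in the matrix.
    """
    gene_expr = _gene_level(expr, annotation)
    up = [g for g in sig.up if g in gene_expr.index]
    down = [g for g in sig.down if g in gene_expr.index]
    if not up or not down:
        missing_up = [g for g in sig.up if g not in gene_expr.index]
        missing_down = [g for g in sig.down if g not in gene_expr.index]
        raise ValueError(
            f"signature genes absent from matrix: up missing {missing_up[:10]}, "
            f"down missing {missing_down[:10]}"
        )
    score = gene_expr.loc[up].mean(axis=0) - gene_expr.loc[down].mean(axis=0)
    score.name = "score"
    return score


def read_directional_signature(path: str | Path) -> DirectionalSignature:
    """Read a TSV with columns gene_symbol, direction in {up, down}[, source]."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_symbol", "direction"}
    if not need <= set(table.columns):
        raise ValueError("signature file needs columns gene_symbol and direction")
    bad = ~table["direction"].isin(["up", "down"])
    if bad.any():
        raise ValueError(f"direction must be 'up' or 'down', got {table['direction'][bad].iloc[0]!r}")
    if "source" not in table.columns:
        table["source"] = "file"
    sources: dict[str, tuple[str, ...]] = {}
    for g, block in table.groupby("gene_symbol"):
        sources[g] = tuple(dict.fromkeys(block["source"]))
    up = list(table.loc[table["direction"] == "up", "gene_symbol"].drop_duplicates())
    down = list(table.loc[table["direction"] == "down", "gene_symbol"].drop_duplicates())
    return DirectionalSignature(up=up, down=down, sources=sources)


def write_directional_signature(sig: DirectionalSignature, path: str | Path) -> None:
    rows = [
        {"gene_symbol": g, "direction": d, "source": ",".join(sig.sources.get(g, ()))}
        for d, genes in (("up", sig.up), ("down", sig.down))
        for g in genes
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["gene_symbol", "direction", "source"]).to_csv(
        path, sep="\t", index=False
    )
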
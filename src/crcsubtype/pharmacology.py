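"""Drug-response centering, target pooling, and subtype comparisons.

Potencies (EC50 or IC50 concentrations) are compared on the centered
negative-log scale: per compound, v = -log(potency) minus the mean of v over
all cell lines with data, so a positive value means the line is more
sensitive to the compound than the panel average.  Compounds sharing a
molecular target are pooled, and per-subtype sensitivity is summarized and
compared across the subtype assignment of the cell lines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DrugResponseTable",
    "SubtypeResponse",
    "center_log_potency",
    "pool_by_target",
    "subtype_response_summary",
    "compare_subtype_response",
    "read_drug_response",
    "read_target_map",
]

logger = logging.getLogger(__name__)


@dataclass
class DrugResponseTable:
    """Cell line x compound potencies with a compound -> target map.

    ``potencies`` has cell lines as rows and compounds as columns; missing
    measurements are NaN, present ones must be positive concentrations.
    ``log_base`` ("10" or "e") sets the negative-log transform used for
    centering (base 10 for EC50 panels, natural log for IC50 panels).
    """

    potencies: pd.DataFrame
    log_base: str = "10"
    targets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.log_base not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")
        vals = self.potencies.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("potencies must be positive where present")


@dataclass
class SubtypeResponse:
    """Mean centered sensitivity of one subtype for one target."""

    target: str
    subtype: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a subtype summary needs at least one cell line")


def center_log_potency(table: DrugResponseTable) -> pd.DataFrame:
    """Per-compound centered -log potency (positive = more sensitive).

    For each compound, v = -log_base(potency); the mean of v over cell lines
    with data is subtracted, so each column sums to zero over its measured
    entries.
    """
    vals = table.potencies.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("potencies must be positive")
    log = np.log10 if table.log_base == "10" else np.log
    neg_log = -log(table.potencies.astype(float))
    return neg_log.sub(neg_log.mean(axis=0, skipna=True), axis=1)


def pool_by_target(
    centered: pd.DataFrame,
    target_map: Mapping[str, str],
) -> dict[str, dict[str, list[float]]]:
    """Group centered values by target: target -> cell line -> value list.

    Compounds without a target mapping are excluded with a warning; missing
    measurements are skipped.
    """
    pooled: dict[str, dict[str, list[float]]] = {}
    for compound in centered.columns:
        target = target_map.get(compound)
        if target is None:
            logger.warning("compound %r has no target mapping; excluded from pooling", compound)
            continue
        col = centered[compound]
        bucket = pooled.setdefault(target, {})
        for line, value in col.items():
            if pd.notna(value):
                bucket.setdefault(line, []).append(float(value))
    return pooled


def _line_means(pooled: dict[str, dict[str, list[float]]], target: str) -> dict[str, float]:
    if target not in pooled:
        raise KeyError(f"no pooled data for target {target!r}")
    return {line: float(np.mean(v)) for line, v in pooled[target].items() if v}


def _labels_of(assignment, level: str) -> dict[str, str]:
    if hasattr(assignment, "labels"):
        return assignment.labels(level)
    return dict(assignment)


def subtype_response_summary(
    pooled: dict[str, dict[str, list[float]]],
    assignment,
    target: str,
    level: str = "subtype",
) -> list[SubtypeResponse]:
    """Mean and standard error of centered sensitivity per subtype.

    Each cell line contributes its mean pooled value for the target; the
    summary is the mean over lines, its standard error (NaN for a single
    line), and the line count.  Subtypes without any measured line are
    omitted with a log message.  ``assignment`` is a SubtypeAssignment or a
    plain cell line -> label mapping.
    """
    labels = _labels_of(assignment, level)
    line_means = _line_means(pooled, target)
    out: list[SubtypeResponse] = []
    for subtype in sorted(set(labels.values())):
        values = [line_means[l] for l in sorted(line_means) if labels.get(l) == subtype]
        if not values:
            logger.info("subtype %s has no data for target %s; omitted", subtype, target)
            continue
        arr = np.asarray(values)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        out.append(SubtypeResponse(target=target, subtype=subtype, mean=float(arr.mean()), se=se, n=len(arr)))
    if not out:
        raise ValueError(f"no assigned cell line has data for target {target!r}")
    return out


def compare_subtype_response(
    pooled: dict[str, dict[str, list[float]]],
    assignment,
    target: str,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    test: str = "wilcoxon",
    level: str = "subtype",
) -> float:
    """Two-sided p-value comparing per-line sensitivity of two label groups.

    ``group_a``/``group_b`` are subtype labels (or lists of labels to merge,
    e.g. all subtypes of one type).  The default test is the Wilcoxon
    rank-sum on per-line mean centered values (exact when sample sizes are
    small and tie-free); ``test="t"`` switches to Welch's t-test.
    """
    labels = _labels_of(assignment, level)
    line_means = _line_means(pooled, target)
    ga = {group_a} if isinstance(group_a, str) else set(group_a)
    gb = {group_b} if isinstance(group_b, str) else set(group_b)
    xa = [line_means[l] for l in sorted(line_means) if labels.get(l) in ga]
    xb = [line_means[l] for l in sorted(line_means) if labels.get(l) in gb]
    if not xa or not xb:
        raise ValueError(f"empty comparison group for target {target!r}")
    if test == "wilcoxon":
        return float(stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto").pvalue)
    if test == "t":
        return float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_drug_response(
    path: str | Path,
    log_base: str = "10",
    target_map: Mapping[str, str] | None = None,
) -> DrugResponseTable:
    """Read a long-format potency TSV (cell_line, compound, potency).

    Replicate measurements of the same (cell line, compound) pair are
    collapsed with the geometric mean before the log transform, the
    conventional summary for log-normally distributed potencies.
    """
    table = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "compound": str})
    need = {"cell_line", "compound", "potency"}
    if not need <= set(table.columns):
        raise ValueError("potency file needs columns cell_line, compound, potency")
    table["potency"] = pd.to_numeric(table["potency"], errors="raise")
    if (table["potency"] <= 0).any():
        bad = table.loc[table["potency"] <= 0].iloc[0]
        raise ValueError(f"non-positive potency for {bad['cell_line']}/{bad['compound']}")
    geo = (
        table.assign(log_potency=np.log(table["potency"]))
        .groupby(["cell_line", "compound"])["log_potency"]
        .mean()
        .pipe(np.exp)
        .unstack("compound")
    )
    return DrugResponseTable(potencies=geo, log_base=log_base, targets=dict(target_map or {}))


def read_target_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (compound, target)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("target map needs two columns: compound, target")
    comp_col, target_col = table.columns[:2]
    if table[comp_col].duplicated().any():
        dup = table[comp_col][table[comp_col].duplicated()].iloc[0]
        raise ValueError(f"compound mapped to more than one target: {dup!r}")
    return dict(zip(table[comp_col], table[target_col]))
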
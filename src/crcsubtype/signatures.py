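"""Subtype signature derivation and multiple-testing utilities.

A subtype signature is the set of probe sets significantly up-regulated in
one core cluster relative to every sibling core cluster: among the
top-variance probes, a probe enters subtype S's signature iff each pairwise
t-test against another core reaches Benjamini-Hochberg FDR below the cutoff
with a higher mean in S.  Signatures of sibling subtypes are disjoint by
construction (a probe cannot have the higher mean in two groups of the same
pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, top_variance_probes

__all__ = [
    "SubtypeSignature",
    "two_sample_t",
    "benjamini_hochberg",
    "derive_signatures",
    "signature_overlap_test",
    "write_signatures",
    "read_signatures",
]


@dataclass
class SubtypeSignature:
    """Up-regulated probe list for one subtype with per-probe statistics.

    ``stats`` is indexed by probe id with columns t, p, fdr, mean_diff; for
    more than two siblings the recorded statistics come from the weakest
    (largest-FDR) pairwise comparison and the smallest mean difference, i.e.
    the binding constraint.
    """

    label: str
    probe_ids: list[str]
    stats: pd.DataFrame


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``variant`` selects Welch (unequal variances, default) or Student
    (pooled variance).  Degenerate input with zero variance in both groups
    and equal means returns (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in t-test input")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_ttests(A: np.ndarray, B: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-tests for matrices with samples in columns."""
    res = stats.ttest_ind(A, B, axis=1, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # rows with zero variance in both groups: t-test undefined
    degenerate = np.isnan(t)
    if degenerate.any():
        d = A.mean(axis=1)[degenerate] - B.mean(axis=1)[degenerate]
        t[degenerate] = np.where(d == 0, 0.0, np.where(d > 0, np.inf, -np.inf))
        p[degenerate] = np.where(d == 0, 1.0, 0.0)
    return t, p


def derive_signatures(
    expr: ExpressionMatrix,
    cores: Iterable[tuple[str, list[str]]] | "CoreClusterSet",
    n_top: int = 5000,
    fdr_cutoff: float = 0.01,
    variant: str = "welch",
) -> list[SubtypeSignature]:
    """Derive per-subtype up-regulated signatures from core clusters.

    Variance filtering to the ``n_top`` most variable probes is computed over
    the core samples; each ordered pair of cores is compared by row-wise
    t-tests with per-comparison BH correction.  A probe enters subtype S's
    signature iff it is significant with the higher mean in S against every
    sibling.

    ``cores`` is either a ``CoreClusterSet`` or an iterable of
    (label, sample id list) pairs.
    """
    pairs = _as_labeled_cores(cores)
    if len(pairs) < 2:
        raise ValueError("need at least 2 core clusters to derive signatures")
    for label, samples in pairs:
        if len(samples) == 0:
            raise ValueError(f"core cluster {label!r} is empty")
        if len(samples) < 2:
            raise ValueError(f"core cluster {label!r} has fewer than 2 samples")
    core_samples = [s for _, samples in pairs for s in samples]
    sub = expr.subset(samples=core_samples)
    n_top = min(n_top, sub.shape[0])
    top = top_variance_probes(sub, n_top)
    sub = sub.subset(probes=top)

    blocks = {label: sub.data[samples].to_numpy() for label, samples in pairs}
    labels = [label for label, _ in pairs]
    signatures: list[SubtypeSignature] = []
    for label in labels:
        A = blocks[label]
        keep = np.ones(len(top), dtype=bool)
        worst_fdr = np.full(len(top), -1.0)
        worst_t = np.zeros(len(top))
        worst_p = np.zeros(len(top))
        min_diff = np.full(len(top), np.inf)
        for other in labels:
            if other == label:
                continue
            B = blocks[other]
            t, p = _row_ttests(A, B, variant)
            fdr = benjamini_hochberg(p)
            diff = A.mean(axis=1) - B.mean(axis=1)
            keep &= (fdr < fdr_cutoff) & (diff > 0)
            binding = fdr > worst_fdr
            worst_fdr = np.where(binding, fdr, worst_fdr)
            worst_p = np.where(binding, p, worst_p)
            worst_t = np.where(binding, t, worst_t)
            min_diff = np.minimum(min_diff, diff)
        idx = np.nonzero(keep)[0]
        table = pd.DataFrame(
            {
                "t": worst_t[idx],
                "p": worst_p[idx],
                "fdr": worst_fdr[idx],
                "mean_diff": min_diff[idx],
            },
            index=pd.Index([top[i] for i in idx], name="probe_id"),
        ).sort_values(["fdr", "probe_id"], kind="mergesort")
        signatures.append(SubtypeSignature(label=label, probe_ids=list(table.index), stats=table))
    return signatures


def _as_labeled_cores(cores) -> list[tuple[str, list[str]]]:
    if hasattr(cores, "clusters"):  # CoreClusterSet without a circular import
        return [(str(i + 1), list(c)) for i, c in enumerate(cores.clusters)]
    return [(str(label), list(samples)) for label, samples in cores]


def signature_overlap_test(
    list_a: Sequence[str],
    list_b: Sequence[str],
    universe_size: int,
) -> tuple[int, float]:
    """Upper-tail hypergeometric test for the overlap of two gene lists.

    Returns (overlap count, P[overlap >= observed]) when drawing |b| items
    from a universe of ``universe_size`` containing |a| marked items.
    """
    a, b = set(list_a), set(list_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the lists")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def write_signatures(signatures: Iterable[SubtypeSignature], path: str | Path) -> None:
    """Write signatures as a TSV: subtype, probe_id, t, p, fdr, mean_diff."""
    rows = []
    for sig in signatures:
        table = sig.stats.reset_index()
        table.insert(0, "subtype", sig.label)
        rows.append(table)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subtype", "probe_id", "t", "p", "fdr", "mean_diff"]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_signatures(path: str | Path) -> list[SubtypeSignature]:
    """Read a signature TSV written by :func:`write_signatures`."""
    table = pd.read_csv(path, sep="\t", dtype={"subtype": str, "probe_id": str})
    out = []
    for label, block in table.groupby("subtype", sort=False):
        block = block.set_index("probe_id")[["t", "p", "fdr", "mean_diff"]]
        out.append(SubtypeSignature(label=str(label), probe_ids=list(block.index), stats=block))
    return out
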
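"""Two-step subtype assignment by hierarchical clustering on signature probes.

New datasets (tumors or cell lines, possibly from another array platform)
are assigned to subtypes by clustering the samples on the union of the
signature probe sets — first into the top-level types, then, within each
type, into that type's subtypes — and labeling each cluster by the signature
it over-expresses.  Distance is 1 - Pearson correlation with complete
linkage, on row mean-centered expression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats
from scipy.special import gammaln

from .expression import ExpressionMatrix, mean_center_rows
from .nmf import _force_k_clusters

__all__ = [
    "SubtypeModel",
    "SubtypeAssignment",
    "pearson_complete_clustering",
    "label_clusters",
    "two_step_assign",
    "compare_stratifications",
]

logger = logging.getLogger(__name__)


@dataclass
class SubtypeModel:
    """Two-level hierarchy of per-subtype up-regulated probe signatures.

    ``level1`` maps type label -> probe list; ``level2`` maps parent type
    label -> {subtype label -> probe list}.  Subtype labels are expected to
    be dotted children of their parent (e.g. "1.2" under "1").
    """

    level1: dict[str, list[str]]
    level2: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for parent in self.level2:
            if parent not in self.level1:
                raise ValueError(f"level-2 parent {parent!r} has no level-1 signature")

    def to_json(self, path: str | Path) -> None:
        payload = {"level1": self.level1, "level2": self.level2}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeModel":
        payload = json.loads(Path(path).read_text())
        return cls(level1=payload["level1"], level2=payload.get("level2", {}))


@dataclass
class SubtypeAssignment:
    """Per-sample (type, subtype) labels plus method provenance."""

    frame: pd.DataFrame  # index sample_id, columns: type, subtype
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, row in self.frame.iterrows():
            sub = row["subtype"]
            if isinstance(sub, str) and sub and not sub.startswith(str(row["type"]) + "."):
                raise ValueError(
                    f"subtype {sub!r} of sample {sample!r} is not a child of type {row['type']!r}"
                )

    def labels(self, level: str = "subtype") -> dict[str, str]:
        """Sample -> label map; subtype falls back to type where absent."""
        if level == "type":
            return dict(self.frame["type"])
        out = {}
        for sample, row in self.frame.iterrows():
            sub = row["subtype"]
            out[sample] = sub if isinstance(sub, str) and sub else row["type"]
        return out

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, sep="\t", index_label="sample_id")


def pearson_complete_clustering(expr: ExpressionMatrix | pd.DataFrame, k: int) -> pd.Series:
    """Cluster samples with 1 - Pearson distance and complete linkage.

    Returns a Series sample id -> cluster index 1..k.  A sample with zero
    variance over the probe subset has no defined correlation and raises.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    if data.shape[1] < k:
        raise ValueError(f"cannot cut {data.shape[1]} samples into {k} clusters")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 probes for correlation distance")
    X = data.to_numpy().T  # samples x probes
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = data.columns[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero variance over the probe subset")
    corr = np.corrcoef(X)
    d = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    Z = linkage(d, method="complete")
    labels = _force_k_clusters(fcluster(Z, k, criterion="maxclust"), k)
    return pd.Series(labels, index=data.columns, name="cluster")


def label_clusters(
    expr: ExpressionMatrix | pd.DataFrame,
    clusters: pd.Series,
    signatures: Mapping[str, Sequence[str]],
) -> dict[int, str]:
    """Match clusters one-to-one to the signatures they over-express.

    The score of (cluster c, signature S) is the mean row-centered expression
    of S's probes over c's samples; clusters are matched greedily to
    signatures in descending score order, ties broken by label order.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    cluster_ids = sorted(set(int(c) for c in clusters))
    sig_labels = sorted(signatures)
    if len(cluster_ids) != len(sig_labels):
        raise ValueError(
            f"{len(cluster_ids)} clusters but {len(sig_labels)} signatures; need a one-to-one match"
        )
    centered = data.sub(data.mean(axis=1), axis=0)
    scores = pd.DataFrame(index=cluster_ids, columns=sig_labels, dtype=float)
    for label in sig_labels:
        probes = [p for p in signatures[label] if p in centered.index]
        if not probes:
            raise ValueError(f"no probes of signature {label!r} present in the matrix")
        block = centered.loc[probes]
        for c in cluster_ids:
            members = clusters.index[clusters == c]
            scores.loc[c, label] = float(block[members].to_numpy().mean())
    if scores.to_numpy().std() == 0:
        logger.warning("all cluster/signature scores equal; falling back to label order")
        return {c: lbl for c, lbl in zip(cluster_ids, sig_labels)}
    mapping: dict[int, str] = {}
    remaining_c, remaining_s = list(cluster_ids), list(sig_labels)
    while remaining_c:
        best = max(
            ((c, s) for c in remaining_c for s in remaining_s),
            key=lambda cs: (scores.loc[cs[0], cs[1]], -remaining_c.index(cs[0]), -remaining_s.index(cs[1])),
        )
        mapping[best[0]] = best[1]
        remaining_c.remove(best[0])
        remaining_s.remove(best[1])
    return mapping


def two_step_assign(
    expr: ExpressionMatrix,
    model: SubtypeModel,
    min_coverage: float = 0.5,
    center: bool = True,
) -> SubtypeAssignment:
    """Assign every sample a (type, subtype) pair by two-step clustering.

    The matrix is row mean-centered (per batch when batch labels are
    present), samples are clustered on the union of level-1 signature probes
    into the number of types and each cluster labeled by its best-matching
    signature; the procedure repeats within each type on that type's level-2
    signatures.  Each signature must have at least ``min_coverage`` of its
    probes present in the matrix.
    """
    _check_coverage(expr, model, min_coverage)
    work = mean_center_rows(expr, by_batch=expr.batches is not None) if center else expr

    level1_probes = sorted({p for sig in model.level1.values() for p in sig if p in work.data.index})
    k1 = len(model.level1)
    clusters1 = pearson_complete_clustering(work.subset(probes=level1_probes), k1)
    lab1 = label_clusters(work.subset(probes=level1_probes), clusters1, model.level1)
    type_of = {s: lab1[int(c)] for s, c in clusters1.items()}

    subtype_of: dict[str, str] = {}
    for parent, sub_sigs in model.level2.items():
        members = [s for s in work.sample_ids if type_of[s] == parent]
        if len(members) < len(sub_sigs):
            logger.warning(
                "type %s has %d samples, fewer than its %d subtypes; level-2 skipped",
                parent, len(members), len(sub_sigs),
            )
            continue
        probes = sorted({p for sig in sub_sigs.values() for p in sig if p in work.data.index})
        # re-center within the type: the second step compares samples inside
        # one type, so per-probe means are taken over that group only
        branch = work.data[members]
        branch = branch.sub(branch.mean(axis=1), axis=0)
        sub_expr = ExpressionMatrix(branch.loc[probes])
        clusters2 = pearson_complete_clustering(sub_expr, len(sub_sigs))
        lab2 = label_clusters(sub_expr, clusters2, sub_sigs)
        for s, c in clusters2.items():
            subtype_of[s] = lab2[int(c)]

    frame = pd.DataFrame(
        {
            "type": [type_of[s] for s in expr.sample_ids],
            "subtype": [subtype_of.get(s, "") for s in expr.sample_ids],
        },
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )
    return SubtypeAssignment(
        frame=frame,
        provenance={"min_coverage": min_coverage, "centered": center, "n_samples": len(expr.sample_ids)},
    )


def _check_coverage(expr: ExpressionMatrix, model: SubtypeModel, floor: float) -> None:
    index = set(expr.data.index)
    all_sigs = dict(model.level1)
    for parent, subs in model.level2.items():
        all_sigs.update(subs)
    for label, probes in all_sigs.items():
        if not probes:
            raise ValueError(f"signature {label!r} is empty")
        present = [p for p in probes if p in index]
        if len(present) / len(probes) < floor:
            missing = [p for p in probes if p not in index]
            raise ValueError(
                f"signature {label!r} coverage {len(present)}/{len(probes)} below floor {floor:.2f}; "
                f"missing probes include {missing[:10]}"
            )


# ---------------------------------------------------------------------------
# Comparing stratifications
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table with fixed margins."""
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def compare_stratifications(
    labels_a: Mapping[str, str] | pd.Series,
    labels_b: Mapping[str, str] | pd.Series,
    n_sim: int = 10000,
    seed: int = 0,
) -> float:
    """Association p-value between two labelings of the same samples.

    2x2 tables use the exact two-sided Fisher test; larger tables use a
    Monte Carlo test with fixed margins (permutation of one labeling) and
    the table's hypergeometric probability as the extremeness statistic,
    p = (1 + #{simulated tables at most as probable}) / (1 + n_sim).
    """
    a = pd.Series(dict(labels_a)) if not isinstance(labels_a, pd.Series) else labels_a
    b = pd.Series(dict(labels_b)) if not isinstance(labels_b, pd.Series) else labels_b
    if set(a.index) != set(b.index):
        raise ValueError("labelings cover different samples")
    b = b[a.index]
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("each labeling needs at least 2 classes")
    table = pd.crosstab(a, b).to_numpy()
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    a_codes = pd.factorize(a)[0]
    b_codes = pd.factorize(b)[0]
    n_a, n_b = a_codes.max() + 1, b_codes.max() + 1
    observed = _log_table_prob(table)
    extreme = 0
    for _ in range(n_sim):
        perm = rng.permutation(b_codes)
        sim = np.zeros((n_a, n_b))
        np.add.at(sim, (a_codes, perm), 1)
        if _log_table_prob(sim) <= observed + 1e-12:
            extreme += 1
    return (1 + extreme) / (1 + n_sim)
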
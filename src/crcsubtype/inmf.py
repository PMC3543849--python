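"""Iterative consensus-NMF subtype discovery.

The procedure clusters samples with NMF on many random probe-set groups
instead of a single highly-variable gene list, which makes it unbiased with
respect to prior gene or pathway knowledge:

1. draw ``n_groups`` random probe-set groups of ``group_size`` probes;
2. for each group, run consensus NMF over a candidate rank range and pick
   the rank with maximal cophenetic correlation; the modal rank across
   groups is the cluster number K for this level;
3. cluster each group's samples into K (average-linkage cut of the group's
   consensus matrix) and count, per sample pair, in how many groups the two
   samples co-cluster;
4. cut a complete-linkage tree of the co-cluster dissimilarity into K
   clusters and trim each cluster to its *core*: samples whose mean
   co-cluster count with the other retained members stays at or above a
   threshold (80 of 100 groups by default);
5. derive per-cluster up-regulated signatures from the cores, assign every
   sample by hierarchical clustering on the signature probes, and recurse
   into each resulting cluster for the second level.

Each iteration operates on a more homogeneous set of samples, so the second
level resolves expression differences too subtle for the first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .nmf import (
    ConsensusResult,
    _consensus_with_stream,
    consensus_cut,
    select_rank,
)
from .signatures import SubtypeSignature, derive_signatures, write_signatures
from .assignment import (
    SubtypeAssignment,
    SubtypeModel,
    label_clusters,
    pearson_complete_clustering,
    two_step_assign,
)

__all__ = [
    "INMFConfig",
    "CoClusterMatrix",
    "CoreClusterSet",
    "LevelResult",
    "INMFResult",
    "WeakStructureError",
    "sample_probe_groups",
    "modal_rank",
    "cocluster_counts",
    "extract_core_clusters",
    "run_inmf",
]

logger = logging.getLogger(__name__)

#: mean cophenetic correlation at the modal rank below which a level is
#: flagged as lacking convincing cluster structure
WEAK_STRUCTURE_COPHENETIC = 0.9


class WeakStructureError(RuntimeError):
    """Raised when a level finds no reproducible cluster structure.

    Carries the per-rank mean cophenetic correlations observed (empty dict
    if the failure happened before any consensus run).
    """

    def __init__(self, message: str, cophenetic_by_rank: dict[int, float] | None = None):
        super().__init__(message)
        self.cophenetic_by_rank = dict(cophenetic_by_rank or {})

    @property
    def max_cophenetic(self) -> float | None:
        return max(self.cophenetic_by_rank.values()) if self.cophenetic_by_rank else None


@dataclass
class INMFConfig:
    """Settings for one iNMF run.

    The consensus stage uses short float32 NMF fits (``max_iter``/``tol``
    below): cluster memberships stabilize long before the divergence tail,
    and each level runs thousands of restarts.
    """

    n_groups: int = 100
    group_size: int = 300
    core_threshold: int = 80
    max_depth: int = 2
    min_cluster_size: int = 10
    seed: int = 0
    ranks: tuple[int, ...] = (2, 3, 4, 5)
    n_runs: int = 30
    max_iter: int = 200
    tol: float = 1e-4
    n_top_variance: int = 5000
    fdr_cutoff: float = 0.01
    redraw_groups_per_level: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.core_threshold <= self.n_groups):
            raise ValueError("core_threshold must be in (0, n_groups]")
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("n_groups and group_size must be positive")
        if not self.ranks:
            raise ValueError("candidate rank list is empty")


@dataclass
class CoClusterMatrix:
    """Symmetric sample x sample co-clustering counts over probe groups."""

    counts: np.ndarray
    sample_ids: list[str]
    n_groups: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape[0] != c.shape[1] or c.shape[0] != len(self.sample_ids):
            raise ValueError("counts shape does not match sample ids")
        if not np.array_equal(c, c.T):
            raise ValueError("co-cluster counts must be symmetric")
        if c.size and (c.min() < 0 or c.max() > self.n_groups):
            raise ValueError("counts must lie in [0, n_groups]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class CoreClusterSet:
    """Disjoint high-confidence sample clusters plus excluded samples."""

    clusters: list[list[str]]
    excluded: list[str]
    k: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & set(c):
                raise ValueError("core clusters are not disjoint")
            seen |= set(c)
        if seen & set(self.excluded):
            raise ValueError("excluded samples overlap a core cluster")

    @property
    def all_samples(self) -> list[str]:
        return [s for c in self.clusters for s in c] + list(self.excluded)


@dataclass
class LevelResult:
    """Everything one iNMF level produced for one input sample set."""

    modal_k: int
    per_group_ranks: list[int]
    cophenetic_by_rank: dict[int, float]  # mean over groups
    cocluster: CoClusterMatrix
    cores: CoreClusterSet
    signatures: list[SubtypeSignature]
    labels: dict[str, str]  # every input sample -> subtype label
    weak_structure: bool
    n_groups_used: int


@dataclass
class INMFResult:
    """Two-level iNMF outcome: per-level details, model, and assignment."""

    config: INMFConfig
    level1: LevelResult
    level2: dict[str, LevelResult]
    model: SubtypeModel
    assignment: SubtypeAssignment
    provenance: dict = field(default_factory=dict)

    def core_labels(self) -> dict[str, str]:
        """Sample -> label for samples in a core at the deepest level reached."""
        out: dict[str, str] = {}
        for i, cluster in enumerate(self.level1.cores.clusters):
            for s in cluster:
                out[s] = _core_label(self.level1, i)
        for parent, level in self.level2.items():
            for i, cluster in enumerate(level.cores.clusters):
                for s in cluster:
                    out[s] = _core_label(level, i)
        return out

    def save(self, outdir: str | Path) -> None:
        """Serialize result artifacts: TSV matrices/memberships + JSON provenance."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.level1.cocluster.to_frame().to_csv(outdir / "cocluster_level1.tsv", sep="\t")
        rows = []
        for label, level in [("1-level", self.level1)] + list(self.level2.items()):
            for i, cluster in enumerate(level.cores.clusters):
                for s in cluster:
                    rows.append({"level": label, "core": _core_label(level, i), "sample_id": s})
            for s in level.cores.excluded:
                rows.append({"level": label, "core": "excluded", "sample_id": s})
        pd.DataFrame(rows).to_csv(outdir / "core_clusters.tsv", sep="\t", index=False)
        write_signatures(
            self.level1.signatures + [s for lv in self.level2.values() for s in lv.signatures],
            outdir / "signatures.tsv",
        )
        self.model.to_json(outdir / "model.json")
        self.assignment.to_tsv(outdir / "assignment.tsv")
        prov = dict(self.provenance)
        prov["config"] = asdict(self.config)
        prov["per_group_ranks_level1"] = self.level1.per_group_ranks
        prov["modal_k_level1"] = self.level1.modal_k
        prov["modal_k_level2"] = {p: lv.modal_k for p, lv in self.level2.items()}
        (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


def _core_label(level: LevelResult, index: int) -> str:
    # signatures carry the canonical labels in cluster order
    return level.signatures[index].label if index < len(level.signatures) else str(index + 1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sample_probe_groups(
    probe_ids: Sequence[str],
    cfg: INMFConfig | None = None,
    n_groups: int | None = None,
    group_size: int | None = None,
    seed: int | None = None,
) -> list[list[str]]:
    """Draw random probe-set groups, each sampled without replacement.

    Groups are drawn independently of one another (a probe can appear in
    several groups) and reproducibly under the seed.
    """
    cfg = cfg or INMFConfig()
    n_groups = cfg.n_groups if n_groups is None else n_groups
    group_size = cfg.group_size if group_size is None else group_size
    seed = cfg.seed if seed is None else seed
    probe_ids = list(probe_ids)
    if group_size > len(probe_ids):
        raise ValueError(f"group_size {group_size} exceeds probe universe {len(probe_ids)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return [
        [probe_ids[i] for i in rng.choice(len(probe_ids), size=group_size, replace=False)]
        for _ in range(n_groups)
    ]


def modal_rank(per_group_ranks: Sequence[int]) -> int:
    """Most frequently selected rank; ties go to the smallest rank."""
    ranks = list(per_group_ranks)
    if not ranks:
        raise ValueError("empty rank list")
    counts: dict[int, int] = {}
    for k in ranks:
        counts[k] = counts.get(k, 0) + 1
    return min(counts, key=lambda k: (-counts[k], k))


def _group_consensus_labels(consensus: ConsensusResult, k: int) -> np.ndarray | None:
    """Cluster readout for one group: consensus tree cut into k, or None if
    the samples are not separable into k groups."""
    labels = consensus_cut(consensus.consensus, k)
    if len(np.unique(labels)) < k:
        return None
    return labels


def cocluster_counts(
    expr: ExpressionMatrix,
    groups: Sequence[Sequence[str]],
    k: int,
    cfg: INMFConfig | None = None,
    return_labels: bool = False,
) -> CoClusterMatrix | tuple[CoClusterMatrix, list[np.ndarray]]:
    """Count, per sample pair, the groups in which the pair co-clusters.

    Each group is clustered into ``k`` clusters by consensus NMF at rank k
    followed by an average-linkage cut of the consensus matrix.  Groups
    whose samples cannot be separated into k clusters are skipped with a
    warning and the effective group count reduced.  With ``return_labels``
    the per-group cluster labels are returned alongside the counts.
    """
    cfg = cfg or INMFConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    m = len(expr.sample_ids)
    counts = np.zeros((m, m), dtype=int)
    used = 0
    all_labels: list[np.ndarray] = []
    streams = np.random.SeedSequence((cfg.seed, 9)).spawn(len(groups))
    for gi, (group, stream) in enumerate(zip(groups, streams)):
        X = expr.subset(probes=list(group)).values
        try:
            cons = _consensus_with_stream(
                X, k, cfg.n_runs, stream, cfg.max_iter, cfg.tol, np.float32
            )
        except ValueError as err:
            logger.warning("group %d skipped: %s", gi, err)
            continue
        labels = _group_consensus_labels(cons, k)
        if labels is None:
            logger.warning("group %d skipped: samples not separable into %d clusters", gi, k)
            continue
        counts += labels[:, None] == labels[None, :]
        used += 1
        all_labels.append(labels)
    cc = CoClusterMatrix(counts=counts, sample_ids=expr.sample_ids, n_groups=used)
    return (cc, all_labels) if return_labels else cc


def extract_core_clusters(
    cc: CoClusterMatrix,
    k: int,
    threshold: int,
) -> CoreClusterSet:
    """Cut the co-cluster matrix into k clusters and trim each to its core.

    Complete-linkage clustering of the dissimilarity ``n_groups - counts``
    is cut into k clusters; within each cluster the member with the lowest
    mean co-cluster count against the other retained members is dropped
    iteratively until every remaining member's mean count is at or above
    ``threshold``.  Dropped samples are reported as excluded.
    """
    if threshold > cc.n_groups:
        raise ValueError("threshold exceeds the number of groups")
    m = len(cc.sample_ids)
    if k > m:
        raise ValueError(f"cannot form {k} clusters from {m} samples")
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dism = (cc.n_groups - cc.counts).astype(float)
    np.fill_diagonal(dism, 0.0)
    labels = fcluster(linkage(squareform(dism, checks=False), method="complete"), k, criterion="maxclust")
    from .nmf import _force_k_clusters

    labels = _force_k_clusters(labels, k)
    clusters: list[list[str]] = []
    excluded: list[str] = []
    for c in range(1, labels.max() + 1):
        member_idx = list(np.nonzero(labels == c)[0])
        retained = list(member_idx)
        while len(retained) > 1:
            block = cc.counts[np.ix_(retained, retained)]
            # mean co-cluster count with the *other* retained members
            means = (block.sum(axis=1) - np.diag(block)) / (len(retained) - 1)
            worst = int(np.argmin(means))
            if means[worst] >= threshold:
                break
            excluded.append(cc.sample_ids[retained[worst]])
            del retained[worst]
        clusters.append([cc.sample_ids[i] for i in retained])
    return CoreClusterSet(clusters=clusters, excluded=sorted(excluded), k=k)


# ---------------------------------------------------------------------------
# The iterative driver
# ---------------------------------------------------------------------------

def _run_level(
    expr: ExpressionMatrix,
    groups: Sequence[Sequence[str]],
    cfg: INMFConfig,
    label_prefix: str,
    seed_tag: int,
) -> LevelResult:
    """One iNMF level on one sample set.

    Raises :class:`WeakStructureError` when the samples do not support a
    reproducible split (too few samples, no separable groups, or fewer than
    two usable cores).
    """
    ranks = [r for r in cfg.ranks if r < len(expr.sample_ids)]
    if not ranks:
        raise WeakStructureError(
            f"no valid candidate ranks for {len(expr.sample_ids)} samples"
        )
    per_group_ranks: list[int] = []
    per_rank_coph: dict[int, list[float]] = {r: [] for r in ranks}
    selections = []
    streams = np.random.SeedSequence((cfg.seed, seed_tag)).spawn(len(groups))
    for group, stream in zip(groups, streams):
        X = expr.subset(probes=list(group)).values
        sel = select_rank(
            X, ranks, n_runs=cfg.n_runs, seed=stream,
            max_iter=cfg.max_iter, tol=cfg.tol, dtype=np.float32,
        )
        selections.append(sel)
        per_group_ranks.append(sel.best_rank)
        for r in ranks:
            per_rank_coph[r].append(sel.cophenetic[r])
    K = modal_rank(per_group_ranks)

    m = len(expr.sample_ids)
    counts = np.zeros((m, m), dtype=int)
    used = 0
    for sel in selections:
        labels = _group_consensus_labels(sel.consensus[K], K)
        if labels is None:
            continue
        counts += labels[:, None] == labels[None, :]
        used += 1
    mean_coph = {r: float(np.mean(per_rank_coph[r])) for r in ranks}
    if used == 0:
        raise WeakStructureError(
            f"no usable probe groups at level {label_prefix or '1'}", mean_coph
        )
    cc = CoClusterMatrix(counts=counts, sample_ids=expr.sample_ids, n_groups=used)
    threshold = int(round(cfg.core_threshold * used / cfg.n_groups))
    cores = extract_core_clusters(cc, K, threshold)

    # canonical cluster order: size descending, then first sample id
    order = sorted(
        range(len(cores.clusters)),
        key=lambda i: (-len(cores.clusters[i]), cores.clusters[i][0] if cores.clusters[i] else ""),
    )
    ordered = [cores.clusters[i] for i in order]
    # a core needs >= 2 samples to support a t-test; smaller ones are excluded
    usable_clusters = [c for c in ordered if len(c) >= 2]
    extra_excluded = [s for c in ordered if len(c) < 2 for s in c]
    cores = CoreClusterSet(
        clusters=usable_clusters,
        excluded=sorted(cores.excluded + extra_excluded),
        k=cores.k,
    )
    labels_for = [
        (f"{label_prefix}{i + 1}" if not label_prefix else f"{label_prefix}.{i + 1}")
        for i in range(len(usable_clusters))
    ]
    if len(usable_clusters) < 2:
        raise WeakStructureError(
            f"fewer than 2 usable cores at level {label_prefix or '1'}", mean_coph
        )
    signatures = derive_signatures(
        expr,
        list(zip(labels_for, usable_clusters)),
        n_top=cfg.n_top_variance,
        fdr_cutoff=cfg.fdr_cutoff,
    )
    if any(len(sig.probe_ids) == 0 for sig in signatures):
        raise WeakStructureError(
            f"empty signature at level {label_prefix or '1'} (cores indistinguishable)",
            mean_coph,
        )

    level_labels = _assign_level(expr, signatures)
    return LevelResult(
        modal_k=K,
        per_group_ranks=per_group_ranks,
        cophenetic_by_rank=mean_coph,
        cocluster=cc,
        cores=cores,
        signatures=signatures,
        labels=level_labels,
        weak_structure=mean_coph[K] < WEAK_STRUCTURE_COPHENETIC,
        n_groups_used=used,
    )


def _assign_level(expr: ExpressionMatrix, signatures: list[SubtypeSignature]) -> dict[str, str]:
    """Cluster all level samples on the signature probe union and label.

    Mirrors exactly what :func:`crcsubtype.assignment.two_step_assign` does
    at one level, so training-set assignment and model application agree.
    """
    sigs = {sig.label: sig.probe_ids for sig in signatures}
    probes = sorted({p for ids in sigs.values() for p in ids})
    centered = expr.data.sub(expr.data.mean(axis=1), axis=0)
    work = ExpressionMatrix(centered.loc[probes])
    clusters = pearson_complete_clustering(work, len(sigs))
    mapping = label_clusters(work, clusters, sigs)
    return {s: mapping[int(c)] for s, c in clusters.items()}


def run_inmf(expr: ExpressionMatrix, cfg: INMFConfig | None = None) -> INMFResult:
    """Run the full two-level iterative NMF subtype discovery.

    Level 1 runs on all samples; each resulting cluster with at least
    ``cfg.min_cluster_size`` samples is then re-analyzed independently with
    the same procedure (reusing the level-1 probe groups unless
    ``cfg.redraw_groups_per_level`` is set).  The returned result carries
    per-level details, the two-level signature model, and the assignment of
    every sample obtained by applying that model to the input matrix.
    """
    cfg = cfg or INMFConfig()
    expr.require_nonnegative()
    if cfg.group_size > expr.shape[0]:
        raise ValueError("group_size exceeds the number of probes")
    if len(expr.sample_ids) < 2 * min(cfg.ranks):
        raise ValueError("too few samples for the smallest candidate rank")

    groups = sample_probe_groups(expr.probe_ids, cfg)
    level1 = _run_level(expr, groups, cfg, label_prefix="", seed_tag=1)

    level2: dict[str, LevelResult] = {}
    if cfg.max_depth >= 2:
        for label in sorted({sig.label for sig in level1.signatures}):
            members = [s for s, lab in level1.labels.items() if lab == label]
            if len(members) < cfg.min_cluster_size:
                logger.info("cluster %s too small (%d) for a second split", label, len(members))
                continue
            sub = expr.subset(samples=members)
            if cfg.redraw_groups_per_level:
                sub_groups = sample_probe_groups(
                    expr.probe_ids, cfg, seed=cfg.seed + 1000 + int(label.replace(".", ""))
                )
            else:
                sub_groups = groups
            try:
                level2[label] = _run_level(
                    sub, sub_groups, cfg, label_prefix=label, seed_tag=100 + int(label)
                )
            except WeakStructureError as err:
                logger.info("cluster %s not split further: %s", label, err)

    model = SubtypeModel(
        level1={sig.label: sig.probe_ids for sig in level1.signatures},
        level2={
            parent: {sig.label: sig.probe_ids for sig in lv.signatures}
            for parent, lv in level2.items()
        },
    )
    assignment = two_step_assign(expr, model)
    provenance = {
        "n_samples": len(expr.sample_ids),
        "n_probes": expr.shape[0],
        "weak_structure_level1": level1.weak_structure,
        "max_cophenetic_level1": max(level1.cophenetic_by_rank.values()),
    }
    return INMFResult(
        config=cfg,
        level1=level1,
        level2=level2,
        model=model,
        assignment=assignment,
        provenance=provenance,
    )
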
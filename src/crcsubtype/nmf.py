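"""Nonnegative matrix factorization with consensus clustering.

Implements Brunet-style multiplicative updates minimizing the generalized
Kullback-Leibler divergence

    D(X || WH) = sum_ij [ X_ij log(X_ij / (WH)_ij) - X_ij + (WH)_ij ],

plus the consensus-clustering machinery built on repeated random restarts:
the consensus matrix (fraction of restarts in which two samples share a
cluster), the cophenetic correlation coefficient of that matrix, and rank
selection by maximal cophenetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "RankSelection",
    "nmf_factorize",
    "cluster_membership",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
]

#: ridge inside logarithms/denominators of the multiplicative updates
EPS = 1e-9


@dataclass
class NMFFactorization:
    """Result of one NMF run: X (n x m) ~= W (n x k) . H (k x m)."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    objective_trace: np.ndarray  # divergence at each recorded iteration
    trace_iterations: np.ndarray  # iteration numbers matching the trace
    seed: int | None
    n_iter: int
    converged: bool

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConsensusResult:
    """Consensus over restarts of NMF at a fixed rank."""

    rank: int
    consensus: np.ndarray  # m x m, symmetric, unit diagonal, in [0, 1]
    cophenetic: float
    n_runs: int
    run_labels: np.ndarray = field(repr=False, default=None)  # (n_runs, m)


@dataclass
class RankSelection:
    """Outcome of a cophenetic-correlation rank search."""

    best_rank: int
    cophenetic: dict[int, float]
    consensus: dict[int, ConsensusResult] = field(repr=False, default_factory=dict)


def _validate_input(X: np.ndarray, rank: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if X.min() < 0:
        raise ValueError("X contains negative entries; NMF requires nonnegative input")
    if not (1 <= rank <= min(X.shape)):
        raise ValueError(f"rank {rank} out of range for matrix of shape {X.shape}")
    return X


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    # X log(X/WH) - X + WH with the 0 log 0 = 0 convention; the ridge lives
    # only inside the logarithm so an exact fit reports divergence ~ 0
    return float(np.sum(X * np.log((X + EPS) / (WH + EPS))) - X.sum() + WH.sum())


def nmf_factorize(
    X: np.ndarray,
    rank: int,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    trace_every: int = 1,
    dtype: np.dtype = np.float64,
) -> NMFFactorization:
    """Factorize a nonnegative matrix by multiplicative KL updates.

    W and H are initialized i.i.d. uniform(0, 1) scaled so that the initial
    product matches X's mean, then updated with the standard multiplicative
    rules until the relative divergence change over a 10-iteration window
    falls below ``tol`` or ``max_iter`` is reached.

    Parameters
    ----------
    trace_every
        Record the divergence every this many iterations (1 = every
        iteration).  The convergence check runs every 10 iterations
        regardless.
    dtype
        float32 roughly halves runtime and is adequate for consensus
        clustering; float64 is the default for single factorizations.
    """
    X = _validate_input(X, rank)
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, None
    else:
        rng, seed_val = np.random.default_rng(seed), seed
    X = X.astype(dtype)
    n, m = X.shape
    scale = np.sqrt(max(X.mean(), EPS) / rank)
    W = (rng.uniform(0.0, 1.0, (n, rank)) * scale + EPS).astype(dtype)
    H = (rng.uniform(0.0, 1.0, (rank, m)) * scale + EPS).astype(dtype)

    trace: list[float] = []
    trace_iters: list[int] = []
    prev_check: float | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + EPS
        H *= (W.T @ (X / WH)) / (W.sum(axis=0)[:, None] + EPS)
        WH = W @ H + EPS
        W *= ((X / WH) @ H.T) / (H.sum(axis=1)[None, :] + EPS)
        record = it % trace_every == 0
        check = it % 10 == 0
        if record or check or it == max_iter:
            div = _kl_divergence(X, W @ H)
            if record or it == max_iter:
                trace.append(div)
                trace_iters.append(it)
            if check:
                if prev_check is not None and abs(prev_check - div) <= tol * max(abs(prev_check), EPS):
                    converged = True
                    if not (record or it == max_iter):
                        trace.append(div)
                        trace_iters.append(it)
                    break
                prev_check = div
    return NMFFactorization(
        W=np.asarray(W, dtype=float),
        H=np.asarray(H, dtype=float),
        rank=rank,
        objective_trace=np.asarray(trace, dtype=float),
        trace_iterations=np.asarray(trace_iters, dtype=int),
        seed=seed_val,
        n_iter=it,
        converged=converged,
    )


def cluster_membership(fact: NMFFactorization) -> np.ndarray:
    """Per-sample cluster labels in 1..k: argmax metagene coefficient.

    Ties break toward the lowest metagene index; an all-zero H column is an
    error (no metagene expresses the sample).
    """
    H = fact.H
    zero = np.all(H <= 0, axis=0)
    if zero.any():
        raise ValueError(f"all-zero H column at sample index {int(np.argmax(zero))}")
    return H.argmax(axis=0) + 1


def _consensus_from_labels(labels: np.ndarray) -> np.ndarray:
    """Fraction of runs in which each sample pair shares a cluster."""
    n_runs, m = labels.shape
    C = np.zeros((m, m))
    for r in range(n_runs):
        lab = labels[r]
        C += lab[:, None] == lab[None, :]
    return C / n_runs


def consensus_matrix(
    X: np.ndarray,
    rank: int,
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    dtype: np.dtype = np.float64,
) -> ConsensusResult:
    """Consensus clustering over ``n_runs`` seeded NMF restarts at one rank.

    Each restart clusters samples by argmax H; the consensus entry (i, j) is
    the fraction of restarts in which i and j land in the same cluster.
    Restart seeds are spawned from ``seed`` so different ranks/groups get
    independent streams.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = _validate_input(X, rank)
    m = X.shape[1]
    labels = np.empty((n_runs, m), dtype=int)
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    for r, stream in enumerate(streams):
        fact = nmf_factorize(
            X, rank, seed=np.random.default_rng(stream),
            max_iter=max_iter, tol=tol, trace_every=10, dtype=dtype,
        )
        labels[r] = cluster_membership(fact)
    C = _consensus_from_labels(labels)
    return ConsensusResult(
        rank=rank,
        consensus=C,
        cophenetic=cophenetic_coefficient(C),
        n_runs=n_runs,
        run_labels=labels,
    )


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity structure.

    Pearson correlation between the off-diagonal dissimilarities
    ``1 - consensus`` and the cophenetic distances of their average-linkage
    hierarchical clustering.  Values near 1 indicate stable, tree-like
    cluster structure.  If all dissimilarities are equal the hierarchy is
    trivially exact and the coefficient is defined as 1.
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(consensus, consensus.T, atol=1e-8):
        raise ValueError("consensus must be symmetric")
    if consensus.min() < -1e-8 or consensus.max() > 1 + 1e-8:
        raise ValueError("consensus entries must lie in [0, 1]")
    d = squareform(1.0 - consensus, checks=False)
    if d.size == 0 or np.ptp(d) < 1e-12:
        return 1.0
    Z = linkage(d, method="average")
    c, coph_d = cophenet(Z, d)
    if np.isnan(c):
        # degenerate: cophenetic distances constant although input is not
        return 1.0
    return float(c)


def consensus_cut(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut the average-linkage tree of ``1 - consensus`` into k clusters.

    Returns labels 1..k.  If tied merges leave fewer than k groups, the
    largest groups are split deterministically so exactly k come back.
    """
    m = consensus.shape[0]
    if k > m:
        raise ValueError(f"cannot cut {m} samples into {k} clusters")
    d = squareform(1.0 - consensus, checks=False)
    Z = linkage(d, method="average")
    labels = fcluster(Z, k, criterion="maxclust")
    labels = _force_k_clusters(labels, k)
    return labels


def _force_k_clusters(labels: np.ndarray, k: int) -> np.ndarray:
    """Ensure exactly k distinct labels by splitting the largest clusters."""
    labels = np.asarray(labels).copy()
    uniq = np.unique(labels)
    next_label = labels.max() + 1
    while len(uniq) < k:
        sizes = {u: int((labels == u).sum()) for u in uniq}
        big = max(uniq, key=lambda u: (sizes[u], -u))
        if sizes[big] < 2:
            break
        idx = np.nonzero(labels == big)[0][0]
        labels[idx] = next_label
        next_label += 1
        uniq = np.unique(labels)
    # relabel to 1..k' preserving first-appearance order
    remap = {u: i + 1 for i, u in enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([remap[u] for u in labels], dtype=int)


def select_rank(
    X: np.ndarray,
    ranks: list[int] | tuple[int, ...],
    n_runs: int = 30,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    dtype: np.dtype = np.float64,
) -> RankSelection:
    """Pick the factorization rank with maximal cophenetic correlation.

    Ties go to the smallest rank.  The per-rank consensus results are kept
    on the return value so callers can reuse them (e.g. for the co-cluster
    readout at the chosen rank).
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty candidate rank list")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(len(ranks))
    results: dict[int, ConsensusResult] = {}
    for rank, stream in zip(ranks, streams):
        results[rank] = _consensus_with_stream(X, rank, n_runs, stream, max_iter, tol, dtype)
    coph = {k: results[k].cophenetic for k in ranks}
    best = max(sorted(ranks), key=lambda k: (coph[k], -k))
    return RankSelection(best_rank=best, cophenetic=coph, consensus=results)


def _consensus_with_stream(
    X: np.ndarray,
    rank: int,
    n_runs: int,
    stream: np.random.SeedSequence,
    max_iter: int,
    tol: float,
    dtype: np.dtype,
) -> ConsensusResult:
    """consensus_matrix taking a SeedSequence (internal seeding plumbing)."""
    X = _validate_input(X, rank)
    m = X.shape[1]
    labels = np.empty((n_runs, m), dtype=int)
    for r, child in enumerate(stream.spawn(n_runs)):
        fact = nmf_factorize(
            X, rank, seed=np.random.default_rng(child),
            max_iter=max_iter, tol=tol, trace_every=10, dtype=dtype,
        )
        labels[r] = cluster_membership(fact)
    C = _consensus_from_labels(labels)
    return ConsensusResult(rank, C, cophenetic_coefficient(C), n_runs, labels)
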
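"""FosBin: partition pooled-assembly contigs into per-clone clusters.

Contigs from a pooled insert library are clustered by K-means on the
composition/coverage feature matrix, with k fixed to the known number of
pooled inserts. Clusterings are scored against truth labels with the
binning notions of sensitivity (fraction of contigs co-clustered with at
least one other contig of the same insert) and specificity (fraction of
clusters whose contigs all derive from one insert).

The K-means here is Lloyd's algorithm with k-means++ seeding and multiple
independent restarts. Reproducibility is a hard requirement for a
pipeline tool, so every random draw flows from the caller's seed: restart
``i`` uses child seed ``seed + i``, ties in point-to-centroid assignment
break toward the lowest cluster index, and empty clusters are repaired by
moving the point farthest from its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "BinAssignment",
    "fosbin_bin",
    "binning_sensitivity",
    "binning_specificity",
]


@dataclass
class BinAssignment:
    """A contig -> cluster mapping produced by one FosBin run."""

    contig_ids: list[str]
    cluster_of: dict[str, int]
    k: int
    inertia: float
    seed: int
    n_restarts: int

    def clusters(self) -> dict[int, set[str]]:
        """Non-empty clusters as cluster index -> set of contig ids."""
        out: dict[int, set[str]] = {}
        for cid, c in self.cluster_of.items():
            out.setdefault(c, set()).add(cid)
        return out

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.cluster_of[c] for c in self.contig_ids])


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances
    return ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all points coincide with a center
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """One restart of Lloyd's algorithm; returns (labels, inertia, trace)."""
    n = X.shape[0]
    centers = _kmeanspp_init(X, k, rng)
    labels = np.full(n, -1, dtype=int)
    trace: list[float] = []
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = _sq_dists(X, centers)
        labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        # empty-cluster repair: move the point farthest from its centroid
        for j in range(k):
            if (labels == j).any():
                continue
            assigned_d2 = d2[np.arange(n), labels]
            # points alone in their cluster must stay, or we just move the hole
            sizes = np.bincount(labels, minlength=k)
            movable = sizes[labels] > 1
            if not movable.any():
                break
            candidates = np.where(movable, assigned_d2, -np.inf)
            far = int(candidates.argmax())
            labels[far] = j
            d2[far, j] = 0.0
        inertia = 0.0
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            inertia += ((X[mask] - centers[j]) ** 2).sum()
        trace.append(float(inertia))
        if prev_inertia - inertia <= tol:
            break
        prev_inertia = inertia
    # final assignment against the converged centers
    d2 = _sq_dists(X, centers)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    trace.append(inertia)
    return labels, inertia, trace


def fosbin_bin(
    matrix: np.ndarray,
    k: int,
    seed: int = 1,
    n_restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    contig_ids: Optional[Sequence[str]] = None,
) -> BinAssignment:
    """Cluster feature rows into ``k`` bins, keeping the best of
    ``n_restarts`` independent k-means++ restarts (lowest inertia; ties go
    to the earliest restart). Deterministic given (matrix, k, seed,
    n_restarts).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows n={n}")
    if contig_ids is None:
        contig_ids = [str(i) for i in range(n)]
    if len(contig_ids) != n:
        raise ValueError("contig_ids length does not match matrix rows")

    best_labels: Optional[np.ndarray] = None
    best_inertia = np.inf
    for i in range(n_restarts):
        rng = np.random.default_rng(seed + i)
        labels, inertia, _ = _lloyd(X, k, rng, max_iter, tol)
        if inertia < best_inertia:
            best_inertia = inertia
            best_labels = labels
    assert best_labels is not None
    return BinAssignment(
        contig_ids=list(contig_ids),
        cluster_of={cid: int(c) for cid, c in zip(contig_ids, best_labels)},
        k=k,
        inertia=float(best_inertia),
        seed=seed,
        n_restarts=n_restarts,
    )


def _check_truth(assignment: BinAssignment, truth: Mapping[str, str]) -> None:
    missing = [c for c in assignment.contig_ids if c not in truth]
    if missing:
        raise ValueError(f"contigs missing from truth labels: {missing[:5]}")


def binning_sensitivity(
    assignment: BinAssignment,
    truth: Mapping[str, str],
    scored_contigs: Optional[set[str]] = None,
) -> float:
    """Fraction of contigs whose cluster holds at least one OTHER contig
    from the same insert. Contigs in singleton clusters never count.

    ``scored_contigs`` restricts the *scored* set (e.g. to contigs above a
    length cutoff) while companionship is still judged against the full
    clustering — misbinned contigs are typically the short ones, and this
    lets that be quantified.
    """
    _check_truth(assignment, truth)
    clusters = assignment.clusters()
    scored = [
        c for c in assignment.contig_ids
        if scored_contigs is None or c in scored_contigs
    ]
    if not scored:
        raise ValueError("no contigs left to score")
    correct = 0
    for cid in scored:
        members = clusters[assignment.cluster_of[cid]]
        if any(truth[m] == truth[cid] for m in members if m != cid):
            correct += 1
    return correct / len(scored)


def binning_specificity(
    assignment: BinAssignment, truth: Mapping[str, str]
) -> float:
    """Fraction of non-empty clusters whose contigs all share one insert.

    Singleton clusters are pure by this definition, which inflates the
    score when fragmentation produces many singletons — callers comparing
    across fragmentation levels should keep that in mind.
    """
    _check_truth(assignment, truth)
    clusters = assignment.clusters()
    pure = sum(
        1 for members in clusters.values()
        if len({truth[m] for m in members}) == 1
    )
    return pure / len(clusters)
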
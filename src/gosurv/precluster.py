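"""Partition each gene group into correlated subclusters.

Dissimilarity between two genes is 1 - Pearson correlation of their
expression profiles, so positively correlated genes are close and
anti-correlated genes are far apart.  Clustering is partitioning around
medoids (PAM): a greedy build phase followed by steepest-descent swaps,
minimizing the total dissimilarity of every gene to its nearest medoid.
The number of clusters K is chosen to maximize the mean intra-cluster
correlation (ICC) over K = 2..N-1 (capped at ``k_max``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gosurv.data import Dataset, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric gene-gene dissimilarity, d = 1 - Pearson correlation."""

    gene_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.gene_ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("dissimilarity diagonal must be zero")
        if self.d.min() < -1e-9 or self.d.max() > 2 + 1e-9:
            raise ValueError("dissimilarities must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusterAssignment:
    """A PAM solution: K medoids, nearest-medoid labels, and ICC summaries.

    ``labels`` are 0-based cluster indices aligned with the medoid list.
    """

    K: int
    medoid_indices: list[int]
    labels: np.ndarray
    objective: float
    per_cluster_icc: list[float]
    mean_icc: float
    gene_ids: list[str]

    @property
    def medoid_ids(self) -> list[str]:
        return [self.gene_ids[m] for m in self.medoid_indices]

    def members(self, k: int) -> list[str]:
        return [self.gene_ids[i] for i in np.flatnonzero(self.labels == k)]


@dataclass
class GroupClustering:
    group_id: str
    assignment: ClusterAssignment

    @property
    def K(self) -> int:
        return self.assignment.K


@dataclass
class PreclusteredGroups:
    """Per GO group, the selected cluster configuration."""

    by_group: dict[str, GroupClustering]

    @property
    def n_clusters_total(self) -> int:
        return sum(gc.K for gc in self.by_group.values())

    def cluster_table(self):
        """Long-format rows: (group_id, cluster_index, medoid_gene, member_gene)."""
        rows = []
        for gid in sorted(self.by_group):
            asg = self.by_group[gid].assignment
            for k in range(asg.K):
                medoid = asg.medoid_ids[k]
                for gene in asg.members(k):
                    rows.append((gid, k + 1, medoid, gene))
        return rows

    def summary_table(self):
        """Per-group rows: (group_id, N, K, mean_icc)."""
        return [
            (gid, len(gc.assignment.gene_ids), gc.K, gc.assignment.mean_icc)
            for gid, gc in sorted(self.by_group.items())
        ]

    def write(self, cluster_path, summary_path, sep="\t") -> None:
        with open(cluster_path, "w") as fh:
            fh.write(sep.join(["group_id", "cluster_index", "medoid_gene", "member_gene"]) + "\n")
            for row in self.cluster_table():
                fh.write(sep.join(str(v) for v in row) + "\n")
        with open(summary_path, "w") as fh:
            fh.write(sep.join(["group_id", "N", "K", "mean_icc"]) + "\n")
            for gid, n, k, icc in self.summary_table():
                fh.write(sep.join([gid, str(n), str(k), f"{icc:.6g}"]) + "\n")


def gene_correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between gene rows; zero-variance genes get Cor = 0.

    A flat gene carries no co-expression information, so rather than
    propagating NaN it is treated as uncorrelated with everything
    (and perfectly correlated with itself).
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    ok = sd > 0
    cor = np.zeros((values.shape[0], values.shape[0]))
    if ok.any():
        sub = np.corrcoef(values[ok])
        sub = np.atleast_2d(sub)
        cor[np.ix_(ok, ok)] = sub
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def correlation_dissimilarity(expr_subset: ExpressionMatrix) -> DissimilarityMatrix:
    """d(i, j) = 1 - Cor(x_i, x_j) over samples; requires >= 2 genes, >= 3 samples."""
    if expr_subset.n_genes < 2:
        raise ValueError("need at least 2 genes for a dissimilarity matrix")
    if expr_subset.n_samples < 3:
        raise ValueError("need at least 3 samples for a stable correlation")
    cor = gene_correlation(expr_subset.values)
    d = 1.0 - cor
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DissimilarityMatrix(list(expr_subset.gene_ids), d)


def _objective(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _build(d: np.ndarray, K: int, first: int | None = None) -> list[int]:
    n = d.shape[0]
    if first is None:
        totals = d.sum(axis=1)
        first = int(np.argmin(totals))  # argmin takes the lowest index on ties
    medoids = [first]
    mind = d[:, first].copy()
    while len(medoids) < K:
        best_gain, best_cand = -np.inf, -1
        for cand in range(n):
            if cand in medoids:
                continue
            gain = np.maximum(mind - d[:, cand], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)
        mind = np.minimum(mind, d[:, best_cand])
    return medoids


def _swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improving (steepest-descent) swaps until no exchange improves."""
    n = d.shape[0]
    current = _objective(d, medoids)
    improved = True
    while improved:
        improved = False
        best_obj, best_swap = current, None
        medoid_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoid_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                obj = _objective(d, trial)
                if obj < best_obj - 1e-12:
                    best_obj, best_swap = obj, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            current = best_obj
            improved = True
    return medoids, current


def pam(dissim: DissimilarityMatrix, K: int, n_starts: int | None = None) -> ClusterAssignment:
    """PAM: greedy build then best-improving (steepest-descent) swaps.

    The objective — the sum over genes of the dissimilarity to the nearest
    medoid — is non-increasing across swap iterations.  Ties are broken
    toward the lowest gene index, making the result deterministic.

    Single-start build+swap is a local search and can miss the global
    optimum even at tiny N (so can the reference R implementation), so for
    small instances (N <= 10 by default) the build is restarted from every
    possible first medoid and the best local optimum kept.  ``n_starts``
    overrides the policy (1 = classic single start).
    """
    n = dissim.n
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of genes N={n}")
    d = dissim.d
    if n_starts is None:
        n_starts = n if n <= 10 else 1
    n_starts = max(1, min(n_starts, n))

    best_medoids, best_obj = _swap(d, _build(d, K))
    if n_starts > 1:
        for first in range(min(n_starts, n)):
            medoids, obj = _swap(d, _build(d, K, first=first))
            if obj < best_obj - 1e-12:
                best_medoids, best_obj = medoids, obj

    medoids = sorted(best_medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    # a medoid is always in its own cluster (d(m,m)=0; argmin keeps lowest index on ties)
    for k, m in enumerate(medoids):
        labels[m] = k
    objective = _objective(d, medoids)
    return ClusterAssignment(
        K=K,
        medoid_indices=medoids,
        labels=labels,
        objective=objective,
        per_cluster_icc=[],
        mean_icc=np.nan,
        gene_ids=list(dissim.gene_ids),
    )


def intra_cluster_correlation(cor_subset: np.ndarray) -> float:
    """Mean of the strictly-lower-triangle entries of a within-cluster correlation matrix.

    For a cluster of n genes this is 2/(n(n-1)) * sum of pairwise
    correlations.  A singleton cluster has no pairs and returns 0.
    """
    cor_subset = np.atleast_2d(np.asarray(cor_subset, dtype=float))
    n = cor_subset.shape[0]
    if n < 2:
        return 0.0
    tril = cor_subset[np.tril_indices(n, k=-1)]
    return float(tril.mean())


def _attach_icc(assignment: ClusterAssignment, cor: np.ndarray) -> ClusterAssignment:
    iccs = []
    for k in range(assignment.K):
        idx = np.flatnonzero(assignment.labels == k)
        iccs.append(intra_cluster_correlation(cor[np.ix_(idx, idx)]))
    assignment.per_cluster_icc = iccs
    assignment.mean_icc = float(np.mean(iccs))
    return assignment


def select_k(dissim: DissimilarityMatrix, cor: np.ndarray, k_max: int = 20) -> ClusterAssignment:
    """Sweep K = 2..min(N-1, k_max) with PAM; keep the max mean-ICC configuration.

    Ties in mean ICC are broken toward smaller K (parsimony).
    """
    n = dissim.n
    if n < 3:
        raise ValueError("select_k requires at least 3 genes")
    best: ClusterAssignment | None = None
    for K in range(2, min(n - 1, k_max) + 1):
        asg = _attach_icc(pam(dissim, K), cor)
        if best is None or asg.mean_icc > best.mean_icc + 1e-12:
            best = asg
    assert best is not None
    return best


def _trivial_cluster(gene_ids: list[str], values: np.ndarray) -> ClusterAssignment:
    """Single cluster for groups of size 1-2 (the K = 2..N-1 sweep is empty)."""
    n = len(gene_ids)
    cor = gene_correlation(values)
    if n == 1:
        medoid = 0
    else:
        d = 1.0 - cor
        np.fill_diagonal(d, 0.0)
        totals = d.sum(axis=1)
        order = sorted(range(n), key=lambda i: (totals[i], gene_ids[i]))
        medoid = order[0]
    icc = intra_cluster_correlation(cor)
    return ClusterAssignment(
        K=1,
        medoid_indices=[medoid],
        labels=np.zeros(n, dtype=int),
        objective=float((1.0 - cor[:, medoid]).sum() - (1.0 - cor[medoid, medoid])),
        per_cluster_icc=[icc],
        mean_icc=icc,
        gene_ids=list(gene_ids),
    )


def precluster_all_groups(
    dataset: Dataset,
    k_max: int = 20,
    sample_ids: list[str] | None = None,
) -> PreclusteredGroups:
    """Run the dissimilarity -> PAM -> ICC pipeline for every gene group.

    ``sample_ids`` restricts the correlation computation (training samples
    only, for leakage-free evaluation).  Genes within a group are processed
    in sorted-id order so the result does not depend on file order.
    """
    expr = dataset.expression
    if sample_ids is not None:
        expr = expr.subset_samples(sample_ids)
    out: dict[str, GroupClustering] = {}
    for gid in dataset.groups.group_ids:
        genes = sorted(dataset.groups.groups[gid])
        values = expr.gene_rows(genes)
        if len(genes) < 3:
            asg = _trivial_cluster(genes, values)
        else:
            sub = ExpressionMatrix(genes, expr.sample_ids, values)
            dissim = correlation_dissimilarity(sub)
            cor = gene_correlation(values)
            asg = select_k(dissim, cor, k_max=k_max)
        out[gid] = GroupClustering(group_id=gid, assignment=asg)
    return PreclusteredGroups(out)
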
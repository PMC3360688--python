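"""SPADE: spanning-tree progression analysis of density-normalized events.

The shared representation for all samples of one tube is built in four steps:

1. **Density-dependent downsampling** of each sample separately.  The local
   density ``LD_i`` of a cell is the number of cells within an L1 ball whose
   radius is ``radius_factor`` (default 5) times the median nearest-neighbor
   L1 distance of a random subsample.  Cells below the *outlier density*
   ``OD`` (1st percentile of local densities) are discarded; cells between
   ``OD`` and the *target density* ``TD`` are kept; cells above ``TD`` are
   kept with probability ``TD / LD_i``.  ``TD`` is solved so that the
   expected retained count equals ``retain_count`` (default 2000) exactly,
   and the actual draw retains exactly that many cells, so every sample
   contributes equally to the pool.

2. **Pooling** of the downsampled samples, uniformly capped at ``pool_cap``
   cells (default 50000).

3. **Size-balanced agglomerative clustering** of the pool into ``k`` clusters
   (default 150), followed by a **minimum spanning tree** over the cluster
   medians under the L1 metric — the SPADE tree whose nodes approximate the
   skeleton of the pooled point cloud.

4. **Upsampling**: every cell of every original file is assigned the cluster
   of its L1-nearest pooled reference cell, yielding a per-sample
   distribution of cells over tree nodes.

All stochastic steps take explicit seeds and are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateInputError,
    InfeasibleRetentionError,
    ParameterError,
    SchemaError,
)
from .io import CellMatrix

__all__ = [
    "DensityEstimate",
    "ClusterAssignment",
    "SpadeTree",
    "SampleDistribution",
    "PooledCells",
    "local_densities",
    "select_target_density",
    "density_dependent_downsample",
    "pool_and_cap",
    "agglomerative_cluster",
    "build_tree",
    "upsample",
    "node_frequencies",
    "SpadeTreeModel",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class DensityEstimate:
    """Local densities of one sample plus the outlier/target thresholds.

    ``local_density[i]`` counts the cells (including cell *i* itself) within
    the L1 ball of ``radius`` around cell *i*, so it is always >= 1.
    ``outlier_density`` is the 1st percentile of the local densities (cells
    below it are treated as outliers and never retained); ``target_density``
    is filled in by :func:`select_target_density`.
    """

    local_density: np.ndarray  # int counts, shape (n_cells,)
    radius: float
    outlier_density: float
    target_density: float | None = None


@dataclass
class ClusterAssignment:
    """Cluster labels of the pooled reference cells."""

    reference_cells: np.ndarray  # (n_ref, n_channels)
    labels: np.ndarray  # (n_ref,), values in 0..n_clusters-1
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.n_clusters:
            raise SchemaError("cluster labels out of range")
        if (counts == 0).any():
            raise SchemaError("empty cluster in assignment")


@dataclass
class SpadeTree:
    """The shared cluster tree: one median vector per node, K-1 weighted edges."""

    node_medians: np.ndarray  # (K, n_channels)
    edges: np.ndarray  # (K-1, 2) int, i < j
    edge_lengths: np.ndarray  # (K-1,) L1 distance between endpoint medians
    channels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_medians.shape[0]

    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "channels": list(self.channels),
            "node_medians": self.node_medians.tolist(),
            "edges": self.edges.tolist(),
            "edge_lengths": self.edge_lengths.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpadeTree":
        d = json.loads(_text_or_file(source))
        return cls(
            node_medians=np.asarray(d["node_medians"], dtype=float),
            edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            edge_lengths=np.asarray(d["edge_lengths"], dtype=float),
            channels=list(d.get("channels", [])),
        )


@dataclass
class SampleDistribution:
    """Relative frequency of one sample's cells over the tree nodes."""

    sample_id: str
    tube_id: int
    freq: np.ndarray  # (K,), >= 0, sums to 1
    n_cells: int

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if (self.freq < 0).any():
            raise SchemaError("negative frequency")
        if abs(self.freq.sum() - 1.0) > 1e-12:
            raise SchemaError("frequencies must sum to 1")


@dataclass
class PooledCells:
    """Pooled downsampled cells with per-cell sample provenance."""

    values: np.ndarray  # (n, n_channels)
    channels: list[str]
    source_ids: np.ndarray  # (n,) sample_id of origin

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def _text_or_file(source) -> str:
    """Accept either a JSON string or a path to a JSON file."""
    s = str(source)
    if s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()


def _cell_values(obj) -> np.ndarray:
    if isinstance(obj, (CellMatrix, PooledCells)):
        return obj.values
    return np.asarray(obj, dtype=float)


# ---------------------------------------------------------------------------
# Density-dependent downsampling


def local_densities(
    cells: CellMatrix | np.ndarray,
    radius_factor: float = 5.0,
    outlier_percentile: float = 1.0,
    seed: int | np.random.Generator | None = None,
    nn_subsample: int = 1000,
) -> DensityEstimate:
    """Estimate per-cell local density by L1-ball counting.

    The neighborhood radius is ``radius_factor`` times the median L1 distance
    from a randomly chosen cell to its nearest neighbor; the median is taken
    over a random subsample of at most ``nn_subsample`` cells, which is ample
    for a stable median while keeping the estimate cheap.
    """
    X = _cell_values(cells)
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("local densities need at least two cells")
    rng = np.random.default_rng(seed)
    # large leaves pay off: the counting radius is much wider than typical
    # leaf cells, so whole leaves are accepted/rejected per query
    tree = cKDTree(X, leafsize=128)
    take = min(n, int(nn_subsample))
    idx = rng.choice(n, size=take, replace=False)
    nn_dist, _ = tree.query(X[idx], k=2, p=1)
    radius = float(radius_factor) * float(np.median(nn_dist[:, 1]))
    ld = tree.query_ball_point(X, r=radius, p=1, return_length=True)
    ld = np.asarray(ld, dtype=int)
    od = float(np.percentile(ld, outlier_percentile))
    return DensityEstimate(local_density=ld, radius=radius, outlier_density=od)


def expected_retention(est: DensityEstimate, target_density: float) -> float:
    """Expected retained count ``sum over eligible cells of min(1, TD/LD)``."""
    ld = est.local_density
    eligible = ld >= est.outlier_density
    return float(np.minimum(1.0, target_density / ld[eligible]).sum())


def select_target_density(
    est: DensityEstimate, retain_count: int = 2000
) -> DensityEstimate:
    """Solve for the target density TD giving an expected retention of exactly
    ``retain_count`` cells under the keep rule.

    The expected retention ``E(TD) = sum_eligible min(1, TD/LD_i)`` is a
    continuous, piecewise-linear, increasing function of TD, so the equation
    ``E(TD) = retain_count`` has an exact solution whenever ``retain_count``
    does not exceed the number of eligible (non-outlier) cells.
    """
    ld = np.asarray(est.local_density, dtype=float)
    elig = np.sort(ld[ld >= est.outlier_density])
    m = elig.size
    if retain_count > m:
        raise InfeasibleRetentionError(
            f"cannot retain {retain_count} cells: only {m} non-outlier cells"
        )
    if retain_count == m:
        return replace(est, target_density=float(elig[-1]))
    # suffix[j] = sum_{i >= j} 1/L_i ; on the segment TD in [L_{j-1}, L_j],
    # E(TD) = j + TD * suffix[j]
    suffix = np.concatenate([np.cumsum((1.0 / elig)[::-1])[::-1], [0.0]])
    j = np.arange(m)
    with np.errstate(divide="ignore"):
        cand = (retain_count - j) / suffix[:-1]
    lower = np.concatenate([[0.0], elig[:-1]])
    ok = np.flatnonzero((cand >= lower) & (cand <= elig))
    td = float(cand[ok[0]])
    return replace(est, target_density=td)


def keep_probabilities(est: DensityEstimate) -> np.ndarray:
    """Per-cell inclusion probability: 0 below OD, min(1, TD/LD) otherwise."""
    if est.target_density is None:
        raise ParameterError("target density not set; call select_target_density")
    ld = np.asarray(est.local_density, dtype=float)
    prob = np.minimum(1.0, est.target_density / ld)
    prob[ld < est.outlier_density] = 0.0
    return prob


def density_dependent_downsample(
    cells: CellMatrix,
    est: DensityEstimate,
    retain_count: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> CellMatrix:
    """Retain exactly ``retain_count`` cells with inclusion probability
    ``min(1, TD/LD_i)`` (0 for outliers).

    Uses systematic sampling on a seeded random permutation of the cells:
    because the inclusion probabilities sum to ``retain_count`` exactly (by
    construction of TD) and none exceeds 1, the draw selects exactly
    ``retain_count`` distinct cells and each cell's inclusion probability is
    exactly its keep probability.  Deterministic given the seed.
    """
    if est.target_density is None:
        est = select_target_density(est, retain_count)
    prob = keep_probabilities(est)
    total = prob.sum()
    if retain_count - total > 1e-6 * max(retain_count, 1):
        raise InfeasibleRetentionError(
            f"keep probabilities sum to {total:.3f} < retain_count {retain_count}"
        )
    prob = prob * (retain_count / total)  # absorb float residue, <= 1e-12 relative
    rng = np.random.default_rng(seed)
    perm = rng.permutation(prob.size)
    cum = np.cumsum(prob[perm])
    thresholds = rng.uniform(0.0, 1.0) + np.arange(retain_count)
    pos = np.searchsorted(cum, thresholds, side="left")
    pos = np.minimum(pos, prob.size - 1)
    keep = np.sort(perm[pos])
    if keep.size != retain_count or np.unique(keep).size != retain_count:
        raise AssertionError("systematic sampling produced a malformed draw")
    return replace(cells, values=cells.values[keep])


# ---------------------------------------------------------------------------
# Pooling and clustering


def pool_and_cap(
    subsets: Sequence[CellMatrix],
    cap: int = 50000,
    seed: int | np.random.Generator | None = None,
) -> PooledCells:
    """Concatenate downsampled samples; uniformly subsample to ``cap`` cells
    if the pool is larger.  Per-cell sample provenance is retained."""
    if not subsets:
        raise DegenerateInputError("nothing to pool")
    channels = subsets[0].channels
    for s in subsets[1:]:
        if s.channels != channels:
            raise SchemaError(
                f"channel mismatch between samples {subsets[0].sample_id!r} "
                f"and {s.sample_id!r}"
            )
    values = np.concatenate([s.values for s in subsets], axis=0)
    source = np.concatenate(
        [np.repeat(s.sample_id, s.n_cells) for s in subsets], axis=0
    )
    if values.shape[0] > cap:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(values.shape[0], size=cap, replace=False))
        values, source = values[keep], source[keep]
    return PooledCells(values=values, channels=list(channels), source_ids=source)


def _pairing_round(medians: np.ndarray) -> list[tuple[int, int]]:
    """One round of size-balancing merges: every mutual-nearest pair of
    clusters (under L1 on medians) merges; all other clusters sit the round
    out.  The globally closest pair is always mutual, so at least one merge
    happens per round, and no cluster is ever forced into a long-range merge
    just because its natural partners are taken."""
    n = medians.shape[0]
    tree = cKDTree(medians)
    _, nbrs = tree.query(medians, k=min(n, 2), p=1)
    nbrs = np.atleast_2d(nbrs)
    nn = np.where(nbrs[:, 0] != np.arange(n), nbrs[:, 0], nbrs[:, -1])
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        j = int(nn[i])
        if i < j and int(nn[j]) == i:
            pairs.append((i, j))
    return pairs


def agglomerative_cluster(
    pooled: PooledCells | CellMatrix | np.ndarray,
    k: int = 150,
    seed: int | np.random.Generator | None = None,
) -> ClusterAssignment:
    """Size-balanced agglomerative clustering of the pooled cells into ``k``
    clusters.

    Merging proceeds in rounds in which every cluster participates in at most
    one merge: all mutual-nearest cluster pairs (L1 distance between current
    medians) merge simultaneously.  Because a large fraction of the clusters
    disappears in every round and no cluster can absorb more than one partner
    per round, sizes stay far more balanced than under plain single linkage,
    which is free to grow one giant chained cluster.  Once fewer than ``2k``
    clusters remain, merging switches to one globally cheapest merge at a
    time until exactly ``k`` clusters are left.

    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the other stages and is unused.
    """
    del seed
    X = _cell_values(pooled)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ParameterError(f"cluster count {k} outside 1..{n}")
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    medians = X.copy()

    while len(members) >= 2 * k and len(members) > 1:
        pairs = _pairing_round(medians)
        merged: list[np.ndarray] = []
        taken = np.zeros(len(members), dtype=bool)
        for i, j in pairs:
            merged.append(np.concatenate([members[i], members[j]]))
            taken[i] = taken[j] = True
        for i in np.flatnonzero(~taken):
            merged.append(members[i])
        members = merged
        medians = np.stack([np.median(X[m], axis=0) for m in members])

    # final phase: sequential cheapest merges down to exactly k
    if len(members) > k:
        from scipy.spatial.distance import cdist

        D = cdist(medians, medians, metric="cityblock")
        np.fill_diagonal(D, np.inf)
        alive = np.ones(len(members), dtype=bool)
        while alive.sum() > k:
            flat = int(np.argmin(D))
            i, j = divmod(flat, D.shape[1])
            if i > j:
                i, j = j, i
            members[i] = np.concatenate([members[i], members[j]])
            alive[j] = False
            medians[i] = np.median(X[members[i]], axis=0)
            D[j, :] = np.inf
            D[:, j] = np.inf
            row = np.abs(medians - medians[i]).sum(axis=1)
            row[~alive] = np.inf
            row[i] = np.inf
            D[i, :] = row
            D[:, i] = row
        members = [members[i] for i in np.flatnonzero(alive)]

    # deterministic node numbering: order clusters by their smallest member
    members.sort(key=lambda m: int(m.min()))
    labels = np.empty(n, dtype=int)
    for node, m in enumerate(members):
        labels[m] = node
    return ClusterAssignment(reference_cells=X, labels=labels, n_clusters=k)


# ---------------------------------------------------------------------------
# Minimum spanning tree over cluster medians


def cluster_medians(assignment: ClusterAssignment) -> np.ndarray:
    X = assignment.reference_cells
    return np.stack(
        [
            np.median(X[assignment.labels == node], axis=0)
            for node in range(assignment.n_clusters)
        ]
    )


def build_tree(
    assignment: ClusterAssignment, channels: Sequence[str] | None = None
) -> SpadeTree:
    """Minimum spanning tree over cluster medians under the L1 metric.

    The contract is minimal *total* edge length over all spanning trees of
    the complete L1-distance graph on the medians; ties between equal-weight
    trees are broken deterministically by node index.
    """
    from scipy.spatial.distance import cdist

    med = cluster_medians(assignment)
    K = med.shape[0]
    if K == 1:
        return SpadeTree(
            node_medians=med,
            edges=np.empty((0, 2), dtype=int),
            edge_lengths=np.empty(0),
            channels=list(channels or []),
        )
    D = cdist(med, med, metric="cityblock")
    # csgraph treats explicit zeros as absent edges; a constant offset on all
    # K*(K-1)/2 candidate edges shifts every spanning tree's total equally
    # (each has K-1 edges) and therefore cannot change the minimizer.
    W = D + 1.0
    np.fill_diagonal(W, 0.0)
    mst = _scipy_mst(csr_matrix(W)).tocoo()
    i = np.minimum(mst.row, mst.col)
    j = np.maximum(mst.row, mst.col)
    order = np.lexsort((j, i))
    edges = np.stack([i[order], j[order]], axis=1).astype(int)
    lengths = D[edges[:, 0], edges[:, 1]]
    return SpadeTree(
        node_medians=med,
        edges=edges,
        edge_lengths=lengths,
        channels=list(channels or []),
    )


# ---------------------------------------------------------------------------
# Upsampling and node frequencies


def upsample(
    original: CellMatrix | np.ndarray, assignment: ClusterAssignment
) -> np.ndarray:
    """Assign every original cell the node of its L1-nearest reference cell.

    Exact ties on the nearest-neighbor distance are resolved toward the
    lowest-index reference cell.
    """
    X = _cell_values(original)
    ref = assignment.reference_cells
    if X.shape[1] != ref.shape[1]:
        raise SchemaError(
            f"cells have {X.shape[1]} channels, reference has {ref.shape[1]}"
        )
    tree = cKDTree(ref, leafsize=64)
    k = min(2, ref.shape[0])
    dist, idx = tree.query(X, k=k, p=1)
    if k == 1:
        nearest = np.atleast_1d(idx)
    else:
        nearest = idx[:, 0].copy()
        tied = np.flatnonzero(dist[:, 1] <= dist[:, 0])
        for t in tied:
            ball = tree.query_ball_point(X[t], r=dist[t, 0], p=1)
            nearest[t] = min(ball)
    return assignment.labels[nearest]


def node_frequencies(
    labels: np.ndarray,
    n_nodes: int,
    sample_id: str = "",
    tube_id: int = 0,
) -> SampleDistribution:
    """Relative frequency of cells per tree node; sums to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise DegenerateInputError("empty label vector")
    if labels.min() < 0 or labels.max() >= n_nodes:
        raise SchemaError("node labels out of range")
    counts = np.bincount(labels, minlength=n_nodes)
    return SampleDistribution(
        sample_id=sample_id,
        tube_id=tube_id,
        freq=counts / labels.size,
        n_cells=int(labels.size),
    )


# ---------------------------------------------------------------------------
# Estimator facade


class SpadeTreeModel(TransformerMixin, BaseEstimator):
    """Build a SPADE tree from a cohort of samples and map samples onto it.

    scikit-learn style estimator: ``fit`` takes a sequence of
    :class:`~cytoemd.io.CellMatrix` (one tube of each sample), performs
    per-sample density-dependent downsampling, pools, clusters and builds the
    minimum spanning tree; ``transform`` maps samples (the fitted ones or new
    ones sharing the channel set) to node-frequency vectors.

    Parameters mirror the published analysis defaults: retain 2000 cells per
    sample, cap the pool at 50000, 150 clusters, neighborhood radius 5x the
    median nearest-neighbor distance, outlier cutoff at the 1st density
    percentile.

    Attributes
    ----------
    tree_ : SpadeTree
    assignment_ : ClusterAssignment
    pooled_ : PooledCells
    """

    def __init__(
        self,
        retain_count: int = 2000,
        pool_cap: int = 50000,
        n_clusters: int = 150,
        radius_factor: float = 5.0,
        outlier_percentile: float = 1.0,
        random_state: int | None = None,
    ):
        self.retain_count = retain_count
        self.pool_cap = pool_cap
        self.n_clusters = n_clusters
        self.radius_factor = radius_factor
        self.outlier_percentile = outlier_percentile
        self.random_state = random_state

    def fit(self, X: Sequence[CellMatrix], y=None) -> "SpadeTreeModel":
        samples = list(X)
        if not samples:
            raise DegenerateInputError("no samples to fit")
        root = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        child = root.spawn(len(samples) + 1)
        subsets = []
        for cells, ss in zip(samples, child[:-1]):
            rng = np.random.default_rng(ss)
            est = local_densities(
                cells,
                radius_factor=self.radius_factor,
                outlier_percentile=self.outlier_percentile,
                seed=rng,
            )
            est = select_target_density(est, self.retain_count)
            subsets.append(
                density_dependent_downsample(cells, est, self.retain_count, seed=rng)
            )
        self.pooled_ = pool_and_cap(
            subsets, cap=self.pool_cap, seed=np.random.default_rng(child[-1])
        )
        self.assignment_ = agglomerative_cluster(self.pooled_, k=self.n_clusters)
        self.tree_ = build_tree(self.assignment_, channels=self.pooled_.channels)
        self.n_features_in_ = self.pooled_.values.shape[1]
        return self

    def transform(self, X: Sequence[CellMatrix]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "tree_")
        rows = []
        for cells in X:
            labels = upsample(cells, self.assignment_)
            rows.append(node_frequencies(labels, self.n_clusters).freq)
        return np.stack(rows)
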
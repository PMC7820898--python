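"""Discretization of expression patterns into significant states.

Cell-timepoint expression vectors are hierarchically clustered and the
dendrogram is cut top-down with the similarity-profile (SIMPROF)
permutation test: a node whose members show no significant multivariate
structure becomes one terminal cluster; a significant node is split
further.  Terminal clusters are the discrete "gene-expression states"
from which trajectories and the state-machine Petri net are built.

The SIMPROF statistic for a group of rows is

    pi = sum_k | d_(k) - mean_perm d_(k) |

where ``d_(k)`` are the ordered pairwise dissimilarities of the group
and the expectation is taken over permutations that shuffle each
variable (gene) independently across rows — the exchangeable null of
"no multivariate structure".  The p-value is the fraction of a second,
independent set of permuted profiles whose statistic reaches the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .errors import ArgumentError, DataError

__all__ = [
    "ClusterAssignment",
    "ClusterProfile",
    "pairwise_distances",
    "agglomerate",
    "simprof_pvalue",
    "significant_clusters",
    "cluster_profiles",
]

LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterAssignment:
    """Map from cell-timepoint to cluster ID, plus the run parameters.

    Cluster IDs are contiguous positive integers numbered by the
    dendrogram leaf order of each terminal cluster's first leaf, so the
    labelling is deterministic for a fixed dendrogram and seed.
    """

    labels: dict[tuple[str, int], int]
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster_id: int) -> list[tuple[str, int]]:
        return [k for k, v in self.labels.items() if v == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, t, k) for (c, t), k in sorted(self.labels.items())]
        return pd.DataFrame(rows, columns=["cell", "time_h", "cluster"])


@dataclass
class ClusterProfile:
    """Per-cluster per-gene geometric-mean expression profiles."""

    values: pd.DataFrame  # index: cluster_id, columns: genes, linear scale
    counts: pd.Series  # members per cluster

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise DataError("cluster profiles must be strictly positive")

    @property
    def clusters(self) -> list[int]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, cluster_id: int) -> pd.Series:
        return self.values.loc[cluster_id]

    def log10(self) -> pd.DataFrame:
        return np.log10(self.values)


def pairwise_distances(matrix: pd.DataFrame, transform: str = "log10") -> np.ndarray:
    """Square Euclidean distance matrix between expression rows.

    ``transform='log10'`` logs the (strictly positive) values first,
    matching the scale on which profiles are displayed and clustered.
    """
    if transform not in ("log10", "none"):
        raise ArgumentError(f"unknown transform {transform!r}")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        holes = [
            (matrix.index[i], matrix.columns[j])
            for i, j in zip(*np.nonzero(np.isnan(values)))
        ]
        raise DataError(f"missing values at {holes[:10]}")
    if transform == "log10":
        if (values <= 0).any():
            raise DataError("log10 transform requires strictly positive values")
        values = np.log10(values)
    return squareform(pdist(values, metric="euclidean"))


def agglomerate(distances: np.ndarray, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of a square distance matrix.

    Returns a SciPy linkage matrix (merge tree with heights).
    """
    if method not in LINKAGES:
        raise ArgumentError(f"linkage must be one of {LINKAGES}, got {method!r}")
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ArgumentError("distances must be a square matrix")
    if distances.shape[0] < 2:
        # a single point needs no merges
        return np.empty((0, 4))
    return linkage(squareform(distances, checks=False), method=method)


def _sorted_profiles(batch: np.ndarray) -> np.ndarray:
    """Ordered condensed Euclidean distance profiles of a batch of matrices."""
    sq = np.einsum("bij,bij->bi", batch, batch)
    gram = batch @ batch.transpose(0, 2, 1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    iu = np.triu_indices(batch.shape[1], k=1)
    profiles = np.sqrt(d2[:, iu[0], iu[1]])
    profiles.sort(axis=1)
    return profiles


def _permuted_profiles(
    values: np.ndarray, n_perm: int, rng: np.random.Generator, chunk: int = 64
) -> np.ndarray:
    """Sorted distance profiles under column-wise row permutation."""
    n, g = values.shape
    out = np.empty((n_perm, n * (n - 1) // 2))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        batch = np.empty((b, n, g))
        for k in range(b):
            perm_cols = [values[rng.permutation(n), j] for j in range(g)]
            batch[k] = np.column_stack(perm_cols)
        out[done : done + b] = _sorted_profiles(batch)
        done += b
    return out


def simprof_pvalue(
    submatrix: np.ndarray | pd.DataFrame,
    n_expected: int = 999,
    n_simulated: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Similarity-profile permutation test for one candidate group.

    Returns ``(p_value, pi)``.  Identical rows give ``(1.0, 0.0)`` by
    convention — there is no structure to detect.
    """
    values = np.asarray(
        submatrix.to_numpy() if isinstance(submatrix, pd.DataFrame) else submatrix,
        dtype=float,
    )
    if values.ndim != 2 or values.shape[0] < 2:
        raise ArgumentError("simprof requires a 2-D matrix with >= 2 rows")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = np.sort(pdist(values, metric="euclidean"))
    if not observed.any():
        return 1.0, 0.0
    expected = _permuted_profiles(values, n_expected, rng).mean(axis=0)
    pi_obs = np.abs(observed - expected).sum()
    sim = _permuted_profiles(values, n_simulated, rng)
    pi_sim = np.abs(sim - expected).sum(axis=1)
    # add-one rule keeps the test valid (conservative) at any perm count
    p = (1.0 + np.count_nonzero(pi_sim >= pi_obs)) / (1.0 + n_simulated)
    return float(p), float(pi_obs)


def significant_clusters(
    dendrogram: np.ndarray,
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    n_expected: int = 999,
    n_simulated: int = 999,
    transform: str = "log10",
) -> ClusterAssignment:
    """Cut a dendrogram into SIMPROF-significant terminal clusters.

    Top-down recursion from the root: each node's members are tested;
    if ``p <= alpha`` the node is split into its children, otherwise its
    leaves form one terminal cluster.  Every row of ``matrix`` is
    assigned to exactly one cluster.
    """
    if not 0 < alpha < 1:
        raise ArgumentError(f"alpha must be in (0, 1), got {alpha}")
    values = matrix.to_numpy(dtype=float)
    if transform == "log10":
        values = np.log10(values)
    n = values.shape[0]

    if n == 1:
        groups = [[0]]
        leaf_order = [0]
    else:
        root = to_tree(dendrogram)
        leaf_order = list(leaves_list(dendrogram))
        groups = []
        stack = [root]
        while stack:
            node = stack.pop(0)
            leaves = node.pre_order(lambda x: x.id)
            if node.is_leaf() or len(leaves) == 1:
                groups.append(leaves)
                continue
            # the permutation stream of a node depends only on the seed
            # and the node's leaf set, so a decision at one node cannot
            # shift the p-values of others: the partition refines
            # monotonically as alpha grows
            node_rng = np.random.default_rng([seed, *sorted(leaves)])
            p, _ = simprof_pvalue(
                values[leaves], n_expected, n_simulated, seed=node_rng
            )
            if p <= alpha:
                stack.insert(0, node.get_right())
                stack.insert(0, node.get_left())
            else:
                groups.append(leaves)

    position = {leaf: k for k, leaf in enumerate(leaf_order)}
    groups.sort(key=lambda g: min(position[i] for i in g))
    labels: dict[tuple[str, int], int] = {}
    for cluster_id, group in enumerate(groups, start=1):
        for i in group:
            cell, time_h = matrix.index[i]
            labels[(str(cell), int(time_h))] = cluster_id
    assert len(labels) == n, "assignment must cover every row exactly once"
    return ClusterAssignment(
        labels,
        params={
            "alpha": alpha,
            "seed": seed,
            "n_expected": n_expected,
            "n_simulated": n_simulated,
            "transform": transform,
            "metric": "euclidean",
        },
    )


def cluster_profiles(
    assignment: ClusterAssignment, matrix: pd.DataFrame
) -> ClusterProfile:
    """Geometric-mean expression profile of each cluster's members."""
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise DataError("geometric means require strictly positive values")
    index = {
        (str(c), int(t)): i for i, (c, t) in enumerate(matrix.index)
    }
    clusters = sorted(set(assignment.labels.values()))
    profiles = []
    counts = []
    log_values = np.log(values)
    for cid in clusters:
        members = assignment.members(cid)
        try:
            rows = [index[m] for m in members]
        except KeyError as exc:
            raise DataError(f"assigned member {exc} absent from matrix") from None
        profiles.append(np.exp(log_values[rows].mean(axis=0)))
        counts.append(len(rows))
    frame = pd.DataFrame(profiles, index=clusters, columns=matrix.columns)
    frame.index.name = "cluster"
    return ClusterProfile(frame, pd.Series(counts, index=clusters, name="n"))
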
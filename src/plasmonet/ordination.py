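"""Classical multidimensional scaling and discretized kinetics curves.

MDS here is classical (Torgerson) scaling: eigendecomposition of the
double-centered squared Euclidean distance matrix, coordinates being
eigenvectors scaled by the square root of their eigenvalues.  The
percent of variance of each coordinate is its eigenvalue over the sum
of positive eigenvalues; negative eigenvalues (non-Euclidean inputs)
are dropped from the denominator, matching the convention of R's
``cmdscale``.

Kinetics curves discretize a single cell's expression time course
through its state sequence: for gene g and trajectory s(t), the curve
is log10 of the state profile value at t relative to the start,

    curve_g(t) = log10( profile[s(t), g] / profile[s(0), g] ),

so every curve starts at exactly 0 and is stepwise constant within a
residence run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ArgumentError, DataError
from .simprof import ClusterProfile
from .trajectories import TrajectoryRow, TrajectoryTable

__all__ = [
    "MDSResult",
    "classical_mds",
    "kinetics_curves",
    "kinetics_table",
    "plot_mds",
    "plot_kinetics",
]


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # index (cell, time_h), columns dim1..dimk
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained coordinate

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(
    matrix: pd.DataFrame,
    k: int = 2,
    gene_subset: Sequence[str] | None = None,
    transform: str = "log10",
) -> MDSResult:
    """Torgerson scaling of per-cell-timepoint expression vectors.

    ``gene_subset`` restricts the analysis to named genes (the study's
    all/up/down/up-and-down/pcnA-group views).  With ``k`` equal to the
    number of positive eigenvalues and a Euclidean input, pairwise
    embedding distances reproduce the input distances to numerical
    precision.  Each coordinate's sign is fixed by making its largest-
    magnitude loading positive.
    """
    if k < 1:
        raise ArgumentError(f"k must be >= 1, got {k}")
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in matrix.columns]
        if missing:
            raise DataError(f"genes absent from matrix: {missing}")
        if not list(gene_subset):
            raise ArgumentError("gene_subset must not be empty")
        matrix = matrix[list(gene_subset)]
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError("matrix contains missing values")
    if transform == "log10":
        if (values <= 0).any():
            raise DataError("log10 transform requires positive values")
        values = np.log10(values)
    elif transform != "none":
        raise ArgumentError(f"unknown transform {transform!r}")

    d2 = squareform(pdist(values, metric="euclidean")) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-12, 1e-9 * abs(eigval[0])) if n else 0.0
    n_pos = int(np.sum(eigval > tol))
    if k > n_pos:
        k = max(n_pos, 1)
    pos = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(pos)
    for col in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, col])))
        if coords[i, col] < 0:
            coords[:, col] = -coords[:, col]
    pos_sum = eigval[eigval > tol].sum()
    percent = (
        100.0 * np.clip(eigval[:k], 0.0, None) / pos_sum if pos_sum > 0 else np.zeros(k)
    )
    frame = pd.DataFrame(
        coords, index=matrix.index, columns=[f"dim{i + 1}" for i in range(k)]
    )
    return MDSResult(frame, eigval, percent)


def kinetics_curves(
    trajectory: TrajectoryRow | Sequence[int],
    profiles: ClusterProfile,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Discretized log10 expression kinetics of one cell.

    Returns a time x gene frame of log10 fold change of the state
    profile relative to the trajectory's start state; the first row is
    exactly zero.
    """
    states = list(trajectory.states if isinstance(trajectory, TrajectoryRow) else trajectory)
    if not states:
        raise ArgumentError("empty trajectory")
    genes = list(genes) if genes is not None else profiles.genes
    missing = [g for g in genes if g not in profiles.genes]
    if missing:
        raise DataError(f"genes absent from profiles: {missing}")
    absent = [s for s in states if s not in profiles.clusters]
    if absent:
        raise DataError(f"states without profiles: {sorted(set(absent))}")
    log_profiles = np.log10(profiles.values.loc[states, genes].to_numpy())
    curves = log_profiles - log_profiles[0]
    return pd.DataFrame(
        curves, index=pd.Index(range(len(states)), name="time_h"), columns=genes
    )


def kinetics_table(
    trajectories: TrajectoryTable,
    profiles: ClusterProfile,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format curves for every cell: (cell, gene, time_h, log10_fc)."""
    frames = []
    for row in trajectories:
        curves = kinetics_curves(row, profiles, genes)
        long = curves.reset_index().melt(
            id_vars="time_h", var_name="gene", value_name="log10_fc"
        )
        long.insert(0, "cell", row.cell)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# plotting (headless; optional visual analytics)


def plot_mds(result: MDSResult, path, color_by_time: bool = True) -> None:
    """Bulk scatter of the first two MDS coordinates, colored by time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x = result.coordinates.iloc[:, 0]
    y = (
        result.coordinates.iloc[:, 1]
        if result.k > 1
        else np.zeros(len(result.coordinates))
    )
    if color_by_time:
        hours = [t for _, t in result.coordinates.index]
        sc = ax.scatter(x, y, c=hours, cmap="viridis", s=18)
        fig.colorbar(sc, ax=ax, label="time (h)")
    else:
        ax.scatter(x, y, s=18)
    ax.set_xlabel(f"coordinate 1 ({result.percent_variance[0]:.1f}% of variance)")
    if result.k > 1:
        ax.set_ylabel(f"coordinate 2 ({result.percent_variance[1]:.1f}% of variance)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_kinetics(curves: pd.DataFrame, path, title: str = "") -> None:
    """Stepwise kinetics curves of one cell, one line per gene."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for gene in curves.columns:
        ax.step(curves.index, curves[gene], where="post", label=gene)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("log10 fold change vs 0 h")
    if title:
        ax.set_title(title)
    if curves.shape[1] <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
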
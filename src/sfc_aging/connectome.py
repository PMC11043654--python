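"""From per-subject node time series to the binary graph SFC walks on.

The functional connectome is the matrix of pairwise Pearson correlations
between node time series.  Only positive correlations carry walk-count
semantics, so the graph keeps an edge (i, j) iff r_ij > 0 and r_ij survives
the chosen rule: Benjamini-Hochberg FDR on the one-sided p-values of all
upper-triangle pairs (default, q = 0.05), or a fixed correlation cutoff.
Edges are binarized and the diagonal zeroed so step-k counts never include
trivial self-loops at the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AssociationMatrix", "BinaryGraph", "correlation_matrix", "threshold_graph"]


@dataclass
class AssociationMatrix:
    """Symmetric Pearson correlation matrix with the sample size that produced it."""

    r: np.ndarray
    n_timepoints: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"association matrix must be square, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.r = r

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    """0/1 symmetric adjacency with zero diagonal; ``node_index`` maps rows to voxels/parcels."""

    adjacency: np.ndarray
    node_index: object | None = None  # typically a sfc_aging.io.NodeTable

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.float64)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_list(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu] > 0
        return np.column_stack([iu[0][keep], iu[1][keep]])


def correlation_matrix(timeseries: np.ndarray) -> AssociationMatrix:
    """Pearson correlation of every node pair from a node x time matrix.

    Requires T >= 3 and nonconstant series for every node; exact symmetry is
    enforced by averaging the matrix with its transpose.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"time series must be a node x time matrix, got {ts.shape}")
    n_nodes, t = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series at node(s) {bad[:10].tolist()}")
    r = np.corrcoef(ts)
    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, t)


def _one_sided_p(r: np.ndarray, n: int) -> np.ndarray:
    """p-value of H1: rho > 0 via the t transform, df = n - 2."""
    rr = np.clip(r, -0.9999999, 0.9999999)
    t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    return stats.t.sf(t, df=n - 2)


def threshold_graph(
    assoc: AssociationMatrix,
    rule: str = "fdr_q",
    value: float = 0.05,
    node_index: object | None = None,
) -> BinaryGraph:
    """Binarize an association matrix into the graph SFC walks on.

    rule="fdr_q": keep positive edges whose one-sided p-values survive
    Benjamini-Hochberg step-up at level ``value`` over all upper-triangle
    pairs.  rule="fixed_r": keep edges with r >= value.  Negative
    correlations are always excluded.  An empty surviving edge set produces a
    warning and a valid empty graph.
    """
    r = assoc.r
    n = assoc.n_nodes
    iu = np.triu_indices(n, k=1)
    rv = r[iu]
    if rule == "fdr_q":
        if not 0 < value < 1:
            raise ValueError(f"fdr_q must lie in (0, 1), got {value}")
        p = _one_sided_p(rv, assoc.n_timepoints)
        p_adj = stats.false_discovery_control(p, method="bh")
        keep = (p_adj <= value) & (rv > 0)
    elif rule == "fixed_r":
        if not 0 < value < 1:
            raise ValueError(f"fixed_r must lie in (0, 1), got {value}")
        keep = rv >= value
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    adj = np.zeros((n, n))
    adj[iu[0][keep], iu[1][keep]] = 1.0
    adj += adj.T
    if not keep.any():
        warnings.warn("no edges survive thresholding; SFC maps will be all-zero", stacklevel=2)
    return BinaryGraph(adj, node_index)
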
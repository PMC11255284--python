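"""tSVD projection of the node-layer contribution structure.

The contribution matrix ``C`` is ``N x M`` with ``C[i, a]`` the (weighted)
number of links node ``i`` shares with layer ``a`` — formally the supra-matrix
sum ``C[i, a] = sum_{j, b} X_ij^{ab}``, i.e. everything incident to the duplet
``(i, a)``.  Under this definition the row sums are exactly the nodewise
multidegree profile and the column sums the layerwise one, so ``C`` is the
joint object both centralities are marginals of.

A truncated singular value decomposition ``C = U S V^T`` yields 2-D maps:
nodes are plotted at ``(s1*U[i,1], s2*U[i,2])`` (rows of ``C V``, so a point's
distance from the origin tracks its multidegree) and layers appear as lines
along ``(V[a,1], V[a,2])``; layers sharing many links point in similar
directions, and nodes contributing mostly to one layer align with its line.
The symmetric construction (swap U and V) maps the layerwise side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netcore import MultilayerNetwork

__all__ = ["ProjectionResult", "contribution_matrix", "project"]


@dataclass
class ProjectionResult:
    """Contribution matrix with its truncated SVD factors and 2-D coordinates."""

    C: np.ndarray
    singular_values: np.ndarray  # non-increasing
    U: np.ndarray
    V: np.ndarray  # right singular vectors as columns
    node_coords: np.ndarray  # N x 2
    layer_coords: np.ndarray  # M x 2
    node_line_dirs: np.ndarray  # unit 2-vectors, one per node (layerwise plot)
    layer_line_dirs: np.ndarray  # unit 2-vectors, one per layer (nodewise plot)


def contribution_matrix(net: MultilayerNetwork) -> np.ndarray:
    """The ``N x M`` matrix of links each node shares with each layer.

    Every edge adds its weight at both of its duplets; row sums equal the
    nodewise multidegrees, column sums the layerwise ones.
    """
    C = np.zeros((net.N, net.M))
    idx, w = net.edge_arrays()
    if len(idx):
        np.add.at(C, (idx[:, 0], idx[:, 1]), w)
        np.add.at(C, (idx[:, 2], idx[:, 3]), w)
    return C


def _fix_signs(U: np.ndarray, V: np.ndarray):
    """Make the first nonzero entry of each left singular vector positive
    (flipping the matching right vector), for deterministic output."""
    for k in range(U.shape[1]):
        col = U[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            U[:, k] = -col
            V[:, k] = -V[:, k]
    return U, V


def project(C: np.ndarray, k: int = 2) -> ProjectionResult:
    """Truncated SVD projection of a contribution matrix.

    Keeps the top ``k`` components (at least 2 are used for the coordinate
    maps; rank-deficient matrices get zero-padded trailing components).
    Raises on an all-zero matrix.
    """
    C = np.asarray(C, dtype=float)
    if not np.any(C):
        raise ValueError("contribution matrix is all zero: nothing to project")
    if k < 1:
        raise ValueError("k must be >= 1")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k = min(k, len(s))
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    U, V = _fix_signs(U, V)

    def two_cols(A, sv):
        out = np.zeros((A.shape[0], 2))
        take = min(2, A.shape[1])
        out[:, :take] = A[:, :take] * sv[:take]
        return out

    node_coords = two_cols(U, s)
    layer_coords = two_cols(V, s)

    def unit_dirs(A):
        out = np.zeros((A.shape[0], 2))
        take = min(2, A.shape[1])
        out[:, :take] = A[:, :take]
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return out / norms

    return ProjectionResult(
        C=C,
        singular_values=s,
        U=U,
        V=V,
        node_coords=node_coords,
        layer_coords=layer_coords,
        node_line_dirs=unit_dirs(U),
        layer_line_dirs=unit_dirs(V),
    )
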
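"""Multilayer network data model, duality transform, and multidegree centralities.

A multilayer network couples ``N`` nodes across ``M`` layers.  The elementary
interacting unit is the *node-layer duplet* ``(i, alpha)``: node ``i`` observed
at layer ``alpha``.  Edges connect unordered pairs of distinct duplets and fall
into three classes:

``replica``
    same node in two different layers, ``(i, alpha)-(i, beta)``;
``intralayer``
    two different nodes in the same layer, ``(i, alpha)-(j, alpha)``;
``interlayer``
    different nodes in different layers, ``(i, alpha)-(j, beta)``.

A *multiplex* network restricts interlayer edges to replicas.

The same system can be encoded in two supra-adjacency matrices of order
``N*M``: the primal ``X`` (layer-major indexing: duplet ``(i, alpha)`` sits at
row ``alpha*N + i``) in which nodes are the units of interest, and the dual
``Y`` (node-major: row ``i*M + alpha``) in which the layers are.  The two are
related by a perfect-shuffle (commutation) permutation ``P``:
``Y = P^T X P``, and the transform is an involution.  Entry-wise the two
encodings are identical, ``X[(i,a),(j,b)] == Y[(a,i),(b,j)]``: duality is a
change of viewpoint, not of information.

Multidegree centrality sums all supra-matrix entries in the row-block of a
unit: nodewise ``k_X[i] = sum_{j,a,b} X_ij^{ab}`` and layerwise
``k_Y[alpha] = sum_{i,j,b} Y_ab^{ij}``.  Under this literal four-index sum a
replica edge contributes twice its weight to its node (both endpoints live in
node ``i``'s row block) and an intralayer edge twice to its layer; this is the
unique convention for which the nodewise and layerwise totals coincide
(``= 2 * total weight``) and duality is exactly symmetric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MULTILAYER = "multilayer"
MULTIPLEX = "multiplex"
NATURES = (MULTILAYER, MULTIPLEX)

__all__ = [
    "Duplet",
    "MultilayerNetwork",
    "SupraAdjacency",
    "CentralityProfile",
    "ValidationError",
    "classify_edge",
    "canonical_edge",
    "admissible_slots",
    "build_supra",
    "dual_transform",
    "dual_network",
    "commutation_matrix",
    "multidegree",
    "link_class_counts",
    "read_edgelist",
    "write_edgelist",
    "read_supra_tsv",
    "write_supra_tsv",
    "network_from_supra",
]


class ValidationError(ValueError):
    """A network or edge violates a structural invariant."""


class Duplet(NamedTuple):
    """A node observed at a layer; the elementary unit of a multilayer network."""

    node: int
    layer: int


#: An edge is an unordered pair of distinct duplets; canonically stored with the
#: lexicographically smaller duplet first.
Edge = tuple  # tuple[tuple[int, int], tuple[int, int]]


def canonical_edge(d1, d2) -> Edge:
    """Return the canonical (sorted) form of the edge between two duplets.

    Raises :class:`ValidationError` for a self-edge (identical duplets).
    """
    d1 = (int(d1[0]), int(d1[1]))
    d2 = (int(d2[0]), int(d2[1]))
    if d1 == d2:
        raise ValidationError(f"self-edge on duplet {d1}")
    return (d1, d2) if d1 < d2 else (d2, d1)


def classify_edge(edge) -> str:
    """Classify an edge as ``'replica'``, ``'intralayer'`` or ``'interlayer'``.

    Replica: same node, different layers.  Intralayer: same layer, different
    nodes.  Interlayer: both differ.  A self-edge raises.
    """
    (i, a), (j, b) = edge
    if i == j:
        if a == b:
            raise ValidationError(f"self-edge on duplet {(i, a)}")
        return "replica"
    if a == b:
        return "intralayer"
    return "interlayer"


def admissible_slots(N: int, M: int, nature: str) -> int:
    """Number of admissible edge slots for a network of the given nature.

    Multilayer: all unordered pairs of distinct duplets, ``D*(D-1)/2`` with
    ``D = N*M``.  Multiplex: intralayer pairs plus replica pairs,
    ``M*N*(N-1)/2 + N*M*(M-1)/2 = (N*M/2)*(N + M - 2)``.
    """
    if nature == MULTILAYER:
        D = N * M
        return D * (D - 1) // 2
    if nature == MULTIPLEX:
        return M * (N * (N - 1) // 2) + N * (M * (M - 1) // 2)
    raise ValueError(f"unknown nature {nature!r}")


class MultilayerNetwork:
    """An undirected, simple multilayer network on ``N`` nodes and ``M`` layers.

    Parameters
    ----------
    n_nodes, n_layers
        Numbers of nodes and layers (``N``, ``M``).
    edges
        Iterable of ``(duplet, duplet)`` or ``(duplet, duplet, weight)``
        items, or a mapping from canonical edges to weights.
    nature
        ``'multilayer'`` (unrestricted) or ``'multiplex'`` (interlayer edges
        only between replicas).
    node_labels, layer_labels
        Optional string labels; indices remain the operational identity.
    """

    __slots__ = ("_N", "_M", "_edges", "_nature", "node_labels", "layer_labels", "_arrays")

    def __init__(
        self,
        n_nodes: int,
        n_layers: int,
        edges: Iterable | Mapping | None = None,
        nature: str = MULTILAYER,
        node_labels: Sequence[str] | None = None,
        layer_labels: Sequence[str] | None = None,
        validate: bool = True,
    ):
        if n_nodes < 1 or n_layers < 1:
            raise ValidationError("need at least one node and one layer")
        if nature not in NATURES:
            raise ValueError(f"nature must be one of {NATURES}, got {nature!r}")
        self._N = int(n_nodes)
        self._M = int(n_layers)
        self._nature = nature
        self._arrays = None
        if edges is None:
            self._edges = {}
        elif isinstance(edges, Mapping):
            self._edges = {e: float(w) for e, w in edges.items()}
        else:
            d = {}
            for item in edges:
                if len(item) == 3:
                    d1, d2, w = item
                else:
                    (d1, d2), w = item, 1.0
                e = canonical_edge(d1, d2)
                if e in d:
                    logger.warning("duplicate edge %s collapsed (keeping first weight)", e)
                    continue
                d[e] = float(w)
            self._edges = d
        self.node_labels = list(node_labels) if node_labels is not None else None
        self.layer_labels = list(layer_labels) if layer_labels is not None else None
        if validate:
            self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        N, M = self._N, self._M
        if self.node_labels is not None and len(self.node_labels) != N:
            raise ValidationError("node_labels length != N")
        if self.layer_labels is not None and len(self.layer_labels) != M:
            raise ValidationError("layer_labels length != M")
        for ((i, a), (j, b)), w in self._edges.items():
            if not (0 <= i < N and 0 <= j < N and 0 <= a < M and 0 <= b < M):
                raise ValidationError(f"duplet index out of range in edge {((i, a), (j, b))}")
            if (i, a) == (j, b):
                raise ValidationError(f"self-edge on duplet {(i, a)}")
            if w < 0:
                raise ValidationError(f"negative weight {w} on edge {((i, a), (j, b))}")
            if self._nature == MULTIPLEX and a != b and i != j:
                raise ValidationError(
                    f"multiplex network contains non-replica interlayer edge {((i, a), (j, b))}"
                )

    # -- basic properties ---------------------------------------------------

    @property
    def N(self) -> int:
        return self._N

    @property
    def M(self) -> int:
        return self._M

    @property
    def L(self) -> int:
        """Number of edges."""
        return len(self._edges)

    @property
    def nature(self) -> str:
        return self._nature

    @property
    def edges(self) -> dict:
        """Mapping canonical edge -> weight (a copy; the network is immutable)."""
        return dict(self._edges)

    @property
    def total_weight(self) -> float:
        return float(sum(self._edges.values()))

    @property
    def density(self) -> float:
        """Connection density q = L / (admissible slots for the declared nature)."""
        return self.L / admissible_slots(self._N, self._M, self._nature)

    def __contains__(self, edge) -> bool:
        return edge in self._edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            self._N == other._N
            and self._M == other._M
            and self._nature == other._nature
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"MultilayerNetwork(N={self._N}, M={self._M}, L={self.L}, "
            f"nature={self._nature!r})"
        )

    # -- array views --------------------------------------------------------

    def edge_arrays(self):
        """Return ``(idx, weights)``: an ``(L, 4)`` int array of columns
        ``(i, a, j, b)`` in canonical edge order, and the matching weights."""
        if self._arrays is None:
            L = self.L
            idx = np.empty((L, 4), dtype=np.int64)
            w = np.empty(L, dtype=float)
            for k, (((i, a), (j, b)), wt) in enumerate(self._edges.items()):
                idx[k, 0] = i
                idx[k, 1] = a
                idx[k, 2] = j
                idx[k, 3] = b
                w[k] = wt
            self._arrays = (idx, w)
        return self._arrays

    @classmethod
    def from_arrays(
        cls,
        n_nodes: int,
        n_layers: int,
        idx: np.ndarray,
        weights: np.ndarray | None = None,
        nature: str = MULTILAYER,
        validate: bool = True,
        **kw,
    ) -> "MultilayerNetwork":
        """Build a network from an ``(L, 4)`` array of ``(i, a, j, b)`` rows."""
        idx = np.asarray(idx, dtype=np.int64)
        if idx.ndim != 2 or idx.shape[1] != 4:
            raise ValueError("idx must have shape (L, 4)")
        if weights is None:
            weights = np.ones(len(idx))
        edges = (
            ((int(r[0]), int(r[1])), (int(r[2]), int(r[3])), float(w))
            for r, w in zip(idx, weights)
        )
        return cls(n_nodes, n_layers, edges, nature=nature, validate=validate, **kw)


def link_class_counts(net: MultilayerNetwork) -> dict:
    """Counts of intralayer, replica and interlayer edges."""
    counts = {"intralayer": 0, "replica": 0, "interlayer": 0}
    for e in net.edges:
        counts[classify_edge(e)] += 1
    return counts


# ---------------------------------------------------------------------------
# Supra-adjacency matrices and the duality transform
# ---------------------------------------------------------------------------

PRIMAL = "primal"
DUAL = "dual"


@dataclass
class SupraAdjacency:
    """A supra-adjacency matrix of order ``N*M`` with an explicit indexing.

    ``side='primal'`` uses layer-major indexing (duplet ``(i, a)`` at row
    ``a*N + i``); ``side='dual'`` uses node-major (row ``i*M + a``).  The
    matrix is symmetric with zero diagonal.
    """

    matrix: np.ndarray
    N: int
    M: int
    side: str = PRIMAL
    node_labels: Sequence[str] | None = None
    layer_labels: Sequence[str] | None = None

    def __post_init__(self):
        order = self.N * self.M
        if self.matrix.shape != (order, order):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match order N*M={order}"
            )
        if self.side not in (PRIMAL, DUAL):
            raise ValueError(f"side must be 'primal' or 'dual', got {self.side!r}")

    def index(self, node: int, layer: int) -> int:
        """Row/column index of duplet ``(node, layer)`` under this side's convention."""
        if self.side == PRIMAL:
            return layer * self.N + node
        return node * self.M + layer

    def __getitem__(self, duplets):
        (i, a), (j, b) = duplets
        return self.matrix[self.index(i, a), self.index(j, b)]


def build_supra(net: MultilayerNetwork, side: str = PRIMAL) -> SupraAdjacency:
    """Assemble the dense supra-adjacency matrix of a network.

    Each edge sets the two mirrored entries to its weight.  Memory is
    ``(N*M)^2`` floats; intended for networks of modest order (the analysis
    pipeline never materializes supra matrices of large random networks).
    """
    order = net.N * net.M
    A = np.zeros((order, order))
    supra = SupraAdjacency(
        A, net.N, net.M, side=side, node_labels=net.node_labels, layer_labels=net.layer_labels
    )
    for ((i, a), (j, b)), w in net.edges.items():
        p, q = supra.index(i, a), supra.index(j, b)
        A[p, q] = w
        A[q, p] = w
    return supra


def _shuffle_permutation(N: int, M: int, from_side: str) -> np.ndarray:
    """Index permutation ``perm`` such that ``out = in_[ix_(perm, perm)]``.

    Going primal -> dual: output row ``k = i*M + a`` must read input row
    ``a*N + i``; the converse for dual -> primal.
    """
    k = np.arange(N * M)
    if from_side == PRIMAL:
        i, a = k // M, k % M  # output (dual) index decomposition
        return a * N + i
    i, a = k % N, k // N  # output (primal) index decomposition
    return i * M + a


def dual_transform(supra: SupraAdjacency) -> SupraAdjacency:
    """Apply the node-layer duality permutation: ``Y = P^T X P`` (and back).

    ``P`` is the commutation (perfect-shuffle) matrix between layer-major and
    node-major vectorization orders; the transform is its own inverse
    direction-wise.  Entry invariance holds exactly:
    ``Y[(a,i),(b,j)] == X[(i,a),(j,b)]``.
    """
    A = supra.matrix
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("supra matrix must be square")
    if not np.allclose(A, A.T):
        raise ValidationError("supra matrix must be symmetric")
    perm = _shuffle_permutation(supra.N, supra.M, supra.side)
    out_side = DUAL if supra.side == PRIMAL else PRIMAL
    return SupraAdjacency(
        A[np.ix_(perm, perm)],
        supra.N,
        supra.M,
        side=out_side,
        node_labels=supra.node_labels,
        layer_labels=supra.layer_labels,
    )


def commutation_matrix(N: int, M: int) -> sp.csr_matrix:
    """The explicit permutation ``P`` with ``Y = P^T X P``.

    ``P[a*N + i, i*M + a] = 1`` for every duplet ``(i, a)``: columns are
    indexed node-major (dual), rows layer-major (primal).
    """
    dual_idx = np.arange(N * M)
    i, a = dual_idx // M, dual_idx % M
    primal_idx = a * N + i
    data = np.ones(N * M)
    return sp.csr_matrix((data, (primal_idx, dual_idx)), shape=(N * M, N * M))


def dual_network(net: MultilayerNetwork) -> MultilayerNetwork:
    """The dual network: layers become nodes and nodes become layers.

    Every edge ``(i,a)-(j,b)`` maps to ``(a,i)-(b,j)``; replica links become
    intralayer, intralayer links become replica, interlayer links stay
    interlayer.  The nature is preserved (the dual of a multiplex is again a
    multiplex, since its edge classes are replica + intralayer).
    """
    edges = {}
    for ((i, a), (j, b)), w in net.edges.items():
        edges[canonical_edge((a, i), (b, j))] = w
    return MultilayerNetwork(
        net.M,
        net.N,
        edges,
        nature=net.nature,
        node_labels=net.layer_labels,
        layer_labels=net.node_labels,
        validate=False,
    )


# ---------------------------------------------------------------------------
# Multidegree centrality
# ---------------------------------------------------------------------------

NODEWISE = "nodewise"
LAYERWISE = "layerwise"


@dataclass
class CentralityProfile:
    """A multidegree sequence with its mean and population standard deviation.

    ``sigma`` divides by the sequence length (population convention): with it
    the closed-form distance ``r*sqrt(n)*sigma*(1-p)`` is exactly the Euclidean
    norm of the expected multidegree displacement.
    """

    values: np.ndarray
    side: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.side not in (NODEWISE, LAYERWISE):
            raise ValueError(f"side must be 'nodewise' or 'layerwise', got {self.side!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mu(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std())  # population (divide by n)


def multidegree(net: MultilayerNetwork, side: str = NODEWISE) -> CentralityProfile:
    """Multidegree centrality profile of a network.

    Nodewise value of node ``i`` is the full row-block sum of the primal supra
    matrix, ``k_X[i] = sum_{j,a,b} X_ij^{ab}``; each incident edge contributes
    its weight once per endpoint duplet belonging to ``i`` (so a replica edge
    counts twice).  Layerwise is the dual statement (intralayer edges count
    twice).  Totals on both sides equal twice the total weight.
    """
    idx, w = net.edge_arrays()
    if side == NODEWISE:
        n = net.N
        cols = (0, 2)
    elif side == LAYERWISE:
        n = net.M
        cols = (1, 3)
    else:
        raise ValueError(f"side must be 'nodewise' or 'layerwise', got {side!r}")
    values = np.zeros(n)
    if len(idx):
        values = np.bincount(idx[:, cols[0]], weights=w, minlength=n) + np.bincount(
            idx[:, cols[1]], weights=w, minlength=n
        )
    return CentralityProfile(values, side)


# ---------------------------------------------------------------------------
# Extended edge-list I/O
# ---------------------------------------------------------------------------


def _parse_tokens(tokens: Sequence[str]):
    """Try to interpret node/layer tokens as integers; fall back to labels."""
    try:
        return [int(t) for t in tokens], True
    except ValueError:
        return list(tokens), False


def read_edgelist(
    path,
    N: int | None = None,
    M: int | None = None,
    nature: str = MULTILAYER,
) -> MultilayerNetwork:
    """Read an extended edge list: ``node_from layer_from node_to layer_to [weight]``.

    Whitespace- or tab-delimited; lines starting with ``#`` are comments.
    Integer tokens are used directly as 0-based indices; if any node (layer)
    token is non-numeric, all node (layer) tokens are treated as labels and
    mapped to dense indices in first-seen order.  Duplicate rows collapse to
    the first occurrence (with a logged warning); directed duplicates are
    symmetrized the same way.  ``N`` and ``M`` default to max index + 1.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise ValidationError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(parts)}")
            w = float(parts[4]) if len(parts) == 5 else 1.0
            rows.append((lineno, parts[0], parts[1], parts[2], parts[3], w))

    node_tokens = [t for r in rows for t in (r[1], r[3])]
    layer_tokens = [t for r in rows for t in (r[2], r[4])]
    _, nodes_numeric = _parse_tokens(node_tokens)
    _, layers_numeric = _parse_tokens(layer_tokens)

    node_map: dict = {}
    layer_map: dict = {}

    def node_idx(tok):
        if nodes_numeric:
            return int(tok)
        return node_map.setdefault(tok, len(node_map))

    def layer_idx(tok):
        if layers_numeric:
            return int(tok)
        return layer_map.setdefault(tok, len(layer_map))

    edges: dict = {}
    max_n = -1
    max_m = -1
    for lineno, nf, lf, nt, lt, w in rows:
        i, a, j, b = node_idx(nf), layer_idx(lf), node_idx(nt), layer_idx(lt)
        if (i, a) == (j, b):
            raise ValidationError(f"{path}:{lineno}: self-edge on duplet {(i, a)}")
        if nature == MULTIPLEX and a != b and i != j:
            raise ValidationError(
                f"{path}:{lineno}: non-replica interlayer edge in declared multiplex"
            )
        e = canonical_edge((i, a), (j, b))
        if e in edges:
            logger.warning("%s:%d: duplicate edge %s collapsed", path, lineno, e)
        else:
            edges[e] = w
        max_n = max(max_n, i, j)
        max_m = max(max_m, a, b)

    n_nodes = N if N is not None else max_n + 1
    n_layers = M if M is not None else max_m + 1
    if n_nodes < 1 or n_layers < 1:
        raise ValidationError("empty edge list requires explicit N and M")
    node_labels = list(node_map) if node_map else None
    layer_labels = list(layer_map) if layer_map else None
    return MultilayerNetwork(
        n_nodes,
        n_layers,
        edges,
        nature=nature,
        node_labels=node_labels,
        layer_labels=layer_labels,
    )


def write_edgelist(net: MultilayerNetwork, path) -> None:
    """Write an extended edge list (sorted rows, full-precision weights).

    Round-trips with :func:`read_edgelist`: same edge set, labels, weights.
    """
    with open(path, "w") as fh:
        fh.write("# node_from layer_from node_to layer_to weight\n")
        fh.write(f"# N={net.N} M={net.M} nature={net.nature}\n")
        for (i, a), (j, b) in sorted(net.edges):
            w = net.edges[((i, a), (j, b))]
            nf = net.node_labels[i] if net.node_labels else i
            nt = net.node_labels[j] if net.node_labels else j
            lf = net.layer_labels[a] if net.layer_labels else a
            lt = net.layer_labels[b] if net.layer_labels else b
            fh.write(f"{nf} {lf} {nt} {lt} {w!r}\n")


# ---------------------------------------------------------------------------
# Dense supra-adjacency TSV (brain-network-style weighted input)
# ---------------------------------------------------------------------------


def write_supra_tsv(supra: SupraAdjacency, path) -> None:
    """Write a dense supra matrix as TSV plus a ``<path>.json`` sidecar.

    The sidecar records ``N``, ``M``, the side/indexing convention and any
    labels, so the file is self-describing.
    """
    path = Path(path)
    np.savetxt(path, supra.matrix, delimiter="\t")
    meta = {
        "N": supra.N,
        "M": supra.M,
        "side": supra.side,
        "indexing": "layer-major (a*N+i)" if supra.side == PRIMAL else "node-major (i*M+a)",
        "node_labels": list(supra.node_labels) if supra.node_labels else None,
        "layer_labels": list(supra.layer_labels) if supra.layer_labels else None,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_supra_tsv(path) -> SupraAdjacency:
    """Read a dense supra matrix written by :func:`write_supra_tsv`."""
    path = Path(path)
    A = np.loadtxt(path, delimiter="\t", ndmin=2)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return SupraAdjacency(
        A,
        meta["N"],
        meta["M"],
        side=meta["side"],
        node_labels=meta.get("node_labels"),
        layer_labels=meta.get("layer_labels"),
    )


def network_from_supra(
    supra: SupraAdjacency, nature: str = MULTILAYER, tol: float = 0.0
) -> MultilayerNetwork:
    """Extract the weighted edge set from a supra-adjacency matrix.

    Entries with absolute value ``<= tol`` are treated as absent.  The matrix
    must be symmetric with zero diagonal.
    """
    A = supra.matrix
    if not np.allclose(A, A.T):
        raise ValidationError("supra matrix must be symmetric")
    if np.any(np.abs(np.diag(A)) > tol):
        raise ValidationError("supra matrix must have zero diagonal (no self-edges)")
    N, M = supra.N, supra.M
    order = N * M

    def duplet(k):
        if supra.side == PRIMAL:
            return (k % N, k // N)
        return (k // M, k % M)

    edges = {}
    rows, cols = np.nonzero(np.triu(np.abs(A) > tol, k=1))
    for p, q in zip(rows, cols):
        edges[canonical_edge(duplet(int(p)), duplet(int(q)))] = float(A[p, q])
    return MultilayerNetwork(
        N,
        M,
        edges,
        nature=nature,
        node_labels=supra.node_labels,
        layer_labels=supra.layer_labels,
    )
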
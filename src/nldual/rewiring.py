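"""Three-parameter stochastic edge rewiring of multilayer networks.

A rewiring event relocates an existing edge to an empty admissible slot.  The
type of relocation is drawn from a categorical distribution over three moves:

``p_node``
    keep the (unordered) layer pair, redraw the node pair — perturbs which
    nodes interact while leaving every layer's connectivity budget intact;
``p_layer``
    keep the node pair, redraw the layer pair — the dual move;
``p_tel``
    "teleportation": redraw both, i.e. a uniform draw over all admissible
    slots of the declared nature.

``p_node + p_layer + p_tel = 1``.  A proportion ``r`` of edges is selected
without replacement and moved one by one against the current edge set; a
proposed destination that is occupied, equal to the source, a self-edge, or
that would break the declared nature (multiplex networks must keep interlayer
edges between replicas) is rejected and redrawn, and after ``max_attempts``
failed draws the move type itself is redrawn.  The edge count ``L``, the
nature, and the weight carried by each moved edge are conserved exactly.

Two exact conservation laws follow from the move geometry: ``p_node = 1``
preserves the layerwise multidegree sequence entirely, and ``p_layer = 1``
preserves the nodewise sequence.

:func:`uniform_rewire` draws destinations uniformly over *all* admissible
empty slots; :func:`effective_params` gives the slot-count mixture
``(p_node, p_layer, p_tel)`` that makes the parametric model statistically
equivalent to the uniform one in the sparse limit.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import numpy as np

from .netcore import (
    MULTILAYER,
    MULTIPLEX,
    MultilayerNetwork,
    canonical_edge,
)

__all__ = ["RewiringParams", "RewireStats", "rewire", "uniform_rewire", "effective_params"]


@dataclass(frozen=True)
class RewiringParams:
    """Perturbation specification ``(p_node, p_layer, p_tel, r)``.

    ``r`` is the fraction of edges selected for rewiring (``round(r*L)``,
    half-to-even); ``seed`` documents the RNG used; ``max_attempts`` bounds
    destination redraws before the move type is redrawn.
    """

    p_node: float
    p_layer: float
    p_tel: float
    r: float = 1.0
    seed: int | None = None
    max_attempts: int = 1000

    def __post_init__(self):
        total = self.p_node + self.p_layer + self.p_tel
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"p_node + p_layer + p_tel = {total}, must equal 1")
        for name in ("p_node", "p_layer", "p_tel"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.r <= 1):
            raise ValueError("r must lie in [0, 1]")


@dataclass
class RewireStats:
    """Bookkeeping of one rewiring run (move-class counts and rejections)."""

    n_moves: int = 0
    n_node_moves: int = 0  # destination kept the layer pair
    n_layer_moves: int = 0  # destination kept the node pair (layer pair changed)
    n_tel_moves: int = 0  # both changed
    n_rejections: int = 0


def _resolve_rng(rng) -> _pyrandom.Random:
    """Accept an int seed, a numpy Generator, a python Random, or None.

    Scalar move loops run on :class:`random.Random` (much faster than numpy
    scalar draws); numpy generators are bridged deterministically by drawing
    one 63-bit seed from them.
    """
    if isinstance(rng, _pyrandom.Random):
        return rng
    if isinstance(rng, np.random.Generator):
        return _pyrandom.Random(int(rng.integers(2**63)))
    return _pyrandom.Random(rng)


def _round_half_even(x: float) -> int:
    return int(round(x))


# -- destination proposal helpers -------------------------------------------
# Each returns a candidate canonical edge or None when the draw is structurally
# invalid (e.g. a self-edge); occupancy/source rejection happens in the caller.


def _propose_same_layers(src, N, M, nature, rng):
    (i, a), (j, b) = src
    if a == b:
        # new unordered node pair within layer a
        ii = rng.randrange(N)
        jj = rng.randrange(N)
        if ii == jj:
            return None
        return canonical_edge((ii, a), (jj, a))
    if nature == MULTIPLEX:
        # keeping an interlayer pair (a != b) in a multiplex forces a replica
        ii = rng.randrange(N)
        return canonical_edge((ii, a), (ii, b))
    ii = rng.randrange(N)
    jj = rng.randrange(N)
    return canonical_edge((ii, a), (jj, b))


def _propose_same_nodes(src, N, M, nature, rng):
    (i, a), (j, b) = src
    if i == j:
        # replica source: new unordered layer pair
        aa = rng.randrange(M)
        bb = rng.randrange(M)
        if aa == bb:
            return None
        return canonical_edge((i, aa), (i, bb))
    if nature == MULTIPLEX:
        aa = rng.randrange(M)
        return canonical_edge((i, aa), (j, aa))
    aa = rng.randrange(M)
    bb = rng.randrange(M)
    return canonical_edge((i, aa), (j, bb))


def _propose_uniform(N, M, nature, s_intra, S, rng):
    if nature == MULTILAYER:
        d1 = rng.randrange(N * M)
        d2 = rng.randrange(N * M)
        if d1 == d2:
            return None
        return canonical_edge((d1 % N, d1 // N), (d2 % N, d2 // N))
    # multiplex: pick the slot class proportionally to its slot count
    if rng.randrange(S) < s_intra:
        a = rng.randrange(M)
        ii = rng.randrange(N)
        jj = rng.randrange(N)
        if ii == jj:
            return None
        return canonical_edge((ii, a), (jj, a))
    i = rng.randrange(N)
    aa = rng.randrange(M)
    bb = rng.randrange(M)
    if aa == bb:
        return None
    return canonical_edge((i, aa), (i, bb))


def _run_rewiring(net, r, rng, move_drawer, max_attempts, stats):
    """Shared selection/relocation loop.

    ``move_drawer(src, rng)`` returns a fresh proposal callable for each
    attempt block (allowing the parametric model to redraw the move type).
    """
    edges = net.edges  # canonical edge -> weight (a copy)
    L = len(edges)
    n_moves = _round_half_even(r * L)
    if n_moves == 0:
        return MultilayerNetwork(
            net.N, net.M, edges, nature=net.nature,
            node_labels=net.node_labels, layer_labels=net.layer_labels, validate=False,
        )
    edge_list = sorted(edges)
    selected = rng.sample(edge_list, n_moves)
    occupied = set(edges)
    total_budget = max_attempts * max(L, 1)
    tries = 0
    for src in selected:
        w = edges.pop(src)
        occupied.discard(src)
        dest = None
        while dest is None:
            propose = move_drawer(src, rng)
            for _ in range(max_attempts):
                tries += 1
                if tries > total_budget:
                    raise RuntimeError(
                        "rewiring failed: no admissible empty slot found "
                        f"within {total_budget} proposals (network too dense?)"
                    )
                cand = propose(rng)
                if cand is None or cand == src or cand in occupied:
                    stats.n_rejections += 1
                    continue
                dest = cand
                break
        edges[dest] = w
        occupied.add(dest)
        stats.n_moves += 1
        (si, sa), (sj, sb) = src
        (di, da), (dj, db) = dest
        if {sa, sb} == {da, db}:
            stats.n_node_moves += 1
        elif {si, sj} == {di, dj}:
            stats.n_layer_moves += 1
        else:
            stats.n_tel_moves += 1
    return MultilayerNetwork(
        net.N, net.M, edges, nature=net.nature,
        node_labels=net.node_labels, layer_labels=net.layer_labels, validate=False,
    )


def rewire(
    net: MultilayerNetwork,
    params: RewiringParams,
    rng=None,
    return_stats: bool = False,
):
    """Rewire ``round(r*L)`` edges under the three-parameter move model.

    ``rng`` may be an int seed, a ``numpy.random.Generator`` or a
    ``random.Random``; identical seed and input give identical output.  When
    ``rng`` is None, ``params.seed`` is used.
    """
    rng = _resolve_rng(params.seed if rng is None else rng)
    N, M, nature = net.N, net.M, net.nature
    cum_node = params.p_node
    cum_layer = params.p_node + params.p_layer
    s_intra = M * (N * (N - 1) // 2)
    S = s_intra + N * (M * (M - 1) // 2)

    def move_drawer(src, rng):
        u = rng.random()
        if u < cum_node:
            return lambda rng: _propose_same_layers(src, N, M, nature, rng)
        if u < cum_layer:
            return lambda rng: _propose_same_nodes(src, N, M, nature, rng)
        return lambda rng: _propose_uniform(N, M, nature, s_intra, S, rng)

    stats = RewireStats()
    out = _run_rewiring(net, params.r, rng, move_drawer, params.max_attempts, stats)
    return (out, stats) if return_stats else out


def uniform_rewire(
    net: MultilayerNetwork,
    r: float = 1.0,
    rng=None,
    max_attempts: int = 1000,
    return_stats: bool = False,
):
    """Complete uniform rewiring: destinations uniform over all admissible
    empty slots of the declared nature.

    Equivalent to :func:`rewire` with the slot-count-weighted mixture of move
    types (see :func:`effective_params`).  ``r`` defaults to 1 ("complete").
    """
    if not (0 <= r <= 1):
        raise ValueError("r must lie in [0, 1]")
    rng = _resolve_rng(rng)
    N, M, nature = net.N, net.M, net.nature
    s_intra = M * (N * (N - 1) // 2)
    S = s_intra + N * (M * (M - 1) // 2)

    def move_drawer(src, rng):
        return lambda rng: _propose_uniform(N, M, nature, s_intra, S, rng)

    stats = RewireStats()
    out = _run_rewiring(net, r, rng, move_drawer, max_attempts, stats)
    return (out, stats) if return_stats else out


def effective_params(N: int, M: int, nature: str) -> RewiringParams:
    """Slot-count fractions turning a uniform draw into move-type probabilities.

    For a uniform draw over all admissible slots, the probability that the
    destination keeps the source's unordered layer pair (a node-type move) or
    its unordered node pair with a new layer pair (a layer-type move) depends
    on the source edge's class.  Classes are weighted by their slot-count
    share — the expected class mix of a uniformly random source edge — giving
    the ``(p_node, p_layer, p_tel)`` for which :func:`rewire` is statistically
    equivalent to :func:`uniform_rewire` in the sparse limit.  Classification
    priority: layer-pair preserved first, then node-pair preserved, else tel.
    """
    if N < 2 or M < 1:
        raise ValueError("need N >= 2 and M >= 1")
    cN2 = N * (N - 1) // 2
    cM2 = M * (M - 1) // 2
    if nature == MULTILAYER:
        S = admissible = N * M * (N * M - 1) // 2
        w_intra = M * cN2 / S
        w_rep = cM2 * N / S
        w_inter = cM2 * N * (N - 1) / S
        p_node = (w_intra * cN2 + (w_rep + w_inter) * N * N) / S
        p_layer = (
            w_intra * (M * M - 1) + w_inter * (M * M - 2) + w_rep * max(cM2 - 1, 0)
        ) / S
    elif nature == MULTIPLEX:
        S = M * cN2 + N * cM2
        if S == 0:
            raise ValueError("degenerate multiplex: no admissible slots")
        w_intra = M * cN2 / S
        w_rep = N * cM2 / S
        p_node = (w_intra * cN2 + w_rep * N) / S
        p_layer = (w_intra * (M - 1) + w_rep * max(cM2 - 1, 0)) / S
    else:
        raise ValueError(f"unknown nature {nature!r}")
    # degenerate geometries (e.g. M = 1) can leave no layer-changing slot at
    # all; every admissible destination then preserves the layer pair
    if M == 1:
        p_node, p_layer = 1.0, 0.0
    p_tel = max(1.0 - p_node - p_layer, 0.0)
    return RewiringParams(p_node=p_node, p_layer=p_layer, p_tel=p_tel, r=1.0)
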
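"""Synthetic multilayer network generators.

Three families are provided:

* :func:`random_multilayer` — every admissible unordered pair of distinct
  duplets is an independent Bernoulli(q) slot;
* :func:`random_multiplex` — same, with slots restricted to intralayer pairs
  and replica pairs;
* :func:`powerlaw_multidegree` — a configuration-style placement producing
  heavy-tailed (power-law) multidegree sequences, emulating the strong hub
  structure of real multiplexes.

Density ``q`` is defined relative to the *nature-specific* slot count, so a
multilayer and a multiplex generated at the same ``q`` do not have comparable
edge counts.  Sparse generation samples integer slot indices with rejection of
duplicates and never enumerates the full slot set (which reaches ~8e8 slots
already at N = M = 200).
"""

from __future__ import annotations

import numpy as np

from .netcore import (
    MULTILAYER,
    MULTIPLEX,
    MultilayerNetwork,
    admissible_slots,
)

__all__ = ["random_multilayer", "random_multiplex", "powerlaw_multidegree"]


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Unordered-pair index codec: pairs (a < b) drawn from range(D) are encoded as
# idx = a*(2D - a - 1)/2 + (b - a - 1), a bijection onto range(D*(D-1)/2).
# ---------------------------------------------------------------------------


def _pair_offset(a: np.ndarray, D: int) -> np.ndarray:
    """Index of the first pair whose smaller element is ``a``."""
    return a * (2 * D - a - 1) // 2


def encode_pair(a, b, D: int):
    """Encode unordered pairs ``a < b`` over ``range(D)`` as flat indices."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    return _pair_offset(lo, D) + (hi - lo - 1)


def decode_pair(idx, D: int):
    """Inverse of :func:`encode_pair`; vectorized, with integer correction of
    the floating-point root so indices up to ~1e15 decode exactly."""
    idx = np.asarray(idx, dtype=np.int64)
    t = 2 * D - 1
    a = ((t - np.sqrt(t * t - 8.0 * idx)) // 2).astype(np.int64)
    a = np.maximum(a - 1, 0)
    # at most two upward corrections are needed after the conservative guess
    for _ in range(3):
        a = np.where(_pair_offset(a + 1, D) <= idx, a + 1, a)
    b = idx - _pair_offset(a, D) + a + 1
    return a, b


def _sample_distinct_indices(S: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform L-subset of ``range(S)`` without replacement.

    Small slot spaces are permuted outright; large sparse ones use sequential
    rejection of duplicates (exact, and collision-free in practice when
    L << S).
    """
    if L > S:
        raise ValueError(f"cannot place {L} edges in {S} slots")
    if S <= max(4 * L, 1_000_000):
        return rng.permutation(S)[:L]
    chosen: list[np.ndarray] = []
    seen = np.array([], dtype=np.int64)
    need = L
    while need > 0:
        draw = rng.integers(0, S, size=int(need * 1.05) + 16)
        # keep first occurrences in draw order (sequential rejection sampling)
        _, first = np.unique(draw, return_index=True)
        fresh = draw[np.sort(first)]
        if len(seen):
            fresh = fresh[~np.isin(fresh, seen)]
        fresh = fresh[:need]
        chosen.append(fresh)
        seen = np.concatenate([seen, fresh])
        need = L - len(seen)
    return np.concatenate(chosen)


def _multilayer_edges_from_slots(slots: np.ndarray, N: int, M: int) -> np.ndarray:
    """Decode multilayer slot indices into ``(i, a, j, b)`` rows.

    Duplets are numbered layer-major, ``d = a*N + i``; slots are unordered
    pairs of distinct duplet ids.
    """
    d1, d2 = decode_pair(slots, N * M)
    return np.column_stack([d1 % N, d1 // N, d2 % N, d2 // N])


def _multiplex_edges_from_slots(slots: np.ndarray, N: int, M: int) -> np.ndarray:
    """Decode multiplex slot indices: intralayer slots first, then replicas."""
    s_intra_per_layer = N * (N - 1) // 2
    s_intra = M * s_intra_per_layer
    s_rep_per_node = M * (M - 1) // 2
    out = np.empty((len(slots), 4), dtype=np.int64)
    is_intra = slots < s_intra
    if is_intra.any():
        s = slots[is_intra]
        layer = s // s_intra_per_layer
        i, j = decode_pair(s % s_intra_per_layer, N)
        out[is_intra] = np.column_stack([i, layer, j, layer])
    if (~is_intra).any():
        s = slots[~is_intra] - s_intra
        node = s // s_rep_per_node
        a, b = decode_pair(s % s_rep_per_node, M)
        out[~is_intra] = np.column_stack([node, a, node, b])
    return out


def _random_network(N, M, q, rng, nature, fixed_l):
    if not (0 <= q <= 1):
        raise ValueError("q must lie in [0, 1]")
    rng = _as_generator(rng)
    S = admissible_slots(N, M, nature)
    L = int(fixed_l) if fixed_l is not None else int(rng.binomial(S, q))
    slots = _sample_distinct_indices(S, L, rng)
    if nature == MULTILAYER:
        idx = _multilayer_edges_from_slots(slots, N, M)
    else:
        idx = _multiplex_edges_from_slots(slots, N, M)
    return MultilayerNetwork.from_arrays(N, M, idx, nature=nature, validate=False)


def random_multilayer(N, M, q, rng=None, fixed_l=None) -> MultilayerNetwork:
    """Erdos-Renyi-style random multilayer network.

    Each of the ``S = NM(NM-1)/2`` duplet-pair slots is occupied independently
    with probability ``q`` (edge count drawn as Binomial(S, q), slots uniform
    without replacement).  Pass ``fixed_l`` to pin the edge count instead.
    """
    return _random_network(N, M, q, rng, MULTILAYER, fixed_l)


def random_multiplex(N, M, q, rng=None, fixed_l=None) -> MultilayerNetwork:
    """Random multiplex: slots restricted to intralayer and replica pairs.

    The slot count is ``S = (N*M/2)*(N + M - 2)``; interlayer edges exist only
    between replicas, so the output nature is ``'multiplex'``.
    """
    return _random_network(N, M, q, rng, MULTIPLEX, fixed_l)


def powerlaw_multidegree(
    N,
    M,
    exponent: float,
    L: int,
    rng=None,
    layer_exponent: float | None = None,
    max_batches: int = 200,
) -> MultilayerNetwork:
    """Multiplex fixture with power-law multidegree centrality distributions.

    Nodes receive Zipf attachment weights ``w_i ~ (i+1)^(-1/(exponent-1))``, so
    the realized nodewise multidegree sequence has tail exponent close to
    ``exponent`` (a rank-size regression of log-degree on log-rank has slope
    ``~ -1/(exponent-1)``).  Layers receive analogous weights with
    ``layer_exponent`` (default: same as ``exponent``); heterogeneous layer
    activity mirrors real multiplexes, where a few layers concentrate most
    links.  Exactly ``L`` distinct intralayer edges are placed by rejection.

    Raises ``ValueError`` when ``exponent <= 1`` or the requested ``L`` exceeds
    half the intralayer slot count (placement infeasible by rejection).
    """
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    if layer_exponent is None:
        layer_exponent = exponent
    rng = _as_generator(rng)
    s_intra = M * (N * (N - 1) // 2)
    if L > s_intra // 2:
        raise ValueError(f"L={L} infeasible: more than half of {s_intra} intralayer slots")

    p_node = (np.arange(1, N + 1, dtype=float)) ** (-1.0 / (exponent - 1.0))
    p_node /= p_node.sum()
    p_layer = (np.arange(1, M + 1, dtype=float)) ** (-1.0 / (layer_exponent - 1.0))
    p_layer /= p_layer.sum()

    s_intra_per_layer = N * (N - 1) // 2
    seen = np.array([], dtype=np.int64)
    rows = []
    need = L
    for _ in range(max_batches):
        if need <= 0:
            break
        size = int(need * 1.3) + 16
        i = rng.choice(N, size=size, p=p_node)
        j = rng.choice(N, size=size, p=p_node)
        a = rng.choice(M, size=size, p=p_layer)
        ok = i != j
        i, j, a = i[ok], j[ok], a[ok]
        key = a * s_intra_per_layer + np.minimum(i, j) * (2 * N - np.minimum(i, j) - 1) // 2 + (
            np.maximum(i, j) - np.minimum(i, j) - 1
        )
        _, first = np.unique(key, return_index=True)
        order = np.sort(first)
        key, i, j, a = key[order], i[order], j[order], a[order]
        if len(seen):
            fresh = ~np.isin(key, seen)
            key, i, j, a = key[fresh], i[fresh], j[fresh], a[fresh]
        key, i, j, a = key[:need], i[:need], j[:need], a[:need]
        rows.append(np.column_stack([i, a, j, a]))
        seen = np.concatenate([seen, key])
        need = L - len(seen)
    if need > 0:
        raise ValueError("could not place the requested number of edges (sequence infeasible)")
    idx = np.concatenate(rows)
    return MultilayerNetwork.from_arrays(N, M, idx, nature=MULTIPLEX, validate=False)
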
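"""Closed-form predictions for multidegree change under stochastic rewiring.

For sufficiently sparse and large networks, a Markov-chain analysis of the
rewiring model yields compact expectations.  After rewiring a fraction ``r``
of edges, the expected multidegree of unit ``u`` is a linear relaxation
towards the mean::

    k(r) = k0 + r * (mu - k0) * factor,

with ``factor = 1 - p_layer`` for nodewise profiles (node multidegrees are
blind to moves that keep the node pair) and ``factor = 1 - p_node`` for
layerwise ones.  The mean is preserved.  The global connectivity change,
measured as the Euclidean norm of the expected displacement, is then exactly::

    d_X(r) = r * sqrt(N) * sigma_X * (1 - p_layer)
    d_Y(r) = r * sqrt(M) * sigma_Y * (1 - p_node)

with population (divide-by-n) standard deviations.  The two distances are
proportional, ``d_Y = c * (1 - p_node)/(1 - p_layer) * d_X`` with the
system-intrinsic scaling constant ``c = sqrt(M)*sigma_Y / (sqrt(N)*sigma_X)``.

For Bernoulli random networks the standard deviations admit closed forms
(:func:`random_sigma`), giving ``c = 1`` exactly at ``N = M`` and the size
scalings ``d ~ N*M`` (multilayer) and ``d_X ~ sqrt(M)*N``,
``d_Y ~ sqrt(2M)*N`` (multiplex) under complete uniform rewiring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .netcore import (
    LAYERWISE,
    MULTILAYER,
    MULTIPLEX,
    NODEWISE,
    CentralityProfile,
    MultilayerNetwork,
    multidegree,
)
from .rewiring import RewiringParams

__all__ = [
    "DistancePrediction",
    "expected_multidegree",
    "expected_distance",
    "scaling_constant",
    "predict",
    "size_scaling",
    "random_sigma",
    "optimal_multiplex_split",
]


@dataclass
class DistancePrediction:
    """Bundle of the two predicted distances, ``c`` and the duality slope.

    ``slope = c*(1-p_node)/(1-p_layer)`` satisfies
    ``d_layerwise = slope * d_nodewise`` whenever ``p_layer < 1``; at
    ``p_layer = 1`` the ratio is undefined (``slope = nan``) and
    ``d_layerwise`` is reported directly from its own closed form.
    """

    d_nodewise: float
    d_layerwise: float
    c: float
    slope: float


def _change_factor(side: str, params: RewiringParams) -> float:
    return 1.0 - params.p_layer if side == NODEWISE else 1.0 - params.p_node


def expected_multidegree(k0: CentralityProfile, params: RewiringParams) -> CentralityProfile:
    """Expected multidegree profile after rewiring a fraction ``r`` of edges.

    Values above the mean decay towards it, values below grow, linearly in
    ``r`` and modulated by the move mix; the profile mean is invariant.
    """
    f = _change_factor(k0.side, params)
    k = k0.values
    return CentralityProfile(k + params.r * (k.mean() - k) * f, k0.side)


def expected_distance(k0: CentralityProfile, params: RewiringParams) -> float:
    """Euclidean norm of the expected multidegree displacement.

    ``d = r * sqrt(n) * sigma * factor`` — an exact identity with
    ``||expected_multidegree(k0) - k0||_2`` under the population-sigma
    convention.
    """
    f = _change_factor(k0.side, params)
    return float(params.r * math.sqrt(len(k0)) * k0.sigma * f)


def scaling_constant(net: MultilayerNetwork) -> float:
    """System-intrinsic constant ``c = sqrt(M)*sigma_Y / (sqrt(N)*sigma_X)``.

    Computed from the network's own multidegree profiles; raises when the
    nodewise profile is degenerate (``sigma_X = 0``, e.g. empty or perfectly
    regular networks).
    """
    kx = multidegree(net, NODEWISE)
    ky = multidegree(net, LAYERWISE)
    if kx.sigma == 0:
        raise ValueError("sigma_X = 0: scaling constant undefined for this network")
    return math.sqrt(net.M) * ky.sigma / (math.sqrt(net.N) * kx.sigma)


def predict(net: MultilayerNetwork, params: RewiringParams) -> DistancePrediction:
    """Closed-form nodewise and layerwise distances for one network + move mix."""
    kx = multidegree(net, NODEWISE)
    ky = multidegree(net, LAYERWISE)
    d_x = expected_distance(kx, params)
    d_y = expected_distance(ky, params)
    c = scaling_constant(net)
    if params.p_layer < 1.0:
        slope = c * (1.0 - params.p_node) / (1.0 - params.p_layer)
    else:
        slope = float("nan")
    return DistancePrediction(d_nodewise=d_x, d_layerwise=d_y, c=c, slope=slope)


def size_scaling(N: int, M: int, nature: str) -> tuple[float, float]:
    """Asymptotic scale factors ``(d_X_scale, d_Y_scale)`` under complete
    uniform rewiring of sparse random networks.

    Multilayer: both distances grow like ``N*M``.  Multiplex:
    ``d_X ~ sqrt(M)*N`` and ``d_Y ~ sqrt(2M)*N`` — layerwise changes outpace
    nodewise by a factor ``sqrt(2)`` at any size.  Absolute prefactors
    (density, rewiring fraction) are deliberately not included.
    """
    if N < 1 or M < 1:
        raise ValueError("need N, M >= 1")
    if nature == MULTILAYER:
        s = float(N * M)
        return s, s
    if nature == MULTIPLEX:
        return math.sqrt(M) * N, math.sqrt(2 * M) * N
    raise ValueError(f"unknown nature {nature!r}")


def optimal_multiplex_split(total: float) -> tuple[float, float]:
    """Continuous ``(N, M)`` maximizing the multiplex nodewise scale
    ``sqrt(M)*N`` subject to ``N + M = total``.

    Found numerically; the analytic optimum is ``M = total/3`` (so
    ``N - M = total/3``), in contrast with the multilayer case whose ``N*M``
    scale peaks at the symmetric split ``N = M``.
    """
    res = minimize_scalar(
        lambda m: -math.sqrt(m) * (total - m), bounds=(1e-9, total - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    m = float(res.x)
    return total - m, m


def random_sigma(N: int, M: int, q: float, nature: str, side: str) -> float:
    """Closed-form multidegree standard deviation of a Bernoulli random network.

    Each admissible slot is occupied independently with probability ``q``; a
    unit's multidegree is the weighted slot-occupancy sum (replica slots count
    twice nodewise, intralayer slots twice layerwise).  The population variance
    across exchangeable units has expectation
    ``(1 - 1/n) * (Var(k) - Cov(k, k'))``, which evaluates to::

        multilayer, nodewise :  (1-1/N) * q(1-q) * [M^2 (N-2) + 2 M (M-1)]
        multilayer, layerwise:  (1-1/M) * q(1-q) * [N^2 (M-2) + 2 N (N-1)]
        multiplex,  nodewise :  (1-1/N) * q(1-q) * [M (N-2)   + 2 M (M-1)]
        multiplex,  layerwise:  (1-1/M) * q(1-q) * [2 N (N-1) + N (M-2)]

    At ``N = M`` the two multilayer forms coincide, hence ``c = 1``.  Valid in
    the sparse independent-slot regime; validated against the generator +
    multidegree simulation oracle in the test suite.
    """
    if not (0 <= q <= 1):
        raise ValueError("q must lie in [0, 1]")
    v = q * (1.0 - q)
    if nature == MULTILAYER:
        if side == NODEWISE:
            var = (1 - 1 / N) * v * (M * M * (N - 2) + 2 * M * (M - 1))
        elif side == LAYERWISE:
            var = (1 - 1 / M) * v * (N * N * (M - 2) + 2 * N * (N - 1))
        else:
            raise ValueError(f"unknown side {side!r}")
    elif nature == MULTIPLEX:
        if side == NODEWISE:
            var = (1 - 1 / N) * v * (M * (N - 2) + 2 * M * (M - 1))
        elif side == LAYERWISE:
            var = (1 - 1 / M) * v * (2 * N * (N - 1) + N * (M - 2))
        else:
            raise ValueError(f"unknown side {side!r}")
    else:
        raise ValueError(f"unknown nature {nature!r}")
    return math.sqrt(max(var, 0.0))
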
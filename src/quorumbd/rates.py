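"""State-dependent birth and death rates of the producer/cheater process.

Per-population (not per-capita) rates for the four reaction channels:
producer birth, producer death, cheater birth, cheater death.  The
public-good benefit and the quorum-sensing activation both enter as Hill
functions of counts; the producer birth rate is clamped at zero because a
high production cost with low activation can otherwise drive the bracketed
per-capita rate negative.  The cheater birth rate has no cost term and is
non-negative by construction, so it carries no clamp.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .params import (
    SYMBOLIC_INFINITY,
    SYMBOLIC_ZERO,
    ModelParameters,
    SignalingMode,
    Strategy,
)

__all__ = [
    "hill",
    "activation",
    "producer_birth_rate",
    "producer_death_rate",
    "cheater_birth_rate",
    "cheater_death_rate",
    "net_growth",
    "equilibrium_producers",
    "rate_tables",
]

ArrayLike = Union[float, int, np.ndarray]


def hill(x: ArrayLike, K, h: float) -> ArrayLike:
    """Hill saturation (x/K)^h / (1 + (x/K)^h).

    ``K`` may be a positive number or the symbolic strings ``"zero"`` /
    ``"infinity"``, which give the exact saturated (1) and silent (0)
    limits without ever forming an extreme float ratio.

    Parameters
    ----------
    x : count (scalar or array), must be >= 0.
    K : half-maximal count, > 0, or symbolic zero/infinity.
    h : Hill exponent, > 0.
    """
    if np.any(np.asarray(x) < 0):
        raise ValueError("hill: x must be non-negative")
    if h <= 0:
        raise ValueError("hill: exponent h must be positive")
    if isinstance(K, str):
        if K == SYMBOLIC_ZERO:
            return np.ones_like(np.asarray(x, dtype=float)) if isinstance(x, np.ndarray) else 1.0
        if K == SYMBOLIC_INFINITY:
            return np.zeros_like(np.asarray(x, dtype=float)) if isinstance(x, np.ndarray) else 0.0
        raise ValueError(f"hill: unknown symbolic K {K!r}")
    if not K > 0:
        raise ValueError("hill: finite K must be positive")
    xarr = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        r = (xarr / K) ** h
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    if not isinstance(x, np.ndarray):
        return float(out)
    return out


def activation(x: ArrayLike, p: ModelParameters, strategy: Strategy) -> ArrayLike:
    """Public-good activation factor in [0, 1] for signaling count ``x``.

    AO is the exact Ka -> 0 limit (identically 1), NP the exact Ka -> inf
    limit (identically 0); QS evaluates the Hill factor at the parameters'
    Ka (which itself may be symbolic).
    """
    strategy = Strategy(strategy)
    if strategy is Strategy.AO:
        return np.ones_like(np.asarray(x, dtype=float)) if isinstance(x, np.ndarray) else 1.0
    if strategy is Strategy.NP:
        return np.zeros_like(np.asarray(x, dtype=float)) if isinstance(x, np.ndarray) else 0.0
    return hill(x, p.Ka, p.ha)


def _signal_count(n: ArrayLike, m: ArrayLike, signaling: SignalingMode) -> ArrayLike:
    signaling = SignalingMode(signaling)
    if signaling is SignalingMode.PRODUCERS_AND_CHEATERS:
        return n + m
    return n


def producer_birth_rate(
    n: ArrayLike,
    m: ArrayLike,
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
) -> ArrayLike:
    """Total producer birth rate max([λ0 + ((g+a)·B(n) − c)·A(x)]·n, 0).

    B is the benefit Hill factor of n; A the activation factor of the
    signaling count x (= n, or n + m when cheaters signal).  The clamp
    applies to the whole bracket times n.
    """
    x = _signal_count(n, m, signaling)
    per_capita = p.lambda0 + ((p.g + p.a) * hill(n, p.Kg, p.hg) - p.c) * activation(x, p, strategy)
    total = per_capita * np.asarray(n, dtype=float)
    out = np.maximum(total, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def producer_death_rate(n: ArrayLike, m: ArrayLike, p: ModelParameters) -> ArrayLike:
    """Total producer death rate μ0·(n+m)·n (density-dependent per capita)."""
    out = p.mu0 * (np.asarray(n, dtype=float) + np.asarray(m, dtype=float)) * np.asarray(n, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def cheater_birth_rate(
    n: ArrayLike,
    m: ArrayLike,
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
) -> ArrayLike:
    """Total cheater birth rate [λ0 + g·B(n)·A(x)]·m.

    Cheaters pay no cost and get no producer advantage; every addend is
    non-negative, so no clamp is needed.
    """
    x = _signal_count(n, m, signaling)
    per_capita = p.lambda0 + p.g * hill(n, p.Kg, p.hg) * activation(x, p, strategy)
    out = per_capita * np.asarray(m, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def cheater_death_rate(n: ArrayLike, m: ArrayLike, p: ModelParameters) -> ArrayLike:
    """Total cheater death rate μ0·(n+m)·m."""
    out = p.mu0 * (np.asarray(n, dtype=float) + np.asarray(m, dtype=float)) * np.asarray(m, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def net_growth(
    n: ArrayLike,
    m: ArrayLike,
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
) -> ArrayLike:
    """Expected net total population growth rate λ^Pr + λ^Ch − μ^Pr − μ^Ch."""
    out = (
        producer_birth_rate(n, m, p, strategy, signaling)
        + cheater_birth_rate(n, m, p, strategy, signaling)
        - producer_death_rate(n, m, p)
        - cheater_death_rate(n, m, p)
    )
    return float(out) if np.ndim(out) == 0 else out


def equilibrium_producers(p: ModelParameters) -> int:
    """Approximate pure-producer equilibrium n* = round((λ0 + g − c) / μ0).

    Rounding is half-up (0.5 rounds away from zero), matching the
    conventional reading of "round" rather than banker's rounding.
    """
    x = (p.lambda0 + p.g - p.c) / p.mu0
    return int(math.floor(x + 0.5))


def rate_tables(
    p: ModelParameters,
    strategy: Strategy,
    signaling: SignalingMode,
    N: int,
):
    """All four rates on the full (N+1) x (N+1) lattice.

    Returns four arrays indexed ``[n, m]``: producer births, producer
    deaths, cheater births, cheater deaths.
    """
    n, m = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
    lam_pr = producer_birth_rate(n, m, p, strategy, signaling)
    mu_pr = producer_death_rate(n, m, p)
    lam_ch = cheater_birth_rate(n, m, p, strategy, signaling)
    mu_ch = cheater_death_rate(n, m, p)
    return lam_pr, mu_pr, lam_ch, mu_ch
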
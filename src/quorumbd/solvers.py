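"""Stationary backward-Kolmogorov solvers on the truncated lattice.

Every quantity of interest is the solution of a boundary-value problem for
the generator Q acting on a field f over states (n, m):

* cheater fixation probability  pi^Ch:   (Q f) = 0,  f = 1 on the cheater
  axis (n = 0, m > 0), f = 0 on the producer axis (m = 0);
* producer fixation probability pi^Pr:   same with the axes swapped;
* time-weighted fixation field  theta:   (Q f) = -pi^Ch, f = 0 on both
  axes; the conditional mean first passage time is tau = theta / pi^Ch;
* mean extinction time          T:       (Q f) = -1 away from (0, 0),
  f(0, 0) = 0.

Direct solution of the extinction-time system becomes numerically unstable
when T is astronomically large; the decomposition estimator replaces it by
the first-axis-hitting distribution combined with closed-form 1-D axis
extinction times, under the assumption that one strain fixes quickly and
the pure population then persists much longer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import RateGenerator, StateGrid, build_generator
from .params import ModelParameters, SignalingMode, Strategy
from .rates import cheater_birth_rate, cheater_death_rate, producer_birth_rate, producer_death_rate

__all__ = [
    "SolutionField",
    "AxisHittingDistribution",
    "SolverError",
    "fixation_probability",
    "producer_fixation_probability",
    "conditional_fixation_time",
    "mean_extinction_time_direct",
    "axis_birth_death_rates",
    "met_axis_closed_form",
    "axis_hitting_distribution",
    "met_decomposition",
    "mean_extinction_time",
]

#: relative residual above which a direct solve is declared unstable
RESIDUAL_TOL = 1e-6


class SolverError(RuntimeError):
    """A linear system could not be solved for the given parameter set."""


@dataclass
class SolutionField:
    """A scalar quantity defined on every state of the grid.

    ``values`` is indexed ``[n, m]``; undefined entries (e.g. tau where
    pi^Ch = 0) are NaN and serialize as null.
    """

    quantity: str  # piCh | piPr | theta | tauCh | T
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.values.shape[0] - 1

    def __getitem__(self, nm):
        n, m = nm
        return self.values[n, m]

    def to_dataframe(self):
        import pandas as pd

        N = self.N
        n, m = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
        return pd.DataFrame(
            {"n": n.ravel(), "m": m.ravel(), "value": self.values.ravel()}
        )


def _meta(gen: RateGenerator, **extra) -> dict:
    d = {
        "strategy": gen.strategy.value,
        "signaling": gen.signaling.value,
        "N": gen.grid.N,
    }
    d.update(extra)
    return d


def _dirichlet_solve(
    gen: RateGenerator,
    boundary_mask: np.ndarray,
    boundary_values: np.ndarray,
    rhs: np.ndarray,
    what: str,
):
    """Solve (Q f)_k = rhs_k on non-boundary states with f fixed on the boundary.

    Returns (full field flat, relative residual on the solved rows).
    """
    Q = gen.Q
    interior = ~boundary_mask
    A = Q[interior][:, interior].tocsc()
    B = Q[interior][:, boundary_mask]
    b = rhs[interior] - B @ boundary_values[boundary_mask]
    try:
        lu = spla.splu(A)
        x = lu.solve(b)
    except RuntimeError as exc:  # singular factorization
        raise SolverError(
            f"{what}: sparse factorization failed for "
            f"{gen.strategy.value}/{gen.signaling.value} at N={gen.grid.N}: {exc}"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SolverError(
            f"{what}: non-finite solution for {gen.strategy.value} at N={gen.grid.N}"
        )
    # residual relative to the right-hand side, not to ||A||*||x||: the
    # forward error of these systems explodes with conditioning while the
    # backward error stays tiny, so scaling by ||b|| is what actually
    # detects untrustworthy extinction times
    resid = A @ x - b
    scale = float(np.abs(b).max())
    rel_resid = float(np.abs(resid).max() / scale) if scale > 0 else float(np.abs(resid).max())
    full = boundary_values.astype(float).copy()
    full[interior] = x
    return full, rel_resid


def _axis_masks(grid: StateGrid):
    n, m = grid.state(np.arange(grid.n_states))
    return n == 0, m == 0  # cheater axis (incl. origin), producer axis (incl. origin)


def fixation_probability(gen: RateGenerator) -> SolutionField:
    """Cheater fixation probability pi^Ch on every state.

    Boundary conditions: pi = 1 on the cheater axis (n = 0, 0 < m <= N) and
    pi = 0 on the producer axis (m = 0, including the origin), imposed
    exactly; the interior solves the stationary backward equation.
    """
    grid = gen.grid
    on_cheater_axis, on_producer_axis = _axis_masks(grid)
    boundary = on_cheater_axis | on_producer_axis
    bvals = np.zeros(grid.n_states)
    bvals[on_cheater_axis & ~on_producer_axis] = 1.0
    full, rr = _dirichlet_solve(gen, boundary, bvals, np.zeros(grid.n_states), "piCh")
    return SolutionField("piCh", full.reshape(grid.N + 1, grid.N + 1), _meta(gen, solver="sparse-direct", residual=rr))


def producer_fixation_probability(gen: RateGenerator) -> SolutionField:
    """Producer fixation probability pi^Pr (complement diagnostic of pi^Ch)."""
    grid = gen.grid
    on_cheater_axis, on_producer_axis = _axis_masks(grid)
    boundary = on_cheater_axis | on_producer_axis
    bvals = np.zeros(grid.n_states)
    bvals[on_producer_axis & ~on_cheater_axis] = 1.0
    full, rr = _dirichlet_solve(gen, boundary, bvals, np.zeros(grid.n_states), "piPr")
    return SolutionField("piPr", full.reshape(grid.N + 1, grid.N + 1), _meta(gen, solver="sparse-direct", residual=rr))


def conditional_fixation_time(gen: RateGenerator, pi_ch: SolutionField):
    """Conditional mean first passage time to cheater fixation.

    Solves the theta system (right-hand side -pi^Ch, theta = 0 on both
    axes) and returns ``(theta, tau)`` where tau = theta / pi^Ch wherever
    pi^Ch > 0 and NaN elsewhere (the conditioning event has probability
    zero there, so the time is undefined).
    """
    grid = gen.grid
    on_cheater_axis, on_producer_axis = _axis_masks(grid)
    boundary = on_cheater_axis | on_producer_axis
    bvals = np.zeros(grid.n_states)
    rhs = -pi_ch.values.ravel()
    full, rr = _dirichlet_solve(gen, boundary, bvals, rhs, "theta")
    theta = SolutionField("theta", full.reshape(grid.N + 1, grid.N + 1), _meta(gen, solver="sparse-direct", residual=rr))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_vals = np.where(pi_ch.values > 0, theta.values / pi_ch.values, np.nan)
    tau = SolutionField("tauCh", tau_vals, _meta(gen, solver="sparse-direct", residual=rr))
    return theta, tau


def mean_extinction_time_direct(gen: RateGenerator) -> SolutionField:
    """Mean time to reach the extinct state (0, 0), by direct sparse solve.

    The system (Q T) = -1 with T(0,0) = 0 covers all states including the
    axes.  The result carries ``meta["unstable"] = True`` when any entry is
    negative or non-finite or the relative residual exceeds 1e-6 — the
    caller should then fall back to the decomposition estimator.
    """
    grid = gen.grid
    boundary = np.zeros(grid.n_states, dtype=bool)
    boundary[grid.index(0, 0)] = True
    bvals = np.zeros(grid.n_states)
    rhs = np.full(grid.n_states, -1.0)
    rhs[grid.index(0, 0)] = 0.0
    full, rr = _dirichlet_solve(gen, boundary, bvals, rhs, "T")
    vals = full.reshape(grid.N + 1, grid.N + 1)
    unstable = bool((vals < 0).any() or not np.all(np.isfinite(vals)) or rr > RESIDUAL_TOL)
    return SolutionField(
        "T", vals, _meta(gen, solver="sparse-direct", residual=rr, unstable=unstable)
    )


# ---------------------------------------------------------------------------
# 1-D axis chains: closed-form extinction times
# ---------------------------------------------------------------------------

def axis_birth_death_rates(
    p: ModelParameters,
    strategy: Strategy,
    signaling: SignalingMode,
    N: int,
    axis: str,
):
    """Birth and death rates of the 1-D chain on a pure-strain axis.

    ``axis="producer"`` restricts to states (i, 0); ``axis="cheater"`` to
    (0, j).  Returns (lam, mu) arrays of length N + 1 indexed by the count,
    with the reflecting truncation applied (lam[N] = 0).
    """
    i = np.arange(N + 1)
    if axis == "producer":
        lam = producer_birth_rate(i, np.zeros_like(i), p, strategy, signaling)
        mu = producer_death_rate(i, np.zeros_like(i), p)
    elif axis == "cheater":
        lam = cheater_birth_rate(np.zeros_like(i), i, p, strategy, signaling)
        mu = cheater_death_rate(np.zeros_like(i), i, p)
    else:
        raise ValueError(f"axis must be 'producer' or 'cheater', got {axis!r}")
    lam = np.asarray(lam, dtype=float).copy()
    lam[N] = 0.0
    return lam, np.asarray(mu, dtype=float)


def _met_1d_closed_form(lam: np.ndarray, mu: np.ndarray, N: int):
    """Mean extinction time of a 1-D birth-death chain, reflecting at N.

    T_n = sum_{i=1..n} [ 1/mu_i + sum_{j=1..N-i} (1/mu_{i+j})
          * prod_{l=1..j} lam_{i+l-1}/mu_{i+l-1} ],
    evaluated with incrementally accumulated products; if the running
    product overflows, the inner sum is recomputed in log space and the
    overflow is flagged.
    """
    S = np.zeros(N + 1)  # S[i] = expected sojourn contribution of level i
    overflow = False
    for i in range(1, N + 1):
        s = 1.0 / mu[i]
        prod = 1.0
        ok = True
        for j in range(1, N - i + 1):
            prod *= lam[i + j - 1] / mu[i + j - 1]
            if prod == 0.0:
                break
            if not math.isfinite(prod):
                ok = False
                break
            s += prod / mu[i + j]
        if not ok:
            overflow = True
            s = _met_1d_level_logspace(lam, mu, N, i)
        S[i] = s
    T = np.concatenate([[0.0], np.cumsum(S[1:])])
    return T, overflow

def _met_1d_level_logspace(lam, mu, N, i):
    """Log-space evaluation of one level's sojourn sum (overflow fallback)."""
    logs = [-math.log(mu[i])]
    logprod = 0.0
    for j in range(1, N - i + 1):
        if lam[i + j - 1] == 0.0:
            break
        logprod += math.log(lam[i + j - 1]) - math.log(mu[i + j - 1])
        logs.append(logprod - math.log(mu[i + j]))
    mx = max(logs)
    return math.exp(mx) * sum(math.exp(v - mx) for v in logs)


def met_axis_closed_form(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
):
    """Closed-form mean extinction times along both pure-strain axes.

    Returns ``(T_producer, T_cheater, overflowed)``: arrays of length
    N + 1 with T_producer[n] = T(n, 0) and T_cheater[m] = T(0, m), plus a
    flag marking that some level needed the log-space fallback.
    """
    lam_p, mu_p = axis_birth_death_rates(p, strategy, signaling, N, "producer")
    lam_c, mu_c = axis_birth_death_rates(p, strategy, signaling, N, "cheater")
    T_p, ov1 = _met_1d_closed_form(lam_p, mu_p, N)
    T_c, ov2 = _met_1d_closed_form(lam_c, mu_c, N)
    return T_p, T_c, (ov1 or ov2)


# ---------------------------------------------------------------------------
# Axis-hitting distribution and the decomposition estimator
# ---------------------------------------------------------------------------

@dataclass
class AxisHittingDistribution:
    """First axis-contact location probabilities, per starting state.

    ``probs_producer_axis[n, m, i-1]`` is the probability that a population
    started at (n, m) first touches an axis at (i, 0) (producer fixation
    with i producers), for i = 1..N; ``probs_cheater_axis[n, m, j-1]``
    likewise for (0, j).  For interior starts the two families partition
    the axis-contact event; axis starts carry a degenerate distribution;
    the origin carries all zeros (already extinct).
    """

    probs_producer_axis: np.ndarray  # (N+1, N+1, N)
    probs_cheater_axis: np.ndarray   # (N+1, N+1, N)
    meta: dict = field(default_factory=dict)

    def pi_cheater(self) -> np.ndarray:
        """Marginal cheater-fixation probability: sum over cheater-axis targets."""
        return self.probs_cheater_axis.sum(axis=2)


def axis_hitting_distribution(gen: RateGenerator) -> AxisHittingDistribution:
    """Distribution of the first axis-contact location from every state.

    All axis states are treated as absorbing; one sparse factorization of
    the interior operator is shared across all 2N target right-hand sides.
    """
    grid = gen.grid
    N = grid.N
    on_cheater_axis, on_producer_axis = _axis_masks(grid)
    boundary = on_cheater_axis | on_producer_axis
    interior = ~boundary
    Q = gen.Q
    A = Q[interior][:, interior].tocsc()

    prod_targets = grid.index(np.arange(1, N + 1), np.zeros(N, dtype=int))
    ch_targets = grid.index(np.zeros(N, dtype=int), np.arange(1, N + 1))
    targets = np.concatenate([prod_targets, ch_targets])
    B = Q[interior][:, targets].toarray()
    try:
        lu = spla.splu(A)
        X = lu.solve(-B)  # interior x 2N hitting probabilities
    except RuntimeError as exc:
        raise SolverError(
            f"axis hitting: factorization failed for {gen.strategy.value} at N={N}: {exc}"
        ) from exc

    P_prod = np.zeros((N + 1, N + 1, N))
    P_ch = np.zeros((N + 1, N + 1, N))
    int_n, int_m = grid.state(np.flatnonzero(interior))
    P_prod[int_n, int_m, :] = X[:, :N]
    P_ch[int_n, int_m, :] = X[:, N:]
    # degenerate distributions on the axes themselves
    i = np.arange(1, N + 1)
    P_prod[i, 0, i - 1] = 1.0
    P_ch[0, i, i - 1] = 1.0
    return AxisHittingDistribution(P_prod, P_ch, _meta(gen, solver="sparse-direct"))


def met_decomposition(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
    gen: Optional[RateGenerator] = None,
    hitting: Optional[AxisHittingDistribution] = None,
) -> SolutionField:
    """Mean extinction time via the fixation/axis decomposition.

    T(n, m) = sum_i pi^{i,0}(n, m) T(i, 0) + sum_j pi^{0,j}(n, m) T(0, j),
    combining the first axis-contact distribution with the closed-form 1-D
    axis extinction times.  On the axes this reduces exactly to the closed
    forms.  The estimate assumes fixation is fast relative to the pure-
    population persistence that follows.
    """
    if gen is None:
        gen = build_generator(p, strategy, signaling, N)
    if hitting is None:
        hitting = axis_hitting_distribution(gen)
    T_p, T_c, overflowed = met_axis_closed_form(p, strategy, signaling, N)
    vals = hitting.probs_producer_axis @ T_p[1:] + hitting.probs_cheater_axis @ T_c[1:]
    vals[0, 0] = 0.0
    return SolutionField(
        "T", vals, _meta(gen, solver="decomposition", axis_overflow=overflowed)
    )


def mean_extinction_time(gen: RateGenerator, method: str = "auto") -> SolutionField:
    """Mean extinction time with automatic instability fallback.

    ``method="auto"`` tries the direct sparse solve and falls back to the
    decomposition estimator when the direct result is flagged unstable;
    ``"direct"`` and ``"decomposition"`` force one path.  The path actually
    used is recorded in ``meta["solver"]``.
    """
    if method not in ("auto", "direct", "decomposition"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "direct"):
        field_ = mean_extinction_time_direct(gen)
        if method == "direct" or not field_.meta.get("unstable", False):
            return field_
    return met_decomposition(
        gen.params, gen.strategy, gen.signaling, gen.grid.N, gen=gen
    )
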
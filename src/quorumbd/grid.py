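"""Truncated state lattice and sparse transition-rate generator.

The chain lives on the square lattice {0..N} x {0..N} of (producer,
cheater) counts.  Truncation at N is *reflecting*: birth transitions that
would leave the grid are assigned rate zero, deaths are untouched.  The
generator Q is the (N+1)^2 x (N+1)^2 sparse matrix with Q[k, k'] the rate
of the single-step move k -> k' and a diagonal closing every row to zero;
its action on a field is the backward-Kolmogorov (adjoint) operator used
by all the stationary solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .params import ModelParameters, SignalingMode, Strategy
from .rates import net_growth, rate_tables

__all__ = ["StateGrid", "RateGenerator", "build_generator", "truncation_adequacy", "write_coo"]


@dataclass(frozen=True)
class StateGrid:
    """Enumeration of the (n, m) lattice with a stable linear indexing.

    The bijection is k = n*(N+1) + m; it round-trips for every state and
    is identical across runs.
    """

    N: int

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("grid bound N must be >= 1")

    @property
    def n_states(self) -> int:
        return (self.N + 1) ** 2

    def index(self, n, m):
        """Linear index of state (n, m)."""
        return np.asarray(n) * (self.N + 1) + np.asarray(m)

    def state(self, k):
        """(n, m) of linear index k."""
        return np.asarray(k) // (self.N + 1), np.asarray(k) % (self.N + 1)

    @property
    def states(self) -> np.ndarray:
        """All states as an (n_states, 2) array in index order."""
        n, m = self.state(np.arange(self.n_states))
        return np.column_stack([n, m])


@dataclass(frozen=True)
class RateGenerator:
    """Sparse generator Q on a StateGrid, with the model that built it."""

    grid: StateGrid
    Q: sp.csr_matrix
    params: ModelParameters
    strategy: Strategy
    signaling: SignalingMode


def build_generator(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
) -> RateGenerator:
    """Assemble the sparse transition-rate generator with reflecting truncation.

    Each state has at most 4 outgoing moves (one birth and one death per
    strain); births out of n = N or m = N are deleted.  The (0, 0) row is
    identically zero (the extinct state is absorbing).
    """
    if N < 2:
        raise ValueError("build_generator requires N >= 2")
    grid = StateGrid(N)
    strategy = Strategy(strategy)
    signaling = SignalingMode(signaling)
    lam_pr, mu_pr, lam_ch, mu_ch = rate_tables(p, strategy, signaling, N)

    n, m = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
    k = grid.index(n, m)

    rows, cols, vals = [], [], []

    def add(mask, dest_n, dest_m, rate):
        rows.append(k[mask])
        cols.append(grid.index(dest_n[mask], dest_m[mask]))
        vals.append(rate[mask])

    add((n < N) & (lam_pr > 0), n + 1, m, lam_pr)   # producer birth
    add((n > 0) & (mu_pr > 0), n - 1, m, mu_pr)     # producer death
    add((m < N) & (lam_ch > 0), n, m + 1, lam_ch)   # cheater birth
    add((m > 0) & (mu_ch > 0), n, m - 1, mu_ch)     # cheater death

    rows = np.concatenate([r.ravel() for r in rows])
    cols = np.concatenate([c.ravel() for c in cols])
    vals = np.concatenate([v.ravel() for v in vals])

    Q = sp.coo_matrix((vals, (rows, cols)), shape=(grid.n_states, grid.n_states)).tocsr()
    diag = -np.asarray(Q.sum(axis=1)).ravel()
    Q = (Q + sp.diags(diag)).tocsr()
    return RateGenerator(grid=grid, Q=Q, params=p, strategy=strategy, signaling=signaling)


@dataclass(frozen=True)
class TruncationReport:
    """Adequacy of the reflecting truncation at the grid edge."""

    min_negative_net_growth: float  # min over boundary states of -net_growth
    threshold: float                # required -net_growth at the boundary
    passed: bool
    N: int


def truncation_adequacy(
    p: ModelParameters,
    strategy: Strategy,
    signaling: SignalingMode,
    N: int,
    threshold: float | None = None,
) -> TruncationReport:
    """Check that net growth is strongly negative everywhere on the boundary.

    The finite-matrix approximation is trustworthy when every state with
    n = N or m = N loses population fast; the default requirement is
    net growth <= -5·μ0·N there (a heuristic, configurable via
    ``threshold`` = the required magnitude of the negative net growth).
    A failing flag is a warning about truncation quality, not an error.
    """
    if threshold is None:
        threshold = 5.0 * p.mu0 * N
    edge = np.arange(N + 1)
    ng_n_edge = net_growth(np.full(N + 1, N), edge, p, strategy, signaling)
    ng_m_edge = net_growth(edge, np.full(N + 1, N), p, strategy, signaling)
    worst = float(np.max(np.concatenate([np.atleast_1d(ng_n_edge), np.atleast_1d(ng_m_edge)])))
    min_neg = -worst
    return TruncationReport(
        min_negative_net_growth=min_neg,
        threshold=float(threshold),
        passed=bool(min_neg >= threshold),
        N=N,
    )


def write_coo(gen: RateGenerator, path) -> None:
    """Export the generator as a plain-text coordinate list: row col rate."""
    coo = gen.Q.tocoo()
    with open(path, "w") as fh:
        fh.write("# row col rate\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {float(v)!r}\n")
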
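"""Independent dense brute-force oracles for the small-grid boundary-value problems.

Everything here is deliberately coded from scratch against the embedded
jump chain (first-step analysis on transition *probabilities*), with its
own inline rate formulas and dense numpy solves — no imports from the
package's solver or rate modules — so agreement with the sparse
generator-based solvers is a genuine cross-check of both the rates and
the linear algebra.
"""

from __future__ import annotations

import numpy as np


def oracle_rates(n, m, p, strategy, signaling):
    """The four channel rates at (n, m), written out longhand."""

    def H(x, K, h):
        if K == "zero":
            return 1.0
        if K == "infinity":
            return 0.0
        if x == 0:
            return 0.0
        r = (x / K) ** h
        return r / (1.0 + r)

    if strategy == "AO":
        act = 1.0
    elif strategy == "NP":
        act = 0.0
    else:
        x = n + m if signaling == "producers_and_cheaters" else n
        act = H(x, p.Ka, p.ha)
    benefit = H(n, p.Kg, p.hg)
    lam_pr = max((p.lambda0 + ((p.g + p.a) * benefit - p.c) * act) * n, 0.0)
    lam_ch = (p.lambda0 + p.g * benefit * act) * m
    mu_pr = p.mu0 * (n + m) * n
    mu_ch = p.mu0 * (n + m) * m
    return lam_pr, mu_pr, lam_ch, mu_ch


def _moves(n, m, N, p, strategy, signaling):
    """Reachable neighbors and their rates, with reflecting truncation."""
    lam_pr, mu_pr, lam_ch, mu_ch = oracle_rates(n, m, p, strategy, signaling)
    out = []
    if n < N and lam_pr > 0:
        out.append(((n + 1, m), lam_pr))
    if n > 0 and mu_pr > 0:
        out.append(((n - 1, m), mu_pr))
    if m < N and lam_ch > 0:
        out.append(((n, m + 1), lam_ch))
    if m > 0 and mu_ch > 0:
        out.append(((n, m - 1), mu_ch))
    return out


def _interior_states(N):
    return [(n, m) for n in range(1, N + 1) for m in range(1, N + 1)]


def _first_step_system(N, p, strategy, signaling):
    """(I - P) over interior states plus the jump-probability map to the axes."""
    interior = _interior_states(N)
    idx = {s: i for i, s in enumerate(interior)}
    k = len(interior)
    A = np.eye(k)
    boundary_flux = {}  # (interior index, axis state) -> probability
    sojourn = np.zeros(k)
    for i, (n, m) in enumerate(interior):
        moves = _moves(n, m, N, p, strategy, signaling)
        total = sum(r for _, r in moves)
        sojourn[i] = 1.0 / total
        for dest, r in moves:
            prob = r / total
            if dest in idx:
                A[i, idx[dest]] -= prob
            else:
                boundary_flux[i, dest] = boundary_flux.get((i, dest), 0.0) + prob
    return interior, idx, A, boundary_flux, sojourn


def oracle_fixation(N, p, strategy, signaling, target="cheater"):
    """pi over the full grid by dense first-step analysis."""
    interior, idx, A, flux, _ = _first_step_system(N, p, strategy, signaling)
    b = np.zeros(len(interior))
    for (i, (bn, bm)), prob in flux.items():
        hit_cheater_axis = bn == 0 and bm > 0
        if (target == "cheater") == hit_cheater_axis and (bn, bm) != (0, 0):
            b[i] += prob
    x = np.linalg.solve(A, b)
    out = np.zeros((N + 1, N + 1))
    for s, i in idx.items():
        out[s] = x[i]
    if target == "cheater":
        out[0, 1:] = 1.0
    else:
        out[1:, 0] = 1.0
    return out


def oracle_theta(N, p, strategy, signaling):
    """theta = E[time * 1{cheater fixation}] by first-step analysis.

    theta(s) = sum_s' p(s->s') theta(s') + pi(s) / total_rate(s).
    """
    pi = oracle_fixation(N, p, strategy, signaling, "cheater")
    interior, idx, A, flux, sojourn = _first_step_system(N, p, strategy, signaling)
    b = np.array([sojourn[i] * pi[s] for i, s in enumerate(interior)])
    x = np.linalg.solve(A, b)
    out = np.zeros((N + 1, N + 1))
    for s, i in idx.items():
        out[s] = x[i]
    return out


def oracle_hitting(N, p, strategy, signaling):
    """First axis-contact distribution: dict target axis state -> grid array."""
    interior, idx, A, flux, _ = _first_step_system(N, p, strategy, signaling)
    targets = [(i, 0) for i in range(1, N + 1)] + [(0, j) for j in range(1, N + 1)]
    out = {}
    for tgt in targets:
        b = np.zeros(len(interior))
        for (i, dest), prob in flux.items():
            if dest == tgt:
                b[i] += prob
        x = np.linalg.solve(A, b)
        grid = np.zeros((N + 1, N + 1))
        for s, i in idx.items():
            grid[s] = x[i]
        grid[tgt] = 1.0
        out[tgt] = grid
    return out


def oracle_mean_extinction(N, p, strategy, signaling):
    """Mean absorption time at (0, 0) over the whole truncated grid."""
    states = [(n, m) for n in range(N + 1) for m in range(N + 1) if (n, m) != (0, 0)]
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    A = np.eye(k)
    b = np.zeros(k)
    for i, (n, m) in enumerate(states):
        moves = _moves(n, m, N, p, strategy, signaling)
        total = sum(r for _, r in moves)
        b[i] = 1.0 / total
        for dest, r in moves:
            if dest != (0, 0):
                A[i, idx[dest]] -= r / total
    x = np.linalg.solve(A, b)
    out = np.zeros((N + 1, N + 1))
    for s, i in idx.items():
        out[s] = x[i]
    return out


def oracle_axis_met_1d(N, p, strategy, signaling, axis="producer"):
    """Mean extinction time of the 1-D pure-strain chain, solved exactly.

    First-step equations T(i) = 1/tot_i + (lam_i/tot_i) T(i+1)
    + (mu_i/tot_i) T(i-1) with T(0) = 0 and reflecting lam_N = 0, solved
    by Gaussian elimination in exact rational arithmetic (the floating
    rates convert to Fractions losslessly), so the oracle keeps full
    accuracy even when the extinction times are astronomically large and
    a floating dense solve would be swamped by conditioning.
    """
    from fractions import Fraction

    lam = [Fraction(0)] * (N + 1)
    mu = [Fraction(0)] * (N + 1)
    for i in range(N + 1):
        if axis == "producer":
            lp, mp, _, _ = oracle_rates(i, 0, p, strategy, signaling)
            lam[i], mu[i] = Fraction(lp), Fraction(mp)
        else:
            _, _, lc, mc = oracle_rates(0, i, p, strategy, signaling)
            lam[i], mu[i] = Fraction(lc), Fraction(mc)
    lam[N] = Fraction(0)
    # forward elimination of the tridiagonal system over unknowns T(1..N):
    # (lam_i + mu_i) T(i) - lam_i T(i+1) - mu_i T(i-1) = 1
    # express T(i) = alpha_i * T(i+1) + beta_i given T(i-1) eliminated
    alpha = [Fraction(0)] * (N + 1)
    beta = [Fraction(0)] * (N + 1)
    for i in range(1, N + 1):
        tot = lam[i] + mu[i]
        denom = tot - mu[i] * alpha[i - 1]
        alpha[i] = lam[i] / denom
        beta[i] = (1 + mu[i] * beta[i - 1]) / denom
    T = [Fraction(0)] * (N + 1)
    T[N] = beta[N]  # alpha_N = 0 (reflecting)
    for i in range(N - 1, 0, -1):
        T[i] = alpha[i] * T[i + 1] + beta[i]
    return np.array([float(v) for v in T])
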
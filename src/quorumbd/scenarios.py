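"""Comparative analyses: strategy maps, phase diagrams, sweeps, and scans.

These drivers orchestrate the solvers to answer the model's comparative
questions: when does regulating public-good production by quorum sensing
(QS) help or harm the population relative to unconditional production
(AO)?  The central classification is by mean extinction time: *destructive*
QS shortens it for every mixed starting composition, *constructive* QS
lengthens it for every one, and *mixed* regimes split.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import build_generator
from .params import DEFAULTS, ModelParameters, SignalingMode, Strategy
from .rates import equilibrium_producers, net_growth
from .solvers import (
    SolutionField,
    conditional_fixation_time,
    fixation_probability,
    mean_extinction_time,
    met_axis_closed_form,
)

__all__ = [
    "ComparisonGrid",
    "PhaseDiagram",
    "ContourSet",
    "reporting_mask",
    "compute_field",
    "compare_strategies",
    "phase_diagram",
    "zero_net_growth_contour",
    "parameter_sweep",
    "colonization_scan",
    "invasion_scan",
    "signaling_comparison",
    "exemplar_regime_report",
]

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA0_GRID = tuple(np.round(np.arange(0.0, 0.5001, 0.05), 10))
DEFAULT_C_GRID = tuple(np.round(np.arange(0.0, 0.2501, 0.025), 10))
DEFAULT_K_SET = (10.0, 15.0, 20.0, 25.0, 30.0)
DEFAULT_H_SET = (1.0, 2.0, 3.0, 4.0, 5.0)


def reporting_mask(N: int, N_report: int | None = None) -> np.ndarray:
    """Boolean (N+1, N+1) mask of the strictly mixed reporting set.

    States with n >= 1, m >= 1 and n + m <= N_report.  Axis states are
    excluded because QS/AO ratios degenerate there (e.g. both extinction
    times coincide on the cheater axis).
    """
    if N_report is None:
        N_report = N
    n, m = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
    return (n >= 1) & (m >= 1) & (n + m <= N_report)


def compute_field(
    p: ModelParameters,
    strategy: Strategy,
    signaling: SignalingMode,
    N: int,
    quantity: str,
) -> SolutionField:
    """Solve for one quantity (piCh | tauCh | T) under one strategy."""
    gen = build_generator(p, strategy, signaling, N)
    if quantity == "piCh":
        return fixation_probability(gen)
    if quantity == "tauCh":
        pi = fixation_probability(gen)
        _, tau = conditional_fixation_time(gen, pi)
        return tau
    if quantity == "T":
        return mean_extinction_time(gen)
    raise ValueError(f"unknown quantity {quantity!r}")


@dataclass
class ComparisonGrid:
    """Fields for several strategies (or signaling modes) on a shared grid."""

    quantity: str
    labels: tuple
    fields: dict
    N: int
    N_report: int

    @property
    def mask(self) -> np.ndarray:
        return reporting_mask(self.N, self.N_report)

    def ratio(self, num, den) -> np.ndarray:
        """Elementwise num/den field ratio, NaN outside the reporting set
        or where the denominator is not positive."""
        a = self.fields[num].values
        b = self.fields[den].values
        out = np.full_like(a, np.nan, dtype=float)
        ok = self.mask & np.isfinite(a) & np.isfinite(b) & (b > 0)
        out[ok] = a[ok] / b[ok]
        return out

    def log_ratio(self, num, den) -> np.ndarray:
        r = self.ratio(num, den)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(r)


def compare_strategies(
    p: ModelParameters,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
    quantity: str = "T",
    strategies: tuple = (Strategy.QS, Strategy.AO, Strategy.NP),
    N_report: int | None = None,
) -> ComparisonGrid:
    """Solve one quantity under several regulation strategies and compare."""
    fields = {}
    for s in strategies:
        s = Strategy(s)
        try:
            fields[s.value] = compute_field(p, s, signaling, N, quantity)
        except Exception as exc:
            raise type(exc)(f"strategy {s.value}: {exc}") from exc
    return ComparisonGrid(
        quantity=quantity,
        labels=tuple(Strategy(s).value for s in strategies),
        fields=fields,
        N=N,
        N_report=N_report if N_report is not None else N,
    )


@dataclass
class PhaseDiagram:
    """Fraction of mixed states favoring QS over AO, per (lambda0, c) cell."""

    lambda0_grid: np.ndarray
    c_grid: np.ndarray
    delta: float
    fraction: np.ndarray       # [i_lambda0, j_c] fraction with log(T_QS/T_AO) > delta
    tie_fraction: np.ndarray   # fraction with exactly equal extinction times
    classification: np.ndarray  # "destructive" | "mixed" | "constructive" | "missing"
    solver_path: np.ndarray    # "direct" | "decomposition" per (cell, strategy) pair
    N: int
    N_report: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lambda0_grid):
            for j, c in enumerate(self.c_grid):
                rows.append({
                    "lambda0": lam, "c": c,
                    "fraction": self.fraction[i, j],
                    "tie_fraction": self.tie_fraction[i, j],
                    "classification": self.classification[i, j],
                    "solver_path": self.solver_path[i, j],
                })
        return pd.DataFrame(rows)


def phase_diagram(
    lambda0_grid=DEFAULT_LAMBDA0_GRID,
    c_grid=DEFAULT_C_GRID,
    p_base: ModelParameters = DEFAULTS,
    N: int = 100,
    delta: float = 0.0,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N_report: int | None = None,
) -> PhaseDiagram:
    """Phase diagram of QS vs AO mean extinction time over (lambda0, c).

    For each cell the T fields for QS and AO are solved and the fraction of
    reporting-set states with log(T_QS / T_AO) > delta is recorded (delta = 0
    is the plain strict comparison T_QS > T_AO; ties count as "not
    greater").  A cell is *destructive* at fraction 0, *constructive* at
    fraction 1, *mixed* in between; cells where a solver fails are marked
    missing, never silently zero.
    """
    lambda0_grid = np.asarray(lambda0_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    if lambda0_grid.size == 0 or c_grid.size == 0:
        raise ValueError("phase_diagram: parameter grids must be non-empty")
    N_rep = N_report if N_report is not None else N
    mask = reporting_mask(N, N_rep)
    shape = (lambda0_grid.size, c_grid.size)
    frac = np.full(shape, np.nan)
    ties = np.full(shape, np.nan)
    cls = np.full(shape, "missing", dtype=object)
    path = np.full(shape, "", dtype=object)
    for i, lam in enumerate(lambda0_grid):
        for j, c in enumerate(c_grid):
            p = p_base.with_(lambda0=float(lam), c=float(c))
            try:
                T_qs = mean_extinction_time(build_generator(p, Strategy.QS, signaling, N))
                T_ao = mean_extinction_time(build_generator(p, Strategy.AO, signaling, N))
            except Exception as exc:
                logger.warning("phase cell (lambda0=%g, c=%g) failed: %s", lam, c, exc)
                continue
            a, b = T_qs.values[mask], T_ao.values[mask]
            ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
            if not ok.any():
                continue
            with np.errstate(divide="ignore"):
                lr = np.log(a[ok] / b[ok])
            frac[i, j] = float(np.mean(lr > delta))
            ties[i, j] = float(np.mean(a[ok] == b[ok]))
            cls[i, j] = (
                "destructive" if frac[i, j] == 0.0
                else "constructive" if frac[i, j] == 1.0
                else "mixed"
            )
            path[i, j] = f"QS:{T_qs.meta['solver']},AO:{T_ao.meta['solver']}"
    return PhaseDiagram(lambda0_grid, c_grid, float(delta), frac, ties, cls, path, N, N_rep)


@dataclass
class ContourSet:
    """Zero net-growth crossings: interpolated points and bracketing pairs."""

    points: np.ndarray    # (k, 2) float (n, m) locations, linear interpolation
    brackets: np.ndarray  # (k, 4) int: n0, m0, n1, m1 of the sign-change pair

    @property
    def empty(self) -> bool:
        return self.points.shape[0] == 0


def zero_net_growth_contour(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
) -> ContourSet:
    """Locate where the expected net total growth rate changes sign.

    Scans every lattice row and column for adjacent pairs where the net
    growth moves between strictly positive and non-positive; a crossing is
    reported as the bracketing pair plus a linearly interpolated zero.
    The origin (net growth exactly 0 with no positive neighbor) produces
    no crossing, so a strictly sub-replacement regime yields an empty set.
    """
    n, m = np.meshgrid(np.arange(N + 1), np.arange(N + 1), indexing="ij")
    ng = net_growth(n, m, p, strategy, signaling)
    points, brackets = [], []

    def scan(a, b, ngline, along_n: bool):
        pos = ngline > 0
        for i in range(len(ngline) - 1):
            if pos[i] != pos[i + 1]:
                t = ngline[i] / (ngline[i] - ngline[i + 1])
                if along_n:
                    points.append((a[i] + t, b[i]))
                    brackets.append((a[i], b[i], a[i + 1], b[i]))
                else:
                    points.append((a[i], b[i] + t))
                    brackets.append((a[i], b[i], a[i], b[i + 1]))

    for j in range(N + 1):  # fixed m, scan n
        scan(np.arange(N + 1), np.full(N + 1, j), ng[:, j], True)
    for i in range(N + 1):  # fixed n, scan m
        scan(np.full(N + 1, i), np.arange(N + 1), ng[i, :], False)
    return ContourSet(
        points=np.array(points, dtype=float).reshape(-1, 2),
        brackets=np.array(brackets, dtype=int).reshape(-1, 4),
    )


def _start_state_check(n_star: int, N: int) -> None:
    if n_star < 1:
        raise ValueError(
            f"invasion start requires at least one producer; n* = {n_star}"
        )
    if n_star > N:
        raise ValueError(
            f"invasion start n* = {n_star} lies outside the grid (N = {N}); "
            "increase N or adjust parameters"
        )


def parameter_sweep(
    Kg_set=DEFAULT_K_SET,
    Ka_set=DEFAULT_K_SET,
    hg_set=DEFAULT_H_SET,
    ha_set=DEFAULT_H_SET,
    p_base: ModelParameters = DEFAULTS,
    scenario: str = "invasion",
    N: int = 100,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
) -> pd.DataFrame:
    """Sweep the Hill parameters and tabulate QS-vs-AO log ratios.

    One row per (Kg, Ka, hg, ha) combination (the default 5x5x5x5 design
    gives 625 rows).  Each row reports log(pi_QS / pi_AO) at the invasion
    start (n*, 1), and log(T_QS / T_AO) at (n*, 1) for ``scenario=
    "invasion"`` or at the colonization start (1, 0) for ``scenario=
    "colonization"``.  AO ignores the activation parameters, so AO solves
    are shared across (Ka, ha).
    """
    if scenario not in ("invasion", "colonization"):
        raise ValueError(f"scenario must be 'invasion' or 'colonization', got {scenario!r}")
    n_star = equilibrium_producers(p_base)
    _start_state_check(n_star, N)

    ao_cache: dict = {}  # (Kg, hg) -> (pi_field, T_value_at_start)
    rows = []
    for Kg, Ka, hg, ha in itertools.product(Kg_set, Ka_set, hg_set, ha_set):
        p = p_base.with_(Kg=float(Kg), Ka=float(Ka), hg=float(hg), ha=float(ha))
        key = (float(Kg), float(hg))
        if key not in ao_cache:
            gen_ao = build_generator(p, Strategy.AO, signaling, N)
            pi_ao = fixation_probability(gen_ao)
            if scenario == "invasion":
                T_ao = mean_extinction_time(gen_ao).values[n_star, 1]
            else:
                T_ao = met_axis_closed_form(p, Strategy.AO, signaling, N)[0][1]
            ao_cache[key] = (pi_ao.values[n_star, 1], float(T_ao))
        pi_ao_v, T_ao_v = ao_cache[key]

        gen_qs = build_generator(p, Strategy.QS, signaling, N)
        pi_qs_v = fixation_probability(gen_qs).values[n_star, 1]
        if scenario == "invasion":
            T_qs_v = float(mean_extinction_time(gen_qs).values[n_star, 1])
        else:
            T_qs_v = float(met_axis_closed_form(p, Strategy.QS, signaling, N)[0][1])
        with np.errstate(divide="ignore", invalid="ignore"):
            rows.append({
                "Kg": Kg, "Ka": Ka, "hg": hg, "ha": ha, "n_star": n_star,
                "pi_qs": pi_qs_v, "pi_ao": pi_ao_v,
                "T_qs": T_qs_v, "T_ao": T_ao_v,
                "log_pi_ratio": float(np.log(pi_qs_v / pi_ao_v)),
                "log_T_ratio": float(np.log(T_qs_v / T_ao_v)),
            })
    return pd.DataFrame(rows)


def colonization_scan(
    Ka_values,
    p_base: ModelParameters = DEFAULTS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
) -> pd.DataFrame:
    """Mean extinction time T(1, 0) of a lone colonizing producer vs Ka.

    Uses the 1-D closed form on the producer axis (a pure-producer chain).
    Ka trades off early activation cost against delayed benefit; at c = 0
    the always-on limit (small Ka) maximizes persistence.
    """
    rows = []
    for ka in Ka_values:
        p = p_base.with_(Ka=ka if isinstance(ka, str) else float(ka))
        T_p, _, _ = met_axis_closed_form(p, Strategy.QS, signaling, N)
        rows.append({"Ka": ka, "T_1_0": float(T_p[1]), "lambda0": p.lambda0, "c": p.c})
    return pd.DataFrame(rows)


def invasion_scan(
    Ka_values,
    p_base: ModelParameters = DEFAULTS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    N: int = 100,
) -> pd.DataFrame:
    """Cheater fixation probability pi^Ch(n*, 1) as a function of Ka.

    The start is the approximate producer equilibrium n* with one invading
    cheater.  Refuses to run when n* < 1 (no producers to invade).
    """
    n_star = equilibrium_producers(p_base)
    _start_state_check(n_star, N)
    rows = []
    for ka in Ka_values:
        p = p_base.with_(Ka=ka if isinstance(ka, str) else float(ka))
        gen = build_generator(p, Strategy.QS, signaling, N)
        pi = fixation_probability(gen)
        rows.append({
            "Ka": ka, "pi_ch": float(pi.values[n_star, 1]),
            "n_star": n_star, "lambda0": p.lambda0, "c": p.c,
        })
    return pd.DataFrame(rows)


def signaling_comparison(
    p: ModelParameters = DEFAULTS,
    N: int = 100,
    strategy: Strategy = Strategy.QS,
    quantities: tuple = ("piCh", "tauCh", "T"),
    N_report: int | None = None,
) -> dict:
    """Effect of cheaters producing autoinducer: signaling vs non-signaling.

    For each quantity, solves under producers_and_cheaters ("S") and
    producers_only ("NS") and returns a ComparisonGrid keyed by quantity;
    ``ratio("S", "NS")`` gives the per-state effect of cheater signaling.
    """
    out = {}
    for q in quantities:
        fields = {
            "S": compute_field(p, strategy, SignalingMode.PRODUCERS_AND_CHEATERS, N, q),
            "NS": compute_field(p, strategy, SignalingMode.PRODUCERS_ONLY, N, q),
        }
        out[q] = ComparisonGrid(
            quantity=q, labels=("S", "NS"), fields=fields, N=N,
            N_report=N_report if N_report is not None else N,
        )
    return out


def exemplar_regime_report(
    p_base: ModelParameters = DEFAULTS,
    N: int = 100,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
) -> dict:
    """Qualitative checks of the two exemplar regimes under the defaults.

    Destructive/mixed exemplar (c = 0.1, lambda0 = 0) and constructive
    exemplar (c = 0.15, lambda0 = 0.2): reports the QS and AO cheater
    fixation probabilities at the invasion start (n*, 1) and the fraction
    of mixed reporting states with T_QS > T_AO.  Directional deviations
    from the expected pattern are logged as warnings, not raised: the
    exact parameter sets behind the published regimes are not fully
    pinned down, so these are regressions of direction, not of value.
    """
    report = {}
    for name, lam, c, expect_constructive in (
        ("destructive", 0.0, 0.1, False),
        ("constructive", 0.2, 0.15, True),
    ):
        p = p_base.with_(lambda0=lam, c=c)
        n_star = equilibrium_producers(p)
        N_cell = max(N, n_star + 5)
        gen_qs = build_generator(p, Strategy.QS, signaling, N_cell)
        gen_ao = build_generator(p, Strategy.AO, signaling, N_cell)
        pi_qs = fixation_probability(gen_qs)
        pi_ao = fixation_probability(gen_ao)
        T_qs = mean_extinction_time(gen_qs)
        T_ao = mean_extinction_time(gen_ao)
        mask = reporting_mask(N_cell, N)
        a, b = T_qs.values[mask], T_ao.values[mask]
        ok = np.isfinite(a) & np.isfinite(b) & (b > 0)
        frac = float(np.mean(a[ok] > b[ok]))
        entry = {
            "lambda0": lam, "c": c, "n_star": n_star, "N": N_cell,
            "pi_qs_invasion": float(pi_qs.values[n_star, 1]),
            "pi_ao_invasion": float(pi_ao.values[n_star, 1]),
            "frac_T_qs_gt_ao": frac,
            "solver_path": (T_qs.meta["solver"], T_ao.meta["solver"]),
        }
        if not entry["pi_qs_invasion"] < entry["pi_ao_invasion"]:
            logger.warning("%s regime: expected pi_QS < pi_AO at invasion start, got %r", name, entry)
        if expect_constructive and frac < 1.0:
            logger.warning("constructive regime: T_QS > T_AO holds on %.1f%% of mixed states", 100 * frac)
        if not expect_constructive and frac in (0.0, 1.0):
            logger.warning("destructive/mixed regime produced a pure classification (frac=%g)", frac)
        report[name] = entry
    return report
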
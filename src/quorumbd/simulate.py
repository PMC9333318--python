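"""Exact stochastic simulation (direct-method SSA) of the four-channel process.

The simulator runs on the unbounded lattice — unlike the solver grid it
needs no truncation, because the quadratic density-dependent death rate
guarantees almost-sure absorption at (0, 0).  Fixation is recorded at the
first axis contact: with no mutation or migration a lost strain cannot
return, so touching an axis decides the evolutionary outcome even though
the population keeps evolving afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParameters, SignalingMode, Strategy
from .rates import (
    cheater_birth_rate,
    cheater_death_rate,
    producer_birth_rate,
    producer_death_rate,
)

__all__ = ["TrajectoryRecord", "SimulationSummary", "TruncatedTrajectoryError", "simulate", "estimate"]

_REACTIONS = ("producer_birth", "producer_death", "cheater_birth", "cheater_death")
_STEPS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])


@dataclass
class TrajectoryRecord:
    """One SSA realization run to population extinction.

    ``events`` holds (time, reaction index, n_after, m_after) rows when
    event recording is on; times are strictly increasing and consecutive
    states differ by one individual.
    """

    seed: object
    n0: int
    m0: int
    fixation: Optional[str]          # None | "cheater" | "producer"
    fixation_time: Optional[float]
    extinction_time: Optional[float]
    n_events: int
    truncated: bool = False
    events: Optional[np.ndarray] = None  # (n_events, 4): time, reaction, n, m


class TruncatedTrajectoryError(RuntimeError):
    """Raised when event_cap is reached before extinction; carries the partial record."""

    def __init__(self, record: TrajectoryRecord):
        super().__init__(
            f"trajectory truncated after {record.n_events} events at state "
            f"({record.events[-1][2] if record.events is not None else '?'}, ...)"
        )
        self.record = record


def simulate(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    n0: int = 1,
    m0: int = 0,
    seed: int | np.random.SeedSequence = 0,
    event_cap: int = 10**6,
    record_events: bool = True,
) -> TrajectoryRecord:
    """Run one direct-method SSA trajectory from (n0, m0) to extinction.

    Two uniforms per event: one for the exponential waiting time, one for
    channel selection.  Identical seeds give identical records.  Raises
    :class:`TruncatedTrajectoryError` (carrying the partial record) if
    ``event_cap`` events pass without absorption.
    """
    if (n0, m0) == (0, 0):
        raise ValueError("initial state must not be the extinct state (0, 0)")
    if event_cap <= 0:
        raise ValueError("event_cap must be positive")
    strategy = Strategy(strategy)
    signaling = SignalingMode(signaling)
    rng = np.random.default_rng(seed)

    n, m = int(n0), int(m0)
    t = 0.0
    fixation: Optional[str] = None
    fixation_time: Optional[float] = None
    if n == 0:
        fixation, fixation_time = "cheater", 0.0
    elif m == 0:
        fixation, fixation_time = "producer", 0.0

    events = [] if record_events else None
    n_events = 0
    rate_cache: dict = {}  # trajectories revisit few states; memoize the 4 rates
    log = np.log
    while (n, m) != (0, 0):
        if n_events >= event_cap:
            rec = TrajectoryRecord(
                seed=seed, n0=n0, m0=m0, fixation=fixation,
                fixation_time=fixation_time, extinction_time=None,
                n_events=n_events, truncated=True,
                events=np.array(events) if events else None,
            )
            raise TruncatedTrajectoryError(rec)
        cached = rate_cache.get((n, m))
        if cached is None:
            cached = (
                producer_birth_rate(n, m, p, strategy, signaling),
                producer_death_rate(n, m, p),
                cheater_birth_rate(n, m, p, strategy, signaling),
                cheater_death_rate(n, m, p),
            )
            rate_cache[n, m] = cached
        r0, r1, r2, r3 = cached
        total = r0 + r1 + r2 + r3
        u1 = rng.random()
        u2 = rng.random()
        t += -log(u1) / total
        x = u2 * total
        if x < r0:
            n += 1
        elif x < r0 + r1:
            n -= 1
        elif x < r0 + r1 + r2:
            m += 1
        else:
            m -= 1
        n_events += 1
        if events is not None:
            r = 0 if x < r0 else (1 if x < r0 + r1 else (2 if x < r0 + r1 + r2 else 3))
            events.append((t, r, n, m))
        if fixation is None:
            if n == 0 and m > 0:
                fixation, fixation_time = "cheater", t
            elif m == 0 and n > 0:
                fixation, fixation_time = "producer", t

    return TrajectoryRecord(
        seed=seed, n0=n0, m0=m0, fixation=fixation, fixation_time=fixation_time,
        extinction_time=t, n_events=n_events, truncated=False,
        events=np.array(events) if events is not None else None,
    )


@dataclass
class SimulationSummary:
    """Monte-Carlo estimates of pi^Ch, tau^Ch, and T with uncertainties."""

    replicates: int
    n_truncated: int
    pi_ch_hat: float
    pi_ch_ci99: tuple  # exact (Clopper-Pearson) 99% binomial CI
    tau_ch_hat: Optional[float]
    tau_ch_se: Optional[float]
    T_hat: float
    T_se: float
    base_seed: int


def estimate(
    p: ModelParameters,
    strategy: Strategy = Strategy.QS,
    signaling: SignalingMode = SignalingMode.PRODUCERS_ONLY,
    n0: int = 1,
    m0: int = 0,
    replicates: int = 100,
    base_seed: int = 0,
    event_cap: int = 10**6,
) -> SimulationSummary:
    """Replicate the SSA and summarize fixation and extinction statistics.

    The default of 100 replicates matches the validation protocol the
    solvers are checked against.  Per-replicate seeds are spawned
    deterministically from ``base_seed``; truncated replicates are counted
    and excluded from the time averages.
    """
    from scipy.stats import binomtest

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(replicates)
    fix_ch, fix_times, ext_times, n_trunc = [], [], [], 0
    for ss in children:
        try:
            rec = simulate(p, strategy, signaling, n0, m0, seed=ss,
                           event_cap=event_cap, record_events=False)
        except TruncatedTrajectoryError:
            n_trunc += 1
            continue
        fix_ch.append(rec.fixation == "cheater")
        if rec.fixation == "cheater":
            fix_times.append(rec.fixation_time)
        ext_times.append(rec.extinction_time)

    done = len(ext_times)
    if done == 0:
        raise RuntimeError("all replicates truncated; raise event_cap")
    k = int(np.sum(fix_ch))
    ci = binomtest(k, done).proportion_ci(confidence_level=0.99, method="exact")
    ext = np.array(ext_times)
    tau_hat = float(np.mean(fix_times)) if fix_times else None
    tau_se = (
        float(np.std(fix_times, ddof=1) / np.sqrt(len(fix_times)))
        if len(fix_times) > 1 else None
    )
    return SimulationSummary(
        replicates=replicates,
        n_truncated=n_trunc,
        pi_ch_hat=k / done,
        pi_ch_ci99=(float(ci.low), float(ci.high)),
        tau_ch_hat=tau_hat,
        tau_ch_se=tau_se,
        T_hat=float(ext.mean()),
        T_se=float(ext.std(ddof=1) / np.sqrt(done)) if done > 1 else float("nan"),
        base_seed=base_seed,
    )
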
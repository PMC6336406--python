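"""Exact stochastic (single-molecule) simulation of rate schemes.

The Gillespie algorithm for a purely first-order network decouples over
molecules, so the simulator advances all molecules in lock-step rounds of
jumps with vectorized draws.  Randomness comes from a counter-based Philox
generator seeded explicitly in every public call; there is no global state.

The dwell time at a state *set* is the total residence time before the
first exit to a state outside the set, matching the "pause lifetime"
semantics of the pause assays: a molecule that hops between C17 pause
states is still paused; it leaves the pause when it first extends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import ProgressCurve
from .schemes import RateScheme

__all__ = ["DwellSample", "gillespie", "empirical_survival", "gillespie_occupancy"]

_MAX_ROUNDS = 1_000_000


@dataclass
class DwellSample:
    """Per-molecule dwell times at a designated state set.

    ``entry_s`` is the time of first entry into the set (NaN if the
    molecule never enters), ``dwell_s`` the residence time before first
    exit, and ``exit_branch`` the transition label by which it left
    (empty string while still inside at the simulation horizon).
    """

    entry_s: np.ndarray
    dwell_s: np.ndarray
    exit_branch: np.ndarray
    seed: int
    states: tuple[str, ...]

    def __len__(self) -> int:
        return self.entry_s.size

    @property
    def completed(self) -> np.ndarray:
        """Mask of molecules that entered and exited the state set."""
        return np.asarray(self.exit_branch != "") & np.isfinite(self.dwell_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": np.arange(len(self)),
                "entry_s": self.entry_s,
                "dwell_s": self.dwell_s,
                "exit_branch": self.exit_branch,
                "seed": self.seed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _CompiledScheme:
    """Per-state exit rates and branch tables for vectorized jumping."""

    def __init__(self, scheme: RateScheme):
        n = len(scheme.states)
        rates: list[list[float]] = [[] for _ in range(n)]
        dests: list[list[int]] = [[] for _ in range(n)]
        labels: list[list[str]] = [[] for _ in range(n)]
        for tr in scheme.transitions:
            i = scheme.state_index(tr.source)
            rates[i].append(scheme.effective_rate(tr))
            dests[i].append(scheme.state_index(tr.dest))
            labels[i].append(tr.label)
        self.exit_rate = np.array([sum(r) for r in rates])
        width = max((len(r) for r in rates), default=1) or 1
        self.cum_prob = np.ones((n, width))
        self.dest = np.zeros((n, width), dtype=np.int64)
        self.labels = labels
        for i in range(n):
            if rates[i]:
                p = np.array(rates[i]) / self.exit_rate[i]
                self.cum_prob[i, : len(p)] = np.cumsum(p)
                self.cum_prob[i, len(p):] = 1.0
                self.dest[i, : len(p)] = dests[i]
                self.dest[i, len(p):] = dests[i][-1]
        # branch index -> global label lookup per state
        self.label_table = np.full((n, width), "", dtype=object)
        for i in range(n):
            for j, lab in enumerate(labels[i]):
                self.label_table[i, j] = lab


def _initial_states(scheme: RateScheme, n: int, rng: np.random.Generator) -> np.ndarray:
    p0 = scheme.initial_occupancy
    return rng.choice(len(p0), size=n, p=p0 / p0.sum())


def gillespie(
    scheme: RateScheme,
    n_molecules: int,
    seed: int,
    dwell_states: tuple[str, ...] | None = None,
    t_max: float = np.inf,
) -> DwellSample:
    """Simulate ``n_molecules`` independent trajectories of the scheme.

    Returns per-molecule dwell times at ``dwell_states`` (default: all
    non-absorbing states).  Reproducible given (scheme, n, seed).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if dwell_states is None:
        dwell_states = tuple(
            s for s in scheme.states if s not in scheme.absorbing_states
        )
    for s in dwell_states:
        scheme.state_index(s)  # raises SchemeError on unknown label

    comp = _CompiledScheme(scheme)
    in_set = np.zeros(len(scheme.states), dtype=bool)
    for s in dwell_states:
        in_set[scheme.state_index(s)] = True

    rng = np.random.Generator(np.random.Philox(seed))
    state = _initial_states(scheme, n_molecules, rng)
    t = np.zeros(n_molecules)

    entry = np.full(n_molecules, np.nan)
    dwell = np.zeros(n_molecules)
    exited = np.zeros(n_molecules, dtype=bool)
    exit_branch = np.full(n_molecules, "", dtype=object)

    start_inside = in_set[state]
    entry[start_inside] = 0.0
    entered = start_inside.copy()

    for _ in range(_MAX_ROUNDS):
        active = (comp.exit_rate[state] > 0) & (t < t_max) & ~(exited & ~np.isnan(entry))
        # molecules that already exited the set but are still moving do not
        # affect dwell statistics; stop advancing them once exited
        active &= ~exited
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        s_old = state[idx]
        r = comp.exit_rate[s_old]
        dt = rng.exponential(1.0 / r)
        u = rng.random(idx.size)
        branch = (u[:, None] > comp.cum_prob[s_old]).sum(axis=1)
        dest = comp.dest[s_old, branch]

        was_in = in_set[s_old]
        dwell[idx[was_in]] += dt[was_in]

        goes_in = in_set[dest]
        newly = goes_in & ~entered[idx]
        entry[idx[newly]] = t[idx[newly]] + dt[newly]
        entered[idx[newly]] = True

        leaves = was_in & ~goes_in
        li = idx[leaves]
        exited[li] = True
        exit_branch[li] = comp.label_table[s_old[leaves], branch[leaves]]

        t[idx] += dt
        state[idx] = dest
    else:  # pragma: no cover - safety valve
        raise RuntimeError("gillespie exceeded maximum number of rounds")

    return DwellSample(
        entry_s=entry,
        dwell_s=np.where(np.isnan(entry), np.nan, dwell),
        exit_branch=np.asarray(exit_branch),
        seed=seed,
        states=tuple(dwell_states),
    )


def empirical_survival(sample: DwellSample, times) -> ProgressCurve:
    """Fraction of molecules inside the dwell-state set at each time.

    Converges to the deterministic occupancy of the set as the number of
    molecules grows (for schemes without re-entry into the set).
    """
    if len(sample) == 0:
        raise ValueError("empty dwell sample")
    t = np.asarray(times, dtype=float)
    inside = np.zeros(t.size)
    entry = sample.entry_s
    leave = sample.entry_s + sample.dwell_s
    ever = np.isfinite(entry)
    still_in = ever & (sample.exit_branch == "")
    for i, tt in enumerate(t):
        occupied = ever & (entry <= tt) & ((leave > tt) | still_in)
        inside[i] = occupied.mean()
    return ProgressCurve(t, inside, species="survival")


def gillespie_occupancy(
    scheme: RateScheme,
    n_molecules: int,
    times,
    seed: int,
) -> np.ndarray:
    """Empirical state occupancy (time × state) from stochastic paths."""
    t_query = np.asarray(times, dtype=float)
    comp = _CompiledScheme(scheme)
    rng = np.random.Generator(np.random.Philox(seed))
    state = _initial_states(scheme, n_molecules, rng)
    t = np.zeros(n_molecules)
    t_end = float(t_query.max())

    # answer[i] = state of each molecule at t_query[i]
    answer = np.empty((t_query.size, n_molecules), dtype=np.int64)
    for i, tq in enumerate(t_query):
        if tq == 0.0:
            answer[i] = state
    recorded = t_query == 0.0

    for _ in range(_MAX_ROUNDS):
        active = (comp.exit_rate[state] > 0) & (t <= t_end)
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        s_old = state[idx]
        r = comp.exit_rate[s_old]
        dt = rng.exponential(1.0 / r)
        u = rng.random(idx.size)
        branch = (u[:, None] > comp.cum_prob[s_old]).sum(axis=1)
        t_new = t[idx] + dt
        for i, tq in enumerate(t_query):
            crossing = (t[idx] <= tq) & (t_new > tq)
            if crossing.any():
                answer[i, idx[crossing]] = s_old[crossing]
        t[idx] = t_new
        state[idx] = comp.dest[s_old, branch]
    else:  # pragma: no cover
        raise RuntimeError("gillespie exceeded maximum number of rounds")

    # molecules that stopped jumping before a query time keep their state
    for i, tq in enumerate(t_query):
        if recorded[i]:
            continue
        settled = t <= tq
        answer[i, settled] = state[settled]

    n_states = len(scheme.states)
    occ = np.zeros((t_query.size, n_states))
    for i in range(t_query.size):
        occ[i] = np.bincount(answer[i], minlength=n_states) / n_molecules
    return occ
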
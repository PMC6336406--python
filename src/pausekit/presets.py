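"""Reference kinetic schemes for the consensus elemental pause.

The consensus preset reproduces the phenomenology reported for the consensus
elemental pause sequence at 37 °C: about 80% of elongation complexes are
captured by the pause (apparent escape lifetime ≈ 5 s), a minor slow
population of ≈ 15% (lifetime ≈ 100 s), and ≈ 20% bypass the pause without
pausing (lifetime ≈ 0.1 s).  The printed fractions (80% pause, 15% slow,
20% bypass) do not sum to one; this preset reconciles them by treating the
slow species as part of the total captured fraction, i.e. a fast amplitude
of 0.65, slow amplitude of 0.15 and bypass of 0.20.

The microscopic rate constants below are illustrative: they were chosen to
reproduce this phenomenology, since the underlying global-fit rate constants
are not tabulated anywhere.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .schemes import RateScheme, Transition

__all__ = [
    "CONSENSUS",
    "consensus_scheme",
    "unbranched_scheme",
    "tandem_scheme",
    "biexp_ground_truth",
    "PAUSE_RNA_STATES",
    "PREPAUSE_STATES",
    "BEYOND_STATES",
]

# Apparent biexponential parameters of the consensus pause-RNA decay:
# fast amplitude 0.65 with lifetime 5 s, slow amplitude 0.15 with lifetime
# 100 s, bypass 0.20 with lifetime ~0.1 s.
CONSENSUS: dict[str, float] = {
    "k_arrival": 10.0,       # s⁻¹, G16 -> C17 nucleotide addition (fast)
    "capture": 0.80,         # fraction partitioning into the pause
    "k_fast_total": 0.20,    # s⁻¹, total exit rate of the fast pause state
    "slow_amplitude": 0.15,  # asymptotic amplitude of the slow phase
    "k_slow_escape": 0.01,   # s⁻¹, escape from the slow pause state
    "k_bypass_exit": 12.0,   # s⁻¹, rapid extension of bypassing complexes
}

# Species aggregates measured on a gel: all C17-length RNAs co-migrate.
PAUSE_RNA_STATES = ("C17_pause", "C17_slow", "C17_bypass")
PREPAUSE_STATES = ("G16",)
BEYOND_STATES = ("G18plus",)


def _slow_entry_rate(params: dict[str, float]) -> float:
    # Choose the pause -> slow branching so that the asymptotic slow-phase
    # amplitude equals `slow_amplitude`:  capture * k_s / (k1 - k2) = b.
    k1 = params["k_fast_total"]
    k2 = params["k_slow_escape"]
    return params["slow_amplitude"] * (k1 - k2) / params["capture"]


def consensus_scheme(**overrides: float) -> RateScheme:
    """Branched elemental-pause scheme (arrival, pause entry, bypass,
    slow branch, escape).

    Five states: G16 (pre-pause), C17_pause (fast pause), C17_slow (slow
    pause), C17_bypass (on-pathway C17 that extends without pausing) and
    the absorbing G18plus.  The pause state has out-degree two: escape and
    the slow branch.
    """
    p = {**CONSENSUS, **overrides}
    k_s = _slow_entry_rate(p)
    k_esc = p["k_fast_total"] - k_s
    if k_esc <= 0:
        raise ValueError("slow-entry rate exceeds total fast exit rate")
    ka, cap = p["k_arrival"], p["capture"]
    transitions = [
        Transition("G16", "C17_pause", ka * cap),
        Transition("G16", "C17_bypass", ka * (1.0 - cap)),
        Transition("C17_bypass", "G18plus", p["k_bypass_exit"]),
        Transition("C17_pause", "G18plus", k_esc),
        Transition("C17_pause", "C17_slow", k_s),
        Transition("C17_slow", "G18plus", p["k_slow_escape"]),
    ]
    states = ("G16", "C17_pause", "C17_slow", "C17_bypass", "G18plus")
    return RateScheme(states, transitions, {"G16": 1.0})


def unbranched_scheme(**overrides: float) -> RateScheme:
    """On-pathway (unbranched) pause scheme: every complex pauses.

    Same arrival and escape steps as the consensus scheme but without the
    bypass branch, so the t→0 intercept of the pause RNA is 1.
    """
    p = {**CONSENSUS, **overrides}
    k_s = _slow_entry_rate({**p, "capture": 1.0})
    k_esc = p["k_fast_total"] - k_s
    transitions = [
        Transition("G16", "C17_pause", p["k_arrival"]),
        Transition("C17_pause", "G18plus", k_esc),
        Transition("C17_pause", "C17_slow", k_s),
        Transition("C17_slow", "G18plus", p["k_slow_escape"]),
    ]
    states = ("G16", "C17_pause", "C17_slow", "G18plus")
    return RateScheme(states, transitions, {"G16": 1.0})


# ---------------------------------------------------------------------------
# Tandem pause sites: does the slow fraction re-form at the second site?
# ---------------------------------------------------------------------------

TANDEM_SITE1 = ("P1", "S1")
TANDEM_SITE2 = ("P2", "S2")


def tandem_scheme(
    hypothesis: str,
    slow_fraction: float = 0.15,
    k_fast: float = 0.20,
    k_slow: float = 0.01,
    k_arrival: float = 10.0,
    k_transit: float = 10.0,
) -> tuple[RateScheme, dict[str, tuple[str, ...]]]:
    """Two consensus pause sites in series under one of two hypotheses.

    ``dynamic_partitioning``: every molecule re-partitions into the slow
    state at each site with probability ``slow_fraction`` (the slow species
    forms from all polymerases arriving at the second site).

    ``fixed_subpopulation``: a fixed molecular class of size
    ``slow_fraction`` pauses slowly at *both* sites while the rest never do
    (a chemically altered slow subpopulation, filtered by the first site).

    Returns the scheme and a mapping of observable species to state sets.
    """
    fs = float(slow_fraction)
    if not 0.0 <= fs < 1.0:
        raise ValueError("slow_fraction must be in [0, 1)")
    if hypothesis == "dynamic_partitioning":
        transitions = [
            Transition("A0", "P1", k_arrival * (1 - fs)),
            Transition("A0", "S1", k_arrival * fs),
            Transition("P1", "T", k_fast),
            Transition("S1", "T", k_slow),
            Transition("T", "P2", k_transit * (1 - fs)),
            Transition("T", "S2", k_transit * fs),
            Transition("P2", "END", k_fast),
            Transition("S2", "END", k_slow),
        ]
        states = ("A0", "P1", "S1", "T", "P2", "S2", "END")
        scheme = RateScheme(states, transitions, {"A0": 1.0})
        observables = {"site1": ("P1", "S1"), "site2": ("P2", "S2")}
    elif hypothesis == "fixed_subpopulation":
        transitions = [
            Transition("A0f", "P1", k_arrival),
            Transition("P1", "Tf", k_fast),
            Transition("Tf", "P2", k_transit),
            Transition("P2", "END", k_fast),
            Transition("A0s", "S1", k_arrival),
            Transition("S1", "Ts", k_slow),
            Transition("Ts", "S2", k_transit),
            Transition("S2", "END", k_slow),
        ]
        states = ("A0f", "P1", "Tf", "P2", "A0s", "S1", "Ts", "S2", "END")
        init = {"A0f": 1 - fs, "A0s": fs} if fs > 0 else {"A0f": 1.0}
        scheme = RateScheme(states, transitions, init)
        observables = {"site1": ("P1", "S1"), "site2": ("P2", "S2")}
    else:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; expected "
            "'dynamic_partitioning' or 'fixed_subpopulation'"
        )
    return scheme, observables


# ---------------------------------------------------------------------------
# Exact biexponential ground truth by modal decomposition
# ---------------------------------------------------------------------------

def biexp_ground_truth(
    scheme: RateScheme,
    pause_states: tuple[str, ...] = PAUSE_RNA_STATES,
) -> dict[str, float]:
    """Exact apparent biexponential parameters of a pause-RNA observable.

    Diagonalizes the rate matrix and projects the observable onto its
    eigenmodes: the two slowest nonzero modes are the fast and slow pause
    phases, and their coefficients are the amplitudes an extrapolated
    double-exponential fit would report (``a``, ``b``); ``bypass`` is
    1 − a − b.  Valid for schemes whose arrival/bypass transients are much
    faster than pause escape.
    """
    K = scheme.rate_matrix
    lam, V = scipy.linalg.eig(K)
    lam = lam.real
    c = scipy.linalg.solve(V, scheme.initial_occupancy.astype(complex))
    members = [s for s in pause_states if s in scheme.states]
    rows = [scheme.state_index(s) for s in members]
    weights = (V[rows, :].sum(axis=0) * c).real

    nonzero = np.where(np.abs(lam) > 1e-9)[0]
    order = nonzero[np.argsort(np.abs(lam[nonzero]))]
    k_slow = float(-lam[order[0]])
    k_fast = float(-lam[order[1]])
    b = float(weights[order[0]])
    a = float(weights[order[1]])
    return {
        "a": a,
        "b": b,
        "k_fast": k_fast,
        "k_slow": k_slow,
        "bypass": 1.0 - a - b,
        "tau_fast": 1.0 / k_fast,
        "tau_slow": 1.0 / k_slow,
    }
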
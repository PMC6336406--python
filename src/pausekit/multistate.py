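"""Rapid-equilibrium multistate model of the paused elongation complex.

The elemental paused complex (ePEC) equilibrates rapidly among several
translocation registers — half-translocated, pretranslocated, 1-bp
backtracked, ≥2-bp backtracked — but can escape the pause only from the
half-translocated register, whose occupancy therefore sets the effective
escape rate.  Under fast pre-equilibrium the mean dwell time is
``1 / (f_half · k_escape)``, so shifting occupancy away from the
half-translocated register lengthens the pause by ``baseline / f_half``
relative to a reference complex that is half-translocated a fraction
``baseline`` (default 0.95) of the time.

The same module houses the NTP-dependent partition model: pause bypass
reflects a kinetic competition between pause entry and on-pathway
nucleotide addition, so the bypass fraction rises hyperbolically with NTP
concentration and plateaus below one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import RateScheme, Transition
from .stochastic import DwellSample, gillespie

__all__ = [
    "RegisterOccupancy",
    "PartitionModel",
    "dwell_factor",
    "register_hopping_scheme",
    "dwell_distribution",
    "bypass_fraction",
    "calibrate_partition",
]

REGISTERS = ("half_translocated", "pretranslocated", "backtracked_1bp",
             "backtracked_2bp_plus")


@dataclass
class RegisterOccupancy:
    """Equilibrium fractions of the ePEC translocation registers.

    Fractions must be nonnegative and sum to one; the half-translocated
    fraction must be positive for the dwell time to be finite.
    ``baseline`` is the comparator occupancy of a reference ePEC that is
    half-translocated >95% of the time.
    """

    half_translocated: float
    pretranslocated: float = 0.0
    backtracked_1bp: float = 0.0
    backtracked_2bp_plus: float = 0.0
    baseline: float = 0.95

    def __post_init__(self) -> None:
        fr = self.fractions
        if np.any(fr < 0):
            raise ValueError("register fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"register fractions sum to {fr.sum():.12g}, expected 1")
        if not 0 < self.baseline <= 1:
            raise ValueError("baseline occupancy must be in (0, 1]")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.half_translocated, self.pretranslocated,
                         self.backtracked_1bp, self.backtracked_2bp_plus])

    @classmethod
    def from_half(cls, half: float, baseline: float = 0.95) -> "RegisterOccupancy":
        """Occupancy with the non-escaping remainder split evenly between
        the pretranslocated and 1-bp backtracked registers."""
        rest = 1.0 - half
        return cls(half, rest / 2, rest / 2, 0.0, baseline=baseline)


def dwell_factor(occ: RegisterOccupancy) -> float:
    """Pause-lengthening factor under rapid pre-equilibrium.

    Mean dwell is proportional to 1 / f_half when escape is possible only
    from the half-translocated register, so the factor relative to the
    baseline complex is ``baseline / f_half``: 0.50 occupancy against a
    0.95 baseline lengthens the pause ~2-fold, 0.25 gives ~3.8, 0.10
    gives ~9.5.
    """
    if occ.half_translocated <= 0:
        raise ValueError("half-translocated fraction must be positive for escape")
    return occ.baseline / occ.half_translocated


def register_hopping_scheme(
    occ: RegisterOccupancy,
    escape_rate: float,
    equilibration_speed: float,
) -> RateScheme:
    """Explicit register-hopping scheme realizing the target occupancies.

    Hop rates between registers are ``kappa * pi_dest`` with
    ``kappa = equilibration_speed * escape_rate``, which satisfies detailed
    balance with stationary distribution ``pi``; escape (to an absorbing
    state) occurs only from the half-translocated register.
    """
    if escape_rate <= 0 or equilibration_speed <= 0:
        raise ValueError("escape rate and equilibration speed must be positive")
    pi = occ.fractions
    kappa = equilibration_speed * escape_rate
    live = [r for r, p in zip(REGISTERS, pi) if p > 0]
    pvec = {r: p for r, p in zip(REGISTERS, pi) if p > 0}
    transitions = [
        Transition(src, dst, kappa * pvec[dst])
        for src in live for dst in live if src != dst
    ]
    transitions.append(Transition("half_translocated", "escaped", escape_rate))
    init = dict(pvec)  # start at the equilibrium distribution
    return RateScheme(tuple(live) + ("escaped",), transitions, init)


def dwell_distribution(
    occ: RegisterOccupancy,
    escape_rate: float,
    equilibration_speed: float,
    n: int,
    seed: int,
) -> DwellSample:
    """Stochastic pause dwell times from the register-hopping scheme.

    As ``equilibration_speed`` grows the mean converges to the
    rapid-equilibrium value ``1 / (f_half · escape_rate)``; at speed
    ratios near one the pre-equilibrium assumption fails and the mean
    deviates (documented non-limit behavior).
    """
    scheme = register_hopping_scheme(occ, escape_rate, equilibration_speed)
    registers = tuple(s for s in scheme.states if s != "escaped")
    return gillespie(scheme, n, seed=seed, dwell_states=registers)


@dataclass
class PartitionModel:
    """NTP-dependent partition between pause entry and on-pathway escape.

    Pause entry competes with nucleotide addition whose rate saturates
    hyperbolically in the NTP concentration:
    ``k_escape(c) = max_escape_rate * c / (K_half + c)``.  The functional
    form is the minimal saturable choice consistent with the observed
    plateau of bypass at high NTP.
    """

    pause_entry_rate: float      # s⁻¹
    max_escape_rate: float       # s⁻¹
    K_half: float                # µM

    def __post_init__(self) -> None:
        if min(self.pause_entry_rate, self.max_escape_rate, self.K_half) <= 0:
            raise ValueError("all partition-model parameters must be positive")


def bypass_fraction(model: PartitionModel, ntp_conc_uM: float | np.ndarray) -> float | np.ndarray:
    """Fraction of complexes bypassing the pause at a given NTP level.

    ``bypass = k_esc(c) / (k_esc(c) + k_pause)``: zero at c = 0, monotone
    increasing, approaching ``k_max / (k_max + k_pause) < 1`` at
    saturation.
    """
    c = np.asarray(ntp_conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("NTP concentration must be nonnegative")
    k_esc = model.max_escape_rate * c / (model.K_half + c)
    out = k_esc / (k_esc + model.pause_entry_rate)
    return float(out) if np.isscalar(ntp_conc_uM) else out


def calibrate_partition(
    obs: list[tuple[float, float]],
    pause_entry_rate: float = 1.0,
) -> PartitionModel:
    """Solve the partition model from two (concentration, bypass) pairs.

    Two observations pin down ``K_half`` and the ratio
    ``max_escape_rate / pause_entry_rate`` exactly (the absolute scale of
    the rates is set by ``pause_entry_rate``, which the bypass fraction
    does not constrain).  With bypass odds ``w = f/(1-f)`` the equations
    ``w_i = r * c_i / (K + c_i)`` give a closed-form solution.
    """
    if len(obs) != 2:
        raise ValueError("exactly two (conc, bypass) observations are required")
    (c1, f1), (c2, f2) = obs
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise ValueError("bypass fractions must be strictly inside (0, 1)")
    w1, w2 = f1 / (1 - f1), f2 / (1 - f2)
    rho = w1 / w2
    # rho = c1 (K + c2) / (c2 (K + c1))  ->  K = c1 c2 (1 - rho) / (rho c2 - c1)
    denom = rho * c2 - c1
    if denom == 0:
        raise ValueError("observations are degenerate (no finite K_half)")
    K = c1 * c2 * (1.0 - rho) / denom
    if K <= 0:
        raise ValueError("observations imply a non-positive K_half")
    r = w1 * (K + c1) / c1
    return PartitionModel(
        pause_entry_rate=pause_entry_rate,
        max_escape_rate=r * pause_entry_rate,
        K_half=K,
    )
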
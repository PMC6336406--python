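"""First-order kinetic schemes for transcription elongation and pausing.

An elongation complex walking through a pause site is modelled as a
continuous-time Markov chain over labelled states (RNA length / register
identities such as ``G16``, ``C17_pause``, ``C17_slow``, ``G18plus``).  A
:class:`RateScheme` stores the states, the first-order transitions between
them, and the initial occupancy; :func:`solve_scheme` integrates the master
equation ``dp/dt = K p`` with a stiff-capable implicit method and the exact
(constant) Jacobian ``K``.

Substrate-dependent steps (e.g. NTP addition) are folded into
pseudo-first-order constants at build time: a transition tagged with a
substrate stores a second-order constant in µM⁻¹ s⁻¹ and is multiplied by
the named concentration in µM.  Re-binding concentrations creates a new
scheme; schemes are immutable after construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .curves import ProgressCurve

__all__ = [
    "Transition",
    "RateScheme",
    "OccupancyTrajectory",
    "SchemeError",
    "IntegrationError",
    "build_scheme",
    "solve_scheme",
    "species_fraction",
]


class SchemeError(ValueError):
    """Invalid kinetic-scheme specification."""


class IntegrationError(RuntimeError):
    """The master-equation integration failed or produced an invalid result."""


@dataclass(frozen=True)
class Transition:
    """A first-order (or pseudo-first-order) step ``source -> dest``.

    ``k`` is in s⁻¹ for plain transitions; when ``substrate`` is set, ``k``
    is a second-order constant in µM⁻¹ s⁻¹ and the effective rate is
    ``k * [substrate]``.
    """

    source: str
    dest: str
    k: float
    substrate: str | None = None

    @property
    def label(self) -> str:
        return f"{self.source}->{self.dest}"


class RateScheme:
    """Labelled first-order reaction network with initial occupancy."""

    def __init__(
        self,
        states: Sequence[str],
        transitions: Iterable[Transition],
        initial_occupancy: Mapping[str, float],
        substrate_concentrations: Mapping[str, float] | None = None,
    ) -> None:
        self.states: tuple[str, ...] = tuple(states)
        self.substrate_concentrations = dict(substrate_concentrations or {})
        if len(set(self.states)) != len(self.states):
            raise SchemeError("state labels must be unique")
        index = {s: i for i, s in enumerate(self.states)}

        kept: list[Transition] = []
        for tr in transitions:
            if tr.source not in index:
                raise SchemeError(f"unknown source state {tr.source!r}")
            if tr.dest not in index:
                raise SchemeError(f"unknown destination state {tr.dest!r}")
            if tr.source == tr.dest:
                raise SchemeError(f"self-transition on {tr.source!r}")
            if not np.isfinite(tr.k) or tr.k < 0:
                raise SchemeError(f"negative or non-finite rate on {tr.label}")
            if tr.substrate is not None and tr.substrate not in self.substrate_concentrations:
                raise SchemeError(
                    f"transition {tr.label} references unknown substrate {tr.substrate!r}"
                )
            if self._effective_rate(tr) == 0.0:
                continue  # zero-rate transitions are pruned
            kept.append(tr)
        self.transitions: tuple[Transition, ...] = tuple(kept)

        occ = np.zeros(len(self.states))
        for name, frac in initial_occupancy.items():
            if name not in index:
                raise SchemeError(f"initial occupancy names unknown state {name!r}")
            if frac < 0:
                raise SchemeError(f"negative initial occupancy for {name!r}")
            occ[index[name]] = float(frac)
        if abs(occ.sum() - 1.0) > 1e-12:
            raise SchemeError(
                f"initial occupancies sum to {occ.sum():.15g}, expected 1"
            )
        self.initial_occupancy: np.ndarray = occ
        self._index = index

        K = np.zeros((len(self.states), len(self.states)))
        for tr in self.transitions:
            rate = self._effective_rate(tr)
            i, j = index[tr.dest], index[tr.source]
            K[i, j] += rate
            K[j, j] -= rate
        self._K = K

        connected = {tr.source for tr in self.transitions} | {
            tr.dest for tr in self.transitions
        }
        isolated = [s for s in self.states if s not in connected]
        if isolated and len(self.states) > 1:
            warnings.warn(f"isolated states in scheme: {isolated}", stacklevel=2)

    def _effective_rate(self, tr: Transition) -> float:
        if tr.substrate is None:
            return tr.k
        return tr.k * self.substrate_concentrations[tr.substrate]

    # -- immutability contract: rebinding substrates yields a new scheme ----
    def with_substrates(self, concentrations: Mapping[str, float]) -> "RateScheme":
        """Return a new scheme with substrate concentrations re-bound (µM)."""
        new = dict(self.substrate_concentrations)
        new.update(concentrations)
        init = {s: float(f) for s, f in zip(self.states, self.initial_occupancy)}
        return RateScheme(self.states, self.transitions, init, new)

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator matrix K of the master equation dp/dt = K p (copy)."""
        return self._K.copy()

    def state_index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise SchemeError(f"unknown state label {label!r}") from None

    def effective_rate(self, transition: Transition) -> float:
        return self._effective_rate(transition)

    @property
    def absorbing_states(self) -> tuple[str, ...]:
        out = np.abs(np.diag(self._K))
        return tuple(s for s, r in zip(self.states, out) if r == 0.0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RateScheme(states={len(self.states)}, "
            f"transitions={len(self.transitions)})"
        )


@dataclass
class OccupancyTrajectory:
    """Solution of the master equation: state occupancies over time.

    Rows of ``occupancy`` (time × state) sum to one; the first row equals
    the scheme's initial occupancy at t = 0.
    """

    times: np.ndarray
    occupancy: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.times[0] != 0.0:
            raise ValueError("trajectory must start at t = 0")
        if self.occupancy.shape != (self.times.size, len(self.states)):
            raise ValueError("occupancy shape must be (n_times, n_states)")

    def column(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(label)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.occupancy, columns=list(self.states))
        out.insert(0, "time_s", self.times)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_scheme(spec: Mapping) -> RateScheme:
    """Build and validate a :class:`RateScheme` from a structured description.

    The description is a key-value tree (e.g. parsed from YAML) with keys
    ``states`` (list of labels), ``transitions`` (list of mappings with
    ``from``, ``to``, ``k`` and optional ``substrate``), ``init`` (mapping
    state → fraction) and optional ``substrates`` (mapping tag → µM).
    """
    try:
        states = list(spec["states"])
        raw_transitions = list(spec["transitions"])
        init = dict(spec["init"])
    except KeyError as exc:
        raise SchemeError(f"scheme spec missing required key {exc.args[0]!r}") from None
    substrates = dict(spec.get("substrates", {}))
    transitions = []
    for row in raw_transitions:
        transitions.append(
            Transition(
                source=row["from"],
                dest=row["to"],
                k=float(row["k"]),
                substrate=row.get("substrate"),
            )
        )
    return RateScheme(states, transitions, init, substrates)


def scheme_to_spec(scheme: RateScheme) -> dict:
    """Inverse of :func:`build_scheme` (for provenance sidecar files)."""
    return {
        "schema_version": 1,
        "states": list(scheme.states),
        "transitions": [
            {
                "from": tr.source,
                "to": tr.dest,
                "k": tr.k,
                **({"substrate": tr.substrate} if tr.substrate else {}),
            }
            for tr in scheme.transitions
        ],
        "init": {
            s: float(f)
            for s, f in zip(scheme.states, scheme.initial_occupancy)
            if f > 0
        },
        "substrates": dict(scheme.substrate_concentrations),
    }


def solve_scheme(
    scheme: RateScheme,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OccupancyTrajectory:
    """Integrate the master equation of ``scheme`` at the requested times.

    Uses LSODA (switching to the implicit BDF method on stiff problems) with
    the exact constant Jacobian K.  Times must be sorted and nonnegative;
    t = 0 is prepended if absent so the output always contains the initial
    condition.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] != 0.0:
        t = np.concatenate(([0.0], t))

    K = scheme._K
    p0 = scheme.initial_occupancy
    if t.size == 1:
        return OccupancyTrajectory(t, p0[None, :].copy(), scheme.states)

    sol, info = odeint(
        lambda p, _t: K @ p,
        p0,
        t,
        Dfun=lambda p, _t: K,
        rtol=rtol,
        atol=atol,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"master-equation integration failed for scheme with states "
            f"{scheme.states}: {info['message']}"
        )
    row_sums = sol.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        worst = float(np.max(np.abs(row_sums - 1.0)))
        raise IntegrationError(
            f"occupancy conservation violated (max |sum-1| = {worst:.3e}); "
            f"scheme states {scheme.states}, stiffness ratio "
            f"{_stiffness_ratio(K):.3g}"
        )
    return OccupancyTrajectory(t, sol, scheme.states)


def _stiffness_ratio(K: np.ndarray) -> float:
    ev = np.abs(np.linalg.eigvals(K).real)
    nz = ev[ev > 1e-300]
    if nz.size < 2:
        return 1.0
    return float(nz.max() / nz.min())


def species_fraction(
    traj: OccupancyTrajectory,
    states: Iterable[str],
    replicate: int = 0,
    species: str = "pause_rna",
) -> ProgressCurve:
    """Sum the occupancies of the named states into a progress curve.

    Supports at-or-beyond aggregates (e.g. C17⁺ = C17 and everything
    longer) by listing all member states.
    """
    labels = list(states)
    for label in labels:
        if label not in traj.states:
            raise SchemeError(f"unknown state label {label!r}")
    if labels:
        idx = [traj.states.index(s) for s in labels]
        frac = traj.occupancy[:, idx].sum(axis=1)
    else:
        frac = np.zeros(traj.times.size)
    return ProgressCurve(
        traj.times.copy(),
        np.clip(frac, 0.0, 1.0),
        replicate=replicate,
        species=species,
    )
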
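"""Shared fixtures: small reference schemes and a random-scheme factory."""

from __future__ import annotations

import numpy as np
import pytest

from pausekit import RateScheme, Transition, consensus_scheme
from pausekit.synthetic import AssayNoiseModel, make_pause_assay


@pytest.fixture
def two_state() -> RateScheme:
    """A -> B at 0.2 /s (5 s lifetime), starting in A."""
    return RateScheme(("A", "B"), [Transition("A", "B", 0.2)], {"A": 1.0})


@pytest.fixture
def branch_scheme() -> RateScheme:
    """A -> B (k=4) competing with A -> C (k=1): 80% reach B."""
    return RateScheme(
        ("A", "B", "C"),
        [Transition("A", "B", 4.0), Transition("A", "C", 1.0)],
        {"A": 1.0},
    )


@pytest.fixture
def consensus():
    return consensus_scheme()


@pytest.fixture
def consensus_dataset():
    def factory(seed: int = 0, sd: float = 0.02, n_replicates: int = 3):
        return make_pause_assay(
            noise=AssayNoiseModel(sd=sd, n_replicates=n_replicates, seed=seed)
        )

    return factory


def random_scheme(rng: np.random.Generator, max_states: int = 8) -> RateScheme:
    """Random first-order network with rates log-uniform in [1e-3, 1e3]."""
    n = int(rng.integers(2, max_states + 1))
    states = tuple(f"S{i}" for i in range(n))
    n_tr = int(rng.integers(1, 2 * n))
    transitions = []
    for _ in range(n_tr):
        i, j = rng.choice(n, size=2, replace=False)
        k = float(10 ** rng.uniform(-3, 3))
        transitions.append(Transition(states[i], states[j], k))
    occ = rng.dirichlet(np.ones(n))
    occ = occ / occ.sum()
    init = {s: float(f) for s, f in zip(states, occ)}
    # re-normalize exactly to 1 against float round-off
    total = sum(init.values())
    init[states[0]] += 1.0 - total
    return RateScheme(states, transitions, init)
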
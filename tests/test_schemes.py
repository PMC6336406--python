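"""Kinetic-scheme construction and master-equation solving."""

import numpy as np
import pytest
import scipy.linalg

from pausekit import (
    RateScheme,
    SchemeError,
    Transition,
    build_scheme,
    consensus_scheme,
    solve_scheme,
    species_fraction,
)
from pausekit.presets import PAUSE_RNA_STATES, biexp_ground_truth

from conftest import random_scheme


class TestBuildScheme:
    def test_minimal_two_state_network(self):
        scheme = build_scheme(
            {
                "states": ["A", "B"],
                "transitions": [{"from": "A", "to": "B", "k": 0.2}],
                "init": {"A": 1.0},
            }
        )
        assert scheme.states == ("A", "B")
        assert len(scheme.transitions) == 1
        assert scheme.transitions[0].k == 0.2

    @pytest.mark.parametrize(
        "spec, match",
        [
            (
                {"states": ["A", "B"],
                 "transitions": [{"from": "A", "to": "X", "k": 1.0}],
                 "init": {"A": 1.0}},
                "unknown destination",
            ),
            (
                {"states": ["A", "B"],
                 "transitions": [{"from": "A", "to": "B", "k": -1.0}],
                 "init": {"A": 1.0}},
                "negative",
            ),
            (
                {"states": ["A", "B"],
                 "transitions": [{"from": "A", "to": "B", "k": 1.0}],
                 "init": {"A": 0.6, "B": 0.5}},
                "sum",
            ),
            (
                {"states": ["A", "A"],
                 "transitions": [],
                 "init": {"A": 1.0}},
                "unique",
            ),
        ],
    )
    def test_invalid_specs_rejected(self, spec, match):
        with pytest.raises(SchemeError, match=match):
            build_scheme(spec)

    def test_branched_pause_scheme_shape(self, consensus):
        # arrival, pause entry, bypass, slow branch, escape: five states
        # with out-degree two at the pause state
        assert len(consensus.states) == 5
        out_of_pause = [t for t in consensus.transitions if t.source == "C17_pause"]
        assert len(out_of_pause) == 2
        assert {t.dest for t in out_of_pause} == {"G18plus", "C17_slow"}

    def test_substrate_folding_and_immutability(self):
        spec = {
            "states": ["EC", "EC+1"],
            "transitions": [{"from": "EC", "to": "EC+1", "k": 0.002,
                             "substrate": "GTP"}],
            "init": {"EC": 1.0},
            "substrates": {"GTP": 100.0},
        }
        scheme = build_scheme(spec)
        assert scheme.rate_matrix[1, 0] == pytest.approx(0.2)
        rebound = scheme.with_substrates({"GTP": 10.0})
        assert rebound.rate_matrix[1, 0] == pytest.approx(0.02)
        # original untouched
        assert scheme.rate_matrix[1, 0] == pytest.approx(0.2)

    def test_zero_rate_transitions_pruned(self):
        scheme = RateScheme(
            ("A", "B"),
            [Transition("A", "B", 0.5), Transition("B", "A", 0.0)],
            {"A": 1.0},
        )
        assert len(scheme.transitions) == 1


class TestSolveScheme:
    def test_initial_condition_and_closed_form(self, two_state):
        traj = solve_scheme(two_state, [0.0, 5.0])
        assert traj.occupancy[0] == pytest.approx([1.0, 0.0])
        # B(5) = 1 - exp(-0.2 * 5) = 1 - 1/e
        assert traj.column("B")[1] == pytest.approx(1 - np.exp(-1), abs=1e-9)

    def test_matches_matrix_exponential_on_random_schemes(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            scheme = random_scheme(rng)
            times = np.sort(rng.uniform(0.0, 10.0, size=8))
            times = np.concatenate(([0.0], times))
            traj = solve_scheme(scheme, np.unique(times))
            K = scheme.rate_matrix
            for t, row in zip(traj.times, traj.occupancy):
                ref = scipy.linalg.expm(K * t) @ scheme.initial_occupancy
                assert np.max(np.abs(ref - row)) < 1e-7

    def test_conservation_and_absorbing_monotonicity(self, consensus):
        t = np.concatenate(([0.0], np.geomspace(0.01, 1000.0, 60)))
        traj = solve_scheme(consensus, t)
        assert np.allclose(traj.occupancy.sum(axis=1), 1.0, atol=1e-9)
        end = traj.column("G18plus")
        assert np.all(np.diff(end) >= -1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        scheme = random_scheme(rng)
        perm = rng.permutation(len(scheme.states))
        p_states = tuple(scheme.states[i] for i in perm)
        init = {s: float(f) for s, f in zip(scheme.states, scheme.initial_occupancy)}
        permuted = RateScheme(p_states, scheme.transitions, init)
        t = np.array([0.0, 0.3, 2.0, 9.0])
        a = solve_scheme(scheme, t)
        b = solve_scheme(permuted, t)
        for s in scheme.states:
            assert np.allclose(a.column(s), b.column(s), atol=1e-9)

    def test_rejects_bad_time_grids(self, two_state):
        with pytest.raises(ValueError):
            solve_scheme(two_state, [-1.0, 2.0])
        with pytest.raises(ValueError):
            solve_scheme(two_state, [0.0, 2.0, 1.0])


class TestSpeciesFraction:
    def test_full_set_is_conserved_unity(self, consensus):
        traj = solve_scheme(consensus, np.linspace(0, 50, 20))
        curve = species_fraction(traj, consensus.states)
        assert np.allclose(curve.fractions, 1.0, atol=1e-9)

    def test_empty_set_is_zero(self, consensus):
        traj = solve_scheme(consensus, np.linspace(0, 50, 20))
        assert np.all(species_fraction(traj, []).fractions == 0.0)

    def test_unknown_label_raises(self, consensus):
        traj = solve_scheme(consensus, [0.0, 1.0])
        with pytest.raises(SchemeError, match="unknown"):
            species_fraction(traj, ["nope"])

    def test_pause_rna_decay_is_biexponential_after_transient(self, consensus):
        """Beyond the arrival transient, the modelled pause-RNA decay equals
        the sum of two exponentials from the modal decomposition."""
        t = np.concatenate(([0.0], np.geomspace(0.01, 500.0, 50)))
        traj = solve_scheme(consensus, t)
        curve = species_fraction(traj, PAUSE_RNA_STATES)
        gt = biexp_ground_truth(consensus)
        late = traj.times > 2.0
        pred = (gt["a"] * np.exp(-gt["k_fast"] * traj.times[late])
                + gt["b"] * np.exp(-gt["k_slow"] * traj.times[late]))
        assert np.max(np.abs(curve.fractions[late] - pred)) < 1e-8


class TestSolverProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        t=st.floats(min_value=1e-3, max_value=50.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_two_state_solution_matches_closed_form(self, k, t):
        scheme = RateScheme(("A", "B"), [Transition("A", "B", k)], {"A": 1.0})
        times = np.unique(np.array([0.0, t]))
        traj = solve_scheme(scheme, times)
        expect = np.exp(-k * times)
        assert np.allclose(traj.column("A"), expect, atol=1e-7)
        assert np.allclose(traj.column("B"), 1 - expect, atol=1e-7)


def test_trajectory_csv_round_trip(tmp_path, consensus):
    import pandas as pd

    traj = solve_scheme(consensus, np.linspace(0, 20, 9))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["time_s", *consensus.states]
    assert np.allclose(back[list(consensus.states)].to_numpy(), traj.occupancy)
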
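"""Constraint schedules, constrained minimization and the scan driver."""

import os
import stat

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnsmech.scan import (
    FunctionBackend,
    PairPotentialBackend,
    ReactionProfile,
    ScanProtocol,
    avoided_crossing,
    compare_profiles,
    constrained_minimize,
    external_backend,
    morse,
    run_scan,
    schedule,
)
from qnsmech.synthetic import make_scan_system


def _protocol(start, covalent, coarse=0.4, fine=0.1, offset=1.0):
    return ScanProtocol(
        reacting_pair=("L/1:C1", "A/1:SG"),
        covalent_target=covalent,
        start_distance=start,
        coarse_step=coarse,
        fine_step=fine,
        switch_offset=offset,
    )


class TestSchedule:
    def test_hand_enumerated_example(self):
        # coarse 0.4 from 4.0 down to the 1.0 Å switch band above 1.8, then 0.1
        got = schedule(_protocol(4.0, 1.8))
        expected = [4.0, 3.6, 3.2, 2.8, 2.7, 2.6, 2.5, 2.4, 2.3, 2.2, 2.1, 2.0, 1.9, 1.8]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_start_equals_covalent_single_point(self):
        assert schedule(_protocol(1.8, 1.8)) == [1.8]

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        start=st.floats(2.0, 8.0),
        covalent=st.floats(1.2, 1.9),
        coarse=st.floats(0.25, 0.6),
        fine=st.floats(0.05, 0.2),
        offset=st.floats(0.0, 1.5),
    )
    def test_step_law_on_randomized_protocols(self, start, covalent, coarse, fine, offset):
        """Gaps are coarse far out, fine inside the switch band, with at most
        one sub-fine remainder; the last point is the covalent target."""
        if coarse <= fine:
            return
        pts = schedule(_protocol(start, covalent, coarse, fine, offset))
        assert pts[0] == start
        assert pts[-1] == covalent
        assert all(a > b for a, b in zip(pts, pts[1:]))
        gaps = [a - b for a, b in zip(pts, pts[1:])]
        for k, g in enumerate(gaps):
            is_last = k == len(gaps) - 1
            assert (
                abs(g - coarse) < 1e-9
                or abs(g - fine) < 1e-9
                or (is_last and g < fine + 1e-9)
            )
        # coarse steps only while above the switch band
        for p, g in zip(pts, gaps):
            if abs(g - coarse) < 1e-9:
                assert p - coarse >= covalent + offset - 1e-9

    def test_schedule_cap(self):
        with pytest.raises(ValueError, match="exceeds"):
            schedule(_protocol(8.0, 1.2, coarse=0.3, fine=0.001))


class TestConstrainedMinimize:
    def test_two_atom_morse_at_minimum(self):
        model, _, man = make_scan_system(seed=5)
        de, a, r0 = 80.0, 1.5, 1.81
        keys = [k for k, _ in model.atoms()]
        pair_idx = (keys.index("L/1:C1"), keys.index("A/1:SG"))
        backend = PairPotentialBackend(pair_idx, morse(de, a, r0), name="morse")
        _, energy, ok = constrained_minimize(
            model, backend, ("L/1:C1", "A/1:SG"), r0
        )
        assert ok
        assert energy == pytest.approx(-de, abs=1e-4)

    def test_fixed_point_at_constrained_minimum(self):
        model, backend, man = make_scan_system(seed=5)
        d = man.truth["start_distance_A"]
        c1, e1, _ = constrained_minimize(model, backend, ("L/1:C1", "A/1:SG"), d)
        c2, e2, _ = constrained_minimize(
            model, backend, ("L/1:C1", "A/1:SG"), d, coords=c1
        )
        assert e2 == pytest.approx(e1, abs=1e-4)

    def test_rigid_atoms_bitwise_unchanged(self):
        model, backend, man = make_scan_system(seed=5)
        keys = [k for k, _ in model.atoms()]
        before = np.stack([a.coords for _, a in model.atoms()])
        c, _, _ = constrained_minimize(model, backend, ("L/1:C1", "A/1:SG"), 2.3)
        rigid = [i for i, k in enumerate(keys) if k in model.rigid_atoms]
        np.testing.assert_array_equal(c[rigid], before[rigid])

    def test_constraint_enforced_exactly(self):
        model, backend, man = make_scan_system(seed=5)
        keys = [k for k, _ in model.atoms()]
        i, j = keys.index("L/1:C1"), keys.index("A/1:SG")
        for d in (3.0, 2.4, 1.81):
            c, _, _ = constrained_minimize(model, backend, ("L/1:C1", "A/1:SG"), d)
            assert np.linalg.norm(c[i] - c[j]) == pytest.approx(d, abs=1e-4)

    def test_multi_atom_toy_beats_random_restarts(self):
        """Five mobile atoms under Morse + soft repulsion: the minimizer
        matches a dense multi-start oracle."""
        rng = np.random.default_rng(0)
        model, _, _ = make_scan_system(seed=5)
        # augment ligand with extra mobile atoms
        from qnsmech.active_site import assign_mobility
        from qnsmech.structures import Atom

        lig = model.ligand
        base = lig.atoms[0].coords
        for k in range(4):
            lig.atoms.append(
                Atom(20 + k, f"X{k}", "C", base + rng.normal(scale=1.0, size=3))
            )
        model = assign_mobility(model, set())
        keys = [k for k, _ in model.atoms()]
        i, j = keys.index("L/1:C1"), keys.index("A/1:SG")
        lig_idx = [keys.index(f"L/1:X{k}") for k in range(4)] + [i]

        def energy(c):
            e = 0.0
            f = morse(50.0, 1.2, 2.0)
            for a in lig_idx:
                for b in lig_idx:
                    if a < b:
                        e += f(np.linalg.norm(c[a] - c[b]))
            return e

        backend = FunctionBackend(energy)
        c, e, _ = constrained_minimize(model, backend, ("L/1:C1", "A/1:SG"), 2.5, tol=1e-6)
        # multi-start oracle
        best = np.inf
        x0 = np.stack([a.coords for _, a in model.atoms()])
        for trial in range(12):
            start = x0.copy()
            start[lig_idx[:-1]] += rng.normal(scale=0.5, size=(4, 3))
            model2 = model.copy()
            for k_, (key, a) in enumerate(model2.atoms()):
                a.coords = start[k_]
            _, e_t, _ = constrained_minimize(
                model2, backend, ("L/1:C1", "A/1:SG"), 2.5, tol=1e-6
            )
            best = min(best, e_t)
        assert e <= best + 1e-3

    def test_both_atoms_rigid_rejected(self):
        model, backend, _ = make_scan_system(seed=5)
        model.mobile_atoms = {"A/1:CB"}  # pair atoms now both effectively rigid
        model.rigid_atoms |= {"L/1:C1"}
        with pytest.raises(ValueError):
            constrained_minimize(model, backend, ("A/1:SG", "A/1:N"), 2.0)


def dense_grid_barrier(f, lo, hi, grid=0.01):
    d = np.arange(lo, hi + grid / 2, grid)
    e = np.asarray(f(d))
    i = int(np.argmax(e))
    return float(e[i] - e[-1]), float(d[i])  # relative to start (hi end)


class TestRunScan:
    @pytest.mark.parametrize("seed", range(3))
    def test_barrier_vs_dense_grid_oracle(self, seed):
        model, backend, man = make_scan_system(
            barrier_height=30.0 + 5 * seed, barrier_position=2.5, seed=seed
        )
        proto = _protocol(man.truth["start_distance_A"], man.truth["covalent_target_A"])
        profile = run_scan(model, backend, proto)
        h, p = dense_grid_barrier(
            backend.f_of_d, man.truth["covalent_target_A"], man.truth["start_distance_A"]
        )
        assert profile.activation_energy == pytest.approx(h, abs=0.1)
        assert abs(profile.ts_distance - p) <= 0.1

    def test_monotonically_attractive_no_barrier(self):
        model, _, man = make_scan_system(seed=5)
        keys = [k for k, _ in model.atoms()]
        pair_idx = (keys.index("L/1:C1"), keys.index("A/1:SG"))
        backend = PairPotentialBackend(pair_idx, morse(60.0, 1.4, 1.81))
        start = man.truth["start_distance_A"]
        profile = run_scan(model, backend, _protocol(start, 1.81))
        assert profile.ts_index == 0
        assert profile.activation_energy == 0.0

    def test_endpoints_reproduce_backend_energy(self):
        model, backend, man = make_scan_system(seed=6)
        proto = _protocol(man.truth["start_distance_A"], man.truth["covalent_target_A"])
        profile = run_scan(model, backend, proto)
        for state in (profile.states[0], profile.states[-1]):
            assert backend.energy(state.coords) == pytest.approx(state.energy, abs=1e-12)

    def test_activation_invariant_to_energy_offset(self):
        model, backend, man = make_scan_system(seed=7)
        proto = _protocol(man.truth["start_distance_A"], man.truth["covalent_target_A"])
        p1 = run_scan(model, backend, proto)
        shifted = PairPotentialBackend(
            backend.pair_indices, lambda d: backend.f_of_d(d) + 123.4
        )
        p2 = run_scan(model, shifted, proto)
        assert p2.activation_energy == pytest.approx(p1.activation_energy, abs=1e-8)
        assert p2.reaction_enthalpy == pytest.approx(p1.reaction_enthalpy, abs=1e-8)

    def test_enthalpy_antisymmetric_on_symmetric_toy(self):
        """Scanning a symmetric double well forward vs backward flips the
        sign of the reaction enthalpy."""
        model, _, man = make_scan_system(seed=8)
        keys = [k for k, _ in model.atoms()]
        pair_idx = (keys.index("L/1:C1"), keys.index("A/1:SG"))
        mid = 2.4
        f = lambda d: 10.0 * ((d - mid) ** 2 - 0.25) ** 2  # wells at mid±0.5
        backend = PairPotentialBackend(pair_idx, f)
        fwd = run_scan(model, backend, _protocol(mid + 0.5, mid - 0.5, coarse=0.2, fine=0.1, offset=0.4))
        assert fwd.reaction_enthalpy == pytest.approx(0.0, abs=1e-6)


class TestCompareProfiles:
    def _fake_profile(self, barrier, enthalpy):
        return ReactionProfile(
            states=[], ts_index=0, ts_distance=0.0,
            activation_energy=barrier, reaction_enthalpy=enthalpy,
        )

    def test_single_profile(self):
        table = compare_profiles([("k1", self._fake_profile(40.0, -5.0))])
        assert list(table["label"]) == ["k1"]

    def test_planted_barriers_ordered(self):
        table = compare_profiles(
            [("k2", self._fake_profile(20.0, 0.0)), ("k1", self._fake_profile(10.0, 0.0))]
        )
        assert list(table["label"]) == ["k1", "k2"]
        assert list(table["activation_energy_kcal_mol"]) == [10.0, 20.0]

    def test_strained_insertion_ranks_above_first(self):
        """A later ketide insertion planted with extra conformational strain
        always shows the higher kinetic barrier."""
        m1, b1, n1 = make_scan_system(barrier_height=40.0, barrier_position=2.5, seed=11)
        m2, b2, n2 = make_scan_system(barrier_height=52.0, barrier_position=2.5, seed=11)
        p1 = run_scan(m1, b1, _protocol(n1.truth["start_distance_A"], 1.81))
        p2 = run_scan(m2, b2, _protocol(n2.truth["start_distance_A"], 1.81))
        table = compare_profiles([("k2", p2), ("k1", p1)])
        assert list(table["label"]) == ["k1", "k2"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles([])


class TestExternalBackend:
    def _mock_engine(self, tmp_path, body):
        script = tmp_path / "engine.sh"
        script.write_text("#!/bin/sh\n" + body)
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        return str(script)

    def test_fixed_energy_mock(self, tmp_path):
        exe = self._mock_engine(tmp_path, "echo 'FINAL HEAT OF FORMATION = -42.5'\n")
        backend = external_backend(exe)
        assert backend.energy(np.zeros((2, 3))) == -42.5

    def test_coordinate_dependent_mock_through_run_scan(self, tmp_path):
        # engine echoes the first x-coordinate of the deck as the energy
        body = "grep '^X' \"$1\" | head -1 | awk '{print \"FINAL HEAT OF FORMATION =\", $2}'\n"
        exe = self._mock_engine(tmp_path, body)
        backend = external_backend(exe)
        e = backend.energy(np.array([[3.25, 0, 0], [0, 0, 0]]))
        assert e == pytest.approx(3.25)

    def test_absent_executable_fails_cleanly(self):
        with pytest.raises(FileNotFoundError):
            external_backend("/no/such/engine-binary")
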
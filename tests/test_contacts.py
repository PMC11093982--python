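"""Probe surfaces, contact classification, traces and mutation screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnsmech.contacts import (
    MutationSpec,
    apply_mutation,
    classify_contact,
    contact_trace,
    residue_contact_areas,
    sample_surface,
    screen_mutation,
)
from qnsmech.structures import Atom, Residue, Structure


def _atom(name, element, pos, serial=1):
    return Atom(serial, name, element, np.asarray(pos, dtype=float))


def _ligand(positions, elements=None):
    elements = elements or ["C"] * len(positions)
    atoms = [_atom(f"C{i+1}", el, p, i + 1) for i, (p, el) in enumerate(zip(positions, elements))]
    return Residue("L", 1, "LIG", atoms, is_polymer=False, is_ligand=True)


def _receptor(entries):
    """entries: list of (chain, seq, res_name, [(atom, element, pos), ...])"""
    chains: dict = {}
    serial = 1
    for chain, seq, name, atoms in entries:
        alist = []
        for an, el, pos in atoms:
            alist.append(_atom(an, el, pos, serial))
            serial += 1
        chains.setdefault(chain, []).append(Residue(chain, seq, name, alist))
    return Structure(chains=chains)


class TestSampleSurface:
    def test_isolated_carbon_analytic_area(self):
        surf = sample_surface([_atom("C1", "C", [0, 0, 0])], probe=1.5, n=960)
        analytic = 4 * np.pi * (1.70 + 1.5) ** 2
        assert surf.total_area == pytest.approx(analytic, rel=0.01)

    def test_coincident_atoms_fully_buried(self):
        a = _atom("C1", "C", [0, 0, 0], 1)
        b = _atom("C2", "C", [0, 0, 0], 2)
        surf = sample_surface([a, b], probe=1.5)
        assert surf.total_area == 0.0

    def test_converges_to_denser_oracle(self):
        rng = np.random.default_rng(4)
        atoms = [
            _atom(f"C{i}", "C", rng.uniform(-2.5, 2.5, size=3), i + 1) for i in range(10)
        ]
        coarse = sample_surface(atoms, probe=1.5, n=960)
        dense = sample_surface(atoms, probe=1.5, n=9600)
        assert coarse.total_area == pytest.approx(dense.total_area, rel=0.01)

    def test_unknown_element_named(self):
        with pytest.raises(KeyError, match="Xx"):
            sample_surface([_atom("X1", "Xx", [0, 0, 0])])

    def test_minimum_sampling_density(self):
        with pytest.raises(ValueError):
            sample_surface([_atom("C1", "C", [0, 0, 0])], n=50)


class TestClassifyContact:
    @pytest.mark.parametrize(
        "area,expected",
        [(0.0, "none"), (0.49, "minor"), (0.5, "major"), (0.499999, "minor"), (3.7, "major")],
    )
    def test_threshold_boundaries(self, area, expected):
        assert classify_contact(area) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_contact(-0.1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.0, 10.0))
    def test_classification_total_and_consistent(self, area):
        c = classify_contact(area)
        assert (c == "none") == (area == 0.0)
        assert (c == "minor") == (0.0 < area < 0.5)
        assert (c == "major") == (area >= 0.5)


class TestResidueContactAreas:
    def test_far_receptor_gives_empty_list(self):
        lig = _ligand([[0, 0, 0]])
        rec = _receptor([("A", 1, "ALA", [("CB", "C", [50, 0, 0])])])
        surf = sample_surface(lig.atoms, probe=1.5)
        assert residue_contact_areas(surf, rec, cutoff=3.0) == []

    def test_planted_single_contact_matches_brute_force(self):
        # one receptor atom 2.5 Å from the expanded surface, another beyond 6 Å
        lig = _ligand([[0, 0, 0]])
        rec = _receptor(
            [
                ("A", 1, "ALA", [("CB", "C", [5.7, 0, 0])]),  # 2.5 from surface points at x=3.2
                ("A", 2, "ALA", [("CB", "C", [0, 0, 12.0])]),
            ]
        )
        surf = sample_surface(lig.atoms, probe=1.5)
        recs = residue_contact_areas(surf, rec, cutoff=3.0)
        assert [r.residue for r in recs] == ["A/1"]
        # O(points × atoms) double-loop oracle
        rec_atoms = [(res, a) for res in rec.residues() for a in res.atoms]
        oracle = 0.0
        for p, wgt in zip(surf.points, surf.weights):
            dists = [np.linalg.norm(p - a.coords) for _, a in rec_atoms]
            j = int(np.argmin(dists))
            if dists[j] <= 3.0 and rec_atoms[j][0].key == "A/1":
                oracle += wgt
        assert recs[0].area == pytest.approx(oracle, abs=1e-9)

    def test_nearest_assignment_partitions_exactly(self):
        """Per-residue areas sum to the total contacted area: each point is
        assigned to exactly one residue."""
        lig = _ligand([[0, 0, 0], [1.5, 0, 0]])
        rec = _receptor(
            [
                ("A", 1, "ALA", [("CB", "C", [4.5, 1.0, 0])]),
                ("A", 2, "SER", [("OG", "O", [-3.0, -2.0, 0])]),
                ("B", 7, "LEU", [("CD1", "C", [1.0, 4.2, 0])]),
            ]
        )
        surf = sample_surface(lig.atoms, probe=1.5)
        recs = residue_contact_areas(surf, rec, cutoff=3.0)
        assert len(recs) >= 2
        # total contacted area oracle: any receptor atom within cutoff
        rec_pos = np.stack([a.coords for res in rec.residues() for a in res.atoms])
        contacted = 0.0
        for p, wgt in zip(surf.points, surf.weights):
            if np.min(np.linalg.norm(rec_pos - p, axis=1)) <= 3.0:
                contacted += wgt
        assert sum(r.area for r in recs) == pytest.approx(contacted, abs=1e-9)
        assert contacted <= surf.total_area + 1e-9


class TestContactTrace:
    def _states(self):
        lig0 = [[0.0, 0.0, 0.0]]
        rec = [("A", 1, "ALA", [("CB", "C", [5.0, 0, 0])])]
        s1 = _receptor(rec)
        s1.chains["L"] = [_ligand(lig0)]
        s2 = _receptor(rec)
        s2.chains["L"] = [_ligand([[-10.0, 0, 0]])]  # moved 10 Å away
        return [("state1", s1), ("state2", s2)]

    def test_single_state_equals_direct_computation(self):
        states = self._states()[:1]
        trace = contact_trace(states, "L/1")
        label, st_ = states[0]
        sub = st_.residue("L/1")
        from qnsmech.contacts import _without_residue

        surf = sample_surface(sub.atoms, probe=1.5)
        recs = residue_contact_areas(surf, _without_residue(st_, "L/1"), cutoff=3.0)
        for r in recs:
            assert trace.loc[r.residue, f"area:{label}"] == pytest.approx(r.area)

    def test_departed_ligand_column_all_none(self):
        trace = contact_trace(self._states(), "L/1")
        assert (trace["class:state2"] == "none").all()
        assert (trace["class:state1"] != "none").any()

    def test_missing_substrate_names_state(self):
        states = self._states()
        del states[1][1].chains["L"]
        with pytest.raises(KeyError, match="state2"):
            contact_trace(states, "L/1")

    def test_three_state_classes_match_per_state_oracle(self):
        states = self._states() + [("state3", self._states()[0][1])]
        trace = contact_trace(states, "L/1")
        for label, st_ in states:
            sub = st_.residue("L/1")
            from qnsmech.contacts import _without_residue

            surf = sample_surface(sub.atoms, probe=1.5)
            recs = residue_contact_areas(surf, _without_residue(st_, "L/1"), cutoff=3.0)
            areas = {r.residue: r.area for r in recs}
            for res_key in trace.index:
                expected = classify_contact(areas.get(res_key, 0.0))
                assert trace.loc[res_key, f"class:{label}"] == expected


class TestApplyMutation:
    def _leu_structure(self):
        from qnsmech.synthetic import make_toy_receptor

        s, _ = make_toy_receptor(seed=7)
        key = next(r.key for r in s.residues() if r.res_name == "LEU")
        return s, key

    def test_leu_to_ala_forced_atom_set(self):
        s, key = self._leu_structure()
        out = apply_mutation(s, MutationSpec.standard(key, "LEU", "ALA"))
        res = out.residue(key)
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O"]
        assert res.res_name == "ALA"

    def test_ser_to_thr_adds_one_methyl_at_ideal_length(self):
        from qnsmech.synthetic import make_toy_receptor

        s, _ = make_toy_receptor(seed=7)
        key = next(r.key for r in s.residues() if r.res_name == "SER")
        before = {a.name for a in s.residue(key).atoms}
        out = apply_mutation(s, MutationSpec.standard(key, "SER", "THR"))
        res = out.residue(key)
        added = {a.name for a in res.atoms} - before
        assert len(added) == 1
        new = res.atom(added.pop())
        d = np.linalg.norm(new.coords - res.atom("CB").coords)
        assert d == pytest.approx(1.52, abs=0.01)

    def test_unsupported_mutation_explicit_error(self):
        with pytest.raises(ValueError, match="unsupported"):
            MutationSpec.standard("A/265", "VAL", "PHE")

    def test_wrong_source_residue_rejected(self):
        s, key = self._leu_structure()
        with pytest.raises(ValueError, match="expects SER"):
            apply_mutation(s, MutationSpec.standard(key, "SER", "GLY"))

    @pytest.mark.parametrize(
        "from_aa,to_aa", [("LEU", "ALA"), ("LEU", "VAL"), ("SER", "GLY")]
    )
    def test_atom_removal_never_increases_own_contact(self, from_aa, to_aa):
        """Deleting atoms of residue R cannot increase R's contact area
        under nearest-atom assignment."""
        from qnsmech.synthetic import make_toy_receptor

        s, _ = make_toy_receptor(seed=7)
        key = next(r.key for r in s.residues() if r.res_name == from_aa)
        mutant = apply_mutation(s, MutationSpec.standard(key, from_aa, to_aa))
        for st_ in (s, mutant):
            pass
        t_wt = contact_trace([("x", s)], "L/1")
        t_mut = contact_trace([("x", mutant)], "L/1")
        a_wt = float(t_wt["area:x"].get(key, 0.0)) if not t_wt.empty else 0.0
        a_mut = float(t_mut["area:x"].get(key, 0.0)) if not t_mut.empty else 0.0
        assert a_mut <= a_wt + 1e-9


class TestScreenMutation:
    def _states_with_contact(self):
        # SER with OG ~2.6 Å from the ligand surface in state A, far in state B
        recA = [
            ("A", 1, "SER", [("CB", "C", [6.5, 0, 0]), ("OG", "O", [5.2, 0.6, 0])]),
        ]
        s1 = _receptor(recA)
        s1.chains["L"] = [_ligand([[0.0, 0.0, 0.0]])]
        s2 = _receptor(recA)
        s2.chains["L"] = [_ligand([[-10.0, 0.0, 0.0]])]
        return [("near", s1), ("far", s2)]

    def test_never_contacting_residue_all_zero_delta(self):
        states = self._states_with_contact()
        far_only = [states[1]]
        spec = MutationSpec.standard("A/1", "SER", "THR")
        report = screen_mutation(far_only, spec, "L/1")
        assert (report["delta"] == 0.0).all()

    def test_identity_edit_equals_wild_type(self):
        states = self._states_with_contact()
        noop = MutationSpec(residue="A/1", from_aa="SER", to_aa="SER")
        report = screen_mutation(states, noop, "L/1")
        assert (report["delta"] == 0.0).all()
        assert list(report["class_wt"]) == list(report["class_mut"])

    def test_added_methyl_in_range_increases_single_state(self):
        """The S→T methyl lands near the ligand surface only in the bound
        state, so Δ > 0 there and Δ = 0 in the unbound state."""
        states = self._states_with_contact()
        spec = MutationSpec.standard("A/1", "SER", "THR")
        report = screen_mutation(states, spec, "L/1").set_index("state")
        assert report.loc["far", "delta"] == 0.0
        # oracle: recompute the bound-state areas directly
        s_near = states[0][1]
        mut = apply_mutation(s_near, spec)
        t_wt = contact_trace([("near", s_near)], "L/1")
        t_mut = contact_trace([("near", mut)], "L/1")
        d_oracle = float(t_mut["area:near"].get("A/1", 0.0)) - float(
            t_wt["area:near"].get("A/1", 0.0)
        )
        assert report.loc["near", "delta"] == pytest.approx(d_oracle, abs=1e-9)
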
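"""Structure reading, pocket distances, contact enumeration and restraint scoring."""

import numpy as np
import pytest

from metaii.buildup import DistanceEstimate
from metaii.structure import (
    AtomSelector,
    CoordinateModel,
    Restraint,
    RestraintSet,
    discriminate_models,
    enumerate_contacts,
    pair_distance,
    read_structure,
    restraints_from_estimates,
    score_model,
)
from metaii.synthetic import generate_toy_structure

POCKET = [
    ("RET:C20", "TYR268:CZ", 4.4),
    ("RET:C12", "TYR268:CZ", 5.6),
    ("RET:C19", "TYR268:CZ", 6.8),
]


@pytest.fixture(scope="module")
def pocket_model():
    return CoordinateModel(generate_toy_structure(POCKET), source="pocket")


@pytest.fixture(scope="module")
def metaii_restraints():
    return RestraintSet([
        Restraint("C20-Tyr268", "POSITIVE", "RET:C20", "TYR268:CZ", r=4.4, sigma=0.3),
        Restraint("C12-Tyr268", "POSITIVE", "RET:C12", "TYR268:CZ", r=5.6, sigma=0.3),
        Restraint("C19-Tyr268", "ABSENT", "RET:C19", "TYR268:CZ", limit=6.0),
    ])


class TestSelectorsAndReading:
    def test_selector_parsing(self):
        sel = AtomSelector.parse("A/TYR268:CZ")
        assert (sel.chain, sel.res_name, sel.res_num, sel.atom) == ("A", "TYR", 268, "CZ")
        assert AtomSelector.parse("RET:C20").res_num is None

    def test_toy_fixture_contains_exactly_the_placed_atoms(self, pocket_model):
        atoms = [(res.name, atom.name)
                 for res in pocket_model.chain for atom in res]
        assert sorted(atoms) == [("RET", "C12"), ("RET", "C19"), ("RET", "C20"),
                                 ("TYR", "CZ")]

    def test_missing_chain_error_names_available_chains(self, tmp_path):
        path = tmp_path / "toy.pdb"
        generate_toy_structure([("ALA1:CA", "ALA2:CA", 3.0)], path=path)
        with pytest.raises(ValueError, match=r"chain 'Z'.*\['A'\]"):
            read_structure(path, chain="Z")

    def test_unreadable_path_rejected(self):
        with pytest.raises(OSError):
            read_structure("no/such/file.pdb")

    def test_unresolved_selector_named_in_error(self, pocket_model):
        with pytest.raises(KeyError, match="PHE261:CZ"):
            pair_distance(pocket_model, "PHE261:CZ", "RET:C20")


class TestPairDistance:
    def test_same_atom_zero(self, pocket_model):
        assert pair_distance(pocket_model, "RET:C20", "RET:C20") == 0.0

    def test_symmetry(self, pocket_model):
        d1 = pair_distance(pocket_model, "RET:C20", "TYR268:CZ")
        d2 = pair_distance(pocket_model, "TYR268:CZ", "RET:C20")
        assert d1 == d2 == pytest.approx(4.4, abs=1e-3)


class TestContacts:
    def test_tiny_cutoff_empty(self, pocket_model):
        assert enumerate_contacts(pocket_model, "RET:C20", "TYR:CZ", 0.5) == []

    def test_equals_brute_force_all_pairs_oracle(self):
        spec = [("TYR1:CZ", "GLY1:CA", 3.0), ("TYR2:CZ", "GLY2:CA", 5.5),
                ("TYR3:CZ", "GLY3:CA", 6.4)]
        m = CoordinateModel(generate_toy_structure(spec), source="bf")
        tyr = [(r, a) for r in m.chain for a in r if r.name == "TYR" and a.name == "CZ"]
        gly = [(r, a) for r in m.chain for a in r if r.name == "GLY" and a.name == "CA"]
        expected = set()
        for rt, at in tyr:
            for rg, ag in gly:
                d = np.linalg.norm(
                    np.array([at.pos.x, at.pos.y, at.pos.z])
                    - np.array([ag.pos.x, ag.pos.y, ag.pos.z]))
                if d <= 6.0:
                    expected.add((rt.seqid.num, rg.seqid.num, round(float(d), 3)))
        got = {(int(c.selector_a[3:].split(":")[0]),
                int(c.selector_b[3:].split(":")[0]),
                round(c.distance, 3))
               for c in enumerate_contacts(m, "TYR:CZ", "GLY:CA", 6.0)}
        assert got == expected

    def test_sorted_by_distance_without_duplicates(self):
        spec = [("TYR1:CZ", "GLY1:CA", 3.0), ("TYR2:CZ", "GLY2:CA", 5.5)]
        m = CoordinateModel(generate_toy_structure(spec), source="s")
        contacts = enumerate_contacts(m, "TYR:CZ", "GLY:CA", 6.0)
        dists = [c.distance for c in contacts]
        assert dists == sorted(dists)
        assert len({(c.selector_a, c.selector_b) for c in contacts}) == len(contacts)

    def test_empty_class_warns(self, pocket_model):
        with pytest.warns(UserWarning, match="empty selector class"):
            assert enumerate_contacts(pocket_model, "TRP:CZ2", "TYR:CZ", 6.0) == []


class TestRestraints:
    def test_estimate_kinds_map_to_restraint_kinds(self):
        estimates = [
            DistanceEstimate("C12-Tyr268", 5.6, 0.3, "estimated"),
            DistanceEstimate("C19-Tyr268", None, 0.0, "absent"),
            DistanceEstimate("C18-Tyr191", None, 0.0, "upper_bound_only",
                             detection_limit=6.5),
        ]
        mapping = {"C12-Tyr268": ("RET:C12", "TYR268:CZ"),
                   "C19-Tyr268": ("RET:C19", "TYR268:CZ"),
                   "C18-Tyr191": ("RET:C18", "TYR191:CZ")}
        rset = restraints_from_estimates(estimates, mapping)
        kinds = {r.label: r.kind for r in rset}
        assert kinds == {"C12-Tyr268": "POSITIVE", "C19-Tyr268": "ABSENT",
                         "C18-Tyr191": "UPPER"}
        limits = {r.label: r.limit for r in rset}
        assert limits["C19-Tyr268"] == 6.0 and limits["C18-Tyr191"] == 6.5

    def test_unmapped_pair_rejected(self):
        with pytest.raises(KeyError):
            restraints_from_estimates(
                [DistanceEstimate("x", 5.0, 0.1, "estimated")], {})

    def test_empty_estimates_give_empty_set(self):
        assert len(restraints_from_estimates([], {})) == 0

    def test_tsv_round_trip(self, tmp_path, metaii_restraints):
        path = tmp_path / "r.tsv"
        metaii_restraints.to_tsv(path)
        back = RestraintSet.from_tsv(path)
        assert [(r.label, r.kind, r.r, r.sigma, r.limit) for r in back] == \
            [(r.label, r.kind, r.r, r.sigma, r.limit) for r in metaii_restraints]


class TestScoring:
    def test_fully_consistent_model_scores_one(self, pocket_model, metaii_restraints):
        sc = score_model(pocket_model, metaii_restraints)
        assert sc.score == 1.0 and sc.violations == []

    def test_one_violated_restraint_lowers_score_by_one_over_n(self, pocket_model):
        rset = RestraintSet([
            Restraint("C20-Tyr268", "POSITIVE", "RET:C20", "TYR268:CZ",
                      r=4.4, sigma=0.3),
            Restraint("C12-Tyr268", "POSITIVE", "RET:C12", "TYR268:CZ",
                      r=2.0, sigma=0.1),  # model has 5.6 -> 36 sigma away
        ])
        sc = score_model(pocket_model, rset)
        assert sc.score == pytest.approx(0.5)
        assert sc.violations == ["C12-Tyr268"]

    def test_crystal_orientation_violates_the_measured_c12_distance(self):
        crystal = CoordinateModel(
            generate_toy_structure([("RET:C12", "TYR268:CZ", 3.9),
                                    ("RET:C20", "TYR268:CZ", 5.9)]),
            source="crystal")
        rset = RestraintSet([Restraint("C12-Tyr268", "POSITIVE", "RET:C12",
                                       "TYR268:CZ", r=5.6, sigma=0.3)])
        sc = score_model(crystal, rset)
        assert sc.violations == ["C12-Tyr268"]

    def test_unresolvable_restraint_excluded_from_denominator(self, pocket_model,
                                                              metaii_restraints):
        rset = RestraintSet(list(metaii_restraints)
                            + [Restraint("ghost", "POSITIVE", "PHE261:CZ",
                                         "RET:C18", r=5.0, sigma=0.3)])
        with pytest.warns(UserWarning, match="ghost"):
            sc = score_model(pocket_model, rset)
        assert sc.unevaluable == ["ghost"]
        assert sc.score == 1.0

    def test_score_invariant_under_rigid_motion(self, pocket_model,
                                                metaii_restraints):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = pocket_model.transformed(rot, np.array([10.0, -5.0, 3.0]))
        a = score_model(pocket_model, metaii_restraints)
        b = score_model(moved, metaii_restraints)
        assert a.score == b.score
        assert a.violations == b.violations


class TestDiscrimination:
    def test_nmr_orientation_beats_crystal_orientation(self, metaii_restraints):
        """Against the measured Meta-II restraints (C20 closer to Tyr268 than
        C12, C19 crosspeak lost) the NMR-derived orientation outranks the
        crystallographic one."""
        models = {
            "nmr": CoordinateModel(generate_toy_structure(POCKET), source="nmr"),
            "crystal": CoordinateModel(
                generate_toy_structure([("RET:C12", "TYR268:CZ", 3.9),
                                        ("RET:C20", "TYR268:CZ", 5.9),
                                        ("RET:C19", "TYR268:CZ", 4.3)]),
                source="crystal"),
        }
        result = discriminate_models(models, metaii_restraints)
        assert result["best"] == "nmr"
        assert result["ranking"] == ["nmr", "crystal"]
        assert result["ties"] == []

    def test_identical_models_reported_as_tie(self, metaii_restraints):
        models = {
            "a": CoordinateModel(generate_toy_structure(POCKET), source="a"),
            "b": CoordinateModel(generate_toy_structure(POCKET), source="b"),
        }
        result = discriminate_models(models, metaii_restraints)
        assert ["a", "b"] in result["ties"] or ["b", "a"] in result["ties"]

    def test_needs_two_models(self, pocket_model, metaii_restraints):
        with pytest.raises(ValueError):
            discriminate_models({"only": pocket_model}, metaii_restraints)
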
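"""Scalar descriptors: distances, piston, dihedrals, H-bond classes."""

import numpy as np
import pytest

from helicoil import (
    DimerSpec,
    HelixSpec,
    ProtomerMap,
    SegmentDef,
    backbone_hbond_pattern,
    build_dimer,
    build_ideal_helix,
    classify_alpha,
    cross_protomer_distance_profile,
    intra_protomer_ca_distance,
    linker_state,
    phi_psi,
    piston_shift,
)
from helicoil.descriptors import HBondPattern
from helicoil.errors import SelectionError
from helicoil.helix_geometry import Line
from helicoil.structures_io import ResidueRecord, StructureModel
from helicoil.synthetic_data import build_chain_from_dihedrals
from tests.conftest import random_rigid

Z = Line([0, 0, 0], [0, 0, 1])


def _toy_model(points_by_chain):
    chains = {
        cid: [
            ResidueRecord(cid, num, "ALA", {"CA": np.asarray(xyz, float)})
            for num, xyz in residues.items()
        ]
        for cid, residues in points_by_chain.items()
    }
    return StructureModel(chains)


class TestDistances:
    def test_three_four_five(self):
        model = _toy_model({"A": {50: (0, 0, 0), 133: (3, 4, 0)}, "B": {50: (9, 9, 9), 133: (9, 9, 14)}})
        pm = ProtomerMap("A", "B")
        assert intra_protomer_ca_distance(model, pm, "A") == pytest.approx(5.0)
        assert intra_protomer_ca_distance(model, pm, "B") == pytest.approx(5.0)
        with pytest.raises(SelectionError):
            intra_protomer_ca_distance(model, pm, "A", 50, 999)

    def test_symmetric_dimer_protomers_agree(self, free_dimer, protomer_map):
        model, _ = free_dimer
        dA = intra_protomer_ca_distance(model, protomer_map, "A")
        dB = intra_protomer_ca_distance(model, protomer_map, "B")
        assert abs(dA - dB) <= 1e-6

    def test_generator_contact_distance_is_honored(self, protomer_map):
        model, gt = build_dimer(DimerSpec(contact_distance_A=7.1))
        assert intra_protomer_ca_distance(model, protomer_map, "A") == pytest.approx(7.1, abs=0.01)
        assert gt.contact_distance_A == pytest.approx(7.1, abs=0.01)


class TestCrossProfile:
    def test_axis_separation_recovered_for_on_axis_points(self):
        model = _toy_model(
            {"A": {1: (5, 0, 0), 2: (5, 0, 1.5)}, "B": {1: (-5, 0, 0), 2: (-5, 0, 1.5)}}
        )
        prof = cross_protomer_distance_profile(model, ProtomerMap("A", "B"), [1, 2])
        np.testing.assert_allclose(prof.values, 10.0)

    def test_missing_residue_flagged_not_fatal(self):
        model = _toy_model({"A": {1: (5, 0, 0)}, "B": {1: (-5, 0, 0)}})
        prof = cross_protomer_distance_profile(model, ProtomerMap("A", "B"), [1, 2])
        assert prof.values[0] == pytest.approx(10.0)
        assert np.isnan(prof.values[1])

    def test_scissor_changes_profile_endpoints_and_trend(self, free_dimer, protomer_map):
        model0, _ = free_dimer
        scissored, _ = build_dimer(DimerSpec(scissor_h1_tip_A=-2.0, scissor_h4_tip_A=2.0))
        h1 = list(range(34, 51))
        h4 = list(range(133, 148))
        d_h1 = (
            cross_protomer_distance_profile(scissored, protomer_map, h1).values
            - cross_protomer_distance_profile(model0, protomer_map, h1).values
        )
        d_h4 = (
            cross_protomer_distance_profile(scissored, protomer_map, h4).values
            - cross_protomer_distance_profile(model0, protomer_map, h4).values
        )
        assert d_h1[0] == pytest.approx(-2.0, abs=0.1)  # H1 tips closer at residue 34
        assert d_h4[-1] == pytest.approx(2.0, abs=0.1)  # H4 tips apart at residue 147
        # the change grows toward the membrane-proximal end (trend, not
        # per-residue monotonicity: helical phase modulates each residue)
        assert np.polyfit(h1, d_h1, 1)[0] > 0  # toward zero going 34 -> 50
        assert np.polyfit(h4, d_h4, 1)[0] > 0  # growing toward 147

    def test_rigid_rotation_leaves_profile_unchanged(self, free_dimer, protomer_map):
        model, _ = free_dimer
        rng = np.random.default_rng(9)
        R, t = random_rigid(rng)
        resnums = list(range(34, 51))
        a = cross_protomer_distance_profile(model, protomer_map, resnums).values
        b = cross_protomer_distance_profile(model.transformed(R, t), protomer_map, resnums).values
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestPistonShift:
    def test_same_span_is_zero_and_axis_flip_changes_sign(self):
        model = _toy_model(
            {"A": {i: (5, 0, float(i)) for i in range(1, 6)},
             "B": {i: (-5, 0, float(i)) for i in range(1, 6)}}
        )
        s1 = SegmentDef("custom", "A", 1, 5)
        s2 = SegmentDef("custom", "B", 1, 5)
        assert piston_shift(model, s1, s2, Z) == pytest.approx(0.0, abs=1e-12)
        model2 = _toy_model(
            {"A": {i: (5, 0, float(i) + 3.0) for i in range(1, 6)},
             "B": {i: (-5, 0, float(i)) for i in range(1, 6)}}
        )
        up = piston_shift(model2, s1, s2, Z)
        down = piston_shift(model2, s1, s2, Line([0, 0, 0], [0, 0, -1]))
        assert up == pytest.approx(3.0, abs=1e-12)
        assert down == pytest.approx(-3.0, abs=1e-12)

    def test_generator_piston_recovery_and_additivity(self, protomer_map):
        def tm_piston(model):
            tm1 = [SegmentDef("TM1", c, 14, 34) for c in "AB"]
            tm2 = [SegmentDef("TM2", c, 147, 167) for c in "AB"]
            return piston_shift(model, tm1, tm2, Z)

        base, _ = build_dimer(DimerSpec())
        p3, _ = build_dimer(DimerSpec(piston_tm1_z_A=3.0, piston_h1_z_A=3.0))
        assert tm_piston(p3) - tm_piston(base) == pytest.approx(3.0, abs=0.01)
        # additivity: a then b along z equals a+b
        a_then_b, _ = build_dimer(DimerSpec(piston_tm1_z_A=1.2 + 0.8, piston_h1_z_A=2.0))
        pa, _ = build_dimer(DimerSpec(piston_tm1_z_A=1.2, piston_h1_z_A=1.2))
        pb_shift = tm_piston(a_then_b) - tm_piston(pa)
        assert pb_shift == pytest.approx(0.8, abs=1e-6)

    def test_rigid_motion_invariance_with_transformed_axis(self, free_dimer):
        model, _ = free_dimer
        tm1 = [SegmentDef("TM1", c, 14, 34) for c in "AB"]
        tm2 = [SegmentDef("TM2", c, 147, 167) for c in "AB"]
        base = piston_shift(model, tm1, tm2, Z)
        rng = np.random.default_rng(21)
        R, t = random_rigid(rng)
        moved_axis = Line(R @ Z.point + t, R @ Z.direction)
        assert piston_shift(model.transformed(R, t), tm1, tm2, moved_axis) == pytest.approx(
            base, abs=1e-6
        )


class TestDihedrals:
    def test_alpha_helix_dihedrals_match_spec(self, ideal_helix):
        phi, psi = phi_psi(ideal_helix, "A", 6)
        assert phi == pytest.approx(-57.0, abs=0.5)
        assert psi == pytest.approx(-47.0, abs=0.5)

    def test_extended_strand_recovered(self):
        strand = build_chain_from_dihedrals([-135.0] * 6, [135.0] * 6)
        phi, psi = phi_psi(strand, "A", 3)
        assert phi == pytest.approx(-135.0, abs=0.5)
        assert psi == pytest.approx(135.0, abs=0.5)

    def test_chain_terminus_flagged(self, ideal_helix):
        phi, psi = phi_psi(ideal_helix, "A", 1)
        assert phi is None and psi is not None
        phi, psi = phi_psi(ideal_helix, "A", 14)
        assert psi is None

    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-57.0, -47.0, "helical"),
            (-135.0, 135.0, "disordered"),
            (-120.0, -5.0, "helical"),  # closed-interval boundary
            (-121.0, -5.0, "disordered"),
            (None, -47.0, "unknown"),
        ],
    )
    def test_classify_alpha(self, phi, psi, expected):
        assert classify_alpha(phi, psi) == expected

    def test_linker_state_classification(self):
        helical, _ = build_dimer(DimerSpec())
        broken, _ = build_dimer(DimerSpec(linker_state="broken"))
        state_h, per_h = linker_state(helical, "A")
        state_b, per_b = linker_state(broken, "A")
        assert state_h == "helical" and all(v == "helical" for v in per_h.values())
        assert state_b == "broken"
        assert all(per_b[r] == "disordered" for r in range(34, 38))


class TestHbonds:
    def test_alpha_helix_has_only_i4_bonds(self, ideal_helix):
        for num in range(2, 9):
            classes = [b.hbond_class for b in backbone_hbond_pattern(ideal_helix, "A", num)]
            assert classes == ["alpha"]

    def test_three_ten_helix_has_only_i3_bonds(self):
        h310 = build_ideal_helix(
            HelixSpec(n_residues=12, twist_deg=120.0, rise=2.0, radius=1.9, phi=-49.0, psi=-26.0)
        )
        for num in range(2, 8):
            classes = [b.hbond_class for b in backbone_hbond_pattern(h310, "A", num)]
            assert classes == ["three_ten"]

    def test_distant_pair_is_no_bond(self):
        model = _toy_model({"A": {1: (0, 0, 0)}})
        model.chains["A"][0].atoms["O"] = np.array([0.0, 0.0, 0.0])
        model.chains["A"].append(
            ResidueRecord("A", 4, "ALA", {"CA": (5, 5, 5), "N": (5.0, 0.0, 0.0)})
        )
        assert backbone_hbond_pattern(model, "A", 1) == []

    def test_missing_oxygen_disables_pair(self, ideal_helix):
        model = ideal_helix.copy()
        del model.residue("A", 5).atoms["O"]
        assert backbone_hbond_pattern(model, "A", 5) == []

    def test_class_must_match_offset(self):
        with pytest.raises(SelectionError):
            HBondPattern(10, 14, 2.9, "three_ten")
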
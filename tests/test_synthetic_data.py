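"""Generator ground truth: geometry, determinism, noise, recovery chain."""

import numpy as np
import pytest

from helicoil import (
    DimerSpec,
    HelixSpec,
    ProtomerMap,
    SegmentDef,
    TwoStateTrajectorySpec,
    build_dimer,
    build_ideal_helix,
    cross_protomer_distance_profile,
    intra_protomer_ca_distance,
    linker_state,
    make_trajectory,
    piston_shift,
    read_structure,
    write_structure,
)
from helicoil.errors import ClashError, FormatError
from helicoil.helix_geometry import Line
from tests.conftest import mean_h1_crick_shift

Z = Line([0, 0, 0], [0, 0, 1])


class TestIdealHelix:
    def test_ca_spacing_is_canonical(self, ideal_helix):
        ca = np.array([r.atoms["CA"] for r in ideal_helix.chains["A"]])
        spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 3.80, atol=0.05)

    def test_azimuth_periodicity_for_three_residue_turn(self):
        h = build_ideal_helix(HelixSpec(n_residues=10, twist_deg=120.0, rise=2.0))
        ca = np.array([r.atoms["CA"] for r in h.chains["A"]])
        az = np.degrees(np.arctan2(ca[:, 1], ca[:, 0]))
        for i in range(len(az) - 3):
            delta = (az[i + 3] - az[i] + 180.0) % 360.0 - 180.0
            assert abs(delta) <= 0.5

    def test_backbone_dihedrals_self_consistent(self, ideal_helix):
        from helicoil import phi_psi

        for num in range(3, 12):
            phi, psi = phi_psi(ideal_helix, "A", num)
            assert phi == pytest.approx(-57.0, abs=0.5)
            assert psi == pytest.approx(-47.0, abs=0.5)

    def test_spec_validation(self):
        with pytest.raises(FormatError):
            HelixSpec(rise=-1.0)
        with pytest.raises(FormatError):
            HelixSpec(twist_deg=200.0)


class TestBuildDimer:
    def test_zero_state_is_exactly_c2_symmetric(self, free_dimer, protomer_map):
        model, _ = free_dimer
        for resnums in (range(34, 51), range(133, 148)):
            prof = cross_protomer_distance_profile(model, protomer_map, list(resnums))
            # C2: swapping protomers leaves every cross distance unchanged
            swapped = cross_protomer_distance_profile(
                model, ProtomerMap("B", "A"), list(resnums)
            )
            np.testing.assert_allclose(prof.values, swapped.values, atol=1e-6)
        dA = intra_protomer_ca_distance(model, protomer_map, "A")
        dB = intra_protomer_ca_distance(model, protomer_map, "B")
        assert abs(dA - dB) <= 1e-6

    def test_piston_parameter_is_recovered_exactly(self):
        def tm_piston(m):
            tm1 = [SegmentDef("TM1", c, 14, 34) for c in "AB"]
            tm2 = [SegmentDef("TM2", c, 147, 167) for c in "AB"]
            return piston_shift(m, tm1, tm2, Z)

        base, _ = build_dimer(DimerSpec())
        moved, _ = build_dimer(DimerSpec(piston_tm1_z_A=3.0, piston_h1_z_A=3.0))
        assert tm_piston(moved) - tm_piston(base) == pytest.approx(3.0, abs=0.01)

    def test_linker_states_by_construction(self):
        broken, _ = build_dimer(DimerSpec(linker_state="broken"))
        helical, _ = build_dimer(DimerSpec())
        for chain in "AB":
            state_b, per_b = linker_state(broken, chain)
            assert state_b == "broken"
            assert sum(v == "disordered" for v in per_b.values()) >= 1
            state_h, per_h = linker_state(helical, chain)
            assert state_h == "helical" and all(v == "helical" for v in per_h.values())

    def test_clashing_geometry_raises(self):
        with pytest.raises(FormatError):
            build_dimer(DimerSpec(core_radius_A=4.0))  # fails the 2x radius bound
        with pytest.raises(ClashError):
            # fold the H1 tips far past each other
            build_dimer(DimerSpec(core_radius_A=4.7, scissor_h1_tip_A=-9.0))

    def test_generated_file_round_trips_through_io(self, tmp_path, free_dimer):
        model, _ = free_dimer
        path = tmp_path / "dimer.pdb"
        write_structure(model, path)
        reread = read_structure(path)
        for cid, resnum, name, xyz in model.all_atoms():
            assert np.abs(reread.residue(cid, resnum).atoms[name] - xyz).max() <= 1e-3


class TestFullRecoveryChain:
    """At sigma=0 the pipeline recovers every imposed state parameter."""

    def test_rotation_piston_scissor_linker(self, free_dimer, protomer_map):
        base, _ = free_dimer
        spec = DimerSpec(
            h1_rotation_deg=26.0,
            piston_tm1_z_A=3.0,
            piston_h1_z_A=3.0,
            scissor_h1_tip_A=-2.0,
            scissor_h4_tip_A=2.0,
            linker_state="broken",
        )
        model, _ = build_dimer(spec)
        # rotation via Crick angles
        rot = mean_h1_crick_shift(base, model)
        assert rot == pytest.approx(26.0, abs=2.0)
        # piston via COM projections
        tm1 = [SegmentDef("TM1", c, 14, 34) for c in "AB"]
        tm2 = [SegmentDef("TM2", c, 147, 167) for c in "AB"]
        dp = piston_shift(model, tm1, tm2, Z) - piston_shift(base, tm1, tm2, Z)
        # scissor tilts displace TM1 slightly along z as well; the piston
        # parameter itself is recovered once that is accounted for, and the
        # piston-only case is exact (test above); here allow the tilt term
        assert dp == pytest.approx(3.0, abs=0.1)
        # scissor via profile endpoints
        h1 = list(range(34, 51))
        h4 = list(range(133, 148))
        dh1 = (
            cross_protomer_distance_profile(model, protomer_map, h1).values[0]
            - cross_protomer_distance_profile(base, protomer_map, h1).values[0]
        )
        dh4 = (
            cross_protomer_distance_profile(model, protomer_map, h4).values[-1]
            - cross_protomer_distance_profile(base, protomer_map, h4).values[-1]
        )
        assert dh1 == pytest.approx(-2.0, abs=0.1)
        assert dh4 == pytest.approx(2.0, abs=0.1)
        # linker state exact
        assert linker_state(model, "A")[0] == "broken"
        assert linker_state(base, "A")[0] == "helical"

    def test_rotation_does_not_move_helix_axes(self, free_dimer):
        """Helical rotation is not scissoring: the fitted H1 axis positions
        are unchanged when H1 spins about its own axis."""
        from helicoil.helix_geometry import fit_local_axis

        base, _ = free_dimer
        rotated, _ = build_dimer(DimerSpec(h1_rotation_deg=26.0))
        seg = SegmentDef("H1", "A", 39, 60)
        a0 = fit_local_axis(seg.ca_coords(base), resnums=list(seg.resnums))
        a1 = fit_local_axis(seg.ca_coords(rotated), resnums=list(seg.resnums))
        np.testing.assert_allclose(a0.points, a1.points, atol=1e-6)


class TestMakeTrajectory:
    def _spec(self, **kw):
        params = dict(
            state_a=DimerSpec(linker_state="broken", h1_rotation_deg=20.0),
            state_b=DimerSpec(),
            n_frames=40,
            frame_dt_ns=10.0,
            switch_fraction=0.5,
            noise_sigma_A=0.0,
            seed=0,
        )
        params.update(kw)
        return TwoStateTrajectorySpec(**params)

    def test_noiseless_switch_partitions_frames_exactly(self):
        traj, labels = make_trajectory(self._spec())
        assert labels.count("A") == 20 and labels.count("B") == 20
        ref_a = traj.frames[0].ca("A", 50)
        ref_b = traj.frames[-1].ca("A", 50)
        for frame, label in zip(traj, labels):
            expected = ref_a if label == "A" else ref_b
            np.testing.assert_allclose(frame.ca("A", 50), expected, atol=1e-12)

    def test_same_seed_bit_identical_different_seed_not(self):
        t1, _ = make_trajectory(self._spec(noise_sigma_A=0.3, seed=4))
        t2, _ = make_trajectory(self._spec(noise_sigma_A=0.3, seed=4))
        t3, _ = make_trajectory(self._spec(noise_sigma_A=0.3, seed=5))
        a = np.array([f.ca("A", 50) for f in t1])
        b = np.array([f.ca("A", 50) for f in t2])
        c = np.array([f.ca("A", 50) for f in t3])
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_noise_propagated_distance_sd_matches_monte_carlo(self, protomer_map):
        sigma = 0.3
        spec = self._spec(
            state_a=DimerSpec(contact_distance_A=7.1),
            state_b=DimerSpec(contact_distance_A=7.8),
            n_frames=400,
            frame_dt_ns=1.0,
            noise_sigma_A=sigma,
            seed=3,
        )
        traj, _ = make_trajectory(spec)
        dists = np.array(
            [intra_protomer_ca_distance(f, protomer_map, "A") for f in traj]
        )
        # brute-force oracle: same noise process on two fixed points
        rng = np.random.default_rng(123)
        p, q = np.zeros(3), np.array([7.1, 0.0, 0.0])
        mc = np.linalg.norm(
            (p + rng.normal(0, sigma, (10_000, 3))) - (q + rng.normal(0, sigma, (10_000, 3))),
            axis=1,
        )
        sample_sd = dists[:200].std(ddof=1)
        assert sample_sd == pytest.approx(mc.std(ddof=1), rel=0.10)

    def test_recovery_degrades_gracefully_with_noise(self, free_dimer):
        """Aggregated rotation-recovery error is non-decreasing in sigma."""
        errors = []
        for sigma in (0.0, 0.1, 0.3, 0.5):
            spec = self._spec(
                state_a=DimerSpec(),
                state_b=DimerSpec(h1_rotation_deg=26.0),
                n_frames=12,
                noise_sigma_A=sigma,
                seed=17,
            )
            traj, _ = make_trajectory(spec)
            errs = []
            for i in range(6):
                shift = mean_h1_crick_shift(traj.frames[i], traj.frames[6 + i])
                errs.append(abs(shift - 26.0))
            errors.append(np.mean(errs))
        assert errors[0] <= 1e-6
        assert all(a <= b + 0.5 for a, b in zip(errors, errors[1:]))

    def test_switch_fraction_validation(self):
        with pytest.raises(FormatError):
            self._spec(switch_fraction=0.0)
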
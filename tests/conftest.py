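"""Shared fixtures: synthetic structures with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from helicoil import (
    AnalysisConfig,
    DimerSpec,
    HelixSpec,
    ProtomerMap,
    SegmentDef,
    build_dimer,
    build_ideal_helix,
)
from helicoil.crick import circular_difference, circular_mean, crick_angles_model
from helicoil.helix_geometry import bundle_axis, fit_local_axis


@pytest.fixture(scope="session")
def ideal_helix():
    """14-residue ideal alpha-helix with default (canonical) parameters."""
    return build_ideal_helix(HelixSpec(n_residues=14))


@pytest.fixture(scope="session")
def protomer_map():
    return ProtomerMap("A", "B")


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def free_dimer():
    """Zero-state reference dimer (all state parameters zero, linker helical)."""
    model, gt = build_dimer(DimerSpec())
    return model, gt


def parametric_helix(n=14, radius=2.3, twist=100.0, rise=1.5, phase=0.0, center=(0.0, 0.0)):
    """Bare CA cylinder trace computed directly (independent of the package
    generator) for axis-fit and Crick oracles."""
    t = np.arange(n)
    ang = np.radians(phase + twist * t)
    return np.c_[
        center[0] + radius * np.cos(ang),
        center[1] + radius * np.sin(ang),
        rise * t,
    ]


def random_rigid(rng):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def recovered_rotation(delta_deg, sigma, seed, n_frames=24):
    """Recover an imposed H1 rotation from a noisy two-state trajectory as
    the circular-mean Crick-angle change between the two state windows."""
    from helicoil import ProtomerMap, TwoStateTrajectorySpec, make_trajectory
    from helicoil.crick import crick_series

    spec = TwoStateTrajectorySpec(
        state_a=DimerSpec(),
        state_b=DimerSpec(h1_rotation_deg=delta_deg),
        n_frames=n_frames,
        frame_dt_ns=1.0,
        noise_sigma_A=sigma,
        seed=seed,
    )
    traj, labels = make_trajectory(spec)
    half = labels.count("A")
    segs = [SegmentDef("H1", c, 39, 60) for c in "AB"] + [
        SegmentDef("H4", c, 120, 146) for c in "AB"
    ]
    series = crick_series(
        traj,
        SegmentDef("H1", "A", 39, 60),
        range(41, 59),
        ProtomerMap("A", "B"),
        bundle_segments=segs,
        orient=[0.0, 0.0, 1.0],
    )
    diffs = []
    for s in series.values():
        for j in range(s.angles.shape[1]):
            a = circular_mean(s.angles[:half, j])
            b = circular_mean(s.angles[half:, j])
            diffs.append(circular_difference(b, a))
    return circular_mean(np.asarray(diffs))


def mean_h1_crick_shift(model_ref, model_rot, resnums=range(41, 59)):
    """Circular-mean Crick-angle change of membrane-proximal H1 residues
    between two dimers, averaged over both protomers."""
    segs = [SegmentDef("H1", c, 39, 60) for c in "AB"] + [
        SegmentDef("H4", c, 120, 146) for c in "AB"
    ]
    diffs = []
    for chain in "AB":
        per_model = []
        for model in (model_ref, model_rot):
            axes = [fit_local_axis(s.ca_coords(model), resnums=list(s.resnums)) for s in segs]
            bundle = bundle_axis(axes, orient=[0.0, 0.0, 1.0])
            per_model.append(
                crick_angles_model(model, SegmentDef("H1", chain, 39, 60), resnums, bundle)
            )
        diffs.extend(
            circular_difference(per_model[1][r], per_model[0][r]) for r in resnums
        )
    return circular_mean(np.asarray(diffs))
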
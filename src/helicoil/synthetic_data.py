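"""Synthetic helices, four-helix transmembrane-like dimers and trajectories.

Every recovery test in the package rests on this module: it builds ideal
alpha-helices with exactly prescribed CA cylinder geometry (rise, twist,
radius), assembles C2-symmetric dimers in which helical rotation, diagonal
scissoring, piston offsets and a sensor-TM linker break are imposed with
known magnitudes, and produces seeded two-state pseudo-trajectories with
i.i.d. Gaussian coordinate noise.  No physics is simulated; the point is a
ground truth that the descriptor pipeline must recover.

Construction notes
------------------
CA atoms are placed exactly on the requested cylinder.  The N/C/O positions
of one residue are solved by weighted least squares so that replicating
them with the helix screw operation reproduces standard backbone bond
lengths/angles and the requested (phi, psi, omega=180) torsions as closely
as the cylinder allows; torsions carry the largest weights, so measured
phi/psi match the spec to a fraction of a degree for canonical parameters.
Non-helical pieces (the broken linker, strand fixtures) are built by
NeRF-style internal-coordinate chain extension.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.spatial.transform import Rotation

from .errors import ClashError, FormatError
from .structures_io import (
    DEFAULT_SEGMENT_RANGES,
    ResidueRecord,
    StructureModel,
    Trajectory,
)

# Ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0

#: Residue ranges of the two helical arms each protomer contributes:
#: arm 1 = TM1 + linker + membrane-proximal H1, arm 2 = H4 + TM2.
ARM1_RANGE = (14, 60)
ARM2_RANGE = (120, 167)
LINKER_RANGE = DEFAULT_SEGMENT_RANGES["linker"]

#: Residue pair whose z levels are matched across the two antiparallel arms
#: (the contact pair of the intra-protomer distance descriptor).
CONTACT_RES_ARM1 = 50
CONTACT_RES_ARM2 = 133

MIN_INTERCHAIN_CA_A = 2.0


# ---------------------------------------------------------------------------
# Internal-coordinate (NeRF) backbone construction
# ---------------------------------------------------------------------------


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d with |cd|=bond, angle(b,c,d) and torsion(a,b,c,d)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _carbonyl_oxygen(ca, c, n_next) -> np.ndarray:
    """O on the C sp2 plane, opposite the CA/N-next bisector."""
    u = ca - c
    u /= np.linalg.norm(u)
    v = n_next - c
    v /= np.linalg.norm(v)
    w = -(u + v)
    w /= np.linalg.norm(w)
    return c + BOND_C_O * w


def build_chain_from_dihedrals(
    phis: Sequence[float],
    psis: Sequence[float],
    omega: float = OMEGA_TRANS,
    chain_id: str = "A",
    start_resnum: int = 1,
    resname: str = "ALA",
) -> StructureModel:
    """Backbone chain from per-residue (phi, psi); phis[0] is ignored.

    Used for non-helical fixtures (extended strands, broken linkers) where
    the conformation is specified by torsions rather than a cylinder.
    """
    n = len(phis)
    if n != len(psis) or n < 2:
        raise FormatError("need equal-length phi/psi lists with >= 2 residues")
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psis[i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega))
        C.append(place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phis[i]))
    n_virtual = place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psis[-1])
    residues = []
    for i in range(n):
        nn = N[i + 1] if i + 1 < n else n_virtual
        residues.append(
            ResidueRecord(
                chain_id,
                start_resnum + i,
                resname,
                {"N": N[i], "CA": CA[i], "C": C[i], "O": _carbonyl_oxygen(CA[i], C[i], nn)},
            )
        )
    return StructureModel({chain_id: residues}, label="dihedral-chain")


# ---------------------------------------------------------------------------
# Screw-symmetric helix template
# ---------------------------------------------------------------------------


def _rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def _torsion(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return math.degrees(math.atan2(np.cross(b1n, v) @ w, v @ w))


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@lru_cache(maxsize=32)
def _helix_template(
    rise: float, twist_deg: float, radius: float, phi: float, psi: float
) -> tuple[tuple[float, ...], ...]:
    """Per-residue backbone offsets (N, CA, C, O) with CA at (radius, 0, 0).

    Replicating the template with the screw (rotate ``twist_deg`` about z,
    translate ``rise`` along z) generates the helix.  The N and C positions
    are refined so torsions hit (phi, psi, 180) and bonds/angles stay ideal.
    """
    S = _rot_z(twist_deg)
    shift = np.array([0.0, 0.0, rise])
    ca0 = np.array([radius, 0.0, 0.0])

    # initial guess from a NeRF chain with uniform (phi, psi), re-expressed
    # in the cylinder frame of its own CA trace
    from .helix_geometry import fit_local_axis  # local import; no cycle at runtime

    ref = build_chain_from_dihedrals([phi] * 9, [psi] * 9)
    res = ref.chains["A"]
    cas = np.array([r.atoms["CA"] for r in res])
    axis = fit_local_axis(cas)
    origin = axis.points.mean(axis=0)
    zdir = axis.mean_direction()
    mid = 4
    radial = cas[mid] - origin
    radial = radial - (radial @ zdir) * zdir
    r_nat = np.linalg.norm(radial)
    xdir = radial / r_nat
    ydir = np.cross(zdir, xdir)
    basis = np.vstack([xdir, ydir, zdir])

    def to_frame(p):
        q = basis @ (p - origin)
        q[2] -= (basis @ (cas[mid] - origin))[2]
        q[0] += radius - r_nat
        return q

    x0 = np.concatenate([to_frame(res[mid].atoms["N"]), to_frame(res[mid].atoms["C"])])

    def residuals(x):
        nat, cat = x[:3], x[3:]
        n1 = S @ nat + shift
        ca1 = S @ ca0 + shift
        c_prev = np.linalg.inv(S) @ (cat - shift)
        r = [
            5.0 * (np.linalg.norm(nat - ca0) - BOND_N_CA),
            5.0 * (np.linalg.norm(cat - ca0) - BOND_CA_C),
            5.0 * (np.linalg.norm(n1 - cat) - BOND_C_N),
            2.0 * math.radians(_angle(nat, ca0, cat) - ANGLE_N_CA_C),
            2.0 * math.radians(_angle(ca0, cat, n1) - ANGLE_CA_C_N),
            2.0 * math.radians(_angle(cat, n1, ca1) - ANGLE_C_N_CA),
            10.0 * math.radians(_wrap(_torsion(c_prev, nat, ca0, cat) - phi)),
            10.0 * math.radians(_wrap(_torsion(nat, ca0, cat, n1) - psi)),
            10.0 * math.radians(_wrap(_torsion(ca0, cat, n1, ca1) - OMEGA_TRANS)),
        ]
        return r

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    nat, cat = sol.x[:3], sol.x[3:]
    n1 = S @ nat + shift
    o0 = _carbonyl_oxygen(ca0, cat, n1)
    return tuple(tuple(p) for p in (nat, ca0, cat, o0))


def _wrap(deg: float) -> float:
    return -((-deg + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class HelixSpec:
    """Geometry of one ideal helix; defaults are canonical alpha values."""

    n_residues: int = 18
    rise: float = 1.5  # A per residue
    twist_deg: float = 100.0  # degrees per residue (3.6 residues/turn)
    radius: float = 2.3  # CA cylinder radius, A
    start_phase_deg: float = 0.0
    phi: float = -57.0
    psi: float = -47.0
    start_resnum: int = 1
    chain_id: str = "A"
    resname: str = "ALA"
    start_z: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise FormatError("helix needs >= 2 residues")
        if self.rise <= 0:
            raise FormatError("rise must be positive")
        if not 0.0 < self.twist_deg < 180.0:
            raise FormatError("twist must be in (0, 180) degrees")


@dataclass
class DimerSpec:
    """A four-helix TM-like C2 dimer with imposed state parameters.

    State parameters (all relative to the ideal symmetric construction):

    h1_rotation_deg
        rotation of the H1 residues about their own helix axis (helical
        rotation readout; positive right-handed about the N->C direction).
    piston_tm1_z_A / piston_h1_z_A
        axial (+z periplasmic) translation of the TM1 / H1 residues; the
        linker residues are translated with a linear ramp between the two.
    scissor_h1_tip_A / scissor_h4_tip_A
        change of the cross-protomer CA-CA distance at the membrane-proximal
        tip residue (34 for the TM1/H1 arm, 147 for the H4/TM2 arm),
        realized as rigid tilts of each arm about its membrane-distal end;
        positive = tips move apart.
    linker_state
        'helical' keeps the TM1-H1 arm continuous; 'broken' rebuilds the
        linker residues with (phi, psi) = (-80, 60).
    contact_distance_A
        optional exact CA-CA distance between residues 50 and 133 within a
        protomer, imposed as a final in-plane adjustment of the H4/TM2 arm.
    """

    rise: float = 1.5
    twist_deg: float = 100.0
    radius: float = 2.3
    phi: float = -57.0
    psi: float = -47.0
    core_radius_A: float = 7.0  # helix-axis distance from the bundle center
    chain_a: str = "A"
    chain_b: str = "B"
    h1_rotation_deg: float = 0.0
    piston_tm1_z_A: float = 0.0
    piston_h1_z_A: float = 0.0
    scissor_h1_tip_A: float = 0.0
    scissor_h4_tip_A: float = 0.0
    linker_state: str = "helical"
    linker_break_phi: float = -80.0
    linker_break_psi: float = 60.0
    contact_distance_A: float | None = None
    noise_sigma_A: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker_state not in ("helical", "broken"):
            raise FormatError("linker_state must be 'helical' or 'broken'")
        if self.core_radius_A <= 2.0 * self.radius:
            raise FormatError("core radius must exceed twice the CA radius")
        if self.chain_a == self.chain_b:
            raise FormatError("protomer chains must differ")


@dataclass
class TwoStateTrajectorySpec:
    """Pseudo-dynamics: state-A frames, then state-B frames, plus noise."""

    state_a: DimerSpec
    state_b: DimerSpec
    n_frames: int = 40
    frame_dt_ns: float = 10.0
    switch_fraction: float = 0.5
    noise_sigma_A: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.switch_fraction < 1.0:
            raise FormatError("switch_fraction must be in (0, 1)")
        if self.n_frames < 2:
            raise FormatError("need at least 2 frames")


@dataclass
class DimerGroundTruth:
    """Everything imposed on a generated dimer, for recovery tests."""

    spec: DimerSpec
    arm1_axis_xy: tuple[float, float]
    arm2_axis_xy: tuple[float, float]
    arm1_z_range: tuple[float, float]
    arm2_z_range: tuple[float, float]
    contact_distance_A: float = float("nan")
    segment_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_RANGES))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_ideal_helix(spec: HelixSpec) -> StructureModel:
    """Ideal helix with CA exactly on the requested cylinder."""
    coords = _helix_residue_atoms(spec)
    residues = [
        ResidueRecord(spec.chain_id, spec.start_resnum + i, spec.resname, atoms)
        for i, atoms in enumerate(coords)
    ]
    return StructureModel({spec.chain_id: residues}, label="ideal-helix")


def _helix_residue_atoms(
    spec: HelixSpec, phase_offsets: dict[int, float] | None = None
) -> list[dict[str, np.ndarray]]:
    template = _helix_template(spec.rise, spec.twist_deg, spec.radius, spec.phi, spec.psi)
    names = ("N", "CA", "C", "O")
    base = {n: np.array(p) for n, p in zip(names, template)}
    out = []
    for i in range(spec.n_residues):
        resnum = spec.start_resnum + i
        extra = phase_offsets.get(resnum, 0.0) if phase_offsets else 0.0
        R = _rot_z(spec.start_phase_deg + i * spec.twist_deg + extra)
        z = spec.start_z + i * spec.rise
        out.append({n: R @ base[n] + np.array([0.0, 0.0, z]) for n in names})
    return out


def _tilt_angle_for_displacement(
    tip: np.ndarray, pivot: np.ndarray, u: np.ndarray, axis: np.ndarray, target: float
) -> float:
    """Rotation angle about ``axis`` through ``pivot`` moving ``tip`` by
    ``target`` along the horizontal unit vector ``u``."""

    def disp(theta):
        R = Rotation.from_rotvec(theta * axis).as_matrix()
        return float(u @ (R @ (tip - pivot) + pivot - tip)) - target

    if abs(target) < 1e-12:
        return 0.0
    return brentq(disp, -0.6, 0.6, xtol=1e-12)


def build_dimer(spec: DimerSpec) -> tuple[StructureModel, DimerGroundTruth]:
    """C2-symmetric two-chain dimer with the spec's state parameters imposed."""
    rise, twist = spec.rise, spec.twist_deg
    R_core = spec.core_radius_A
    tm1_lo, tm1_hi = DEFAULT_SEGMENT_RANGES["TM1"]
    lk_lo, lk_hi = LINKER_RANGE
    h1_lo, h1_hi = DEFAULT_SEGMENT_RANGES["H1"]
    a1_lo, a1_hi = ARM1_RANGE
    a2_lo, a2_hi = ARM2_RANGE

    # --- arm 1 (TM1 + linker + H1), axis along +z at (R_core, 0) -----------
    phase1 = 180.0 - (CONTACT_RES_ARM1 - a1_lo) * twist  # CA(50) faces the core
    offsets = (
        {r: spec.h1_rotation_deg for r in range(h1_lo, a1_hi + 1)}
        if spec.h1_rotation_deg
        else None
    )
    arm1_spec = HelixSpec(
        n_residues=a1_hi - a1_lo + 1,
        rise=rise,
        twist_deg=twist,
        radius=spec.radius,
        start_phase_deg=phase1,
        phi=spec.phi,
        psi=spec.psi,
        start_resnum=a1_lo,
        chain_id=spec.chain_a,
    )
    arm1 = _helix_residue_atoms(arm1_spec, offsets)
    arm1 = [
        {k: v + np.array([R_core, 0.0, 0.0]) for k, v in atoms.items()} for atoms in arm1
    ]
    residues = {
        a1_lo + i: ResidueRecord(spec.chain_a, a1_lo + i, "ALA", atoms)
        for i, atoms in enumerate(arm1)
    }

    # optional broken linker: rebuild linker residues by torsion continuation
    if spec.linker_state == "broken":
        _rebuild_linker(residues, spec)

    # --- arm 2 (H4 + TM2), antiparallel, axis at (0, -R_core) --------------
    z_contact = (CONTACT_RES_ARM1 - a1_lo) * rise
    start_z = -(z_contact + (CONTACT_RES_ARM2 - a2_lo) * rise)
    phase2 = -90.0 - (CONTACT_RES_ARM2 - a2_lo) * twist  # CA(133) faces the core
    arm2_spec = HelixSpec(
        n_residues=a2_hi - a2_lo + 1,
        rise=rise,
        twist_deg=twist,
        radius=spec.radius,
        start_phase_deg=phase2,
        phi=spec.phi,
        psi=spec.psi,
        start_resnum=a2_lo,
        chain_id=spec.chain_a,
        start_z=start_z,
    )
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    arm2 = _helix_residue_atoms(arm2_spec)
    arm2 = [
        {k: flip @ v + np.array([0.0, -R_core, 0.0]) for k, v in atoms.items()}
        for atoms in arm2
    ]
    for i, atoms in enumerate(arm2):
        num = a2_lo + i
        residues[num] = ResidueRecord(spec.chain_a, num, "ALA", atoms)

    arm1_nums = list(range(a1_lo, a1_hi + 1))
    arm2_nums = list(range(a2_lo, a2_hi + 1))

    # --- scissoring: rigid tilts about the membrane-distal arm ends --------
    z_top1 = (a1_hi - a1_lo) * rise
    z_top2 = z_contact + (CONTACT_RES_ARM2 - a2_lo) * rise
    for nums, tip_res, pivot_xy, z_top, delta in (
        (arm1_nums, 34, (R_core, 0.0), z_top1, spec.scissor_h1_tip_A),
        (arm2_nums, 147, (0.0, -R_core), z_top2, spec.scissor_h4_tip_A),
    ):
        if abs(delta) < 1e-12:
            continue
        tip = residues[tip_res].atoms["CA"]
        u = np.array([tip[0], tip[1], 0.0])
        u /= np.linalg.norm(u)
        axis = np.cross(np.array([0.0, 0.0, 1.0]), u)
        pivot = np.array([pivot_xy[0], pivot_xy[1], z_top])
        theta = _tilt_angle_for_displacement(tip, pivot, u, axis, delta / 2.0)
        Rm = Rotation.from_rotvec(theta * axis).as_matrix()
        for num in nums:
            res = residues[num]
            for k in res.atoms:
                res.atoms[k] = Rm @ (res.atoms[k] - pivot) + pivot

    # --- pistons: axial translations of TM1 and H1, ramped over the linker -
    if spec.piston_tm1_z_A or spec.piston_h1_z_A:
        for num in arm1_nums:
            if num <= lk_lo:
                dz = spec.piston_tm1_z_A
            elif num >= h1_lo:
                dz = spec.piston_h1_z_A
            else:
                f = (num - lk_lo) / (h1_lo - lk_lo)
                dz = spec.piston_tm1_z_A + f * (spec.piston_h1_z_A - spec.piston_tm1_z_A)
            res = residues[num]
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([0.0, 0.0, dz])

    # --- optional exact residue-50/133 contact distance ---------------------
    if spec.contact_distance_A is not None:
        c50 = residues[CONTACT_RES_ARM1].atoms["CA"]
        c133 = residues[CONTACT_RES_ARM2].atoms["CA"]
        w = c50 - c133
        wz = w[2]
        wh = np.array([w[0], w[1], 0.0])
        norm_h = np.linalg.norm(wh)
        if spec.contact_distance_A <= abs(wz) or norm_h < 1e-9:
            raise FormatError("contact distance unreachable by in-plane adjustment")
        alpha = norm_h - math.sqrt(spec.contact_distance_A**2 - wz**2)
        shift = alpha * wh / norm_h
        for num in arm2_nums:
            res = residues[num]
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + shift

    # --- protomer B by C2 about the bundle axis -----------------------------
    c2 = _rot_z(180.0)
    chain_b = [
        ResidueRecord(
            spec.chain_b, r.resnum, r.resname, {k: c2 @ v for k, v in r.atoms.items()}
        )
        for r in residues.values()
    ]
    model = StructureModel(
        {spec.chain_a: list(residues.values()), spec.chain_b: chain_b},
        label="synthetic-dimer",
    )

    _check_clashes(model, spec.chain_a, spec.chain_b)

    if spec.noise_sigma_A > 0:
        rng = np.random.default_rng(spec.seed)
        model = perturb(model, spec.noise_sigma_A, rng)

    gt = DimerGroundTruth(
        spec=spec,
        arm1_axis_xy=(R_core, 0.0),
        arm2_axis_xy=(0.0, -R_core),
        arm1_z_range=(0.0, z_top1),
        arm2_z_range=(z_contact - (a2_hi - CONTACT_RES_ARM2) * rise, z_top2),
        contact_distance_A=float(
            np.linalg.norm(
                residues[CONTACT_RES_ARM1].atoms["CA"] - residues[CONTACT_RES_ARM2].atoms["CA"]
            )
        ),
    )
    return model, gt


def _rebuild_linker(residues: dict[int, ResidueRecord], spec: DimerSpec) -> None:
    """Re-place linker backbone by NeRF continuation with break torsions."""
    lk_lo, lk_hi = LINKER_RANGE
    prev = residues[lk_lo - 1]
    n_prev, ca_prev, c_prev = (prev.atoms[k] for k in ("N", "CA", "C"))
    N, CA, C = [n_prev], [ca_prev], [c_prev]
    psis = [spec.psi] + [spec.linker_break_psi] * (lk_hi - lk_lo + 1)
    phis = [None] + [spec.linker_break_phi] * (lk_hi - lk_lo + 1)
    for k in range(1, lk_hi - lk_lo + 2):
        N.append(place_atom(N[k - 1], CA[k - 1], C[k - 1], BOND_C_N, ANGLE_CA_C_N, psis[k - 1]))
        CA.append(place_atom(CA[k - 1], C[k - 1], N[k], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS))
        C.append(place_atom(C[k - 1], N[k], CA[k], BOND_CA_C, ANGLE_N_CA_C, phis[k]))
    n_virtual = place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psis[-1])
    for k in range(1, lk_hi - lk_lo + 2):
        num = lk_lo - 1 + k
        nn = N[k + 1] if k + 1 <= lk_hi - lk_lo + 1 else n_virtual
        residues[num].atoms = {
            "N": N[k],
            "CA": CA[k],
            "C": C[k],
            "O": _carbonyl_oxygen(CA[k], C[k], nn),
        }
    # previous residue's O now pairs with the rebuilt N of the first linker residue
    residues[lk_lo - 1].atoms["O"] = _carbonyl_oxygen(ca_prev, c_prev, N[1])


def _check_clashes(model: StructureModel, chain_a: str, chain_b: str) -> None:
    ca_a = np.array([r.atoms["CA"] for r in model.chains[chain_a]])
    ca_b = np.array([r.atoms["CA"] for r in model.chains[chain_b]])
    d2 = np.sum((ca_a[:, None, :] - ca_b[None, :, :]) ** 2, axis=-1)
    dmin = math.sqrt(float(d2.min()))
    if dmin < MIN_INTERCHAIN_CA_A:
        raise ClashError(
            f"inter-chain CA-CA distance {dmin:.2f} A below {MIN_INTERCHAIN_CA_A} A"
        )


def perturb(model: StructureModel, sigma: float, rng: np.random.Generator) -> StructureModel:
    """Copy with i.i.d. Gaussian noise (sigma, A) on every coordinate."""
    noisy = model.copy()
    for residues in noisy.chains.values():
        for res in residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + rng.normal(0.0, sigma, size=3)
    return noisy


def make_trajectory(spec: TwoStateTrajectorySpec) -> tuple[Trajectory, list[str]]:
    """Two-state pseudo-trajectory; returns (trajectory, per-frame state labels)."""
    base_a = asdict(spec.state_a)
    base_b = asdict(spec.state_b)
    for d in (base_a, base_b):
        d["noise_sigma_A"] = 0.0
    model_a, _ = build_dimer(DimerSpec(**base_a))
    model_b, _ = build_dimer(DimerSpec(**base_b))

    switch = round(spec.n_frames * spec.switch_fraction)
    rng = np.random.default_rng(spec.seed)
    frames, labels = [], []
    for i in range(spec.n_frames):
        state, base = ("A", model_a) if i < switch else ("B", model_b)
        frame = (
            perturb(base, spec.noise_sigma_A, rng)
            if spec.noise_sigma_A > 0
            else base.copy()
        )
        frame.label = f"frame{i}"
        frames.append(frame)
        labels.append(state)
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_dt_ns
    return Trajectory(frames, times), labels


# ---------------------------------------------------------------------------
# Presets: the qualitative activation mechanism, usable as regression anchors
# ---------------------------------------------------------------------------


def bound_like_spec(**overrides) -> DimerSpec:
    """Ligand-bound-like state: H1 rotated, linker broken, piston offsets on,
    H1 tips apart / H4 tips together relative to the free-like reference."""
    params = dict(
        h1_rotation_deg=26.0,
        piston_tm1_z_A=3.0,
        piston_h1_z_A=1.0,
        scissor_h1_tip_A=2.0,
        scissor_h4_tip_A=-2.0,
        linker_state="broken",
        contact_distance_A=7.1,
    )
    params.update(overrides)
    return DimerSpec(**params)


def free_like_spec(**overrides) -> DimerSpec:
    """Ligand-free-like reference state: continuous linker, no imposed modes."""
    params = dict(linker_state="helical", contact_distance_A=7.8)
    params.update(overrides)
    return DimerSpec(**params)


def write_provenance(spec, path) -> None:
    """Sidecar JSON recording the generating spec (including the seed)."""
    def _default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(asdict(spec), indent=2, default=_default) + "\n")
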
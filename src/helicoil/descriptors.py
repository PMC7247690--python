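"""Scalar conformational descriptors evaluated on a single structure.

These are the per-snapshot readouts of the receptor's activation modes:

* intra-protomer CA-CA contact distance (residue 50 to 133 by default),
  a backbone proxy for the Arg50-Asp133 interaction;
* cross-protomer per-residue CA-CA distance profiles, whose opposing
  changes on the H1 and H4 sides constitute diagonal scissoring;
* piston shift: difference of segment CA-centroid projections on the
  bundle/membrane-normal axis;
* backbone phi/psi dihedrals and an alpha-region classification for the
  sensor-TM linker;
* backbone hydrogen-bond patterns distinguishing alpha (i->i+4) from
  3_10-like (i->i+3) bonding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .helix_geometry import Line
from .structures_io import ProtomerMap, SegmentDef, StructureModel

#: Donor-acceptor N...O distance threshold for a backbone hydrogen bond (A).
HBOND_NO_CUTOFF_A = 3.5

#: O...H distance threshold (A) with the amide hydrogen placed geometrically
#: on the donor N.  A pure N...O distance cutoff cannot tell alpha from 3_10
#: bonding on an ideal helix (the non-bonded O(i)...N(i+3) separation in an
#: alpha-helix is ~3.1 A, inside any defensible N...O cutoff), so the bond
#: additionally requires the donor hydrogen to point at the acceptor.
HBOND_HO_CUTOFF_A = 2.5
AMIDE_NH_BOND_A = 1.01

#: Alpha-helical region of the Ramachandran map used by classify_alpha.
#: Closed intervals; boundary values classify as helical.
ALPHA_PHI_RANGE = (-120.0, -30.0)
ALPHA_PSI_RANGE = (-80.0, -5.0)


@dataclass
class DescriptorSeries:
    """A named numeric series over frames or residues, tagged by protomer."""

    name: str
    units: str  # "A", "deg" or "state"
    index: np.ndarray  # frame times (ns) or residue numbers
    values: np.ndarray
    protomer: str = "dimer"
    index_name: str = "index"

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index)
        self.values = np.asarray(self.values)
        if len(self.index) != len(self.values):
            raise SelectionError(
                f"series {self.name!r}: index and values lengths differ"
            )


def intra_protomer_ca_distance(
    model: StructureModel,
    protomer_map: ProtomerMap,
    protomer: str,
    res_a: int = 50,
    res_b: int = 133,
) -> float:
    """CA-CA distance (A) between two residues within one protomer chain."""
    chain = protomer_map.chain(protomer)
    return float(np.linalg.norm(model.ca(chain, res_a) - model.ca(chain, res_b)))


def cross_protomer_distance_profile(
    model: StructureModel,
    protomer_map: ProtomerMap,
    resnums: Sequence[int],
    name: str = "cross_protomer_distance",
) -> DescriptorSeries:
    """Per-residue CA(A, r) - CA(B, r) distances across the dimer.

    Missing residues are flagged NaN; the rest of the profile is computed.
    """
    values = np.full(len(resnums), np.nan)
    for i, num in enumerate(resnums):
        try:
            values[i] = np.linalg.norm(
                model.ca(protomer_map.A, num) - model.ca(protomer_map.B, num)
            )
        except SelectionError:
            continue
    return DescriptorSeries(
        name=name,
        units="A",
        index=np.asarray(list(resnums)),
        values=values,
        protomer="dimer",
        index_name="resnum",
    )


def segment_ca_centroid(model: StructureModel, segment: SegmentDef) -> np.ndarray:
    """Equal-weight CA centroid of a segment (backbone-level center of mass)."""
    coords = segment.ca_coords(model)
    if len(coords) == 0:
        raise SelectionError(f"segment {segment.role} selects no residues")
    return coords.mean(axis=0)


def piston_shift(
    model: StructureModel,
    seg1: SegmentDef | Sequence[SegmentDef],
    seg2: SegmentDef | Sequence[SegmentDef],
    z_axis: Line,
) -> float:
    """Axial (piston) offset: z-projection of seg1 centroid minus seg2's.

    Segments may be given per protomer (a sequence); their CA atoms are
    pooled before taking the centroid.  The sign follows the bundle-axis
    orientation convention (+z periplasmic).
    """

    def _centroid(seg) -> np.ndarray:
        segs = [seg] if isinstance(seg, SegmentDef) else list(seg)
        coords = np.vstack([s.ca_coords(model) for s in segs])
        return coords.mean(axis=0)

    z = z_axis.direction
    return float(np.dot(_centroid(seg1) - _centroid(seg2), z))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees, in (-180, 180]) of four points, IUPAC sign."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def phi_psi(
    model: StructureModel, chain: str, resnum: int
) -> tuple[float | None, float | None]:
    """Backbone (phi, psi) in degrees; None where a terminus/atom gap leaves
    the dihedral undefined."""
    phi = psi = None
    try:
        res = model.residue(chain, resnum)
    except SelectionError:
        return None, None
    try:
        prev = model.residue(chain, resnum - 1)
        if prev.has("C") and res.has("N") and res.has("CA") and res.has("C"):
            phi = dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    except SelectionError:
        pass
    try:
        nxt = model.residue(chain, resnum + 1)
        if res.has("N") and res.has("CA") and res.has("C") and nxt.has("N"):
            psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
    except SelectionError:
        pass
    return phi, psi


def classify_alpha(
    phi: float | None,
    psi: float | None,
    phi_range: tuple[float, float] = ALPHA_PHI_RANGE,
    psi_range: tuple[float, float] = ALPHA_PSI_RANGE,
) -> str:
    """'helical' | 'disordered' | 'unknown' from backbone dihedrals.

    Helical iff phi and psi fall inside the (closed) alpha-region windows.
    """
    if phi is None or psi is None:
        return "unknown"
    helical = phi_range[0] <= phi <= phi_range[1] and psi_range[0] <= psi <= psi_range[1]
    return "helical" if helical else "disordered"


def linker_state(
    model: StructureModel,
    chain: str,
    resnums: Sequence[int] = range(34, 39),
) -> tuple[str, dict[int, str]]:
    """Classify the sensor-TM linker of one chain.

    Returns the per-residue classes and the overall state: 'helical' iff
    every classifiable residue is helical, else 'broken'.
    """
    per_res = {}
    for num in resnums:
        per_res[num] = classify_alpha(*phi_psi(model, chain, num))
    known = [c for c in per_res.values() if c != "unknown"]
    state = "helical" if known and all(c == "helical" for c in known) else "broken"
    return state, per_res


@dataclass(frozen=True)
class HBondPattern:
    """One backbone O(i)...N(j) hydrogen bond with its helical class."""

    acceptor_resnum: int  # residue i providing the backbone O
    donor_resnum: int  # residue j providing the backbone N
    distance: float  # O...N distance, A
    hbond_class: str  # "alpha" (j = i+4) | "three_ten" (j = i+3) | "other"

    def __post_init__(self) -> None:
        offset = self.donor_resnum - self.acceptor_resnum
        expect = {4: "alpha", 3: "three_ten"}.get(offset, "other")
        if self.hbond_class != expect:
            raise SelectionError(
                f"class {self.hbond_class!r} inconsistent with offset {offset}"
            )


def amide_hydrogen(model: StructureModel, chain: str, resnum: int) -> np.ndarray | None:
    """Geometric amide H on the backbone N (in the C(prev)-N-CA plane,
    opposite their bisector); None at a terminus or with atoms missing."""
    try:
        res = model.residue(chain, resnum)
        prev = model.residue(chain, resnum - 1)
    except SelectionError:
        return None
    if not (res.has("N") and res.has("CA") and prev.has("C")):
        return None
    n = res.atoms["N"]
    u = prev.atoms["C"] - n
    u /= np.linalg.norm(u)
    v = res.atoms["CA"] - n
    v /= np.linalg.norm(v)
    w = -(u + v)
    w /= np.linalg.norm(w)
    return n + AMIDE_NH_BOND_A * w


def backbone_hbond_pattern(
    model: StructureModel,
    chain: str,
    acceptor_resnum: int,
    cutoff: float = HBOND_NO_CUTOFF_A,
    h_cutoff: float = HBOND_HO_CUTOFF_A,
) -> list[HBondPattern]:
    """Backbone H-bonds donated to residue i's O by N-H of i+3 and i+4.

    A bond requires O...N <= ``cutoff`` and, when the donor hydrogen can be
    placed, O...H <= ``h_cutoff`` (directionality; see HBOND_HO_CUTOFF_A).
    Both offsets may coexist (bifurcated bond).  Pairs with missing O/N
    atoms are skipped; a residue whose O is absent yields no bonds rather
    than an estimated position.
    """
    try:
        acceptor = model.residue(chain, acceptor_resnum)
    except SelectionError:
        return []
    if not acceptor.has("O"):
        return []
    out: list[HBondPattern] = []
    for offset, cls in ((3, "three_ten"), (4, "alpha")):
        try:
            donor = model.residue(chain, acceptor_resnum + offset)
        except SelectionError:
            continue
        if not donor.has("N"):
            continue
        d = float(np.linalg.norm(acceptor.atoms["O"] - donor.atoms["N"]))
        if d > cutoff:
            continue
        h = amide_hydrogen(model, chain, acceptor_resnum + offset)
        if h is not None and np.linalg.norm(acceptor.atoms["O"] - h) > h_cutoff:
            continue
        out.append(HBondPattern(acceptor_resnum, acceptor_resnum + offset, d, cls))
    return out


def helix_hbond_classes(
    model: StructureModel,
    chain: str,
    resnums: Sequence[int],
    cutoff: float = HBOND_NO_CUTOFF_A,
) -> dict[int, list[str]]:
    """H-bond classes per acceptor residue over a range (for pattern summaries)."""
    return {
        num: [b.hbond_class for b in backbone_hbond_pattern(model, chain, num, cutoff)]
        for num in resnums
    }
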
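"""Local helix axis fitting, bundle axis, and CA superposition.

The local axis follows the bisector construction used for coiled-coil
parameterization: for residue i the angle bisectors of the CA traces at
residues i and i+1 both point at the helix axis; the axis point attributed
to residue i is the midpoint of the shortest segment connecting the two
bisector lines, so it draws on CA(i-1..i+2).  Tangents come from central
differences of the axis points, oriented N->C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InsufficientInputError,
    SelectionError,
    UnderdeterminedError,
)
from .structures_io import StructureModel

#: Orientation convention for the bundle axis used everywhere downstream:
#: the +z end is the periplasmic (sensor-domain) side, i.e. the direction in
#: which TM1 residue numbers increase (residue 14 cytoplasmic -> 34
#: periplasmic).  This single constant fixes all piston-shift signs.
PERIPLASMIC_IS_PLUS_Z = True

AXIS_WINDOW = 4  # CA atoms per bisector construction; minimum for the method


@dataclass
class AxisPolyline:
    """Fitted local helix axis: per-residue points and unit tangents."""

    resnums: np.ndarray  # residues owning an axis point (interior only)
    points: np.ndarray  # (n, 3) axis points, Angstrom
    tangents: np.ndarray  # (n, 3) unit tangents, oriented N->C

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise DegenerateGeometryError("axis tangents not unit-norm")

    def has(self, resnum: int) -> bool:
        return resnum in self.resnums

    def at(self, resnum: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.nonzero(self.resnums == resnum)[0]
        if idx.size == 0:
            raise SelectionError(f"no axis point for residue {resnum}")
        i = int(idx[0])
        return self.points[i], self.tangents[i]

    def mean_direction(self) -> np.ndarray:
        d = self.tangents.mean(axis=0)
        return d / np.linalg.norm(d)


@dataclass
class Line:
    """Infinite line: a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateGeometryError("zero-length line direction")
        self.direction = d / n

    def nearest_point(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.point + np.dot(x - self.point, self.direction) * self.direction


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping the mobile set onto the reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # so that x' = R @ x + t
    rmsd: float  # Angstrom, over the fitted atom set
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def apply_model(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def _bisector(ca: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit bisector of the CA trace at interior index i (points at the axis)."""
    b = (ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i])
    n = np.linalg.norm(b)
    if n < 1e-9:
        raise DegenerateGeometryError(f"straight or degenerate CA trace at index {i}")
    return ca[i], b / n


def _closest_approach_midpoint(
    p1: np.ndarray, d1: np.ndarray, p2: np.ndarray, d2: np.ndarray
) -> np.ndarray:
    """Midpoint of the shortest segment between two (possibly skew) lines."""
    w0 = p1 - p2
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ w0, d2 @ w0
    denom = a * c - b * b
    if abs(denom) < 1e-12:  # parallel bisectors: fall back to projection
        t = 0.0
        s = e / c
    else:
        t = (b * e - c * d) / denom
        s = (a * e - b * d) / denom
    return 0.5 * ((p1 + t * d1) + (p2 + s * d2))


def fit_local_axis(
    ca_coords: np.ndarray,
    resnums: Sequence[int] | None = None,
    window: int = AXIS_WINDOW,
) -> AxisPolyline:
    """Fit the local helix axis of an ordered CA trace.

    Residue i (0-based index within the trace) receives an axis point built
    from CA(i-1..i+2); the first and the last ``window - 2`` residues get
    none.  ``resnums`` labels the trace (defaults to 0..n-1).
    """
    ca = np.asarray(ca_coords, dtype=float)
    n = len(ca)
    if window < 4:
        raise InsufficientInputError("bisector construction needs window >= 4")
    if n < window + 1:
        raise InsufficientInputError(
            f"need at least {window + 1} CA atoms, got {n}"
        )
    if resnums is None:
        resnums = np.arange(n)
    resnums = np.asarray(resnums, dtype=int)

    bisectors = {i: _bisector(ca, i) for i in range(1, n - 1)}
    owners, points = [], []
    for i in range(1, n - 2):  # needs bisectors at i and i+1 -> CA(i-1..i+2)
        (pa, da), (pb, db) = bisectors[i], bisectors[i + 1]
        points.append(_closest_approach_midpoint(pa, da, pb, db))
        owners.append(resnums[i])
    points = np.asarray(points)

    tangents = np.empty_like(points)
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    if len(points) > 2:
        tangents[1:-1] = points[2:] - points[:-2]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError("coincident axis points")
    tangents = tangents / norms
    # orient N->C
    nc = ca[-1] - ca[0]
    flip = (tangents @ nc) < 0
    tangents[flip] *= -1.0
    return AxisPolyline(owners, points, tangents)


def bundle_axis(
    axes: Iterable[AxisPolyline], orient: np.ndarray | None = None
) -> Line:
    """Bundle reference axis: first principal component of pooled axis points.

    ``orient`` is a reference vector fixing the sign of the direction (the
    pipeline passes the N->C direction of TM1, so +z is periplasmic); without
    it the N->C direction of the first axis is used.  A single axis is
    returned as its own line (documented fallback).
    """
    axes = list(axes)
    if not axes:
        raise InsufficientInputError("bundle_axis needs at least one axis")
    # center each helix's points on its own centroid before pooling, so the
    # direction reflects the helix axes rather than their lateral separation
    centroids = [a.points.mean(axis=0) for a in axes]
    centered = np.vstack([a.points - c for a, c in zip(axes, centroids)])
    centroid = np.mean(centroids, axis=0)
    if np.linalg.norm(centered) < 1e-9:
        raise DegenerateGeometryError("all axis points coincide")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError("degenerate axis point cloud")
    direction = vt[0]
    ref = np.asarray(orient, float) if orient is not None else axes[0].mean_direction()
    if np.dot(direction, ref) < 0:
        direction = -direction
    return Line(centroid, direction)


def kabsch_superpose(
    reference: StructureModel,
    mobile: StructureModel,
    residue_set: Sequence[tuple[str, int]],
) -> SuperpositionResult:
    """Least-squares optimal rigid transform over CA atoms of ``residue_set``."""
    if len(residue_set) < 3:
        raise UnderdeterminedError("superposition needs at least 3 residues")
    ref = reference.ca_coords(residue_set)
    mob = mobile.ca_coords(residue_set)
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(len(residue_set)))
    return SuperpositionResult(R, t, rmsd, len(residue_set))


def ca_rmsd(
    a: StructureModel,
    b: StructureModel,
    residue_set: Sequence[tuple[str, int]],
) -> float:
    """CA RMSD over ``residue_set`` after optimal superposition of b onto a."""
    return kabsch_superpose(a, b, residue_set).rmsd
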
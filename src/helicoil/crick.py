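"""Per-residue Crick angles: the phase of each CA about its local helix axis.

The Crick angle of residue i is the signed angle, measured in the plane
perpendicular to the local axis tangent at i, between the direction from the
axis point towards the bundle axis (zero reference, the coiled-coil core)
and the direction from the axis point to the CA.  A uniform shift of the
angles of one helix reads out as rotation of that helix about its own axis.

All aggregation over frames uses circular statistics; linear means of
angles are deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InsufficientInputError
from .helix_geometry import AxisPolyline, Line, bundle_axis, fit_local_axis
from .structures_io import ProtomerMap, SegmentDef, StructureModel, Trajectory

#: Sign convention: +1 measures angles right-handed about the local N->C
#: tangent.  One constant so the convention can be audited (and flipped) in
#: exactly one place.
CRICK_HANDEDNESS = +1

#: Minimum CA-to-axis distance before the angle is declared degenerate.
MIN_RADIUS_A = 0.3


def wrap_angle(deg):
    """Wrap angle(s) into (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def circular_mean(deg: np.ndarray) -> float:
    """Mean direction of angles in degrees (mean of unit vectors)."""
    a = np.radians(np.asarray(deg, float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    return wrap_angle(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def circular_std(deg: np.ndarray) -> float:
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    a = np.radians(np.asarray(deg, float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    R = np.hypot(np.sin(a).mean(), np.cos(a).mean())
    R = min(max(R, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


def circular_difference(a_deg, b_deg):
    """Signed smallest difference a - b in (-180, 180]."""
    return wrap_angle(np.asarray(a_deg, float) - np.asarray(b_deg, float))


def crick_angle(
    helix_axis: AxisPolyline,
    ca_coord: np.ndarray,
    bundle: Line,
    resnum: int,
) -> float:
    """Signed Crick angle (degrees) of one residue.

    Positive sense is right-handed about the local tangent (N->C) from the
    bundle-pointing reference to the CA direction.
    """
    point, tangent = helix_axis.at(resnum)
    ca = np.asarray(ca_coord, dtype=float)

    def _project(v):
        return v - np.dot(v, tangent) * tangent

    v_ca = _project(ca - point)
    if np.linalg.norm(v_ca) < MIN_RADIUS_A:
        raise DegenerateGeometryError(
            f"residue {resnum}: CA within {MIN_RADIUS_A} A of its axis point"
        )
    v_ref = _project(bundle.nearest_point(point) - point)
    if np.linalg.norm(v_ref) < 1e-6:
        raise DegenerateGeometryError(
            f"residue {resnum}: axis point lies on the bundle axis"
        )
    sin_term = np.dot(tangent, np.cross(v_ref, v_ca)) * CRICK_HANDEDNESS
    cos_term = np.dot(v_ref, v_ca)
    return wrap_angle(np.degrees(np.arctan2(sin_term, cos_term)))


@dataclass
class CrickSeries:
    """Crick angles for one protomer: frames x residues, degrees in (-180, 180]."""

    protomer: str
    resnums: np.ndarray  # (n_res,)
    frame_times: np.ndarray  # (n_frames,) ns
    angles: np.ndarray  # (n_frames, n_res), NaN where flagged missing
    n_missing: int = 0
    units: str = "deg"

    def per_residue_mean(self) -> np.ndarray:
        return np.array([circular_mean(self.angles[:, j]) for j in range(self.angles.shape[1])])

    def per_residue_std(self) -> np.ndarray:
        return np.array([circular_std(self.angles[:, j]) for j in range(self.angles.shape[1])])

    def column(self, resnum: int) -> np.ndarray:
        j = int(np.nonzero(self.resnums == resnum)[0][0])
        return self.angles[:, j]


def crick_angles_model(
    model: StructureModel,
    segment: SegmentDef,
    resnums: Sequence[int],
    bundle: Line,
) -> dict[int, float]:
    """Crick angles of ``resnums`` within one helix segment of one model."""
    trace = segment.ca_coords(model)
    axis = fit_local_axis(trace, resnums=list(segment.resnums))
    out: dict[int, float] = {}
    for num in resnums:
        if not axis.has(num):
            out[num] = float("nan")
            continue
        out[num] = crick_angle(axis, model.ca(segment.chain_id, num), bundle, num)
    return out


def helix_axes_for_bundle(
    model: StructureModel, segments: Sequence[SegmentDef]
) -> list[AxisPolyline]:
    return [
        fit_local_axis(seg.ca_coords(model), resnums=list(seg.resnums))
        for seg in segments
    ]


def crick_series(
    traj: Trajectory,
    segment: SegmentDef | Mapping[str, SegmentDef],
    resnums: Sequence[int],
    protomer_map: ProtomerMap,
    bundle_segments: Sequence[SegmentDef] | None = None,
    orient: np.ndarray | None = None,
) -> dict[str, CrickSeries]:
    """Per-frame Crick angles of ``resnums`` for both protomers.

    ``segment`` is either one SegmentDef per protomer (mapping protomer label
    -> SegmentDef) or a single SegmentDef whose chain is re-bound per
    protomer.  The bundle axis is refit per frame from ``bundle_segments``
    (default: the analysed segment in both protomers).
    """
    if isinstance(segment, SegmentDef):
        seg_by_protomer = {
            p: SegmentDef(segment.role, cid, segment.first_resnum, segment.last_resnum)
            for p, cid in protomer_map.items()
        }
    else:
        seg_by_protomer = dict(segment)
    if bundle_segments is None:
        bundle_segments = list(seg_by_protomer.values())

    resnums = list(resnums)
    n_frames = traj.n_frames
    out: dict[str, CrickSeries] = {}
    angles = {p: np.full((n_frames, len(resnums)), np.nan) for p in seg_by_protomer}
    missing = {p: 0 for p in seg_by_protomer}

    for fi, frame in enumerate(traj):
        try:
            axes = helix_axes_for_bundle(frame, bundle_segments)
            bundle = bundle_axis(axes, orient=orient)
        except (InsufficientInputError, DegenerateGeometryError):
            for p in seg_by_protomer:
                missing[p] += len(resnums)
            continue
        for p, seg in seg_by_protomer.items():
            try:
                vals = crick_angles_model(frame, seg, resnums, bundle)
            except (InsufficientInputError, DegenerateGeometryError):
                missing[p] += len(resnums)
                continue
            for j, num in enumerate(resnums):
                v = vals[num]
                if np.isnan(v):
                    missing[p] += 1
                angles[p][fi, j] = v

    for p in seg_by_protomer:
        out[p] = CrickSeries(
            protomer=p,
            resnums=np.asarray(resnums),
            frame_times=traj.frame_times.copy(),
            angles=angles[p],
            n_missing=missing[p],
        )
    return out
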
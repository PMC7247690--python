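"""Descriptor evaluation over trajectory windows and structure pairs.

Orchestrates the per-frame descriptors into the standard analysis products:
per-protomer Crick-angle and contact-distance series over the last part of
a trajectory, cross-protomer distance profiles, piston-shift series, linker
secondary-structure state matrices, crystal-reference overlays, aligned
snapshot export, and the two-state (ligand-bound vs ligand-free) structure
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crick as _crick
from . import descriptors as _desc
from .errors import ConfigError, SelectionError, WindowError
from .helix_geometry import (
    Line,
    bundle_axis,
    fit_local_axis,
    kabsch_superpose,
)
from .structures_io import (
    DEFAULT_SEGMENT_RANGES,
    ProtomerMap,
    SegmentDef,
    StructureModel,
    Trajectory,
    write_structure,
)

log = logging.getLogger("helicoil")


def _both_chains(ranges: Sequence[tuple[int, int]], protomers: ProtomerMap):
    return tuple(
        (cid, num)
        for _, cid in protomers.items()
        for lo, hi in ranges
        for num in range(lo, hi + 1)
    )


@dataclass
class AnalysisConfig:
    """Parameters of a descriptor run; defaults follow the receptor study."""

    protomer_map: ProtomerMap = field(default_factory=lambda: ProtomerMap("A", "B"))
    segment_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_RANGES)
    )
    crick_resnums: tuple[int, ...] = (47, 50)  # Gly47 and Arg50/Ser50
    contact_pair: tuple[int, int] = (50, 133)
    profile_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"H1_side": (34, 50), "H4_side": (133, 147)}
    )
    window_last_ns: float = 200.0
    snapshot_stride_ns: float = 10.0
    #: superposition core for two-state comparison (membrane-distal halves
    #: of H1 and H4, which barely move on ligand binding)
    compare_align_ranges: tuple[tuple[int, int], ...] = ((48, 54), (122, 130))
    #: superposition set for snapshot export
    snapshot_align_ranges: tuple[tuple[int, int], ...] = ((45, 55),)
    reference_paths: tuple[str, ...] = ()
    output_dir: str = "helicoil_out"
    seed: int = 0
    distance_bin_A: float = 0.1
    angle_bin_deg: float = 5.0

    def segment(self, role: str, protomer: str) -> SegmentDef:
        lo, hi = self.segment_ranges[role]
        return SegmentDef(role, self.protomer_map.chain(protomer), lo, hi)

    def segments(self, role: str) -> list[SegmentDef]:
        return [self.segment(role, p) for p, _ in self.protomer_map.items()]

    def bundle_segments(self) -> list[SegmentDef]:
        return self.segments("H1") + self.segments("H4")

    def orientation_hint(self, model: StructureModel) -> np.ndarray:
        """+z points periplasmic: along increasing TM1 residue numbers."""
        lo, hi = self.segment_ranges["TM1"]
        chain = self.protomer_map.A
        try:
            return model.ca(chain, hi) - model.ca(chain, lo)
        except SelectionError:
            lo, hi = self.segment_ranges["H1"]
            return model.ca(chain, hi) - model.ca(chain, lo)

    def bundle_line(self, model: StructureModel) -> Line:
        axes = [
            fit_local_axis(s.ca_coords(model), resnums=list(s.resnums))
            for s in self.bundle_segments()
        ]
        return bundle_axis(axes, orient=self.orientation_hint(model))

    def validate(self, model: StructureModel) -> None:
        """Fail before any computation if the topology lacks needed residues."""
        missing = []
        for role in ("TM1", "linker", "H1", "H4", "TM2"):
            for seg in self.segments(role):
                for num in seg.resnums:
                    if not model.has_residue(seg.chain_id, num):
                        missing.append(f"{seg.chain_id}/{num} ({role})")
        for _, cid in self.protomer_map.items():
            for num in self.contact_pair + self.crick_resnums:
                if not model.has_residue(cid, num):
                    missing.append(f"{cid}/{num}")
        if missing:
            raise ConfigError(
                "config requests residues absent from topology: "
                + ", ".join(sorted(set(missing))[:12])
            )


def window_last(traj: Trajectory, T_ns: float = 200.0) -> Trajectory:
    """Frames with time strictly inside the trailing ``T_ns`` of the span."""
    span = traj.span_ns
    if span < T_ns:
        raise WindowError(
            f"trajectory spans {span:g} ns, cannot take the last {T_ns:g} ns; "
            f"use T_ns <= {span:g}"
        )
    cutoff = traj.frame_times[-1] - T_ns
    keep = traj.frame_times > cutoff
    if T_ns == span:  # whole trajectory, including the first frame
        keep[:] = True
    return Trajectory(
        [traj.frames[i] for i in np.nonzero(keep)[0]], traj.frame_times[keep]
    )


def make_histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with bin edges aligned to multiples of ``bin_width``."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.array([]), np.array([])
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    n = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(v, bins=n, range=(lo, lo + n * bin_width))
    return counts, edges


@dataclass
class AnalysisResult:
    """Everything run_descriptors computes on one trajectory window."""

    config: AnalysisConfig
    frame_times: np.ndarray
    crick: dict[str, _crick.CrickSeries]  # per protomer
    contact: dict[str, _desc.DescriptorSeries]  # per protomer, per frame
    profiles: dict[str, pd.DataFrame]  # name -> frames x resnums distances
    piston: _desc.DescriptorSeries  # per frame, dimer
    linker_states: dict[str, pd.DataFrame]  # protomer -> frames x resnums {H,D,U}
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    failure_counts: dict[str, int]

    def reference_overlays(self) -> dict:
        return getattr(self, "_overlays", {})


_STATE_CODE = {"helical": "H", "disordered": "D", "unknown": "U"}


def run_descriptors(traj: Trajectory, config: AnalysisConfig) -> AnalysisResult:
    """Evaluate all configured descriptors on every frame of ``traj``."""
    config.validate(traj.frames[0])
    pm = config.protomer_map
    n = traj.n_frames
    times = traj.frame_times

    crick_series = _crick.crick_series(
        traj,
        config.segment("H1", "A"),
        config.crick_resnums,
        pm,
        bundle_segments=config.bundle_segments(),
        orient=config.orientation_hint(traj.frames[0]),
    )

    failures: dict[str, int] = {"crick": sum(s.n_missing for s in crick_series.values())}

    contact = {}
    for p, _cid in pm.items():
        vals = np.full(n, np.nan)
        for i, frame in enumerate(traj):
            try:
                vals[i] = _desc.intra_protomer_ca_distance(
                    frame, pm, p, *config.contact_pair
                )
            except SelectionError:
                pass
        failures[f"contact_{p}"] = int(np.isnan(vals).sum())
        contact[p] = _desc.DescriptorSeries(
            name=f"contact_{config.contact_pair[0]}_{config.contact_pair[1]}",
            units="A",
            index=times,
            values=vals,
            protomer=p,
            index_name="frame_time_ns",
        )

    profiles = {}
    for name, (lo, hi) in config.profile_ranges.items():
        resnums = list(range(lo, hi + 1))
        mat = np.full((n, len(resnums)), np.nan)
        for i, frame in enumerate(traj):
            mat[i] = _desc.cross_protomer_distance_profile(frame, pm, resnums).values
        failures[f"profile_{name}"] = int(np.isnan(mat).sum())
        profiles[name] = pd.DataFrame(mat, index=times, columns=resnums)

    piston_vals = np.full(n, np.nan)
    seg_tm1 = config.segments("TM1")
    seg_tm2 = config.segments("TM2")
    for i, frame in enumerate(traj):
        try:
            z = config.bundle_line(frame)
            piston_vals[i] = _desc.piston_shift(frame, seg_tm1, seg_tm2, z)
        except (SelectionError, ConfigError):
            pass
    failures["piston"] = int(np.isnan(piston_vals).sum())
    piston = _desc.DescriptorSeries(
        name="piston_TM1_minus_TM2",
        units="A",
        index=times,
        values=piston_vals,
        protomer="dimer",
        index_name="frame_time_ns",
    )

    linker_lo, linker_hi = config.segment_ranges["linker"]
    linker_resnums = list(range(linker_lo, linker_hi + 1))
    linker_states = {}
    for p, cid in pm.items():
        mat = np.empty((n, len(linker_resnums)), dtype=object)
        for i, frame in enumerate(traj):
            _, per_res = _desc.linker_state(frame, cid, linker_resnums)
            mat[i] = [_STATE_CODE[per_res[r]] for r in linker_resnums]
        linker_states[p] = pd.DataFrame(mat, index=times, columns=linker_resnums)

    for key, count in failures.items():
        if count > 0:
            log.warning("descriptor %s: %d flagged/missing values", key, count)
    worst = {k: v for k, v in failures.items() if v > 0.5 * n}
    if worst:
        raise ConfigError(
            f"descriptors failing on >50% of frames: {sorted(worst)}; "
            "check segment definitions against the topology"
        )

    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p, series in contact.items():
        histograms[f"contact_{p}"] = make_histogram(series.values, config.distance_bin_A)
    for p, series in crick_series.items():
        for num in config.crick_resnums:
            histograms[f"crick_{num}_{p}"] = make_histogram(
                series.column(num), config.angle_bin_deg
            )
    histograms["piston"] = make_histogram(piston.values, config.distance_bin_A)

    return AnalysisResult(
        config=config,
        frame_times=times,
        crick=crick_series,
        contact=contact,
        profiles=profiles,
        piston=piston,
        linker_states=linker_states,
        histograms=histograms,
        failure_counts=failures,
    )


def overlay_reference(
    result: AnalysisResult, reference_models: Mapping[str, StructureModel]
) -> dict[str, dict[str, object]]:
    """Evaluate each descriptor once per reference structure (crystal overlay).

    Returns {reference label -> {descriptor -> value}}; references missing a
    needed residue contribute a warning and skip that descriptor only.
    The overlays are also attached to ``result``.
    """
    config = result.config
    pm = config.protomer_map
    overlays: dict[str, dict[str, object]] = {}
    for label, model in reference_models.items():
        entry: dict[str, object] = {}
        for p, _cid in pm.items():
            try:
                entry[f"contact_{p}"] = _desc.intra_protomer_ca_distance(
                    model, pm, p, *config.contact_pair
                )
            except SelectionError as exc:
                warnings.warn(f"reference {label}: contact skipped ({exc})")
        try:
            bundle = config.bundle_line(model)
            seg = config.segment("H1", "A")
            for p, _cid in pm.items():
                seg_p = config.segment("H1", p)
                vals = _crick.crick_angles_model(
                    model, seg_p, config.crick_resnums, bundle
                )
                for num, v in vals.items():
                    entry[f"crick_{num}_{p}"] = v
            entry["piston"] = _desc.piston_shift(
                model, config.segments("TM1"), config.segments("TM2"), bundle
            )
        except (SelectionError, ConfigError) as exc:
            warnings.warn(f"reference {label}: axis descriptors skipped ({exc})")
        for name, (lo, hi) in config.profile_ranges.items():
            prof = _desc.cross_protomer_distance_profile(
                model, pm, list(range(lo, hi + 1))
            )
            entry[f"profile_{name}"] = dict(zip(prof.index.tolist(), prof.values))
        overlays[label] = entry
    result._overlays = overlays
    return overlays


def export_snapshots(
    traj: Trajectory, config: AnalysisConfig, path
) -> list[float]:
    """Write aligned snapshots over the trailing window as a multi-model PDB.

    Snapshots target times t_end - T + k*stride (k = 1..T/stride); the
    nearest frame is used, each frame at most once.  Every snapshot is
    superposed onto the first using the CA atoms of the configured
    alignment set from both protomers.  Returns the snapshot times.
    """
    win = window_last(traj, config.window_last_ns)
    t_end = traj.frame_times[-1]
    t0 = t_end - config.window_last_ns
    n_snap = int(round(config.window_last_ns / config.snapshot_stride_ns))
    targets = t0 + config.snapshot_stride_ns * np.arange(1, n_snap + 1)

    chosen: list[int] = []
    for t in targets:
        order = np.argsort(np.abs(win.frame_times - t))
        for idx in order:
            if idx not in chosen:
                chosen.append(int(idx))
                break
    chosen.sort()

    align_set = _both_chains(config.snapshot_align_ranges, config.protomer_map)
    models = []
    ref = win.frames[chosen[0]]
    for k, idx in enumerate(chosen):
        frame = win.frames[idx]
        if k == 0:
            models.append(frame.copy())
            continue
        try:
            sup = kabsch_superpose(ref, frame, align_set)
            models.append(sup.apply_model(frame))
        except SelectionError as exc:
            warnings.warn(f"snapshot alignment set missing ({exc}); exporting unaligned")
            models.append(frame.copy())
    write_structure(models, path)
    return [float(win.frame_times[i]) for i in chosen]


@dataclass
class TwoStateComparison:
    """Differences between two conformational states after core superposition.

    All fields are state2 - state1 (the sign flips if the arguments swap).
    """

    crick_change: dict[str, dict[int, float]]  # protomer -> resnum -> deg
    profile_change: dict[str, dict[int, float]]  # set name -> resnum -> A
    axial_tm1_vs_tm2: dict[str, dict[int, float]]  # protomer -> TM1 resnum -> A
    axial_h1_vs_h4: dict[str, dict[int, float]]  # protomer -> H1 resnum -> A
    linker_states: dict[str, dict[str, str]]  # state label -> protomer -> state
    summary: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, d in self.crick_change.items():
            for num, v in d.items():
                rows.append(("crick_change_deg", p, num, v))
        for name, d in self.profile_change.items():
            for num, v in d.items():
                rows.append((f"profile_change_{name}_A", "dimer", num, v))
        for p, d in self.axial_tm1_vs_tm2.items():
            for num, v in d.items():
                rows.append(("axial_TM1_vs_TM2_A", p, num, v))
        for p, d in self.axial_h1_vs_h4.items():
            for num, v in d.items():
                rows.append(("axial_H1_vs_H4_A", p, num, v))
        return pd.DataFrame(rows, columns=["descriptor", "protomer", "resnum", "value"])


def _axial_displacement(
    state1: StructureModel,
    state2: StructureModel,
    moving: SegmentDef,
    anchor: SegmentDef,
    z: Line,
) -> dict[int, float]:
    """Per-residue z-displacement of ``moving`` after superposing state2 onto
    state1 using the ``anchor`` segment CA atoms."""
    anchor_set = [(anchor.chain_id, n) for n in anchor.resnums]
    sup = kabsch_superpose(state1, state2, anchor_set)
    moved = sup.apply_model(state2)
    out = {}
    for num in moving.resnums:
        d = moved.ca(moving.chain_id, num) - state1.ca(moving.chain_id, num)
        out[num] = float(np.dot(d, z.direction))
    return out


def compare_two_states(
    state1: StructureModel,
    state2: StructureModel,
    config: AnalysisConfig | None = None,
) -> TwoStateComparison:
    """Conformational differences (state2 - state1) between two dimers.

    After superposition on the configured core residue set: per-residue
    Crick-angle change over H1, cross-protomer distance changes for both
    profile sets, and per-residue axial (piston) displacement of TM1
    measured relative to TM2 and of H1 relative to H4.
    """
    config = config or AnalysisConfig()
    pm = config.protomer_map
    for model in (state1, state2):
        if len(model.chain_ids) < 2:
            raise ConfigError("two-state comparison needs dimeric models")
    config.validate(state1)
    config.validate(state2)

    core = _both_chains(config.compare_align_ranges, pm)
    sup = kabsch_superpose(state1, state2, core)
    state2_aligned = sup.apply_model(state2)

    z = config.bundle_line(state1)

    crick_change: dict[str, dict[int, float]] = {}
    bundle1 = z
    bundle2 = config.bundle_line(state2_aligned)
    for p, _cid in pm.items():
        seg = config.segment("H1", p)
        resnums = list(seg.resnums)
        v1 = _crick.crick_angles_model(state1, seg, resnums, bundle1)
        v2 = _crick.crick_angles_model(state2_aligned, seg, resnums, bundle2)
        crick_change[p] = {
            n: float(_crick.circular_difference(v2[n], v1[n]))
            for n in resnums
            if np.isfinite(v1[n]) and np.isfinite(v2[n])
        }

    profile_change: dict[str, dict[int, float]] = {}
    for name, (lo, hi) in config.profile_ranges.items():
        resnums = list(range(lo, hi + 1))
        p1 = _desc.cross_protomer_distance_profile(state1, pm, resnums)
        p2 = _desc.cross_protomer_distance_profile(state2_aligned, pm, resnums)
        profile_change[name] = {
            n: float(b - a) for n, a, b in zip(resnums, p1.values, p2.values)
        }

    axial_tm1: dict[str, dict[int, float]] = {}
    axial_h1: dict[str, dict[int, float]] = {}
    for p, _cid in pm.items():
        axial_tm1[p] = _axial_displacement(
            state1, state2, config.segment("TM1", p), config.segment("TM2", p), z
        )
        axial_h1[p] = _axial_displacement(
            state1, state2, config.segment("H1", p), config.segment("H4", p), z
        )

    linker_states = {}
    for label, model in (("state1", state1), ("state2", state2)):
        linker_states[label] = {
            p: _desc.linker_state(
                model, cid, list(range(*_incl(config.segment_ranges["linker"])))
            )[0]
            for p, cid in pm.items()
        }

    def _absmax(d: dict[str, dict[int, float]]) -> float:
        vals = [v for sub in d.values() for v in sub.values()]
        return float(max(np.abs(vals))) if vals else float("nan")

    def _mean(d: dict[str, dict[int, float]]) -> float:
        vals = [v for sub in d.values() for v in sub.values()]
        return float(np.mean(vals)) if vals else float("nan")

    summary = {
        "max_axial_TM1_vs_TM2_A": _absmax(axial_tm1),
        "mean_axial_TM1_vs_TM2_A": _mean(axial_tm1),
        "max_axial_H1_vs_H4_A": _absmax(axial_h1),
        "mean_axial_H1_vs_H4_A": _mean(axial_h1),
        "mean_crick_change_H1_deg": float(
            _crick.circular_mean(
                np.array([v for sub in crick_change.values() for v in sub.values()])
            )
        ),
        "core_superposition_rmsd_A": sup.rmsd,
    }
    return TwoStateComparison(
        crick_change=crick_change,
        profile_change=profile_change,
        axial_tm1_vs_tm2=axial_tm1,
        axial_h1_vs_h4=axial_h1,
        linker_states=linker_states,
        summary=summary,
    )


def _incl(lohi: tuple[int, int]) -> tuple[int, int]:
    return lohi[0], lohi[1] + 1


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------


def write_outputs(result: AnalysisResult, outdir) -> list[Path]:
    """Write the standard CSV products of a run; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for p, series in result.crick.items():
        for j, num in enumerate(series.resnums):
            for t, v in zip(series.frame_times, series.angles[:, j]):
                rows.append((t, p, int(num), v))
    path = outdir / "crick_angles.csv"
    pd.DataFrame(rows, columns=["frame_time_ns", "protomer", "resnum", "crick_deg"]).to_csv(
        path, index=False
    )
    written.append(path)

    rows = []
    for p, series in result.contact.items():
        for t, v in zip(series.index, series.values):
            rows.append((t, p, v))
    path = outdir / "contact_distance.csv"
    pd.DataFrame(rows, columns=["frame_time_ns", "protomer", "distance_A"]).to_csv(
        path, index=False
    )
    written.append(path)

    for name, df in result.profiles.items():
        path = outdir / f"cross_profile_{name}.csv"
        long = df.stack().rename("distance_A").reset_index()
        long.columns = ["frame_time_ns", "resnum", "distance_A"]
        long.to_csv(path, index=False)
        written.append(path)

    path = outdir / "piston_shift.csv"
    pd.DataFrame(
        {"frame_time_ns": result.piston.index, "piston_A": result.piston.values}
    ).to_csv(path, index=False)
    written.append(path)

    for p, df in result.linker_states.items():
        path = outdir / f"linker_states_{p}.csv"
        df.rename_axis("frame_time_ns").to_csv(path)
        written.append(path)
    return written


def plot_histograms(result: AnalysisResult, outdir) -> list[Path]:
    """Optional PNG histograms of the per-frame descriptor distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (counts, edges) in result.histograms.items():
        if counts.size == 0:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
        ax.set_xlabel(name)
        ax.set_ylabel("frames")
        fig.tight_layout()
        path = outdir / f"hist_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
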
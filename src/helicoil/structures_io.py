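"""Structures, trajectories, segment definitions and descriptor tables.

Conventions established here and relied on by every other module:

* residue numbers are author numbering (1-based), never re-indexed;
* coordinates are in Angstrom, frame times in nanoseconds;
* only backbone atoms (N, CA, C, O) are kept -- CA is mandatory for a
  residue to be represented, the others are optional but flagged;
* multi-model PDB is the canonical interchange trajectory dialect; XTC/DCD
  are read through MDAnalysis when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyModelError,
    FormatError,
    SelectionError,
    TopologyError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Helix-role residue ranges of the nitrate sensor receptor dimer analysed
#: throughout: first transmembrane helix TM1, the sensor-TM linker, the
#: membrane-proximal part of sensor helix H1, sensor helix H4 and the second
#: transmembrane helix TM2.  H1/H4 cover the bundle-forming portions that the
#: synthetic generator models explicitly.
DEFAULT_SEGMENT_RANGES: dict[str, tuple[int, int]] = {
    "TM1": (14, 34),
    "linker": (34, 38),
    "H1": (39, 60),
    "H4": (120, 146),
    "TM2": (147, 167),
}

SEGMENT_ROLES = ("TM1", "H1", "H4", "TM2", "linker", "custom")


@dataclass
class ResidueRecord:
    """One residue with its backbone atom coordinates (Angstrom)."""

    chain_id: str
    resnum: int
    resname: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, xyz in self.atoms.items():
            if name not in BACKBONE_ATOMS:
                continue
            arr = np.asarray(xyz, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise FormatError(
                    f"non-finite coordinates for {self.chain_id}/{self.resnum}/{name}"
                )
            clean[name] = arr
        self.atoms = clean

    @property
    def ca(self) -> np.ndarray:
        try:
            return self.atoms["CA"]
        except KeyError:
            raise SelectionError(
                f"residue {self.chain_id}/{self.resnum} has no CA atom"
            ) from None

    def has(self, name: str) -> bool:
        return name in self.atoms

    @property
    def missing_backbone(self) -> tuple[str, ...]:
        """Backbone atom names absent from this residue (flagged, never guessed)."""
        return tuple(a for a in BACKBONE_ATOMS if a not in self.atoms)

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.chain_id,
            self.resnum,
            self.resname,
            {k: v.copy() for k, v in self.atoms.items()},
        )


@dataclass
class StructureModel:
    """One conformer: ordered residues grouped by chain."""

    chains: dict[str, list[ResidueRecord]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyModelError("model has no chains")
        for cid, residues in self.chains.items():
            residues.sort(key=lambda r: r.resnum)
            nums = [r.resnum for r in residues]
            if len(set(nums)) != len(nums):
                raise FormatError(f"duplicate residue numbers in chain {cid}")

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str) -> list[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise SelectionError(f"no chain {chain_id!r} in model") from None

    def residue(self, chain_id: str, resnum: int) -> ResidueRecord:
        for r in self.residues(chain_id):
            if r.resnum == resnum:
                return r
        raise SelectionError(f"residue {chain_id}/{resnum} not in model")

    def has_residue(self, chain_id: str, resnum: int) -> bool:
        return chain_id in self.chains and any(
            r.resnum == resnum for r in self.chains[chain_id]
        )

    def ca(self, chain_id: str, resnum: int) -> np.ndarray:
        return self.residue(chain_id, resnum).ca

    def ca_coords(self, selection: Iterable[tuple[str, int]]) -> np.ndarray:
        """CA coordinates for (chain, resnum) pairs, in the given order."""
        return np.array([self.ca(c, r) for c, r in selection], dtype=float)

    def n_ca(self) -> int:
        return sum(1 for rs in self.chains.values() for r in rs if r.has("CA"))

    def all_atoms(self) -> Iterable[tuple[str, int, str, np.ndarray]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for name in BACKBONE_ATOMS:
                    if name in res.atoms:
                        yield cid, res.resnum, name, res.atoms[name]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with every coordinate mapped to ``R @ x + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float).reshape(3)
        new = self.copy()
        for residues in new.chains.values():
            for res in residues:
                for name in res.atoms:
                    res.atoms[name] = R @ res.atoms[name] + t
        return new

    def copy(self) -> "StructureModel":
        return StructureModel(
            {cid: [r.copy() for r in rs] for cid, rs in self.chains.items()},
            label=self.label,
        )

    def topology_key(self):
        return tuple(
            (
                cid,
                tuple(
                    (r.resnum, r.resname, tuple(sorted(r.atoms)))
                    for r in residues
                ),
            )
            for cid, residues in sorted(self.chains.items())
        )


@dataclass
class SegmentDef:
    """A helix role bound to a chain and an inclusive author-numbering range."""

    role: str
    chain_id: str
    first_resnum: int
    last_resnum: int

    def __post_init__(self) -> None:
        if self.role not in SEGMENT_ROLES:
            raise FormatError(f"unknown segment role {self.role!r}")
        if self.first_resnum > self.last_resnum:
            raise FormatError(
                f"segment {self.role}: first {self.first_resnum} > last {self.last_resnum}"
            )

    @property
    def resnums(self) -> range:
        return range(self.first_resnum, self.last_resnum + 1)

    def __len__(self) -> int:
        return self.last_resnum - self.first_resnum + 1

    def select(self, model: StructureModel) -> list[ResidueRecord]:
        """All residues of the range; raises if any is missing from the model."""
        out = []
        for num in self.resnums:
            out.append(model.residue(self.chain_id, num))
        return out

    def ca_coords(self, model: StructureModel) -> np.ndarray:
        return np.array([r.ca for r in self.select(model)])


@dataclass(frozen=True)
class ProtomerMap:
    """Protomer labels A/B of the homodimer mapped onto chain ids."""

    A: str
    B: str

    def __post_init__(self) -> None:
        if self.A == self.B:
            raise FormatError("protomers must map to distinct chains")

    def chain(self, protomer: str) -> str:
        if protomer == "A":
            return self.A
        if protomer == "B":
            return self.B
        raise SelectionError(f"unknown protomer label {protomer!r}")

    def items(self):
        return (("A", self.A), ("B", self.B))


@dataclass
class Trajectory:
    """Time-ordered frames sharing one topology; times in ns, strictly increasing."""

    frames: list[StructureModel]
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frames) != len(self.frame_times):
            raise TopologyError("frame_times length differs from frame count")
        if len(self.frames) == 0:
            raise TopologyError("empty trajectory")
        if np.any(np.diff(self.frame_times) <= 0):
            raise TopologyError("frame times must be strictly increasing")
        key = self.frames[0].topology_key()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.topology_key() != key:
                raise TopologyError(f"frame {i} topology differs from frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def span_ns(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, idx) -> StructureModel:
        return self.frames[idx]


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------


def _model_from_gemmi(gmodel: gemmi.Model, label: str) -> StructureModel:
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in gmodel:
        records: dict[int, ResidueRecord] = {}
        for res in chain:
            # highest-occupancy conformer wins for alternate locations
            picked: dict[str, tuple[float, np.ndarray]] = {}
            for atom in res:
                name = atom.name.strip()
                if name not in BACKBONE_ATOMS:
                    continue
                occ = atom.occ if atom.occ > 0 else 1.0
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if name not in picked or occ > picked[name][0]:
                    picked[name] = (occ, pos)
            if not picked:
                continue
            num = res.seqid.num
            rec = ResidueRecord(
                chain.name, num, res.name, {k: v for k, (_, v) in picked.items()}
            )
            if num in records:  # altloc split across residue entries
                records[num].atoms.update(
                    {k: v for k, v in rec.atoms.items() if k not in records[num].atoms}
                )
            else:
                records[num] = rec
        if records:
            chains.setdefault(chain.name, []).extend(records.values())
    if not chains:
        raise EmptyModelError(f"{label}: no backbone atoms found")
    model = StructureModel(chains, label=label)
    if model.n_ca() == 0:
        raise EmptyModelError(f"{label}: no CA atoms found")
    return model


def _read_gemmi(path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: file contains no models")
    return st


def read_structure(path, format: str = "pdb") -> StructureModel:
    """Read a single-conformer structure (first model of a multi-model file)."""
    if format not in ("pdb", "auto"):
        raise FormatError(f"unsupported structure format {format!r}")
    st = _read_gemmi(path)
    return _model_from_gemmi(st[0], label=Path(path).stem)


def read_trajectory(
    coords_path,
    frame_dt_ns: float | None = None,
    topology_path=None,
    frame_times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB (canonical) or XTC/DCD.

    Binary formats need ``topology_path`` (a PDB) and MDAnalysis.  Times are
    ``frame_index * frame_dt_ns`` unless ``frame_times`` is given explicitly.
    """
    suffix = Path(coords_path).suffix.lower()
    if suffix in (".pdb", ".ent", ""):
        st = _read_gemmi(coords_path)
        frames = [
            _model_from_gemmi(m, label=f"{Path(coords_path).stem}:{i}")
            for i, m in enumerate(st)
        ]
    elif suffix in (".xtc", ".dcd", ".trr"):
        if topology_path is None:
            raise TopologyError(f"{suffix} trajectories need a PDB topology_path")
        frames = _read_binary_trajectory(topology_path, coords_path)
    else:
        raise FormatError(f"unsupported trajectory format {suffix!r}")

    if frame_times is not None:
        times = np.asarray(frame_times, float)
    elif frame_dt_ns is not None:
        times = np.arange(len(frames), dtype=float) * float(frame_dt_ns)
    else:
        raise TopologyError("provide frame_dt_ns or frame_times")
    return Trajectory(frames, times)


def _read_binary_trajectory(topology_path, coords_path) -> list[StructureModel]:
    import MDAnalysis as mda  # optional dependency, imported on demand

    u = mda.Universe(str(topology_path), str(coords_path))
    sel = u.select_atoms("name N CA C O and protein")
    if sel.n_atoms == 0:
        raise EmptyModelError(f"{topology_path}: no backbone atoms selected")
    frames: list[StructureModel] = []
    for ts in u.trajectory:
        chains: dict[str, dict[int, ResidueRecord]] = {}
        for atom in sel:
            cid = atom.segid.strip() or getattr(atom, "chainID", "A")
            num = int(atom.resid)
            rec = chains.setdefault(cid, {}).setdefault(
                num, ResidueRecord(cid, num, atom.resname, {})
            )
            rec.atoms[atom.name] = np.array(atom.position, dtype=float)
        frames.append(
            StructureModel(
                {cid: list(rs.values()) for cid, rs in chains.items()},
                label=f"{Path(coords_path).stem}:{ts.frame}",
            )
        )
    return frames


def write_structure(models, path) -> None:
    """Write a StructureModel (or a sequence -> multi-model PDB) to ``path``."""
    if isinstance(models, StructureModel):
        models = [models]
    st = gemmi.Structure()
    st.name = models[0].label or "helicoil"
    for i, model in enumerate(models, start=1):
        gmodel = gemmi.Model(i)
        for cid, residues in model.chains.items():
            gchain = gemmi.Chain(cid)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.resname
                gres.seqid = gemmi.SeqId(res.resnum, " ")
                for name in BACKBONE_ATOMS:
                    if name not in res.atoms:
                        continue
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(name[0])
                    x, y, z = res.atoms[name]
                    atom.pos = gemmi.Position(x, y, z)
                    atom.occ = 1.0
                    gres.add_atom(atom)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    write_structure(traj.frames, path)


# ---------------------------------------------------------------------------
# Descriptor tables
# ---------------------------------------------------------------------------


def write_descriptor_table(series_collection, path) -> None:
    """Write named series sharing one index to a CSV (NaN -> empty cell).

    Each series must expose ``name``, ``units``, ``index`` and ``values``
    (optionally ``protomer``); all indices must agree element-wise.
    """
    series = list(series_collection)
    if not series:
        pd.DataFrame().to_csv(path, index=False)
        return
    index = np.asarray(series[0].index)
    data: dict[str, np.ndarray] = {"index": index}
    for s in series:
        if len(np.asarray(s.index)) != len(index) or np.any(
            np.asarray(s.index) != index
        ):
            raise AlignmentError(f"series {s.name!r} index mismatch")
        col = s.name
        protomer = getattr(s, "protomer", None)
        if protomer and protomer != "dimer":
            col = f"{col}_{protomer}"
        data[f"{col} ({s.units})"] = np.asarray(s.values, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_descriptor_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Segment config: flat key-value text, one "role chain first last" per line
# ---------------------------------------------------------------------------


def read_segment_config(path) -> list[SegmentDef]:
    segments = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").replace(",", " ").split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'role chain first last'")
        role, chain, first, last = parts
        try:
            segments.append(SegmentDef(role, chain, int(first), int(last)))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return segments


def write_segment_config(segments: Iterable[SegmentDef], path) -> None:
    lines = [
        f"{s.role} {s.chain_id} {s.first_resnum} {s.last_resnum}" for s in segments
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def default_segments(protomers: ProtomerMap | Mapping[str, str]) -> dict[str, list[SegmentDef]]:
    """Default helix-role segments for both protomer chains."""
    if isinstance(protomers, ProtomerMap):
        items = protomers.items()
    else:
        items = protomers.items()
    out: dict[str, list[SegmentDef]] = {}
    for role, (first, last) in DEFAULT_SEGMENT_RANGES.items():
        out[role] = [SegmentDef(role, cid, first, last) for _, cid in items]
    return out
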
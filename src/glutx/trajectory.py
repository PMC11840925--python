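"""Trajectory data model and I/O.

The package-internal trajectory is a light container of per-frame,
per-ligand centre-of-mass positions in a membrane-centred frame:
``Z = 0`` at the bilayer centre of mass, positive Z extracellular.
Trajectories come from the Brownian channel generator
(:mod:`glutx.channel`) or are extracted from atomistic MD output via
MDAnalysis (:func:`load_md_trajectory`).

On disk a trajectory is plain delimited text with header
``frame,time_ns,ligand_id,x_A,y_A,z_A`` (rows sorted by frame then
ligand id) plus an optional JSON sidecar ``<path>.meta.json`` holding
box dimensions and provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "load_md_trajectory",
]


class TrajectoryFormatError(ValueError):
    """Raised when an on-disk trajectory violates the internal format."""


@dataclass
class Trajectory:
    """Per-frame, per-ligand 3-D positions in the membrane frame.

    Parameters
    ----------
    times : (F,) array
        Frame times in ns, strictly increasing.
    ligand_ids : list of str
        Stable ligand identifiers; the second axis of ``positions``.
    positions : (F, N, 3) array
        Cartesian positions in Å. ``Z = 0`` is the membrane centre and
        positive Z is extracellular.
    box : (3,) or (F, 3) array, optional
        Orthorhombic box edge lengths in Å.
    pore_lining_z : dict, optional
        Per-reference-atom Z series (label -> (F,) array) of pore-lining
        atoms, for plotting Z-trace context.
    atom_positions : dict, optional
        ligand_id -> (F, n_atoms, 3) heavy-atom coordinates, retained
        from atomistic input for distance/H-bond analyses.
    atom_names : dict, optional
        ligand_id -> list of atom names matching ``atom_positions``.
    meta : dict
        Free-form provenance (generator config, selections, seed ...).
    """

    times: np.ndarray
    ligand_ids: list[str]
    positions: np.ndarray
    box: np.ndarray | None = None
    pore_lining_z: dict[str, np.ndarray] | None = None
    atom_positions: dict[str, np.ndarray] | None = None
    atom_names: dict[str, list[str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        F, N = self.n_frames, self.n_ligands
        if self.positions.shape != (F, N, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{F} frames x {N} ligands x 3"
            )
        if F > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if len(set(self.ligand_ids)) != N:
            raise ValueError("ligand_ids must be unique")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def duration(self) -> float:
        """Total spanned time in ns (0 for <2 frames)."""
        return float(self.times[-1] - self.times[0]) if self.n_frames > 1 else 0.0

    def z(self, ligand_id: str | None = None) -> np.ndarray:
        """Z series of one ligand, or the (F, N) matrix of all of them."""
        if ligand_id is None:
            return self.positions[:, :, 2]
        return self.positions[:, self.ligand_ids.index(ligand_id), 2]

    def has_atoms(self) -> bool:
        return bool(self.atom_positions)


_COLUMNS = ["frame", "time_ns", "ligand_id", "x_A", "y_A", "z_A"]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory to the internal delimited-text format.

    Positions and times keep >= 9 significant digits so a read back is
    lossless at double precision for all downstream statistics. Box and
    meta go to a ``<path>.meta.json`` sidecar; pore-lining reference
    atoms, when present, to ``<path>.pore.csv`` with header
    ``frame,atom_label,z_A``.
    """
    path = Path(path)
    F, N = trajectory.n_frames, trajectory.n_ligands
    frames = np.repeat(np.arange(F), N)
    order = np.argsort(trajectory.ligand_ids, kind="stable")
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_ns": np.repeat(trajectory.times, N),
            "ligand_id": np.tile(np.asarray(trajectory.ligand_ids)[order], F),
            "x_A": trajectory.positions[:, order, 0].ravel(),
            "y_A": trajectory.positions[:, order, 1].ravel(),
            "z_A": trajectory.positions[:, order, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")

    sidecar: dict = dict(trajectory.meta)
    if trajectory.box is not None:
        sidecar["box_A"] = np.asarray(trajectory.box).tolist()
    if sidecar:
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))
    if trajectory.pore_lining_z:
        rows = []
        for label, zs in trajectory.pore_lining_z.items():
            for f, z in enumerate(np.asarray(zs)):
                rows.append((f, label, z))
        pd.DataFrame(rows, columns=["frame", "atom_label", "z_A"]).to_csv(
            Path(str(path) + ".pore.csv"), index=False, float_format="%.10g"
        )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises
    ------
    TrajectoryFormatError
        On missing columns, duplicated (frame, ligand) pairs or
        non-monotone frame times; the message names the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["frame", "ligand_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TrajectoryFormatError(
            f"{path}: duplicate entry for frame {int(row['frame'])}, "
            f"ligand {row['ligand_id']}"
        )
    frames = np.sort(df["frame"].unique())
    ligand_ids = sorted(df["ligand_id"].astype(str).unique())
    F, N = len(frames), len(ligand_ids)
    if len(df) != F * N:
        counts = df.groupby("frame")["ligand_id"].count()
        bad = counts[counts != N].index[0]
        raise TrajectoryFormatError(
            f"{path}: frame {bad} does not contain every ligand exactly once"
        )
    df = df.sort_values(["frame", "ligand_id"], kind="stable")
    times = df.groupby("frame", sort=True)["time_ns"].first().to_numpy()
    if F > 1 and not np.all(np.diff(times) > 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise TrajectoryFormatError(
            f"{path}: non-monotone time at frame {frames[bad]}"
        )
    positions = df[["x_A", "y_A", "z_A"]].to_numpy().reshape(F, N, 3)

    meta_path = Path(str(path) + ".meta.json")
    meta: dict = {}
    box = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "box_A" in meta:
            box = np.asarray(meta.pop("box_A"), dtype=float)
    return Trajectory(
        times=times,
        ligand_ids=[str(l) for l in ligand_ids],
        positions=positions,
        box=box,
        meta=meta,
    )


def load_md_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    ligand_selection: str = "resname BGLC",
    membrane_selection: str = "resname DPPC",
    keep_atoms: bool = True,
) -> Trajectory:
    """Extract per-ligand heavy-atom CoM Z-series from an MD trajectory.

    Topology may be PDB/PSF/GRO and coordinates DCD/XTC/TRR (anything
    MDAnalysis reads). Each residue matched by ``ligand_selection``
    becomes one ligand; its centre of mass is computed over heavy atoms
    only, so the result is insensitive to how hydrogens are represented.
    All Z values are recentred by subtracting the membrane selection's
    centre-of-mass Z frame by frame, putting the bilayer midplane at
    Z = 0.

    Heavy-atom coordinates per ligand are retained (``keep_atoms``) so
    that exchange classification can use minimum heavy-atom distances
    and the H-bond descriptor stays applicable.
    """
    import MDAnalysis as mda

    if not str(ligand_selection).strip() or not str(membrane_selection).strip():
        raise ValueError("ligand and membrane selections must be non-empty")
    if coords_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(coords_path))
    ligands_all = u.select_atoms(ligand_selection)
    membrane = u.select_atoms(membrane_selection)
    if len(ligands_all) == 0:
        raise ValueError(f"ligand selection {ligand_selection!r} matched no atoms")
    if len(membrane) == 0:
        raise ValueError(f"membrane selection {membrane_selection!r} matched no atoms")

    groups = []
    for i, res in enumerate(ligands_all.residues):
        heavy = res.atoms.select_atoms("not name H* and not type H*")
        if len(heavy) == 0:  # fall back if names are uninformative
            heavy = res.atoms
        groups.append((f"{res.resname}_{res.resid}_{i}", heavy))
    ligand_ids = [g[0] for g in groups]

    F = len(u.trajectory)
    positions = np.empty((F, len(groups), 3))
    boxes = np.empty((F, 3))
    atom_positions: dict[str, list[np.ndarray]] = {lid: [] for lid in ligand_ids}
    for fi, ts in enumerate(u.trajectory):
        z_mem = membrane.center_of_mass()[2]
        for gi, (lid, heavy) in enumerate(groups):
            com = heavy.center_of_mass()
            positions[fi, gi] = com - [0.0, 0.0, z_mem]
            if keep_atoms:
                atom_positions[lid].append(
                    heavy.positions - [0.0, 0.0, z_mem]
                )
        boxes[fi] = ts.dimensions[:3] if ts.dimensions is not None else np.nan
    times = np.array([ts.time / 1000.0 for ts in u.trajectory])  # ps -> ns
    if F > 1 and not np.all(np.diff(times) > 0):
        warnings.warn("input frame times not increasing; using frame index as ns")
        times = np.arange(F, dtype=float)

    traj = Trajectory(
        times=times,
        ligand_ids=ligand_ids,
        positions=positions,
        box=boxes if np.isfinite(boxes).all() else None,
        atom_positions=(
            {lid: np.asarray(v) for lid, v in atom_positions.items()}
            if keep_atoms
            else None
        ),
        atom_names={lid: list(g.names) for (lid, g) in groups} if keep_atoms else None,
        meta={
            "source_topology": str(topology_path),
            "source_coordinates": str(coords_path) if coords_path else None,
            "ligand_selection": ligand_selection,
            "membrane_selection": membrane_selection,
            "com": "heavy atoms",
        },
    )
    return traj
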
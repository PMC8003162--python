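"""Readers/writers for trajectories and volumetric grids; alignment utilities.

Formats
-------
* extended-XYZ text: one block per frame, a ``time=... box=...`` comment
  line, four decimal places per coordinate; the particle table travels in a
  TSV sidecar (``<stem>.particles.tsv``).
* internal binary: a ``.npz`` container with exact float64 coordinates.
* OpenDX scalar fields for density / free-energy grids, readable by the
  standard molecular viewers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import AlignmentError, SelectionError, TrajectoryFormatError
from .toy_dynamics import Trajectory


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D voxel grid.

    Voxel (i, j, k) covers the half-open box
    [origin + i*spacing, origin + (i+1)*spacing) per axis; a point maps to
    voxel floor((x - origin)/spacing) and points on the upper boundary of the
    grid are discarded.
    """

    origin: tuple
    shape: tuple
    spacing: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape components must be >= 1")

    @classmethod
    def covering(cls, lo, hi, spacing: float = 2.0) -> "GridSpec":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        shape = np.ceil((hi - lo) / spacing - 1e-12).astype(int)
        return cls(origin=tuple(lo), shape=tuple(shape), spacing=spacing)

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing

    def voxel_indices(self, points: np.ndarray):
        """(indices, inside) for an array of points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        idx = np.floor((pts - np.asarray(self.origin)) / self.spacing).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        return idx, inside

    def center_points(self) -> np.ndarray:
        """All voxel centers, shape (*shape, 3)."""
        axes = [self.centers(a) for a in range(3)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)


@dataclass(frozen=True)
class SelectionQuery:
    """Declarative particle selection on a trajectory's particle table."""

    role: str | None = None
    molecule_id: int | None = None
    monomer_index: int | None = None
    name: str | None = None
    particle_ids: tuple | None = None

    def resolve(self, table: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(table), dtype=bool)
        if self.role is not None:
            mask &= (table["role"] == self.role).to_numpy()
        if self.molecule_id is not None:
            mask &= (table["molecule_id"] == self.molecule_id).to_numpy()
        if self.monomer_index is not None:
            mask &= (table["monomer_index"] == self.monomer_index).to_numpy()
        if self.name is not None:
            mask &= (table["name"] == self.name).to_numpy()
        if self.particle_ids is not None:
            mask &= table["particle_id"].isin(self.particle_ids).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection {self} matches no particles")
        return idx


def write_trajectory(traj: Trajectory, path, format: str = "xyz") -> Path:
    """Write a trajectory; returns the main file path.

    ``xyz`` writes extended-XYZ text (coordinates to 1e-4 Å) plus a
    ``.particles.tsv`` sidecar; ``npz`` writes the exact binary container.
    """
    path = Path(path)
    if format == "npz":
        np.savez_compressed(
            path,
            times=traj.times,
            coords=traj.coords,
            box_lengths=np.asarray(traj.box_lengths),
            particle_id=traj.table["particle_id"].to_numpy(np.int64),
            molecule_id=traj.table["molecule_id"].to_numpy(np.int64),
            monomer_index=traj.table["monomer_index"].to_numpy(np.int64),
            role=traj.table["role"].to_numpy(dtype="U16"),
            name=traj.table["name"].to_numpy(dtype="U16"),
        )
        return path
    if format != "xyz":
        raise ValueError(f"unknown trajectory format {format!r}")
    names = traj.table["name"].to_numpy()
    box = ",".join(f"{b:.6g}" for b in traj.box_lengths)
    buf = io.StringIO()
    for f in range(traj.n_frames):
        buf.write(f"{traj.n_particles}\n")
        buf.write(f"time={traj.times[f]:.9g} box={box}\n")
        frame = traj.coords[f]
        for i in range(traj.n_particles):
            buf.write(
                f"{names[i]} {frame[i, 0]:.4f} {frame[i, 1]:.4f} {frame[i, 2]:.4f}\n"
            )
    path.write_text(buf.getvalue())
    traj.table.to_csv(_sidecar_path(path), sep="\t", index=False)
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".particles.tsv")


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Malformed frames (inconsistent particle count, truncation) raise
    :class:`TrajectoryFormatError` carrying the frame index.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "xyz"
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            table = pd.DataFrame(
                {
                    "particle_id": data["particle_id"],
                    "molecule_id": data["molecule_id"],
                    "monomer_index": data["monomer_index"],
                    "role": data["role"].astype(str),
                    "name": data["name"].astype(str),
                }
            )
            return Trajectory(
                times=data["times"],
                coords=data["coords"],
                box_lengths=tuple(data["box_lengths"]),
                table=table,
            )
    lines = path.read_text().splitlines()
    frames = []
    times = []
    box = (0.0, 0.0, 0.0)
    pos = 0
    n_expected = None
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: bad particle-count line {lines[pos]!r}",
                frame_index=frame_idx,
            ) from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: particle count {n} != {n_expected}",
                frame_index=frame_idx,
            )
        if pos + 2 + n > len(lines):
            raise TrajectoryFormatError(
                f"frame {frame_idx}: truncated (expected {n} particle lines)",
                frame_index=frame_idx,
            )
        comment = lines[pos + 1]
        fields = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        try:
            times.append(float(fields["time"]))
            box = tuple(float(v) for v in fields["box"].split(","))
        except (KeyError, ValueError) as exc:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: bad comment line {comment!r}",
                frame_index=frame_idx,
            ) from exc
        frame = np.empty((n, 3))
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: bad particle line {lines[pos + 2 + i]!r}",
                    frame_index=frame_idx,
                )
            frame[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(frame)
        pos += 2 + n
        frame_idx += 1
    if not frames:
        raise TrajectoryFormatError("no frames found", frame_index=0)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        table = pd.read_csv(sidecar, sep="\t")
    else:
        table = pd.DataFrame(
            {
                "particle_id": np.arange(n_expected),
                "molecule_id": np.zeros(n_expected, dtype=int),
                "monomer_index": np.arange(n_expected),
                "role": "ligand",
                "name": "monomer",
            }
        )
    return Trajectory(
        times=np.asarray(times),
        coords=np.stack(frames),
        box_lengths=box,
        table=table,
    )


def kabsch_transform(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid motion (R, t) mapping ``mobile`` onto ``reference``.

    Least-squares superposition of point sets; raises AlignmentError for
    fewer than 3 points or a collinear reference set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape[0] < 3:
        raise AlignmentError("need at least 3 reference particles for alignment")
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise AlignmentError("reference particles are collinear; rotation undetermined")
    rot, _ = Rotation.align_vectors(ref_c, mobile - mobile.mean(axis=0))
    R = rot.as_matrix()
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    return R, t


def align_frames(traj: Trajectory, reference: SelectionQuery | None = None) -> Trajectory:
    """Superpose every frame's reference selection onto frame 0 (Kabsch).

    All particles of a frame are moved by that frame's rigid motion.
    Alignment treats coordinates as whole (unwrapped) molecules; with the
    rigid toy receptor it is an exact no-op, but real trajectories pass
    through the identical code path.
    """
    reference = reference or SelectionQuery(role="receptor")
    idx = traj.select(reference)
    ref0 = traj.coords[0, idx]
    aligned = np.empty_like(traj.coords)
    aligned[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        if np.array_equal(traj.coords[f, idx], ref0):
            # static (e.g. restrained-rigid) reference: exact identity motion
            aligned[f] = traj.coords[f]
            continue
        R, t = kabsch_transform(traj.coords[f, idx], ref0)
        aligned[f] = traj.coords[f] @ R.T + t
    return Trajectory(
        times=traj.times.copy(),
        coords=aligned,
        box_lengths=traj.box_lengths,
        table=traj.table.copy(),
    )


def write_density_dx(values: np.ndarray, grid: GridSpec, path) -> Path:
    """Write a scalar field as an OpenDX file (C-order data, cubic deltas).

    The written origin is the grid origin (voxel corner), matching the
    regular-positions convention used by molecular viewers.  Non-finite
    voxels are rejected with their indices listed.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.shape):
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    bad = np.argwhere(~np.isfinite(values))
    if len(bad):
        shown = ", ".join(str(tuple(int(v) for v in b)) for b in bad[:5])
        raise ValueError(f"non-finite values at voxel indices {shown}")
    nx, ny, nz = grid.shape
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    flat = values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.10g}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_density_dx(path) -> tuple:
    """Read an OpenDX scalar field back as (values, GridSpec)."""
    shape = None
    origin = None
    deltas = []
    data = []
    n_items = None
    for line in Path(path).read_text().splitlines():
        t = line.split()
        if not t:
            continue
        if t[0] == "object" and "gridpositions" in line:
            shape = tuple(int(v) for v in t[-3:])
        elif t[0] == "origin":
            origin = tuple(float(v) for v in t[1:4])
        elif t[0] == "delta":
            deltas.append([float(v) for v in t[1:4]])
        elif t[0] == "object" and "data follows" in line:
            n_items = int(t[t.index("items") + 1])
        elif n_items is not None and len(data) < n_items:
            try:
                data.extend(float(v) for v in t)
            except ValueError:
                continue
    spacing = deltas[0][0]
    values = np.asarray(data[:n_items]).reshape(shape, order="C")
    return values, GridSpec(origin=origin, shape=shape, spacing=spacing)
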
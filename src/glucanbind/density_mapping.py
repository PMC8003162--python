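"""3D occupancy-density maps of ligand monomers around a receptor.

The mean number density of selected monomers is accumulated on a regular
grid (2 Å spacing by default), normalised by the ambient (far-field)
concentration, and summarised by the enrichment statistic M — the maximum of
the local-to-ambient concentration ratio — together with the volume of the
iso-concentration region above a threshold (e.g. 30x or 8x ambient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import AmbientConcentrationError, DensityError
from .io_formats import GridSpec, SelectionQuery
from .toy_dynamics import ReceptorModel, Trajectory


@dataclass
class DensityGrid:
    """Voxel counts of (selected monomer, frame) events plus derived fields.

    ``concentration`` is counts/(n_frames * spacing³) in Å⁻³; the ratio field
    divides by the ambient concentration ``c_amb`` (set via
    :func:`ambient_concentration`).
    """

    spec: GridSpec
    counts: np.ndarray
    n_frames: int
    n_selected: int
    c_amb: float | None = None
    c_amb_mode: str | None = None

    def concentration(self) -> np.ndarray:
        return self.counts / (self.n_frames * self.spec.voxel_volume)

    def ratio(self) -> np.ndarray:
        if self.c_amb is None or self.c_amb <= 0:
            raise AmbientConcentrationError(
                "ambient concentration not set or non-positive; call "
                "ambient_concentration first (nominal mode if the far field is empty)"
            )
        return self.concentration() / self.c_amb


@dataclass
class DensitySummary:
    """Headline statistics of a density map at one iso-threshold."""

    M: float
    threshold: float
    volume_above: float
    n_voxels_above: int
    c_amb: float
    voxels: pd.DataFrame = field(repr=False, default=None)

    @property
    def argmax_center(self) -> tuple:
        row = self.voxels.iloc[0]
        return (row["x"], row["y"], row["z"])


def monomer_positions(traj: Trajectory, selection: SelectionQuery) -> np.ndarray:
    """Per-frame monomer centre-of-mass positions, shape (n_frames, n_sel, 3).

    A monomer's position is the unweighted mean of its selected particles
    (one particle per monomer in the toy system, where this is the identity).
    """
    idx = traj.select(selection)
    sub = traj.table.iloc[idx]
    keys = sub[["molecule_id", "monomer_index"]].to_numpy()
    _, group = np.unique(keys, axis=0, return_inverse=True)
    n_groups = group.max() + 1
    pos = traj.coords[:, idx, :]
    if n_groups == len(idx):
        order = np.argsort(group)
        return pos[:, order, :]
    out = np.zeros((traj.n_frames, n_groups, 3))
    np.add.at(out, (slice(None), group), pos)
    counts = np.bincount(group, minlength=n_groups).astype(float)
    return out / counts[None, :, None]


def accumulate_density(
    traj: Trajectory,
    selection: SelectionQuery,
    grid: GridSpec,
    smooth_sigma: float | None = None,
) -> DensityGrid:
    """Count selected-monomer positions per voxel over all frames.

    ``smooth_sigma`` (Å) optionally applies a Gaussian filter to the count
    field (off by default; enrichment statistics are then computed on the
    smoothed field).
    """
    if traj.n_frames == 0:
        raise DensityError("trajectory has zero frames")
    pos = monomer_positions(traj, selection)
    n_sel = pos.shape[1]
    flat = pos.reshape(-1, 3)
    idx, inside = grid.voxel_indices(flat)
    idx = idx[inside]
    counts = np.zeros(grid.shape, dtype=float)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if smooth_sigma is not None and smooth_sigma > 0:
        counts = gaussian_filter(counts, sigma=smooth_sigma / grid.spacing)
    return DensityGrid(
        spec=grid, counts=counts, n_frames=traj.n_frames, n_selected=n_sel
    )


def ambient_concentration(
    density: DensityGrid,
    receptor: ReceptorModel | None = None,
    exclusion_distance: float = 15.0,
    mode: str = "far_field",
    box_volume: float | None = None,
) -> float:
    """Estimate the ambient monomer concentration (Å⁻³) and store it.

    ``far_field`` averages the concentration over voxels whose centres lie at
    least ``exclusion_distance`` from every receptor bead surface (at least
    10% of voxels must qualify).  ``nominal`` returns
    n_selected / box_volume, the ideal-gas value.
    """
    if mode == "nominal":
        if box_volume is None or box_volume <= 0:
            raise ValueError("nominal mode requires box_volume")
        c = density.n_selected / box_volume
    elif mode == "far_field":
        conc = density.concentration()
        if receptor is None:
            far = np.ones(density.spec.shape, dtype=bool)
        else:
            centers = density.spec.center_points().reshape(-1, 3)
            d = np.linalg.norm(
                centers[:, None, :] - receptor.centers_array[None, :, :], axis=-1
            ) - receptor.radii_array[None, :]
            far = (d.min(axis=1) >= exclusion_distance).reshape(density.spec.shape)
        if np.count_nonzero(far) < 0.1 * far.size:
            raise AmbientConcentrationError(
                "fewer than 10% of voxels lie beyond the exclusion distance; "
                "enlarge the grid or use mode='nominal'"
            )
        c = float(conc[far].mean())
    else:
        raise ValueError(f"unknown ambient mode {mode!r}")
    density.c_amb = float(c)
    density.c_amb_mode = mode
    return density.c_amb


def density_summary(density: DensityGrid, threshold: float = 30.0) -> DensitySummary:
    """Enrichment statistic M and the iso-region volume above ``threshold``."""
    if threshold <= 0:
        raise DensityError("threshold must be positive")
    ratio = density.ratio()
    above = ratio >= threshold
    n_above = int(np.count_nonzero(above))
    order = np.argsort(ratio, axis=None)[::-1]
    top = np.unravel_index(order[: max(n_above, 1)], ratio.shape)
    voxels = pd.DataFrame(
        {
            "i": top[0],
            "j": top[1],
            "k": top[2],
            "x": density.spec.centers(0)[top[0]],
            "y": density.spec.centers(1)[top[1]],
            "z": density.spec.centers(2)[top[2]],
            "ratio": ratio[top],
        }
    )
    return DensitySummary(
        M=float(ratio.max()),
        threshold=float(threshold),
        volume_above=n_above * density.spec.voxel_volume,
        n_voxels_above=n_above,
        c_amb=density.c_amb,
        voxels=voxels,
    )
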
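"""Overdamped-Langevin model of a bead-chain ligand around a fixed receptor.

The receptor is a rigid set of soft-core beads carrying a single anisotropic
Gaussian binding well at a surface "channel" site plus a weak nonspecific
surface attraction.  The ligand is a harmonic bead chain.  Dynamics are
Brownian (overdamped Euler-Maruyama) in a periodic box with minimum-image
distances, which reproduces the exact Boltzmann equilibrium of the model
potential; this makes every downstream analysis verifiable against analytic
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .constants import ThermoConstants
from .errors import PackingError, TimestepError
from .maps import CoordinateSpec, FreeEnergyMap

#: Default per-step displacement sanity bound (Å).
MAX_STEP_DISPLACEMENT = 1.0


@dataclass(frozen=True)
class ReceptorModel:
    """Rigid bead receptor with one high-affinity surface channel.

    The binding site is an anisotropic Gaussian well of depth ``site_depth``
    (kcal/mol) and per-axis widths ``site_widths`` (Å) centred at
    ``site_center``; narrow widths make the channel geometrically selective.
    ``nonspecific_eps`` sets a weak Gaussian shell of attraction at each bead
    surface (width ``nonspecific_width``).  The soft-core wall is a logistic
    sigmoid of height ``repulsion_strength`` and width ``repulsion_range``,
    so the total potential is finite everywhere and continuously
    differentiable away from bead centres.
    """

    bead_centers: tuple = ((0.0, 0.0, 0.0),)
    bead_radii: tuple = (3.0,)
    site_center: tuple = (0.0, 0.0, 4.8)
    site_depth: float = 5.0
    site_widths: tuple = (1.1, 1.1, 1.6)
    nonspecific_eps: float = 0.3
    nonspecific_width: float = 1.5
    repulsion_strength: float = 15.0
    repulsion_range: float = 0.5

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.bead_centers, dtype=float))
        radii = np.broadcast_to(
            np.asarray(self.bead_radii, dtype=float), (centers.shape[0],)
        )
        object.__setattr__(self, "bead_centers", tuple(map(tuple, centers)))
        object.__setattr__(self, "bead_radii", tuple(radii))
        object.__setattr__(self, "site_center", tuple(float(v) for v in self.site_center))
        object.__setattr__(self, "site_widths", tuple(float(v) for v in self.site_widths))
        if self.site_depth < 0:
            raise ValueError("site_depth must be >= 0")
        # the site must be a surface channel, not a bulk well
        d = np.linalg.norm(centers - np.asarray(self.site_center), axis=1) - radii
        if float(np.min(np.abs(d))) > self.repulsion_range + max(self.site_widths):
            raise ValueError("site_center must lie near a bead surface")

    @property
    def centers_array(self) -> np.ndarray:
        return np.asarray(self.bead_centers, dtype=float)

    @property
    def radii_array(self) -> np.ndarray:
        return np.asarray(self.bead_radii, dtype=float)


@dataclass(frozen=True)
class LigandModel:
    """Harmonic bead-chain ligand (toy analogue of a linear oligoglucan)."""

    n_monomers: int = 1
    bond_length: float = 2.0
    bond_stiffness: float = 10.0
    monomer_radius: float = 0.0

    def __post_init__(self):
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


@dataclass(frozen=True)
class SimulationSettings:
    """Brownian-dynamics run settings.

    ``timestep`` in ns, ``diffusion`` in Å²/ns, ``box_lengths`` in Å
    (periodic).  ``save_stride`` is the number of steps between saved frames.
    """

    n_steps: int
    box_lengths: tuple = (60.0, 60.0, 60.0)
    timestep: float = 5.0e-5
    temperature: float = 310.0
    diffusion: float = 100.0
    seed: int = 0
    save_stride: int = 50

    def __post_init__(self):
        object.__setattr__(
            self, "box_lengths", tuple(float(v) for v in np.broadcast_to(np.asarray(self.box_lengths, dtype=float), (3,)))
        )
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")

    @property
    def kT(self) -> float:
        return ThermoConstants(self.temperature).kT

    def validate_for(self, ligand: LigandModel):
        span = (ligand.n_monomers - 1) * ligand.bond_length
        if span >= min(self.box_lengths) / 2:
            raise ValueError("ligand could span half a box length; enlarge the box")


@dataclass
class Trajectory:
    """Time-ordered frames of labelled particle coordinates.

    ``coords`` has shape (n_frames, n_particles, 3) in Å; ``times`` in ns with
    uniform stride.  ``table`` is the particle table with columns
    particle_id, molecule_id, monomer_index, role, name.  Receptor beads are
    molecule 0 (role "receptor"); a "site" marker particle pins the binding
    channel centre; ligand chains are molecules 1..n with role "ligand".
    """

    times: np.ndarray
    coords: np.ndarray
    box_lengths: tuple
    table: pd.DataFrame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != len(self.times):
            raise ValueError("coords must be (n_frames, n_particles, 3)")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("frame times must have uniform stride")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def stride(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def select(self, query) -> np.ndarray:
        """Resolve a SelectionQuery (or boolean helper) to particle indices."""
        return query.resolve(self.table)


def particle_table(receptor: ReceptorModel | None, ligand: LigandModel, n_ligands: int) -> pd.DataFrame:
    rows = []
    pid = 0
    if receptor is not None:
        for i in range(len(receptor.bead_centers)):
            rows.append((pid, 0, i, "receptor", "bead"))
            pid += 1
        rows.append((pid, 0, -1, "receptor", "site"))
        pid += 1
    for m in range(1, n_ligands + 1):
        for j in range(ligand.n_monomers):
            rows.append((pid, m, j, "ligand", "monomer"))
            pid += 1
    return pd.DataFrame(
        rows, columns=["particle_id", "molecule_id", "monomer_index", "role", "name"]
    )


def _receptor_arrays(receptor: ReceptorModel | None):
    if receptor is None:
        return (
            np.zeros((0, 3)),
            np.zeros((0,)),
            np.zeros(3),
            np.zeros(10),
        )
    pp = np.array(
        [
            receptor.repulsion_strength,
            receptor.repulsion_range,
            receptor.nonspecific_eps,
            receptor.nonspecific_width,
            receptor.site_depth,
            receptor.site_widths[0],
            receptor.site_widths[1],
            receptor.site_widths[2],
            0.0,
            0.0,
        ]
    )
    return (
        receptor.centers_array,
        receptor.radii_array,
        np.asarray(receptor.site_center, dtype=float),
        pp,
    )


def potential_energy(
    receptor: ReceptorModel | None,
    positions: np.ndarray,
    ligand: LigandModel | None = None,
    box_lengths=None,
) -> tuple:
    """Total potential energy (kcal/mol) and exact forces (kcal/mol/Å).

    ``positions`` is (n, 3); when ``ligand`` is given, consecutive blocks of
    ``n_monomers`` rows form one chain with harmonic bonds.  Vectorised numpy
    reference implementation — the numba kernels mirror it term by term.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    box = (
        np.asarray(box_lengths, dtype=float)
        if box_lengths is not None
        else np.full(3, 1e12)
    )

    def mi(d):
        return d - box * np.round(d / box)

    U = 0.0
    F = np.zeros_like(pos)
    if receptor is not None:
        bead_c = receptor.centers_array
        bead_R = receptor.radii_array
        if ligand is not None and ligand.monomer_radius:
            bead_R = bead_R + ligand.monomer_radius
        dvec = mi(pos[:, None, :] - bead_c[None, :, :])  # (n, nb, 3)
        d = np.linalg.norm(dvec, axis=-1)
        d = np.where(d < 1e-9, 1e-9, d)
        s = d - bead_R[None, :]
        lam = receptor.repulsion_range
        t = np.clip(s / lam, -200.0, 40.0)
        e = np.exp(t)
        sig = 1.0 / (1.0 + e)
        U += receptor.repulsion_strength * np.sum(sig)
        dudd = -receptor.repulsion_strength * e * sig**2 / lam
        if receptor.nonspecific_eps != 0.0:
            w = receptor.nonspecific_width
            g = np.exp(-np.clip(s**2 / (2 * w**2), 0.0, 60.0))
            U += -receptor.nonspecific_eps * np.sum(g)
            dudd = dudd + receptor.nonspecific_eps * g * s / w**2
        F += np.sum(-dudd[..., None] * dvec / d[..., None], axis=1)
        if receptor.site_depth != 0.0:
            widths = np.asarray(receptor.site_widths)
            dv = mi(pos - np.asarray(receptor.site_center))
            q = 0.5 * np.sum((dv / widths) ** 2, axis=-1)
            g = receptor.site_depth * np.exp(-np.clip(q, 0.0, 60.0))
            U += -np.sum(g)
            F += -g[:, None] * dv / widths[None, :] ** 2
    if ligand is not None and ligand.n_monomers > 1 and ligand.bond_stiffness != 0.0:
        n_mon = ligand.n_monomers
        if pos.shape[0] % n_mon:
            raise ValueError("positions rows must be a multiple of n_monomers")
        chains = pos.reshape(-1, n_mon, 3)
        dvec = mi(chains[:, 1:, :] - chains[:, :-1, :])
        d = np.linalg.norm(dvec, axis=-1)
        dev = d - ligand.bond_length
        U += 0.5 * ligand.bond_stiffness * np.sum(dev**2)
        with np.errstate(invalid="ignore"):
            unit = np.where(d[..., None] > 1e-12, dvec / d[..., None], 0.0)
        fb = -ligand.bond_stiffness * dev[..., None] * unit
        Fc = np.zeros_like(chains)
        Fc[:, 1:, :] += fb
        Fc[:, :-1, :] -= fb
        F += Fc.reshape(-1, 3)
    return float(U), F


def build_toy_system(
    receptor: ReceptorModel,
    ligand: LigandModel,
    n_ligands: int,
    box_lengths,
    seed: int,
    standoff: float = 8.0,
    max_attempts: int = 10000,
) -> tuple:
    """Random initial placement with every monomer >= ``standoff`` from the
    receptor surface.

    Chains are grown as random walks of fixed bond length from a uniformly
    drawn start; candidates violating the standoff are rejected.  Raises
    :class:`PackingError` after ``max_attempts`` rejections per molecule.
    """
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    box = np.broadcast_to(np.asarray(box_lengths, dtype=float), (3,))
    rng = np.random.default_rng(seed)
    centers = receptor.centers_array
    radii = receptor.radii_array

    def clearance(points):
        d = points[:, None, :] - centers[None, :, :]
        d -= box * np.round(d / box)
        return np.min(np.linalg.norm(d, axis=-1) - radii[None, :])

    placed = []
    for _ in range(n_ligands):
        for attempt in range(max_attempts):
            start = (rng.random(3) - 0.5) * box
            chain = [start]
            for _ in range(ligand.n_monomers - 1):
                step = rng.normal(size=3)
                step *= ligand.bond_length / np.linalg.norm(step)
                chain.append(chain[-1] + step)
            pts = np.asarray(chain)
            if clearance(pts) >= standoff:
                placed.append(pts)
                break
        else:
            raise PackingError(
                f"could not place ligand with a {standoff} Å receptor standoff "
                f"after {max_attempts} attempts; enlarge the box or reduce n_ligands"
            )
    positions = np.concatenate(placed, axis=0)
    positions -= box * np.floor(positions / box + 0.5)
    return receptor, positions


def _ligand_pp(receptor, ligand):
    bead_c, bead_R, site_c, pp = _receptor_arrays(receptor)
    pp = pp.copy()
    if ligand is not None:
        if ligand.n_monomers > 1:
            pp[8] = ligand.bond_stiffness
            pp[9] = ligand.bond_length
        if ligand.monomer_radius:
            # a bulky monomer is excluded earlier: the wall (and surface
            # shell) act at the bead surface plus the monomer radius
            bead_R = bead_R + ligand.monomer_radius
    return bead_c, bead_R, site_c, pp


def simulate(
    receptor: ReceptorModel | None,
    ligand: LigandModel,
    positions0: np.ndarray,
    settings: SimulationSettings,
    external_bias=None,
    restraints=None,
    max_displacement: float = MAX_STEP_DISPLACEMENT,
) -> Trajectory:
    """Run overdamped Langevin dynamics and return a Trajectory.

    Identical seeds give bit-identical trajectories.  ``external_bias``,
    if given, must be a callable ``(positions, step) -> forces`` evaluated on
    all particles; this generic path runs in Python (numpy RNG) and is
    intended for prototyping biases — the ABF engine uses fused kernels with
    the same update rule.  ``restraints`` is an optional
    :class:`~glucanbind.binding_dg.StageRestraints`-style parameter vector
    used by the staged protocol (single-molecule runs only).
    """
    settings.validate_for(ligand)
    pos0 = np.asarray(positions0, dtype=float)
    n_mon = ligand.n_monomers
    if pos0.shape[0] % n_mon:
        raise ValueError("positions0 rows must be a multiple of n_monomers")
    n_ligands = pos0.shape[0] // n_mon
    box = np.asarray(settings.box_lengths)
    n_saved = settings.n_steps // settings.save_stride + 1
    bead_c, bead_R, site_c, pp = _ligand_pp(receptor, ligand)
    rp = np.zeros(11)
    m_idx = 0
    use_restraints = False
    if restraints is not None:
        rp, m_idx = restraints.as_arrays(n_mon)
        use_restraints = True
        if n_ligands != 1:
            raise ValueError("stage restraints support a single ligand molecule")

    out = np.empty((n_saved, pos0.shape[0], 3))
    if external_bias is None:
        status = _kernels.bd_run(
            pos0,
            settings.n_steps,
            settings.save_stride,
            settings.timestep,
            settings.diffusion,
            settings.kT,
            box,
            settings.seed % 2**31,
            bead_c,
            bead_R,
            site_c,
            pp,
            n_mon,
            rp,
            m_idx,
            use_restraints,
            max_displacement,
            out,
        )
        if status != 0:
            raise TimestepError(
                f"displacement exceeded {max_displacement} Å at step {-status}; "
                "reduce the timestep"
            )
    else:
        rng = np.random.default_rng(settings.seed)
        pos = pos0.copy()
        out[0] = pos
        mob = settings.diffusion / settings.kT
        noise = np.sqrt(2 * settings.diffusion * settings.timestep)
        ks = 1
        for step in range(1, settings.n_steps + 1):
            _, F = potential_energy(receptor, pos, ligand, settings.box_lengths)
            F = F + external_bias(pos, step)
            disp = mob * F * settings.timestep + noise * rng.standard_normal(pos.shape)
            if np.max(np.abs(disp)) > max_displacement:
                raise TimestepError(
                    f"displacement exceeded {max_displacement} Å at step {step}; "
                    "reduce the timestep"
                )
            pos = pos + disp
            pos -= box * np.floor(pos / box + 0.5)
            if step % settings.save_stride == 0:
                out[ks] = pos
                ks += 1

    times = np.arange(n_saved) * settings.save_stride * settings.timestep
    table = particle_table(receptor, ligand, n_ligands)
    n_static = len(table) - pos0.shape[0]
    if n_static:
        static = np.concatenate(
            [np.asarray(receptor.bead_centers, dtype=float), [receptor.site_center]]
        )
        coords = np.concatenate(
            [np.broadcast_to(static, (n_saved, n_static, 3)), out], axis=1
        )
    else:
        coords = out
    return Trajectory(times=times, coords=coords, box_lengths=tuple(box), table=table)


def ground_truth_pmf(
    receptor: ReceptorModel | None,
    spec: CoordinateSpec,
    fixed: dict | None = None,
) -> FreeEnergyMap:
    """Exact free-energy map of a single monomer on the given coordinate grid.

    For a one-monomer ligand the potential of mean force over Cartesian
    position coordinates equals the potential itself up to a constant, so the
    exact map is the model potential evaluated at bin centres, gauge-fixed to
    zero at its minimum.  Cartesian axes absent from ``spec`` are held at the
    site-centre value (override via ``fixed``, e.g. ``{"y": 0.0}``).
    """
    if spec.kind != "cartesian":
        raise ValueError("ground-truth maps are defined on cartesian coordinates")
    ref = np.asarray(spec.reference, dtype=float)
    fixed = dict(fixed or {})
    grids = [spec.centers(d) for d in range(spec.ndim)]
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.tile(ref, mesh[0].shape + (1,)).astype(float)
    for name, val in fixed.items():
        pts[..., {"x": 0, "y": 1, "z": 2}[name]] = val
    for d, ai in enumerate(spec.axis_indices):
        pts[..., ai] = ref[ai] + mesh[d]
    flat = pts.reshape(-1, 3)
    vals = _point_energies(receptor, flat).reshape(mesh[0].shape)
    vals = vals - vals.min()
    return FreeEnergyMap.from_spec(spec, vals, np.ones_like(vals, dtype=bool))


def _point_energies(receptor: ReceptorModel | None, points: np.ndarray) -> np.ndarray:
    """Single-particle model potential evaluated at each point (no bonds)."""
    pts = np.atleast_2d(points)
    vals = np.zeros(pts.shape[0])
    if receptor is None:
        return vals
    bead_c = receptor.centers_array
    bead_R = receptor.radii_array
    d = np.linalg.norm(pts[:, None, :] - bead_c[None, :, :], axis=-1)
    s = d - bead_R[None, :]
    t = np.clip(s / receptor.repulsion_range, -200.0, 40.0)
    vals += receptor.repulsion_strength * np.sum(1.0 / (1.0 + np.exp(t)), axis=1)
    if receptor.nonspecific_eps != 0.0:
        w = receptor.nonspecific_width
        vals += -receptor.nonspecific_eps * np.sum(
            np.exp(-np.clip(s**2 / (2 * w**2), 0, 60)), axis=1
        )
    if receptor.site_depth != 0.0:
        widths = np.asarray(receptor.site_widths)
        dv = pts - np.asarray(receptor.site_center)
        q = 0.5 * np.sum((dv / widths) ** 2, axis=-1)
        vals += -receptor.site_depth * np.exp(-np.clip(q, 0, 60))
    return vals
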
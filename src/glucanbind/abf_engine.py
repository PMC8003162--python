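"""Adaptive biasing force sampling and free-energy map assembly.

The ABF estimator accumulates, per bin of the transition coordinates, the
count n(b) and sum S(b) of instantaneous force samples along the
coordinates, and applies the bias -(S(b)/n(b)) * min(1, n(b)/n_full) so the
landscape flattens as the running mean force converges.  For Cartesian
centre-of-mass displacement coordinates the instantaneous sample is simply
the systematic force component (no Jacobian correction); the radial
(distance) coordinate carries the 2*kB*T/r entropic term.

Free-energy maps are recovered from the estimated mean-force field by
least-squares (discrete Poisson) integration over the sampled bins, which
reduces exactly to cumulative trapezoidal integration in one dimension.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import lsqr

from . import _kernels
from .maps import CoordinateSpec, FreeEnergyMap, MeanForceGrid
from .toy_dynamics import LigandModel, ReceptorModel, SimulationSettings
from .errors import TimestepError

__all__ = [
    "CoordinateSpec",
    "MeanForceGrid",
    "FreeEnergyMap",
    "abf_step",
    "make_abf_bias",
    "run_abf",
    "run_abf_analytic1d",
    "combine_replicas",
    "integrate_gradient",
    "min_projection",
]


def abf_step(grid: MeanForceGrid, bin_index, force_sample) -> np.ndarray:
    """One ABF update: accumulate the sample, return the bias force.

    Pure-Python reference for the kernel update rule; ``bin_index`` is a
    tuple of bin coordinates and ``force_sample`` the instantaneous force
    along each transition coordinate (kcal/mol/Å).
    """
    b = tuple(int(i) for i in np.atleast_1d(bin_index))
    f = np.atleast_1d(np.asarray(force_sample, dtype=float))
    grid.counts[b] += 1
    grid.fsum[b] += f
    n = grid.counts[b]
    ramp = min(1.0, n / grid.n_full)
    return -(grid.fsum[b] / n) * ramp


def make_abf_bias(grid: MeanForceGrid, particle_index: int):
    """Adapt a MeanForceGrid into a ``simulate(external_bias=...)`` callable.

    Supports Cartesian coordinate specs; the bias acts on the tracked
    particle only.  Note the force sample fed to :func:`abf_step` here is
    unavailable to a pure position callback, so this adapter recomputes
    nothing and simply applies the current bias — it exists for
    prototyping bias application, while :func:`run_abf` performs the full
    estimator update in the fused kernel.
    """
    spec = grid.spec
    if spec.kind != "cartesian":
        raise ValueError("external-bias adapter supports cartesian coordinates")
    axis_idx = np.asarray(spec.axis_indices)
    ref = np.asarray(spec.reference)

    def bias(positions, step):
        F = np.zeros_like(positions)
        xi = positions[particle_index, axis_idx] - ref[axis_idx]
        idx, inside = spec.bin_index(xi)
        if inside:
            b = tuple(idx)
            n = grid.counts[b]
            if n > 0:
                ramp = min(1.0, n / grid.n_full)
                F[particle_index, axis_idx] = -(grid.fsum[b] / n) * ramp
        return F

    return bias


def run_abf(
    receptor: ReceptorModel | None,
    ligand: LigandModel,
    spec: CoordinateSpec,
    settings: SimulationSettings,
    seed: int | None = None,
    positions0: np.ndarray | None = None,
    restraints=None,
    n_full: int = 200,
    domain_wall_k: float = 20.0,
    max_displacement: float = 1.0,
) -> MeanForceGrid:
    """Run ABF on the toy system over the given transition coordinates.

    The tracked monomer and reference point come from ``spec``.  The
    coordinate domain is enforced by half-harmonic walls whose forces (like
    the bias itself) are excluded from the accumulated samples.  Returns the
    accumulated grid; a warning is recorded on the result if fewer than half
    of the bins were sampled.  Deterministic per seed.
    """
    from .toy_dynamics import _ligand_pp, build_toy_system

    settings.validate_for(ligand)
    seed = settings.seed if seed is None else seed
    if positions0 is None:
        _, positions0 = build_toy_system(
            receptor, ligand, 1, settings.box_lengths, seed
        ) if receptor is not None else (None, np.zeros((ligand.n_monomers, 3)))
    pos0 = np.asarray(positions0, dtype=float)
    bead_c, bead_R, site_c, pp = _ligand_pp(receptor, ligand)
    rp = np.zeros(11)
    use_restraints = False
    if restraints is not None:
        rp, _ = restraints.as_arrays(ligand.n_monomers)
        use_restraints = True
    grid = MeanForceGrid(spec=spec, n_full=n_full)
    counts = np.zeros(int(np.prod(spec.shape)), dtype=np.int64)
    fsum = np.zeros(counts.size * spec.ndim, dtype=float)
    status = _kernels.bd_run_abf(
        pos0,
        settings.n_steps,
        settings.timestep,
        settings.diffusion,
        settings.kT,
        np.asarray(settings.box_lengths),
        seed % 2**31,
        bead_c,
        bead_R,
        site_c,
        pp,
        ligand.n_monomers,
        rp,
        use_restraints,
        spec.kind == "radial",
        spec.monomer,
        np.asarray(spec.reference, dtype=float),
        np.asarray(spec.axis_indices if spec.kind == "cartesian" else (0,), dtype=np.int64),
        np.asarray(spec.lo, dtype=float),
        spec.width,
        np.asarray(spec.shape, dtype=np.int64),
        n_full,
        domain_wall_k,
        counts,
        fsum,
        max_displacement,
    )
    if status != 0:
        raise TimestepError(
            f"displacement exceeded {max_displacement} Å at step {-status}; "
            "reduce the timestep"
        )
    grid.counts = counts.reshape(spec.shape)
    grid.fsum = fsum.reshape(spec.shape + (spec.ndim,))
    if grid.sampled_fraction() < 0.5:
        grid.warnings.append(
            f"only {100 * grid.sampled_fraction():.1f}% of bins sampled; "
            "free energies on unsampled bins are undefined"
        )
    return grid


def run_abf_analytic1d(
    coeffs,
    lo: float,
    hi: float,
    width: float,
    n_steps: int,
    timestep: float = 1e-4,
    diffusion: float = 100.0,
    temperature: float = 310.0,
    seed: int = 0,
    x0: float | None = None,
    n_full: int = 200,
    domain_wall_k: float = 20.0,
    max_displacement: float = 1.0,
) -> MeanForceGrid:
    """1D ABF on an analytic polynomial potential U(x) = sum c_i x^i (i<=4).

    Validation fixture: the estimated per-bin mean force can be compared
    directly against -U'(x) and the integrated profile against U.
    """
    from .constants import ThermoConstants

    c = np.zeros(5)
    c[: len(coeffs)] = coeffs
    spec = CoordinateSpec(lo=(lo,), hi=(hi,), width=width, axes=("x",))
    grid = MeanForceGrid(spec=spec, n_full=n_full)
    counts = np.zeros(spec.shape[0], dtype=np.int64)
    fsum = np.zeros(spec.shape[0], dtype=float)
    kT = ThermoConstants(temperature).kT
    status = _kernels.abf_run_1d_poly(
        0.5 * (lo + hi) if x0 is None else x0,
        n_steps,
        timestep,
        diffusion,
        kT,
        seed % 2**31,
        c,
        lo,
        hi,
        width,
        n_full,
        domain_wall_k,
        counts,
        fsum,
        max_displacement,
    )
    if status != 0:
        raise TimestepError(
            f"displacement exceeded {max_displacement} Å at step {-status}; "
            "reduce the timestep"
        )
    grid.counts = counts
    grid.fsum = fsum[:, None]
    if grid.sampled_fraction() < 0.5:
        grid.warnings.append(
            f"only {100 * grid.sampled_fraction():.1f}% of bins sampled; "
            "free energies on unsampled bins are undefined"
        )
    return grid


def combine_replicas(grids: list[MeanForceGrid]) -> MeanForceGrid:
    """Pool replicas bin-wise: n and S add, so the combined mean force is the
    pooled sample mean.  Commutative and associative by construction."""
    if not grids:
        raise ValueError("no grids to combine")
    first = grids[0]
    out = MeanForceGrid(spec=first.spec, n_full=first.n_full)
    for g in grids:
        first.require_compatible(g)
        out.counts = out.counts + g.counts
        out.fsum = out.fsum + g.fsum
        out.warnings.extend(g.warnings)
    return out


def integrate_gradient(grid: MeanForceGrid) -> FreeEnergyMap:
    """Least-squares integration of the estimated free-energy gradient.

    The free-energy gradient is the negative mean force.  For every pair of
    adjacent sampled bins the centred-difference equation
    (F[b+e] - F[b])/h = (g[b] + g[b+e])/2 enters a sparse least-squares
    system; unsampled bins are excluded.  Each connected sampled component
    is gauge-fixed so its minimum is zero.
    """
    sampled = grid.sampled
    if not np.any(sampled):
        raise ValueError("no sampled bins to integrate")
    g = -grid.mean_force()
    shape = sampled.shape
    ndim = grid.spec.ndim
    h = grid.spec.width
    index = -np.ones(shape, dtype=np.int64)
    flat_ids = np.flatnonzero(sampled.ravel())
    index.ravel()[flat_ids] = np.arange(flat_ids.size)
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for d in range(ndim):
        sl_a = [slice(None)] * ndim
        sl_b = [slice(None)] * ndim
        sl_a[d] = slice(None, -1)
        sl_b[d] = slice(1, None)
        a_ok = sampled[tuple(sl_a)] & sampled[tuple(sl_b)]
        ia = index[tuple(sl_a)][a_ok]
        ib = index[tuple(sl_b)][a_ok]
        ga = g[tuple(sl_a) + (d,)][a_ok]
        gb = g[tuple(sl_b) + (d,)][a_ok]
        n_eq = ia.size
        rows.extend(range(eq, eq + n_eq))
        cols.extend(ib)
        vals.extend(np.full(n_eq, 1.0 / h))
        rows.extend(range(eq, eq + n_eq))
        cols.extend(ia)
        vals.extend(np.full(n_eq, -1.0 / h))
        rhs.extend(0.5 * (ga + gb))
        eq += n_eq
    n_unknown = flat_ids.size
    if eq == 0:
        F = np.zeros(n_unknown)
    else:
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(eq, n_unknown)
        )
        F = lsqr(A, np.asarray(rhs), atol=1e-12, btol=1e-12, iter_lim=20000)[0]
    values = np.full(shape, np.nan)
    values.ravel()[flat_ids] = F
    # gauge each connected sampled component to min-zero
    labels, n_comp = ndimage.label(sampled)
    for c in range(1, n_comp + 1):
        comp = labels == c
        values[comp] -= np.nanmin(values[comp])
    return FreeEnergyMap.from_spec(grid.spec, values, sampled)


def min_projection(fmap: FreeEnergyMap, axis: str = "z") -> FreeEnergyMap:
    """Project a 3D map to 2D by taking the minimum over sampled bins along
    ``axis``; (x, y) bins with no sampled bin along the line are unsampled."""
    if fmap.ndim != 3:
        raise ValueError("min_projection expects a 3D free-energy map")
    if axis not in fmap.axes:
        raise ValueError(f"axis {axis!r} not in map axes {fmap.axes}")
    d = fmap.axes.index(axis)
    vals = np.where(fmap.mask, fmap.values, np.inf)
    proj = vals.min(axis=d)
    mask2 = fmap.mask.any(axis=d)
    proj = np.where(mask2, proj, np.nan)
    keep = [i for i in range(3) if i != d]
    return FreeEnergyMap(
        values=proj,
        mask=mask2,
        lo=tuple(fmap.lo[i] for i in keep),
        width=fmap.width,
        axes=tuple(fmap.axes[i] for i in keep),
    )
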
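"""Transition-coordinate grids, mean-force accumulators and free-energy maps.

These containers are shared between the toy simulator (which can evaluate
exact free energies on them) and the adaptive-biasing-force engine (which
accumulates per-bin force statistics on them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class CoordinateSpec:
    """Definition of 1-3 transition coordinates on a regular grid.

    Two coordinate kinds are supported:

    ``cartesian``
        Displacement components (a subset of x, y, z) of a chosen ligand
        monomer relative to a fixed reference point.
    ``radial``
        The minimum-image distance between the monomer and the reference
        point (one dimension; its mean-force estimator carries the
        2*kB*T/r Jacobian term).

    ``lo``/``hi`` give the domain per component in Å and ``width`` the bin
    width in Å (0.25 Å by default, matching the resolution at which the
    free-energy maps are rendered).
    """

    lo: tuple
    hi: tuple
    width: float = 0.25
    kind: str = "cartesian"
    axes: tuple = ("x", "y", "z")
    monomer: int = 0
    reference: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in ("cartesian", "radial"):
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        lo = tuple(float(v) for v in np.atleast_1d(self.lo))
        hi = tuple(float(v) for v in np.atleast_1d(self.hi))
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "reference", tuple(float(v) for v in self.reference))
        if self.kind == "radial":
            object.__setattr__(self, "axes", ("r",))
        else:
            object.__setattr__(self, "axes", tuple(self.axes))
            if not all(a in _AXIS_INDEX for a in self.axes):
                raise ValueError("cartesian axes must be drawn from x, y, z")
        if len(lo) != len(hi) or len(lo) != len(self.axes):
            raise ValueError("lo, hi and axes must have matching lengths")
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        for a, b in zip(lo, hi):
            if b <= a:
                raise ValueError("hi must exceed lo on every component")
            n = (b - a) / self.width
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError("(hi-lo)/width must be integral")

    @property
    def ndim(self) -> int:
        return len(self.lo)

    @property
    def shape(self) -> tuple:
        return tuple(
            int(round((b - a) / self.width)) for a, b in zip(self.lo, self.hi)
        )

    @property
    def axis_indices(self) -> tuple:
        """Cartesian component indices (0/1/2) for each coordinate dimension."""
        if self.kind == "radial":
            return ()
        return tuple(_AXIS_INDEX[a] for a in self.axes)

    def centers(self, dim: int) -> np.ndarray:
        n = self.shape[dim]
        return self.lo[dim] + (np.arange(n) + 0.5) * self.width

    def bin_index(self, values: np.ndarray):
        """Map coordinate values (..., ndim) to integer bin indices.

        Returns (indices, inside) where ``inside`` marks points within the
        domain.  Half-open voxel convention: floor((v - lo)/width).
        """
        values = np.asarray(values, dtype=float)
        lo = np.asarray(self.lo)
        idx = np.floor((values - lo) / self.width).astype(np.int64)
        shape = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=-1)
        return idx, inside


@dataclass
class MeanForceGrid:
    """Per-bin force-sample accumulators of the ABF estimator.

    ``counts[b]`` is the number of samples collected in bin ``b`` and
    ``fsum[b]`` the vector sum of instantaneous force samples along each
    coordinate (kcal/mol/Å).  ``n_full`` is the linear ramp threshold: the
    applied bias is scaled by min(1, n/n_full) so that poorly sampled bins
    are biased gently.
    """

    spec: CoordinateSpec
    counts: np.ndarray = None
    fsum: np.ndarray = None
    n_full: int = 200
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        shape = self.spec.shape
        if self.counts is None:
            self.counts = np.zeros(shape, dtype=np.int64)
        if self.fsum is None:
            self.fsum = np.zeros(shape + (self.spec.ndim,), dtype=float)
        if self.n_full < 1:
            raise ValueError("n_full must be >= 1")

    @property
    def sampled(self) -> np.ndarray:
        return self.counts > 0

    def sampled_fraction(self) -> float:
        return float(np.count_nonzero(self.counts) / self.counts.size)

    def mean_force(self) -> np.ndarray:
        """Per-bin mean force (NaN where unsampled)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            mf = self.fsum / self.counts[..., None]
        mf[~self.sampled] = np.nan
        return mf

    def require_compatible(self, other: "MeanForceGrid"):
        if self.spec != other.spec:
            raise GridMismatchError(
                "mean-force grids have different coordinate specifications"
            )


@dataclass
class FreeEnergyMap:
    """Free energy (kcal/mol) on a regular grid of transition coordinates.

    ``values`` holds NaN in unsampled bins; ``mask`` marks sampled bins.
    Under the default "min-zero" gauge the minimum over sampled bins of each
    connected sampled region is zero.
    """

    values: np.ndarray
    mask: np.ndarray
    lo: tuple
    width: float
    axes: tuple

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def centers(self, dim: int) -> np.ndarray:
        n = self.values.shape[dim]
        return self.lo[dim] + (np.arange(n) + 0.5) * self.width

    def min_position(self) -> tuple:
        """Coordinates of the bin-center with the lowest free energy."""
        masked = np.where(self.mask, self.values, np.inf)
        idx = np.unravel_index(int(np.argmin(masked)), self.values.shape)
        return tuple(
            self.lo[d] + (idx[d] + 0.5) * self.width for d in range(self.ndim)
        )

    @classmethod
    def from_spec(cls, spec: CoordinateSpec, values, mask) -> "FreeEnergyMap":
        return cls(
            values=np.asarray(values, dtype=float),
            mask=np.asarray(mask, dtype=bool),
            lo=spec.lo,
            width=spec.width,
            axes=spec.axes,
        )
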
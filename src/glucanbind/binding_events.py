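"""Persistence-based binding-event detection from distance time series.

A binding event is a contiguous run of frames during which the
minimum-image centre-of-mass distance between a ligand's tracked monomer
and a reference site stays strictly below a contact cutoff (5 Å by
default) for strictly longer than a persistence threshold (30 ns by
default for reported events).  Runs separated by short excursions above
the cutoff can optionally be merged (``max_gap``); merging is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EventConsistencyError, SelectionError, StrideError
from .io_formats import SelectionQuery
from .toy_dynamics import Trajectory


@dataclass
class DistanceSeries:
    """Uniformly sampled ligand-site distance time series for one molecule."""

    molecule_id: int
    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def stride(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass(frozen=True)
class BindingEvent:
    """One contiguous ligand-site contact episode."""

    molecule_id: int
    t_start: float
    t_end: float
    min_distance: float
    mean_distance: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def central_monomer_index(n_monomers: int, override: int | None = None) -> int:
    """0-based index of the chain's central monomer.

    Odd chains have an unambiguous centre (1-based ceil(n/2)); even chains
    require an explicit ``override``.
    """
    if override is not None:
        if not 0 <= override < n_monomers:
            raise ValueError("central-monomer override out of range")
        return override
    if n_monomers % 2 == 0:
        raise SelectionError(
            f"chain length {n_monomers} is even: the central monomer is ambiguous; "
            "pass an explicit monomer index"
        )
    return (n_monomers - 1) // 2


def _com(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return traj.coords[:, idx, :].mean(axis=1)


def distance_series(
    traj: Trajectory,
    reference: SelectionQuery | None = None,
    ligand_monomer: int | None = None,
) -> list[DistanceSeries]:
    """Per-ligand minimum-image COM distance to the reference selection.

    The tracked ligand monomer defaults to the central monomer of each
    chain; ``ligand_monomer`` overrides it (required for even-length
    chains).  The reference defaults to the site marker particle.
    """
    reference = reference or SelectionQuery(name="site")
    ref_idx = traj.select(reference)
    ref_com = _com(traj, ref_idx)
    box = np.asarray(traj.box_lengths)
    series = []
    lig = traj.table[traj.table["role"] == "ligand"]
    for mol_id, sub in lig.groupby("molecule_id"):
        n_mon = int(sub["monomer_index"].max()) + 1
        central = central_monomer_index(n_mon, ligand_monomer)
        rows = sub[sub["monomer_index"] == central].index.to_numpy()
        com = _com(traj, rows)
        d = com - ref_com
        d -= box * np.round(d / box)
        series.append(
            DistanceSeries(
                molecule_id=int(mol_id),
                times=traj.times,
                distances=np.linalg.norm(d, axis=-1),
            )
        )
    if not series:
        raise SelectionError("trajectory contains no ligand molecules")
    return series


def detect_events(
    series: DistanceSeries,
    contact_cutoff: float = 5.0,
    min_duration: float = 30.0,
    max_gap: float = 0.0,
) -> list[BindingEvent]:
    """Maximal below-cutoff runs, gap-merged, filtered by persistence.

    Contact is strict (< cutoff) and so is persistence (duration strictly
    greater than ``min_duration``), matching the selection rule used for
    reported events.  Runs separated by above-cutoff stretches of total
    duration <= ``max_gap`` are merged, with the gap counted into the event.
    """
    t = series.times
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise StrideError("non-uniform time stride; resample before detection")
        stride = dt[0]
    else:
        stride = 0.0
    if len(t) > 1 and min_duration < stride:
        min_duration = stride
    below = series.distances < contact_cutoff
    if not np.any(below):
        return []
    padded = np.concatenate([[False], below, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1  # inclusive frame indices
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        prev_s, prev_e = merged[-1]
        gap = (s - prev_e - 1) * stride
        if max_gap > 0 and gap <= max_gap:
            merged[-1] = (prev_s, e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        duration = t[e] - t[s]
        if duration > min_duration:
            d = series.distances[s : e + 1]
            events.append(
                BindingEvent(
                    molecule_id=series.molecule_id,
                    t_start=float(t[s]),
                    t_end=float(t[e]),
                    min_distance=float(d.min()),
                    mean_distance=float(d.mean()),
                )
            )
    return events


@dataclass
class EventSummary:
    """Aggregate statistics of detected binding events."""

    n_events: int
    mean_duration: float
    max_duration: float
    bound_fraction: float
    per_molecule: pd.DataFrame


def event_statistics(events: list[BindingEvent], total_time: float) -> EventSummary:
    """Event counts, durations and the bound-time fraction per molecule."""
    by_mol = {}
    for ev in sorted(events, key=lambda e: (e.molecule_id, e.t_start)):
        by_mol.setdefault(ev.molecule_id, []).append(ev)
    for mol, evs in by_mol.items():
        for a, b in zip(evs, evs[1:]):
            if b.t_start < a.t_end:
                raise EventConsistencyError(
                    f"molecule {mol}: events [{a.t_start}, {a.t_end}] and "
                    f"[{b.t_start}, {b.t_end}] overlap"
                )
    rows = []
    for mol, evs in by_mol.items():
        durations = np.array([e.duration for e in evs])
        rows.append(
            {
                "molecule_id": mol,
                "n_events": len(evs),
                "mean_duration": durations.mean(),
                "max_duration": durations.max(),
                "bound_fraction": durations.sum() / total_time,
            }
        )
    per_mol = pd.DataFrame(
        rows,
        columns=["molecule_id", "n_events", "mean_duration", "max_duration", "bound_fraction"],
    )
    durations = np.array([e.duration for e in events], dtype=float)
    return EventSummary(
        n_events=len(events),
        mean_duration=float(durations.mean()) if len(events) else 0.0,
        max_duration=float(durations.max()) if len(events) else 0.0,
        bound_fraction=float(durations.sum() / total_time) if total_time > 0 else 0.0,
        per_molecule=per_mol,
    )


def events_dataframe(events: list[BindingEvent]) -> pd.DataFrame:
    """Tabulate events with the CSV column layout used by the CLI."""
    return pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "t_start_ns": e.t_start,
                "t_end_ns": e.t_end,
                "duration_ns": e.duration,
                "min_dist_A": e.min_distance,
                "mean_dist_A": e.mean_distance,
            }
            for e in events
        ],
        columns=[
            "molecule_id",
            "t_start_ns",
            "t_end_ns",
            "duration_ns",
            "min_dist_A",
            "mean_dist_A",
        ],
    )
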
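"""Distance series, persistence-based event detection and statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glucanbind import DistanceSeries, Trajectory, detect_events, distance_series, event_statistics
from glucanbind.binding_events import central_monomer_index
from glucanbind.errors import EventConsistencyError, SelectionError, StrideError
from glucanbind.validation import brute_force_events


def _two_particle_traj(p_site, p_lig, box=100.0, n_frames=5):
    table = pd.DataFrame(
        {
            "particle_id": [0, 1],
            "molecule_id": [0, 1],
            "monomer_index": [-1, 0],
            "role": ["receptor", "ligand"],
            "name": ["site", "monomer"],
        }
    )
    coords = np.broadcast_to(
        np.array([p_site, p_lig]), (n_frames, 2, 3)
    ).copy()
    return Trajectory(
        times=np.arange(n_frames) * 1.0,
        coords=coords,
        box_lengths=(box, box, box),
        table=table,
    )


def _series(below, stride=1.0):
    below = np.asarray(below, dtype=bool)
    return DistanceSeries(
        molecule_id=1,
        times=np.arange(len(below)) * stride,
        distances=np.where(below, 2.0, 9.0),
    )


class TestDistanceSeries:
    def test_constant_distance(self):
        traj = _two_particle_traj([0, 0, 0], [7, 0, 0])
        s = distance_series(traj)[0]
        np.testing.assert_allclose(s.distances, 7.0)

    def test_minimum_image(self):
        traj = _two_particle_traj([0, 0, 0], [99.0, 0, 0], box=100.0)
        s = distance_series(traj)[0]
        np.testing.assert_allclose(s.distances, 1.0)

    def test_monomer_com_is_mass_weighted_mean(self):
        table = pd.DataFrame(
            {
                "particle_id": [0, 1, 2, 3],
                "molecule_id": [0, 1, 1, 1],
                "monomer_index": [-1, 0, 0, 0],
                "role": ["receptor", "ligand", "ligand", "ligand"],
                "name": ["site", "monomer", "monomer", "monomer"],
            }
        )
        pts = np.array([[0, 0, 0], [1.0, 2.0, 3.0], [4.0, -1.0, 0.5], [-2.0, 0.0, 1.0]])
        traj = Trajectory(
            times=np.array([0.0]),
            coords=pts[None, ...],
            box_lengths=(1000, 1000, 1000),
            table=table,
        )
        s = distance_series(traj)[0]
        expected = np.linalg.norm(pts[1:].mean(axis=0))
        assert s.distances[0] == pytest.approx(expected, abs=1e-12)

    def test_even_chain_requires_override(self):
        assert central_monomer_index(5) == 2  # 1-based monomer 3
        with pytest.raises(SelectionError, match="even"):
            central_monomer_index(8)
        assert central_monomer_index(8, override=3) == 3


class TestDetectEvents:
    def test_single_persistent_event(self):
        t = np.arange(0.0, 100.0)
        d = np.where((t >= 10) & (t <= 50), 2.0, 9.0)
        ev = detect_events(DistanceSeries(1, t, d), 5.0, 30.0)
        assert len(ev) == 1
        assert ev[0].duration == pytest.approx(40.0)
        assert ev[0].t_start == 10.0 and ev[0].t_end == 50.0

    def test_short_event_rejected(self):
        t = np.arange(0.0, 100.0)
        d = np.where((t >= 10) & (t <= 30), 2.0, 9.0)
        assert detect_events(DistanceSeries(1, t, d), 5.0, 30.0) == []

    def test_gap_merging_example(self):
        t = np.arange(0.0, 60.0)
        below = ((t >= 0) & (t <= 20)) | ((t >= 22) & (t <= 45))
        s = _series(below)
        merged = detect_events(s, 5.0, 30.0, max_gap=3.0)
        assert len(merged) == 1
        assert (merged[0].t_start, merged[0].t_end) == (0.0, 45.0)
        assert detect_events(s, 5.0, 30.0, max_gap=0.0) == []

    def test_strict_inequalities(self):
        # exactly 30 ns is not > 30 ns; exactly 5.0 Å is not a contact
        t = np.arange(0.0, 100.0)
        d = np.where((t >= 10) & (t <= 40), 2.0, 9.0)
        assert detect_events(DistanceSeries(1, t, d), 5.0, 30.0) == []
        d5 = np.full_like(t, 5.0)
        assert detect_events(DistanceSeries(1, t, d5), 5.0, 0.0) == []

    def test_non_uniform_stride_raises(self):
        s = DistanceSeries(1, np.array([0.0, 1.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(StrideError):
            detect_events(s)

    def test_padding_invariance(self):
        below = [False, True, True, True, True, True, False]
        base = detect_events(_series(below), 5.0, 2.0)
        padded = detect_events(_series([False] * 4 + below + [False] * 6), 5.0, 2.0)
        assert [e.duration for e in base] == [e.duration for e in padded]

    @settings(max_examples=200, derandomize=True)
    @given(
        below=st.lists(st.booleans(), min_size=2, max_size=60),
        min_dur=st.integers(0, 8),
        max_gap=st.integers(0, 4),
    )
    def test_matches_brute_force_enumeration(self, below, min_dur, max_gap):
        s = _series(below)
        got = [(e.t_start, e.t_end) for e in detect_events(s, 5.0, float(min_dur), float(max_gap))]
        want = brute_force_events(
            np.asarray(below, dtype=bool), s.times, max(float(min_dur), 1.0), float(max_gap)
        )
        assert got == want

    @settings(max_examples=100, derandomize=True)
    @given(below=st.lists(st.booleans(), min_size=2, max_size=60))
    def test_monotonicity_properties(self, below):
        s = _series(below)
        t_low = sum(e.duration for e in detect_events(s, 2.0, 0.0))
        t_high = sum(e.duration for e in detect_events(s, 5.0, 0.0))
        assert t_low <= t_high  # lowering the cutoff never adds bound time
        n_strict = len(detect_events(s, 5.0, 5.0))
        n_loose = len(detect_events(s, 5.0, 2.0))
        assert n_strict <= n_loose  # raising persistence never adds events


class TestStatistics:
    def test_bound_fraction(self):
        t = np.arange(0.0, 401.0)
        d = np.where((t >= 100) & (t <= 140), 2.0, 9.0)
        ev = detect_events(DistanceSeries(7, t, d), 5.0, 30.0)
        stats = event_statistics(ev, total_time=400.0)
        assert stats.n_events == 1
        assert stats.bound_fraction == pytest.approx(0.10)
        assert stats.per_molecule.iloc[0]["molecule_id"] == 7

    def test_zero_events(self):
        stats = event_statistics([], total_time=100.0)
        assert stats.n_events == 0
        assert stats.bound_fraction == 0.0

    def test_overlapping_events_rejected(self):
        from glucanbind import BindingEvent

        a = BindingEvent(1, 0.0, 10.0, 1.0, 2.0)
        b = BindingEvent(1, 5.0, 15.0, 1.0, 2.0)
        with pytest.raises(EventConsistencyError):
            event_statistics([a, b], 20.0)
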
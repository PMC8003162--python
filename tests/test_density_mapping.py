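"""Occupancy-density accumulation, ambient normalisation and enrichment."""

import numpy as np
import pandas as pd
import pytest

from glucanbind import (
    GridSpec,
    LigandModel,
    ReceptorModel,
    SelectionQuery,
    SimulationSettings,
    Trajectory,
    accumulate_density,
    ambient_concentration,
    build_toy_system,
    density_summary,
    simulate,
)
from glucanbind.density_mapping import DensityGrid
from glucanbind.errors import AmbientConcentrationError, DensityError


def _static_traj(points, n_frames=100, box=40.0):
    points = np.atleast_2d(points)
    n = len(points)
    table = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "molecule_id": np.arange(1, n + 1),
            "monomer_index": 0,
            "role": "ligand",
            "name": "monomer",
        }
    )
    return Trajectory(
        times=np.arange(n_frames) * 0.1,
        coords=np.broadcast_to(points, (n_frames, n, 3)).copy(),
        box_lengths=(box, box, box),
        table=table,
    )


def _uniform_traj(rng, n_points=1000, n_frames=100, box=40.0):
    coords = (rng.random((n_frames, n_points, 3)) - 0.5) * box
    table = pd.DataFrame(
        {
            "particle_id": np.arange(n_points),
            "molecule_id": np.arange(1, n_points + 1),
            "monomer_index": 0,
            "role": "ligand",
            "name": "monomer",
        }
    )
    return Trajectory(
        times=np.arange(n_frames) * 0.1,
        coords=coords,
        box_lengths=(box, box, box),
        table=table,
    )


GRID = GridSpec(origin=(-20.0, -20.0, -20.0), shape=(20, 20, 20), spacing=2.0)


class TestAccumulate:
    def test_static_particle_counts_and_concentration(self):
        traj = _static_traj([[1.0, 1.0, 1.0]])
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        assert dens.counts.sum() == 100
        assert dens.counts[10, 10, 10] == 100
        assert dens.concentration()[10, 10, 10] == pytest.approx(1.0 / 8.0)

    def test_total_count_conservation(self, rng):
        traj = _uniform_traj(rng)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        assert dens.counts.sum() == 1000 * 100

    def test_monomer_center_of_mass_grouping(self):
        # one monomer split over three particles: counted once, at its COM
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [1.0, 3.0, 0.0]])
        traj = _static_traj(pts, n_frames=10)
        traj.table["molecule_id"] = 1
        traj.table["monomer_index"] = 0
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        assert dens.counts.sum() == 10
        com = pts.mean(axis=0)
        idx, _ = GRID.voxel_indices(com)
        assert dens.counts[tuple(idx)] == 10


class TestAmbient:
    def test_nominal_equals_number_density(self, rng):
        traj = _uniform_traj(rng)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        c = ambient_concentration(dens, None, mode="nominal", box_volume=40.0**3)
        assert c == pytest.approx(1000 / 40.0**3)

    def test_far_field_matches_nominal_within_counting_noise(self, rng):
        traj = _uniform_traj(rng, n_points=1000, n_frames=100)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        receptor = ReceptorModel()
        c_far = ambient_concentration(dens, receptor, exclusion_distance=15.0)
        c_nom = 1000 / 40.0**3
        # binomial counting: samples in the far field
        n_far_vox = 1e5 * c_far / c_nom  # rough; use 3 sigma of total far counts
        assert abs(c_far - c_nom) / c_nom < 3 / np.sqrt(1e5 * 0.1)

    def test_empty_far_field_raises(self, rng):
        traj = _uniform_traj(rng)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        receptor = ReceptorModel()
        with pytest.raises(AmbientConcentrationError):
            ambient_concentration(dens, receptor, exclusion_distance=100.0)

    def test_ratio_requires_ambient(self):
        traj = _static_traj([[1.0, 1.0, 1.0]])
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        with pytest.raises(AmbientConcentrationError):
            dens.ratio()


class TestSummary:
    def test_single_voxel_arithmetic(self):
        traj = _static_traj([[1.0, 1.0, 1.0]])
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        dens.c_amb = dens.concentration()[10, 10, 10] / 50.0
        summ = density_summary(dens, threshold=30.0)
        assert summ.M == pytest.approx(50.0)
        assert summ.volume_above == pytest.approx(8.0)
        assert summ.n_voxels_above == 1

    def test_threshold_monotonicity(self, rng):
        traj = _uniform_traj(rng)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        ambient_concentration(dens, None, mode="nominal", box_volume=40.0**3)
        vols = [density_summary(dens, t).volume_above for t in (0.5, 1.0, 1.5, 30.0)]
        assert vols == sorted(vols, reverse=True)

    def test_invalid_threshold(self, rng):
        traj = _uniform_traj(rng)
        dens = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        ambient_concentration(dens, None, mode="nominal", box_volume=40.0**3)
        with pytest.raises(DensityError):
            density_summary(dens, threshold=0.0)

    def test_duplicated_trajectory_leaves_statistics_unchanged(self, rng):
        traj = _uniform_traj(rng, n_frames=50)
        dens1 = accumulate_density(traj, SelectionQuery(role="ligand"), GRID)
        doubled = Trajectory(
            times=np.arange(100) * 0.1,
            coords=np.concatenate([traj.coords, traj.coords]),
            box_lengths=traj.box_lengths,
            table=traj.table,
        )
        dens2 = accumulate_density(doubled, SelectionQuery(role="ligand"), GRID)
        for d in (dens1, dens2):
            ambient_concentration(d, None, mode="nominal", box_volume=40.0**3)
        s1 = density_summary(dens1, 1.0)
        s2 = density_summary(dens2, 1.0)
        assert s1.M == pytest.approx(s2.M)
        assert s1.volume_above == pytest.approx(s2.volume_above)
        np.testing.assert_allclose(dens1.concentration(), dens2.concentration())


class TestSelectivity:
    def test_narrow_channel_excludes_bulky_ligand(self, receptor):
        """A slim chain enriches >8x at the channel; a bulky variant cannot
        reach it and shows no 8x iso-region anywhere."""
        box = (45.0, 45.0, 45.0)
        grid = GridSpec(origin=(-16.0, -16.0, -16.0), shape=(16, 16, 16), spacing=2.0)
        results = {}
        for name, radius in (("slim", 0.0), ("bulky", 2.5)):
            ligand = LigandModel(n_monomers=3, monomer_radius=radius)
            _, pos0 = build_toy_system(receptor, ligand, 3, box, seed=21)
            s = SimulationSettings(n_steps=2_000_000, box_lengths=box, seed=22, save_stride=20)
            traj = simulate(receptor, ligand, pos0, s)
            dens = accumulate_density(traj, SelectionQuery(role="ligand"), grid)
            ambient_concentration(dens, None, mode="nominal", box_volume=float(np.prod(box)))
            results[name] = density_summary(dens, threshold=8.0)
        assert results["slim"].n_voxels_above > 0
        site_xy = np.asarray(receptor.site_center)
        top = results["slim"].voxels.iloc[0]
        assert np.linalg.norm([top["x"] - site_xy[0], top["y"] - site_xy[1], top["z"] - site_xy[2]]) < 4.0
        assert results["bulky"].n_voxels_above == 0
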
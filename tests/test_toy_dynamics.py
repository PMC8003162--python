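"""Unit tests for the Brownian-dynamics toy system and its ground truth."""

import numpy as np
import pytest
from scipy import stats

from glucanbind import (
    CoordinateSpec,
    LigandModel,
    ReceptorModel,
    SimulationSettings,
    build_toy_system,
    ground_truth_pmf,
    potential_energy,
    simulate,
)
from glucanbind.errors import PackingError, TimestepError
from glucanbind.toy_dynamics import _point_energies


class TestPlacement:
    def test_standoff_respected(self, receptor, chain_ligand):
        _, pos = build_toy_system(receptor, chain_ligand, 3, (60, 60, 60), seed=5)
        d = np.linalg.norm(pos - np.asarray(receptor.bead_centers)[0], axis=1)
        assert np.all(d - receptor.bead_radii[0] >= 8.0)

    def test_same_seed_identical(self, receptor, chain_ligand):
        _, a = build_toy_system(receptor, chain_ligand, 2, (60, 60, 60), seed=9)
        _, b = build_toy_system(receptor, chain_ligand, 2, (60, 60, 60), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_impossible_packing_raises(self, receptor, monomer_ligand):
        with pytest.raises(PackingError, match="standoff"):
            build_toy_system(receptor, monomer_ligand, 1, (12, 12, 12), seed=1)


class TestPotential:
    def test_forces_match_finite_differences(self, receptor, rng):
        """Exact-gradient contract on 100 random multi-chain configurations."""
        ligand = LigandModel(n_monomers=3)
        box = (40.0, 40.0, 40.0)
        h = 1e-5
        worst = 0.0
        for _ in range(100):
            pos = rng.uniform(-10, 10, (6, 3))
            _, F = potential_energy(receptor, pos, ligand, box)
            i = int(rng.integers(6))
            c = int(rng.integers(3))
            p1, p2 = pos.copy(), pos.copy()
            p1[i, c] += h
            p2[i, c] -= h
            num = -(
                potential_energy(receptor, p1, ligand, box)[0]
                - potential_energy(receptor, p2, ligand, box)[0]
            ) / (2 * h)
            worst = max(worst, abs(num - F[i, c]))
        assert worst <= 1e-6

    def test_site_center_energy_is_minus_depth(self):
        r = ReceptorModel(nonspecific_eps=0.0, repulsion_strength=0.0)
        U, _ = potential_energy(r, np.asarray([r.site_center]))
        assert U == pytest.approx(-r.site_depth, abs=1e-9)

    def test_relaxed_bond_has_zero_energy(self):
        ligand = LigandModel(n_monomers=2, bond_length=2.0)
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        U, F = potential_energy(None, pos, ligand)
        assert U == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_kernel_matches_numpy_reference(self, receptor, rng):
        from glucanbind import _kernels
        from glucanbind.toy_dynamics import _ligand_pp

        ligand = LigandModel(n_monomers=3, monomer_radius=0.5)
        bead_c, bead_R, site_c, pp = _ligand_pp(receptor, ligand)
        pos = rng.uniform(-8, 8, (6, 3))
        F = np.zeros_like(pos)
        box = np.array([40.0, 40.0, 40.0])
        Uk = _kernels._forces(pos, F, bead_c, bead_R, site_c, pp, 3, box)
        Un, Fn = potential_energy(receptor, pos, ligand, box)
        assert Uk == pytest.approx(Un, rel=1e-12)
        np.testing.assert_allclose(F, Fn, atol=1e-10)


class TestDynamics:
    def test_free_diffusion_msd(self):
        """<|Δx|²> = 6 D t for non-interacting particles."""
        ligand = LigandModel(n_monomers=1)
        n = 1000
        pos0 = np.zeros((n, 3))
        s = SimulationSettings(
            n_steps=10_000, box_lengths=(1e6, 1e6, 1e6), timestep=1e-4,
            diffusion=100.0, seed=3, save_stride=10_000,
        )
        traj = simulate(None, ligand, pos0, s)
        t = traj.times[-1]
        msd = float(np.mean(np.sum(traj.coords[-1] ** 2, axis=1)))
        assert msd == pytest.approx(6 * 100.0 * t, rel=0.05)

    def test_harmonic_bond_variance(self):
        """Boltzmann statistics: bond-length variance approaches kBT/k."""
        k = 10.0
        ligand = LigandModel(n_monomers=2, bond_length=4.0, bond_stiffness=k)
        pos0 = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        s = SimulationSettings(
            n_steps=1_000_000, box_lengths=(1e6, 1e6, 1e6), timestep=2e-5,
            diffusion=100.0, seed=4, save_stride=10,
        )
        traj = simulate(None, ligand, pos0, s)
        b = np.linalg.norm(traj.coords[100:, 1, :] - traj.coords[100:, 0, :], axis=1)
        assert np.var(b) == pytest.approx(s.kT / k, rel=0.05)

    def test_external_bias_harmonic_well(self):
        """The Python external-bias path samples the biased Boltzmann state."""
        k = 5.0
        ligand = LigandModel(n_monomers=1)
        s = SimulationSettings(
            n_steps=20_000, box_lengths=(1e6, 1e6, 1e6), timestep=2e-5,
            diffusion=100.0, seed=4, save_stride=5,
        )
        traj = simulate(
            None, ligand, np.zeros((1, 3)), s, external_bias=lambda pos, step: -k * pos
        )
        x = traj.coords[800:, 0, :].ravel()
        assert np.var(x) == pytest.approx(s.kT / k, rel=0.25)

    def test_same_seed_bit_identical(self, receptor, monomer_ligand):
        box = (40, 40, 40)
        _, pos0 = build_toy_system(receptor, monomer_ligand, 1, box, seed=2)
        s = SimulationSettings(n_steps=5_000, box_lengths=box, seed=42, save_stride=50)
        a = simulate(receptor, monomer_ligand, pos0, s)
        b = simulate(receptor, monomer_ligand, pos0, s)
        np.testing.assert_array_equal(a.coords, b.coords)
        s2 = SimulationSettings(n_steps=5_000, box_lengths=box, seed=43, save_stride=50)
        c = simulate(receptor, monomer_ligand, pos0, s2)
        assert not np.array_equal(a.coords, c.coords)

    def test_oversized_timestep_raises(self, receptor, monomer_ligand):
        box = (40, 40, 40)
        _, pos0 = build_toy_system(receptor, monomer_ligand, 1, box, seed=2)
        s = SimulationSettings(n_steps=1_000, box_lengths=box, timestep=0.1, seed=1)
        with pytest.raises(TimestepError, match="timestep"):
            simulate(receptor, monomer_ligand, pos0, s)

    def test_boltzmann_sampling_chi_square(self):
        """Long-run cell occupancy follows exp(-U/kBT) on a coarse grid."""
        r = ReceptorModel(site_depth=2.0)
        ligand = LigandModel(n_monomers=1)
        box = (15.0, 15.0, 15.0)
        s = SimulationSettings(
            n_steps=20_000_000, box_lengths=box, seed=8, save_stride=40_000
        )
        traj = simulate(receptor=r, ligand=ligand, positions0=np.array([[0, 0, 6.0]]), settings=s)
        samples = traj.coords[1:, -1, :]
        # coarse 3x3x3 cells of 5 Å; expected weights by fine sub-quadrature
        edges = np.linspace(-7.5, 7.5, 4)
        fine = np.arange(-7.5 + 0.25, 7.5, 0.5)
        X, Y, Z = np.meshgrid(fine, fine, fine, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        boltz = np.exp(-_point_energies(r, pts) / s.kT)
        cell = tuple(np.clip(((pts[:, c] + 7.5) // 5).astype(int), 0, 2) for c in range(3))
        weights = np.zeros((3, 3, 3))
        np.add.at(weights, cell, boltz)
        p = (weights / weights.sum()).ravel()
        obs_cell = tuple(np.clip(((samples[:, c] + 7.5) // 5).astype(int), 0, 2) for c in range(3))
        obs = np.zeros((3, 3, 3))
        np.add.at(obs, obs_cell, 1.0)
        obs = obs.ravel()
        n = obs.sum()
        keep = p * n >= 5
        chi2 = float(np.sum((obs[keep] - n * p[keep]) ** 2 / (n * p[keep])))
        dof = int(keep.sum()) - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)

    def test_reversible_binding_fixture_contract(self, receptor, monomer_ligand):
        """Default parameters give repeated association AND dissociation."""
        from glucanbind import detect_events, distance_series

        box = (45.0, 45.0, 45.0)
        _, pos0 = build_toy_system(receptor, monomer_ligand, 1, box, seed=6)
        s = SimulationSettings(n_steps=10_000_000, box_lengths=box, seed=6, save_stride=50)
        traj = simulate(receptor, monomer_ligand, pos0, s)
        series = distance_series(traj)[0]
        events = detect_events(series, contact_cutoff=5.0, min_duration=0.02)
        assert len(events) >= 3
        dissociations = [e for e in events if e.t_end < series.times[-1]]
        assert len(dissociations) >= 3


class TestGroundTruth:
    def test_minimum_at_site_center(self, receptor):
        spec = CoordinateSpec(
            lo=(-3, -3, -3), hi=(3, 3, 3), width=0.25, reference=receptor.site_center
        )
        fmap = ground_truth_pmf(receptor, spec)
        pos = np.asarray(fmap.min_position()) + np.asarray(receptor.site_center)
        np.testing.assert_allclose(pos, receptor.site_center, atol=0.25)
        assert np.nanmin(fmap.values) == 0.0

    def test_flat_potential_is_constant(self):
        spec = CoordinateSpec(lo=(-2,), hi=(2,), width=0.5, axes=("x",))
        fmap = ground_truth_pmf(None, spec)
        np.testing.assert_allclose(fmap.values, 0.0, atol=1e-12)

    def test_matches_unbiased_histogram_on_slice(self, receptor):
        """-kBT ln p along a 1D slice reproduces the exact profile."""
        ligand = LigandModel(n_monomers=1)
        box = (20.0, 20.0, 20.0)
        s = SimulationSettings(n_steps=8_000_000, box_lengths=box, seed=12, save_stride=20)
        traj = simulate(receptor, ligand, np.array([[0.0, 0.0, 6.0]]), s)
        pos = traj.coords[:, -1, :]
        # slice: |x|,|y| < 1 Å column through the site, z profile
        m = (np.abs(pos[:, 0]) < 1.0) & (np.abs(pos[:, 1]) < 1.0) & (pos[:, 2] > 3.0) & (pos[:, 2] < 9.0)
        counts, edges = np.histogram(pos[m, 2], bins=12, range=(3.0, 9.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = -s.kT * np.log(counts)
        w -= w.min()
        # exact profile of the same observable: column-averaged Boltzmann
        # weight over |x|,|y| < 1 and the z-bin width
        xy = np.linspace(-0.95, 0.95, 20)
        exact = np.empty_like(centers)
        for i, zc in enumerate(centers):
            zz = np.linspace(zc - 0.2, zc + 0.2, 5)
            X, Y, Z = np.meshgrid(xy, xy, zz, indexing="ij")
            pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
            boltz = np.exp(-_point_energies(receptor, pts) / s.kT)
            exact[i] = -s.kT * np.log(boltz.mean())
        exact -= exact.min()
        err = np.abs(w - exact)[counts > 200]
        assert np.max(err) < 0.35  # a few kBT·N^{-1/2} of counting noise
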
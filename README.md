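# glucanbind

Analytics for receptor–ligand binding in particle simulations: 3D
occupancy-density enrichment maps, persistence-based binding-event
detection, adaptive-biasing-force (ABF) free-energy mapping, and a staged
geometric-restraint absolute binding free energy with conversion to a
dissociation constant.

The scientific setting is the computational case for weak, site-specific
binding of short β-1,3 oligoglucans (5-mer/8-mer glucose chains) to the
T-cell costimulatory receptor CD28: simulations of ligands diffusing
around a receptor are screened for regions where the ligand-monomer
density far exceeds its ambient concentration, persistent contacts with
the candidate site are catalogued as binding events, the free-energy
landscape around the site is mapped with ABF, and a staged restraint
protocol turns the landscape into a standard-state ΔG° and a Kd range in
the millimolar regime.

Because all-atom trajectories are not reproducible at desk scale, the
package pairs the analysis stack with its own synthetic data source: an
overdamped-Langevin (Brownian) simulator of a bead-chain ligand around a
rigid bead receptor carrying a narrow Gaussian "channel" site.  The model
potential is analytic, so every stage of the pipeline is validated against
exact ground truth (quadrature of the potential, Boltzmann occupancies,
brute-force event enumeration).

## The quantities computed

- **Enrichment statistic M** — the maximum over a 2 Å grid of
  c(v)/c_ambient, the mean ligand-monomer concentration per voxel divided
  by its far-field value, plus the volume of the iso-region above a
  threshold (30× or 8× ambient).
- **Binding events** — maximal runs of frames with the central monomer's
  minimum-image COM distance to the site < 5 Å, kept when they persist
  > 30 ns (both defaults configurable; optional gap merging).
- **ABF free-energy maps** — per-bin running-mean force with the bias
  −⟨F⟩·min(1, n/n_full), least-squares integration of the gradient field,
  and minimum projections F₂(x,y) = min_z F(x,y,z).
- **Staged ΔG°** — nine bookkeeping terms: restrain the bound ligand
  (conformation, orientation, position), separate it at the standard state
  via −k_BT·ln(S\*·I\*·C°), release the restraints in bulk (one simulated,
  one analytic).  The sum is the standard binding free energy;
  Kd = C°·e^{ΔG°/k_BT}.

## Worked example

Assembling the published stage table for the 8-mer ligand (shipped as a
fixture) into the total and the Kd range:

```bash
glucanbind fixtures --seed 7 --out demo/
glucanbind dg-table --stages demo/stages.csv
```

prints (abbreviated):

```json
{
  "dG0": -2.57,
  "uncertainty": 0.3739,
  "Kd_central_mM": 15.4237,
  "Kd_low_mM": 8.4061,
  "Kd_high_mM": 28.2996,
  "T_K": 310.0
}
```

The nine stage values sum to −2.57 kcal/mol at 310 K, i.e. a central Kd
of ≈15 mM — weak but genuine binding, in the concentration regime where
oligoglucans are biologically active.  (The root-sum-square uncertainty
shown, ±0.37, differs from the ±0.48 quoted alongside the original table;
neither quadrature nor absolute summation reproduces that value, so both
combination rules are provided and the discrepancy is documented rather
than hidden.)

Running the staged protocol end-to-end on the toy system and checking it
against the independent quadrature oracle:

```python
from glucanbind import (ReceptorModel, LigandModel, SimulationSettings,
                        staged_dg_toy, quadrature_dg_reference, ThermoConstants)

receptor = ReceptorModel()               # single bead + narrow channel site
ligand = LigandModel(n_monomers=1)
settings = SimulationSettings(n_steps=1, box_lengths=(40, 40, 40))
res = staged_dg_toy(receptor, ligand, settings, seed=11, abf_steps=2_000_000)
print(f"dG0 = {res.dG0:+.2f} +/- {res.uncertainty:.2f} kcal/mol; "
      f"Kd = {res.kd_central*1e3:.0f} mM")
print(f"oracle = {quadrature_dg_reference(receptor, ThermoConstants(310.0)):+.2f} kcal/mol")
```

```
dG0 = -0.53 +/- 0.01 kcal/mol; Kd = 420 mM
oracle = -0.60 kcal/mol
```

The staged estimate (two pooled ABF replicas over the separation
coordinate) agrees with direct 3D quadrature of the model potential to
well under 0.1 kcal/mol at the default run lengths.

The full pipeline — simulate, align, density map, events, 3D ABF, staged
ΔG° and a markdown report — runs from one config:

```bash
glucanbind run --seed 7 --out run/        # built-in demo configuration
```

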
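# Methods

This note records the models, estimators and numerical choices behind
glucanbind, and what the validation suite does and does not establish.

## The synthetic receptor–ligand system

The data source is an overdamped Langevin (Brownian) simulation

x(t+Δt) = x(t) + (D/k_BT)·F(x)·Δt + √(2DΔt)·ξ,  ξ ~ N(0,1),

in a periodic box with minimum-image distances.  Overdamped dynamics were
chosen over inertial Langevin because they are simpler, have one fewer
parameter, and sample exactly the same Boltzmann distribution — which is
all the downstream analyses depend on.  Units are Å, ns, kcal/mol;
k_B = 0.0019872041 kcal/mol/K, T = 310 K by default.

The receptor is a rigid set of soft-core beads (taking literally the
common practice of restraining a receptor's core during simulation).  Its
potential, per ligand monomer at distance d from a bead of radius R:

- soft-core wall: A/(1+exp((d−R−ρ)/λ)), finite everywhere and C¹ away
  from bead centres; ρ is the ligand's monomer radius, so bulky ligands
  are excluded from narrow geometry — the mechanism behind the
  slim-vs-bulky selectivity test;
- nonspecific surface shell: −ε·exp(−(d−R−ρ)²/2w²), a weak attraction
  everywhere on the surface;
- one anisotropic Gaussian channel site:
  −depth·exp(−½Σ((x−s_i)/σ_i)²) at a point just outside a bead surface.

The ligand is a freely-jointed harmonic bead chain (bond energy
½k(ℓ−b)²); deliberately no angle or torsion terms.  The chemistry that
makes a real oligoglucan lie flat in a receptor channel is not modelled —
site selectivity here is purely geometric.

Default study conditions, chosen once: bead radius 3 Å, wall A = 15
kcal/mol, λ = 0.5 Å; site at (0,0,4.8) with depth 5 kcal/mol and widths
(1.1, 1.1, 1.6) Å; surface shell ε = 0.3 kcal/mol, w = 1.5 Å; D = 100
Å²/ns; Δt = 5·10⁻⁵ ns.  The wall sharpness matters: the sigmoid tail
reaches past the site, so the *effective* well depth is the site depth
minus the residual wall energy (~0.4 kcal/mol here).  With these values a
single-monomer ligand binds with ΔG° ≈ −0.6 kcal/mol (Kd ≈ 0.4 M,
occupancy ≈ 6% at one ligand per 40³ Å box) and shows many association/
dissociation cycles per 10⁷ steps — the reversibility the event detector
needs.  A 5-mer binds far more strongly (all monomers can occupy the
well), which usefully exercises the staged bookkeeping at a deeper ΔG°.

The timestep respects the stiffest feature of the landscape: the largest
curvature (wall ≈ 6 kcal/mol/Å²) gives a relaxation time k_BT/(D·U'') ≈
10⁻³ ns, 20× the step.  The residual Euler–Maruyama bias in stationary
variances is ≲2%; a per-step displacement cap of 1 Å converts parameter
mistakes into an explicit error instead of silent instability.

## Density maps and the M statistic

Ligand-monomer positions (a monomer's position is its centre of mass) are
binned on a half-open regular grid (2 Å default).  The concentration
c(v) = counts/(frames·spacing³) is normalised by the ambient concentration
to give the enrichment ratio field; M is its maximum, and iso-region
volumes count voxels with ratio ≥ threshold.

The ambient concentration has no universal estimator; the default here is
the far-field voxel mean, excluding voxels within 15 Å of the receptor
surface, with a nominal (N/V) mode as cross-check — the two agree within
counting noise on uniform systems.  Voxels overlapping the receptor are
not masked; their ratios are reported as-is.  No smoothing is applied by
default (a Gaussian-filter option exists for visualisation).

Validation: on uniform (ideal-gas) data M stays within Poisson
fluctuations of 1; on long unbiased runs of the default system the 30×
iso-region matches the analytic Boltzmann level set {x : e^{−βU(x)} ≥ 30}
(voxel-averaged, by sub-voxel quadrature) to within ±2 voxels, and the
argmax voxel falls within one voxel of the channel centre.  The site
centre sits on a voxel-boundary plane of the default grid, so a one-voxel
argmax offset is expected from the symmetric split of the well.

## Binding events

Events are maximal runs of frames with minimum-image COM distance below a
strict cutoff (< 5 Å), emitted when their duration strictly exceeds the
persistence threshold (30 ns default).  Runs separated by above-cutoff
stretches of total duration ≤ max_gap can be merged (off by default; the
literature criterion gives no merging rule, so merging is opt-in).  The
"central monomer" of an even-length chain is ambiguous and must be given
explicitly.  The detector is checked for exact agreement against an
independent brute-force run-length enumeration on randomized series, and
event bound-fractions on the toy system against exact Boltzmann
occupancies across independent seeds.

## ABF estimator

Per bin b of 1–3 transition coordinates the estimator keeps n(b) and the
force-sample sum S(b); the applied bias is −(S/n)·min(1, n/n_full) with
n_full = 200 samples (the ramp protects barely-sampled bins; the value is
a convergence dial, not physics).  For Cartesian displacement coordinates
of a monomer relative to a fixed reference the instantaneous sample is
the bare systematic force component — no Jacobian correction is needed.
The radial (distance-to-site) coordinate carries the +2k_BT/r entropic
term, so the integrated w(r) is the true radial PMF including the r²
measure.  Domain confinement uses half-harmonic walls (20 kcal/mol/Å²;
stiffer walls are unstable at the default timestep because the wall
relaxation time drops below Δt).  Wall and bias forces are excluded from
the samples.

Free-energy maps come from least-squares integration of the negative mean
force: for every adjacent sampled bin pair, (F_{b+e}−F_b)/h is matched to
the average of the two bin gradients; the sparse system is solved by LSQR
and each connected sampled component gauged to min-zero.  In 1D this
reduces exactly to cumulative trapezoidal integration.  Unsampled bins
are masked, never inpainted.  Replicas pool by summing n and S, i.e. the
pooled mean force is the sample mean of the union.

Accuracy at the shipped problem sizes (5·10⁶ steps, 0.25 Å bins): mean
force RMSE ≈ 0.006 kcal/mol/Å on a k = 2 harmonic fixture; a 3 kcal/mol
double-well barrier is recovered to ≈2% (the residual is dominated by
integrator discretization, not sampling noise).

## Staged absolute binding free energy

The decomposition: restrain the bound ligand (stages 1–6: conformation as
bond-length RMSD, orientation as chain-axis angles, position as polar/
azimuth about the site), separate at standard state (stage 7), release
restraints on the free ligand (stage 8 simulated, stage 9 analytic).
Each restraint stage uses
ΔG = −k_BT·ln[∫e^{−β(w+u)}dμ / ∫e^{−βw}dμ] with the sinθ measure for
polar angles; printed stage values for the bound side carry a minus sign
so that the nine-term arithmetic sum is ΔG°_bind.  Stage 7 is
−k_BT·ln(S\*·I\*·C°) with C° = 1/1661 Å⁻³, S\* the restrained angular
area at the bulk reference separation r\* (exactly 4πr\*² when no angular
restraints are imposed) and I\* = ∫_well e^{−βw(r)}dr with w gauged to
zero at r\*.  With this gauge S\*·I\* equals the configurational integral
of the bound region, so for a single-monomer ligand the stage-7 term
alone is the binding free energy — the identity behind the quadrature
oracle test.  Uncertainties follow the two-segment rule (maximum
deviation of either half-data value from the full value); stage 7 uses
two independent replicas as its segments.  The total uncertainty is the
root-sum-square of stage uncertainties by default (absolute summation is
available; for the published 8-mer table neither rule reproduces the
quoted total uncertainty, which is why both are exposed).

Toy reduction.  Only the conformational restraint is imposed on the toy
chain.  Rigid-body orientation restraints are ill-posed for a
freely-jointed chain — its end-to-end axis can pass through zero, where
the restraint torque k·Δ/|axis| diverges — and positional angle
restraints are singular for a ligand bound at the reference point.  The
decomposition is exact for any restraint subset (an omitted restraint's
freedom simply stays inside the stage-7 PMF), so stages 2–6 and 9 are
exact zeros for the toy while remaining fully implemented and validated
against stiff-spring Gaussian closed forms for use with systems where
they are well-posed.  Stage PMFs for barrier-free coordinates
(bond RMSD) are estimated by unbiased histogramming (−k_BT ln p) rather
than ABF; the quadrature boundary check is disabled for histogram PMFs,
whose support edge is a sampling artifact rather than a truncated
integrand.

Defaults: restraint constants 10 kcal/mol/Å² (distance/RMSD) and 0.1
kcal/mol/deg² (angles); r\* = 13 Å, well boundary 6 Å, radial domain
0–14 Å at 0.25 Å bins; 6·10⁶ steps per stage-7 replica, 10⁶ per histogram
stage; angular quadratures at 1° (0.25° in the stiff-limit tests).
Halving any quadrature resolution moves the terms by < 10⁻³ kcal/mol.
If stage-7 sampling never reaches r\*, the term is gauged at the farthest
sampled separation and the result flagged with a warning instead of
failing.

## Validation studies and their scope

`glucanbind.validation` holds the seeded studies the acceptance script
re-runs: ABF fixtures (harmonic, double well), staged-ΔG° vs a 0.05 Å 3D
quadrature of the model potential (agreement ≲0.05 kcal/mol, tolerance
0.3), a ten-seed occupancy study comparing the event-detector bound
fraction with exact Boltzmann occupancy and the occupancy-route ΔG° with
the staged route, the density level-set/argmax study, uniform-density
null, event brute-force oracle and closed-form restraint limits.  Problem
sizes (5·10⁶–6·10⁶ steps per run, 8-ligand density runs of 600k frames,
10 occupancy seeds) were fixed once for statistical adequacy of each
comparison.

What passing does not show: the toy system has no solvent, no
electrostatics, no ligand–ligand excluded volume, no conformational
chemistry, and a rigid receptor.  The validation establishes that the
*analytics* — density normalisation, event logic, ABF estimator,
gradient integration, staged bookkeeping and unit conversions — are
correct on a system where truth is computable.  It says nothing about
force-field accuracy or sampling adequacy for real all-atom trajectories,
and the published per-stage values for the 8-mer/CD28 system are not
reproducible here (they depend on the original trajectories and
unpublished restraint parameters).  The published stage *table*, shipped
as a fixture, is used only for arithmetic: its nine values sum to −2.57
kcal/mol, consistent with the quoted −2.56 ± 0.48 (Kd 7–34 mmol/L at
310 K) and inconsistent with the table's own total row (−2.46), a
discrepancy the package reports rather than resolves.

## Known limitations

- The Python `external_bias` path of `simulate()` uses numpy's RNG, the
  fused kernels numba's: each path is bit-reproducible per seed, but they
  are only statistically equivalent to each other.
- Alignment assumes whole (unwrapped) reference coordinates; for the
  rigid toy receptor it is an exact identity but stays in the pipeline so
  real trajectories traverse the same path.
- Ambient concentration in small boxes is biased high by the site's own
  excess occupancy; the exclusion-distance default (15 Å) assumes the box
  comfortably exceeds the receptor.
- `staged_dg_toy` assumes one ligand molecule and one binding site.
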
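"""Restraint free-energy terms, Kd conversion and the staged assembly."""

import math

import numpy as np
import pytest

from glucanbind import (
    LigandModel,
    RestraintDefinition,
    SimulationSettings,
    StageFreeEnergy,
    ThermoConstants,
    assemble_total,
    kd_from_dg,
    restraint_term,
    separation_term,
    staged_dg_toy,
    two_segment_uncertainty,
    unbound_orientation_term,
)
from glucanbind.binding_dg import angular_surface, gauge_pmf
from glucanbind.errors import GaugeError, TruncationError

C = ThermoConstants(310.0)
KT = C.kT


class TestRestraintTerm:
    def test_zero_restraint_is_exactly_zero(self):
        xi = np.linspace(-3, 3, 101)
        w = np.sin(xi)  # arbitrary PMF
        rdef = RestraintDefinition("conformation", 0.0, 0.0, "A")
        assert restraint_term(xi, w, rdef, C) == 0.0

    def test_flat_pmf_gaussian_closed_form(self):
        k, L = 100.0, 10.0
        xi = np.linspace(-L, L, 40001)
        rdef = RestraintDefinition("conformation", 0.0, k, "A")
        got = restraint_term(xi, np.zeros_like(xi), rdef, C)
        want = -KT * math.log(math.sqrt(2 * math.pi * KT / k) / (2 * L))
        assert got == pytest.approx(want, rel=1e-3)

    def test_product_of_gaussians_closed_form(self):
        k_w, k_u = 3.0, 7.0
        xi = np.linspace(-6, 6, 20001)
        w = 0.5 * k_w * xi**2
        rdef = RestraintDefinition("conformation", 0.0, k_u, "A")
        got = restraint_term(xi, w, rdef, C)
        want = -(KT / 2) * math.log(k_w / (k_w + k_u))
        assert got == pytest.approx(want, rel=1e-4)

    def test_truncated_domain_raises(self):
        xi = np.linspace(-1, 1, 101)
        rdef = RestraintDefinition("conformation", 0.0, 0.01, "A")  # too soft to decay
        with pytest.raises(TruncationError):
            restraint_term(xi, np.zeros_like(xi), rdef, C)

    def test_quadrature_converges_under_refinement(self):
        k = 50.0
        rdef = RestraintDefinition("conformation", 0.0, k, "A")
        vals = []
        for n in (2001, 4001):
            xi = np.linspace(-5, 5, n)
            vals.append(restraint_term(xi, 0.1 * xi**2, rdef, C))
        assert abs(vals[1] - vals[0]) < 1e-3


class TestSeparationTerm:
    def test_standard_volume_cancellation(self):
        # S* I* = 1661 Å^3 exactly -> term is 0
        r_star = 5.0
        L = 1661.0 / (4 * math.pi * r_star**2)
        r = np.linspace(0.0, L, 601)  # grid ends exactly at the well boundary
        w = np.zeros_like(r)
        val, geom = separation_term(r, w, r_star, C, well_boundary=L)
        assert val == pytest.approx(0.0, abs=1e-9)
        assert geom.S_star == pytest.approx(4 * math.pi * r_star**2)

    def test_square_well_closed_form(self):
        beta = C.beta
        rb, r_star = 4.0, 8.0
        # w = -5 on [0, 2], 0 elsewhere; duplicated knot makes the step exact
        r = np.concatenate([np.linspace(0, 2, 201), [2.0], np.linspace(2 + 1e-12, rb, 201), [r_star]])
        w = np.concatenate([np.full(201, -5.0), [0.0], np.zeros(202)])
        val, geom = separation_term(r, w, r_star, C, well_boundary=rb)
        I_want = 2 * math.exp(5 * beta) + (rb - 2)
        assert geom.I_star == pytest.approx(I_want, rel=1e-6)
        want = -KT * math.log(4 * math.pi * r_star**2 * I_want / 1661.0)
        assert val == pytest.approx(want, abs=1e-6)

    def test_ungauged_pmf_rejected(self):
        r = np.linspace(0, 10, 101)
        w = np.full_like(r, 0.5)
        with pytest.raises(GaugeError):
            separation_term(r, w, 9.0, C)
        w2 = gauge_pmf(r, w, 9.0)
        val, _ = separation_term(r, w2, 9.0, C, well_boundary=5.0)
        assert np.isfinite(val)

    def test_stiff_angular_surface_limit(self):
        k, r_star = 500.0, 10.0
        rds = [
            RestraintDefinition("polar_theta", math.pi / 2, k, "rad"),
            RestraintDefinition("azimuth_phi", 0.0, k, "rad"),
        ]
        S = angular_surface(rds, r_star, C, resolution_deg=0.25)
        want = r_star**2 * (2 * math.pi * KT / k)
        assert S == pytest.approx(want, rel=5e-3)


class TestUnboundOrientation:
    def test_zero_restraints_exactly_zero(self):
        assert unbound_orientation_term([], C) == 0.0
        rds = [RestraintDefinition("euler_theta", 1.0, 0.0, "rad")]
        assert unbound_orientation_term(rds, C) == 0.0

    def test_stiff_limit_closed_form(self):
        k = 500.0
        rds = [
            RestraintDefinition("euler_theta", math.pi / 2, k, "rad"),
            RestraintDefinition("euler_phi", 0.0, k, "rad"),
            RestraintDefinition("euler_psi", 0.0, k, "rad"),
        ]
        got = unbound_orientation_term(rds, C, resolution_deg=0.25)
        want = -KT * math.log((2 * math.pi * KT) ** 1.5 / (8 * math.pi**2 * k**1.5))
        assert got == pytest.approx(want, rel=5e-3)
        assert got > 0

    def test_monotone_in_each_force_constant(self):
        ks = [0.0, 1.0, 10.0, 100.0, 500.0]
        prev = None
        values = np.empty((5, 5, 5))
        for i, kT_ in enumerate(ks):
            for j, kP in enumerate(ks):
                for l, kS in enumerate(ks):
                    rds = [
                        RestraintDefinition("euler_theta", math.pi / 2, kT_, "rad"),
                        RestraintDefinition("euler_phi", 0.0, kP, "rad"),
                        RestraintDefinition("euler_psi", 0.0, kS, "rad"),
                    ]
                    values[i, j, l] = unbound_orientation_term(rds, C, resolution_deg=2.0)
        for axis in range(3):
            assert np.all(np.diff(values, axis=axis) >= -1e-9)


class TestKdConversion:
    def test_published_headline_rounds_to_reported_range(self):
        central, low, high = kd_from_dg(-2.56, 0.48, C)
        assert round(low * 1000) == 7
        assert round(high * 1000) == 34
        assert central * 1000 == pytest.approx(15.7, abs=0.05)

    def test_standard_state_identity(self):
        central, low, high = kd_from_dg(0.0, 0.0, C)
        assert central == low == high == 1.0

    def test_strictly_increasing_and_inverse_law(self):
        for x in (2.0, 10.0, 123.0):
            dg = -KT * math.log(x)
            assert kd_from_dg(dg, 0.0, C)[0] == pytest.approx(1.0 / x, rel=1e-12)
        assert kd_from_dg(-1.0, 0, C)[0] < kd_from_dg(-0.5, 0, C)[0]


class TestAssembly:
    VALUES = [-6.79, -0.46, -0.48, -0.37, -0.20, -0.10, -8.46, 7.49, 6.80]

    def _stages(self, values=None):
        values = self.VALUES if values is None else values
        return [
            StageFreeEnergy(i + 1, f"s{i + 1}", v, 0.1) for i, v in enumerate(values)
        ]

    def test_reported_stage_values_sum(self):
        result = assemble_total(self._stages(), C)
        assert result.dG0 == pytest.approx(-2.57, abs=1e-9)

    def test_order_invariance(self):
        stages = self._stages()
        shuffled = [stages[i] for i in (3, 8, 0, 5, 2, 7, 1, 6, 4)]
        assert assemble_total(shuffled, C).dG0 == pytest.approx(-2.57)

    def test_all_zero_gives_unit_kd(self):
        result = assemble_total(self._stages([0.0] * 9), C)
        assert result.dG0 == 0.0
        assert result.kd_central == pytest.approx(1.0)

    def test_missing_stage_rejected(self):
        with pytest.raises(ValueError, match="stages 1..9"):
            assemble_total(self._stages()[:8], C)

    def test_uncertainty_combination_modes(self):
        rss = assemble_total(self._stages(), C).dG0
        r1 = assemble_total(self._stages(), C, combine_uncertainty="rss")
        r2 = assemble_total(self._stages(), C, combine_uncertainty="sum_abs")
        assert r1.uncertainty == pytest.approx(0.1 * 3)
        assert r2.uncertainty == pytest.approx(0.9)
        assert r1.kd_low <= r1.kd_central <= r1.kd_high

    def test_two_segment_uncertainty(self):
        assert two_segment_uncertainty(1.00, 0.90, 1.05) == pytest.approx(0.10)
        assert two_segment_uncertainty(3.3, 3.3, 3.3) == 0.0
        assert two_segment_uncertainty(1.0, 0.8, 1.1) == two_segment_uncertainty(1.0, 1.1, 0.8)


class TestStagedToy:
    def test_chain_protocol_structure(self, receptor):
        """Scaled-down 3-mer staged run: bookkeeping structure and the
        near-cancellation of the site/bulk conformational terms."""
        ligand = LigandModel(n_monomers=3)
        settings = SimulationSettings(n_steps=1, box_lengths=(40, 40, 40))
        result = staged_dg_toy(
            receptor, ligand, settings, seed=3, abf_steps=150_000, sample_steps=60_000
        )
        assert [s.stage for s in result.stages] == list(range(1, 10))
        for s in result.stages:
            assert np.isfinite(s.value)
        # orientation stages vanish for the toy chain
        for i in (1, 2, 3, 4, 5, 8):
            assert result.stages[i].value == 0.0
        # conformational restraint nearly cancels between site and bulk
        assert abs(result.stages[0].value + result.stages[7].value) < 0.3
        assert result.stages[0].value < 0 < result.stages[7].value
        assert result.kd_low <= result.kd_central <= result.kd_high
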
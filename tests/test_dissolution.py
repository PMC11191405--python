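"""Binding energies, energy differentials, modified model and ratios."""

import numpy as np
import pytest

from facetsolv import (FaceModelInput, binding_energy, dissolution_ratio,
                       energy_differential, modified_binding_energy,
                       normalize_by_mw, percent_discrepancy,
                       predict_dissolution)
from facetsolv.dissolution import BindingEnergyResult
from facetsolv.errors import AnalysisError, ConvergenceError, GeometryError
from facetsolv.fixtures import brute_force_pair_oracle
from facetsolv.forcefield import pair_energy
from facetsolv.structures import Atom, CrystalStructure, Molecule, UnitCell


def single_atom_cubic(a: float) -> CrystalStructure:
    cell = UnitCell(a, a, a, 90, 90, 90)
    mol = Molecule([Atom("Ar", [0.0, 0.0, 0.0], 0.0, "X_")], label="m")
    return CrystalStructure(cell, [mol], [(np.eye(3), np.zeros(3))], [mol])


class TestBindingEnergy:
    def test_single_contribution_closed_form(self, params):
        # cubic a = 4 Å single-atom crystal, face (100): only the +x
        # neighbor at 4 Å passes the -0.01 kcal/mol threshold, so
        # E_b = E_pair(4 Å) / 4 exactly
        crystal = single_atom_cubic(4.0)
        res = binding_energy(crystal, (1, 0, 0), params)
        e_pair = pair_energy(crystal.full_cell[0].atoms[0],
                             crystal.full_cell[0].atoms[0], 4.0, params).e_total
        assert e_pair <= -0.01
        assert len(res.contributions) == 1
        assert res.e_b == pytest.approx(e_pair / 4.0, abs=1e-12)

    def test_matches_independent_enumeration_oracle(self, params,
                                                    polar_crystal):
        res = binding_energy(polar_crystal, (0, 0, 1), params, max_shell=6)
        # oracle: direct loop over all images in a fixed supercell
        cellm = polar_crystal.cell.matrix
        normal = np.linalg.inv(cellm).T[2]
        normal = normal / np.linalg.norm(normal)
        center = polar_crystal.cell.frac_to_cart(np.array([0.5, 0.5, 0.5]))
        ref_i = int(np.argmin([np.linalg.norm(m.centroid - center)
                               for m in polar_crystal.full_cell]))
        ref = polar_crystal.full_cell[ref_i]
        expected = 0.0
        n_terms = 0
        for i in range(-4, 5):
            for j in range(-4, 5):
                for k in range(-4, 5):
                    shift = i * cellm[0] + j * cellm[1] + k * cellm[2]
                    for mi, mol in enumerate(polar_crystal.full_cell):
                        if i == j == k == 0 and mi == ref_i:
                            continue
                        other = mol.translated(shift)
                        if np.dot(other.centroid - ref.centroid, normal) <= 1e-9:
                            continue
                        d, h, c = brute_force_pair_oracle(ref, other, params)
                        e = d + h + c
                        if e <= -0.01:
                            expected += e / np.linalg.norm(other.centroid - ref.centroid)
                            n_terms += 1
        assert len(res.contributions) == n_terms
        assert res.e_b == pytest.approx(expected, abs=1e-9)

    def test_loosening_threshold_never_removes_contributions(self, params):
        crystal = single_atom_cubic(4.0)
        strict = binding_energy(crystal, (1, 0, 0), params, threshold=-0.01)
        loose = binding_energy(crystal, (1, 0, 0), params, threshold=-0.001)
        strict_ids = {c[0] for c in strict.contributions}
        loose_ids = {c[0] for c in loose.contributions}
        assert strict_ids <= loose_ids

    def test_recompute_consistency(self, params):
        res = binding_energy(single_atom_cubic(4.0), (1, 0, 0), params)
        assert res.recompute() == pytest.approx(res.e_b, abs=1e-12)

    def test_unconverged_sum_raises_with_residual(self, params):
        # a dense crystal cannot converge within zero shells
        crystal = single_atom_cubic(4.0)
        with pytest.raises(ConvergenceError) as exc:
            binding_energy(crystal, (1, 0, 0), params, max_shell=0)
        assert exc.value.residual is not None


class TestNormalization:
    @pytest.mark.parametrize("e,mw,expected", [
        (-4.93, 46.07, -0.10701),   # ethanol-normalized surface energy
        (-5.86, 206.28, -0.02841),  # ibuprofen-normalized surface energy
        (0.0, 18.02, 0.0),
    ])
    def test_values(self, e, mw, expected):
        assert normalize_by_mw(e, mw) == pytest.approx(expected, abs=5e-6)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(GeometryError):
            normalize_by_mw(-1.0, 0.0)


class TestEnergyDifferential:
    @pytest.mark.parametrize("es_solv,mw_solv,es_solu,mw_solu,expected,tol", [
        (-4.93, 46.07, -5.86, 206.28, -0.078, 1e-3),   # ibuprofen (011)
        (-3.49, 46.07, -5.55, 206.28, -0.049, 1e-3),   # ibuprofen (002)
        (-5.89, 18.02, -5.77, 330.74, -0.31, 1e-2),    # furosemide (10-1)
        (-5.06, 18.02, -6.91, 330.74, -0.26, 1e-2),    # furosemide (010)
        (-4.08, 18.02, -5.76, 330.74, -0.21, 1e-2),    # furosemide (001)
    ])
    def test_reproduces_tabulated_differentials(self, es_solv, mw_solv,
                                                es_solu, mw_solu, expected, tol):
        e_d = energy_differential(normalize_by_mw(es_solv, mw_solv),
                                  normalize_by_mw(es_solu, mw_solu))
        assert e_d == pytest.approx(expected, abs=tol)


class TestModifiedBindingEnergy:
    def test_deterministic(self):
        args = (-0.005, -0.078, 1000.0, 100.0, 2.0)
        assert modified_binding_energy(*args) == modified_binding_energy(*args)

    def test_default_combination_sign_and_scale(self):
        # both energy terms stabilizing -> positive modified binding energy
        v = modified_binding_energy(-0.005, -0.078, 1000.0, 100.0, 2.0)
        assert v == pytest.approx((0.005 + 0.078) * 100.0 * 2.0 / 1000.0)
        assert v > 0

    def test_custom_combination_callable(self):
        v = modified_binding_energy(-0.005, -0.078, 1.0, 1.0, 1.0,
                                    combine=lambda eb, ed, vc, s, r: eb - ed)
        assert v == pytest.approx(0.073)

    def test_missing_geometry_rejected(self):
        with pytest.raises(GeometryError):
            modified_binding_energy(-0.005, -0.078, None, 100.0, 2.0)


class TestRatiosAndDiscrepancy:
    def test_experimental_ratio_definition(self):
        assert dissolution_ratio(16.1, 2.8) == pytest.approx(5.75)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 5.0, 2)
            assert dissolution_ratio(a, b) * dissolution_ratio(b, a) == \
                pytest.approx(1.0, rel=1e-12)

    def test_scale_invariance(self):
        assert dissolution_ratio(0.128 * 7.3, 0.026 * 7.3) == \
            pytest.approx(dissolution_ratio(0.128, 0.026), rel=1e-12)

    def test_rounded_input_ratio(self):
        assert dissolution_ratio(0.128, 0.026) == pytest.approx(4.92, abs=0.01)

    def test_zero_denominator_rejected(self):
        with pytest.raises(GeometryError):
            dissolution_ratio(1.0, 0.0)

    @pytest.mark.parametrize("pred,exp,val", [
        (1.51, 1.50, 0.67),
        (4.91, 5.75, 14.6),
        (3.3, 3.3, 0.0),
    ])
    def test_percent_discrepancy_values(self, pred, exp, val):
        assert percent_discrepancy(pred, exp) == pytest.approx(val, abs=0.05)

    def test_discrepancy_nonnegative(self, rng):
        for _ in range(20):
            p, e = rng.uniform(0.1, 10.0, 2)
            assert percent_discrepancy(p, e) >= 0

    def test_zero_experimental_rejected(self):
        with pytest.raises(GeometryError):
            percent_discrepancy(1.0, 0.0)


class TestPredictDissolution:
    def faces(self):
        return [
            FaceModelInput("(10-1)", e_b=-0.38,
                           e_s={"furosemide": -5.77, "water": -5.89},
                           e_b_mod=0.128, experimental_rate=16.1),
            FaceModelInput("(010)", e_b=-0.03,
                           e_s={"furosemide": -6.91, "water": -5.06},
                           e_b_mod=0.147, experimental_rate=12.6),
            FaceModelInput("(001)", e_b=-0.01,
                           e_s={"furosemide": -5.76, "water": -4.08},
                           e_b_mod=0.026, experimental_rate=2.8),
        ]

    def test_assembles_tabulated_arithmetic(self):
        pred = predict_dissolution(self.faces(), "furosemide", "water",
                                   {"furosemide": 330.74, "water": 18.02})
        assert pred.faces.loc["(10-1)", "e_d"] == pytest.approx(-0.31, abs=0.01)
        assert pred.ratios.loc["(10-1)/(001)", "experimental"] == \
            pytest.approx(5.75, abs=0.005)
        assert pred.ratios.loc["(010)/(001)", "experimental"] == \
            pytest.approx(4.50, abs=0.005)

    def test_missing_probe_energy_rejected(self):
        faces = self.faces()
        del faces[0].e_s["water"]
        with pytest.raises(AnalysisError):
            predict_dissolution(faces, "furosemide", "water",
                                {"furosemide": 330.74, "water": 18.02})

    def test_geometry_combination_used_without_override(self):
        faces = [FaceModelInput("A", e_b=-1.0, e_s={"s": -5.0, "v": -4.0},
                                v_cell=500.0, s_hkl=50.0, rugosity=2.0),
                 FaceModelInput("B", e_b=-0.5, e_s={"s": -5.0, "v": -3.0},
                                v_cell=500.0, s_hkl=60.0, rugosity=1.0)]
        pred = predict_dissolution(faces, "s", "v", {"s": 100.0, "v": 50.0},
                                   [("A", "B")])
        expected_a = modified_binding_energy(
            -1.0 / 100.0, energy_differential(-4.0 / 50.0, -5.0 / 100.0),
            500.0, 50.0, 2.0)
        assert pred.faces.loc["A", "e_b_mod"] == pytest.approx(expected_a)

    def test_binding_energy_result_roundtrip(self):
        res = BindingEnergyResult("(100)", -0.5, [("m", -1.0, 2.0)])
        assert res.recompute() == pytest.approx(-0.5)
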
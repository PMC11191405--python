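"""Cell geometry, CIF parsing, symmetry expansion and face quantities."""

import gemmi
import numpy as np
import pytest

from facetsolv import (Atom, MillerFace, Molecule, UnitCell,
                       interplanar_spacing, parse_crystal, reticular_area,
                       write_p1_cif)
from facetsolv.errors import GeometryError, ParseError, StructureError
from facetsolv.structures import read_xyz, write_xyz

CUBIC10 = UnitCell(10, 10, 10, 90, 90, 90)


def random_cell(rng) -> UnitCell:
    a, b, c = rng.uniform(4, 15, 3)
    alpha, beta, gamma = rng.uniform(60, 120, 3)
    return UnitCell(a, b, c, alpha, beta, gamma)


class TestUnitCell:
    def test_cubic_volume(self):
        assert CUBIC10.volume == pytest.approx(1000.0)

    def test_triclinic_volume_matches_matrix_determinant(self, rng):
        for _ in range(20):
            cell = random_cell(rng)
            assert cell.volume == pytest.approx(
                abs(np.linalg.det(cell.matrix)), rel=1e-8)

    def test_frac_cart_roundtrip(self, rng):
        cell = random_cell(rng)
        frac = rng.uniform(-1, 2, (5, 3))
        assert np.allclose(cell.cart_to_frac(cell.frac_to_cart(frac)), frac)

    @pytest.mark.parametrize("kwargs", [
        dict(a=-1, b=5, c=5, alpha=90, beta=90, gamma=90),
        dict(a=5, b=5, c=5, alpha=0, beta=90, gamma=90),
        dict(a=5, b=5, c=5, alpha=181, beta=90, gamma=90),
    ])
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            UnitCell(**kwargs)


class TestInterplanarSpacing:
    @pytest.mark.parametrize("hkl,expected", [
        ((1, 0, 0), 10.0),
        ((1, 1, 0), 10.0 / np.sqrt(2)),
        ((1, 1, 1), 10.0 / np.sqrt(3)),
    ])
    def test_cubic_closed_forms(self, hkl, expected):
        assert interplanar_spacing(CUBIC10, hkl) == pytest.approx(expected)

    def test_orthorhombic_011_against_reciprocal_vector_oracle(self):
        cell = UnitCell(5, 6, 7, 90, 90, 90)
        # oracle: norm of the reciprocal-lattice vector, built from scratch
        a1, a2, a3 = cell.matrix
        vol = np.dot(a1, np.cross(a2, a3))
        b2 = np.cross(a3, a1) / vol
        b3 = np.cross(a1, a2) / vol
        expected = 1.0 / np.linalg.norm(0 * a1 + 1 * b2 + 1 * b3)
        assert interplanar_spacing(cell, (0, 1, 1)) == pytest.approx(expected)

    def test_random_cells_against_gemmi(self, rng):
        for _ in range(15):
            cell = random_cell(rng)
            g = gemmi.UnitCell(cell.a, cell.b, cell.c,
                               cell.alpha, cell.beta, cell.gamma)
            hkl = tuple(int(x) for x in rng.integers(-3, 4, 3))
            if hkl == (0, 0, 0):
                hkl = (1, 1, 1)
            assert interplanar_spacing(cell, hkl) == pytest.approx(
                g.calculate_d(hkl), rel=1e-8)

    def test_cubic_d_weakly_decreases_with_index_sum(self):
        faces = [(1, 0, 0), (1, 1, 0), (1, 1, 1), (2, 1, 1), (2, 2, 1)]
        ds = [interplanar_spacing(CUBIC10, f) for f in faces]
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(ds, ds[1:]))

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            interplanar_spacing(CUBIC10, (0, 0, 0))


class TestReticularArea:
    def test_cubic_001(self):
        assert reticular_area(CUBIC10, (0, 0, 1)) == pytest.approx(100.0)

    def test_area_times_spacing_equals_volume(self, rng):
        for _ in range(30):
            cell = random_cell(rng)
            hkl = tuple(int(x) for x in rng.integers(-4, 5, 3))
            if hkl == (0, 0, 0):
                continue
            s = reticular_area(cell, hkl)
            d = interplanar_spacing(cell, hkl)
            assert s * d == pytest.approx(cell.volume, rel=1e-8)

    def test_orthorhombic_011_against_cross_product_oracle(self):
        cell = UnitCell(5, 6, 7, 90, 90, 90)
        # in-plane lattice vectors of (011): a and b - c
        a1, a2, a3 = cell.matrix
        expected = np.linalg.norm(np.cross(a1, a2 - a3))
        assert reticular_area(cell, (0, 1, 1)) == pytest.approx(expected)

    def test_miller_face_carries_consistent_quantities(self):
        face = MillerFace.from_cell(CUBIC10, (0, 1, 1))
        assert face.s_hkl * face.d_hkl == pytest.approx(CUBIC10.volume)


P1_ONE_ATOM = """data_one
_cell_length_a 5
_cell_length_b 5
_cell_length_c 5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_space_group_symop_operation_xyz
x,y,z
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Ar1 Ar 0.1 0.2 0.3
"""

PM1_DIATOMIC = """data_two
_cell_length_a 8
_cell_length_b 8
_cell_length_c 8
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_space_group_symop_operation_xyz
x,y,z
-x,-y,-z
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
O1 O 0.10 0.20 0.20
H1 H 0.22 0.20 0.20
"""

# toy P2_1/c-type setting: 4 operators
P21C = """data_p21c
_cell_length_a 7
_cell_length_b 8
_cell_length_c 9
_cell_angle_alpha 90
_cell_angle_beta 100
_cell_angle_gamma 90
loop_
_space_group_symop_operation_xyz
x,y,z
-x,y+1/2,-z+1/2
-x,-y,-z
x,-y+1/2,z+1/2
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Ar1 Ar 0.13 0.17 0.21
"""


class TestParseCrystal:
    def test_p1_single_atom(self):
        crystal = parse_crystal(P1_ONE_ATOM)
        assert crystal.z == 1
        assert len(crystal.full_cell[0].atoms) == 1

    def test_inversion_doubles_z(self):
        crystal = parse_crystal(PM1_DIATOMIC)
        assert crystal.z == 2
        assert all(len(m.atoms) == 2 for m in crystal.full_cell)

    def test_p21c_expansion_matches_direct_operator_oracle(self):
        crystal = parse_crystal(P21C)
        assert crystal.z == 4
        # oracle: apply each operator matrix directly to the lone site
        site = np.array([0.13, 0.17, 0.21])
        ops = [
            (np.eye(3), np.zeros(3)),
            (np.diag([-1, 1, -1]), np.array([0, 0.5, 0.5])),
            (-np.eye(3), np.zeros(3)),
            (np.diag([1, -1, 1]), np.array([0, 0.5, 0.5])),
        ]
        expected = sorted(tuple(np.round((r @ site + t) % 1.0, 6))
                          for r, t in ops)
        got = sorted(tuple(np.round(crystal.cell.cart_to_frac(m.atoms[0].position) % 1.0, 6))
                     for m in crystal.full_cell)
        assert got == expected

    def test_missing_cell_raises(self):
        with pytest.raises(ParseError):
            parse_crystal("data_x\nloop_\n_atom_site_label\nC1\n")

    def test_collision_after_expansion_raises(self):
        bad = P1_ONE_ATOM.replace("Ar1 Ar 0.1 0.2 0.3",
                                  "Ar1 Ar 0.1 0.2 0.3\nO1 O 0.1 0.2 0.31")
        with pytest.raises(StructureError):
            parse_crystal(bad)

    def test_sidecar_charges_and_types(self):
        sidecar = "index,charge,ff_type\n0,-0.5,O_3\n1,0.5,H__HB\n"
        crystal = parse_crystal(PM1_DIATOMIC, charge_table=sidecar)
        charges = sorted(a.charge for a in crystal.full_cell[0].atoms)
        assert charges == [-0.5, 0.5]
        assert {a.ff_type for m in crystal.full_cell for a in m.atoms} == {"O_3", "H__HB"}

    def test_expansion_is_idempotent(self):
        crystal = parse_crystal(PM1_DIATOMIC)
        again = parse_crystal(write_p1_cif(crystal))
        assert again.z == crystal.z
        ours = sorted(np.round(np.concatenate([m.coords for m in crystal.full_cell]).ravel(), 4))
        theirs = sorted(np.round(np.concatenate([m.coords for m in again.full_cell]).ravel(), 4))
        assert np.allclose(ours, theirs, atol=2e-4)


class TestMolecule:
    def test_molar_mass_water_standard_value(self):
        mol = Molecule([Atom("O", [0, 0, 0]), Atom("H", [0.96, 0, 0]),
                        Atom("H", [-0.24, 0.93, 0])], [(0, 1), (0, 2)])
        assert mol.molar_mass == pytest.approx(18.02, abs=0.5)

    def test_bonded_molecule_is_connected(self, polar_crystal):
        assert all(m.is_connected() for m in polar_crystal.full_cell)

    def test_unknown_element_rejected(self):
        with pytest.raises(StructureError):
            Atom("Qq", [0, 0, 0])


class TestXyzRoundTrip:
    def test_round_trip_preserves_geometry(self, probes):
        mol = probes["diatomic"]
        back = read_xyz(write_xyz([mol]))
        assert np.allclose(back.coords, mol.coords, atol=1e-6)
        assert [a.element for a in back.atoms] == [a.element for a in mol.atoms]

    def test_truncated_xyz_rejected(self):
        with pytest.raises(ParseError):
            read_xyz("3\ncomment\nC 0 0 0\n")
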
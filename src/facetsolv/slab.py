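"""Oriented (hkl) surface slabs.

A slab is a W × L × H supercell (default 3 × 3 × 2) re-based so that two
lattice vectors span the (hkl) plane, rotated so the outward surface
normal is the +X axis, and terminated at an interplanar boundary with no
relaxation.  Molecules are included iff their centroid lies inside the
slab region, which keeps them whole and makes the termination unambiguous.
The termination plane is placed, by default, in the widest interplanar gap
of the centroid distribution along the normal (the cut severing the fewest
intermolecular contacts); the fractional offset is exposed so alternative
terminations can be scanned.

The in-plane lattice basis is found by the standard unimodular
(extended-Euclid) construction: an integer matrix C with |det C| = 1 whose
first two rows c1, c2 satisfy c·(h,k,l) = 0 and whose third row advances
one interplanar spacing along the normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import gcd

import numpy as np

from .errors import GeometryError
from .structures import CrystalStructure, MillerFace, Molecule, reduced_miller, write_xyz

_EPS = 1e-9


def _ext_gcd(a: int, b: int) -> tuple[int, int]:
    """(p, q) with p*a + q*b = gcd(a, b)."""
    if b == 0:
        return (1 if a >= 0 else -1, 0)
    p, q = _ext_gcd(b, a % b)
    return q, p - (a // b) * q


def inplane_basis(hkl: tuple[int, int, int],
                  cell_matrix: np.ndarray | None = None) -> np.ndarray:
    """Integer 3×3 matrix (rows c1, c2, c3) with c1, c2 in the (hkl) plane,
    |det| = 1 and c3 crossing the plane stack by one spacing."""
    h, k, l = reduced_miller(hkl)
    if k == 0 and l == 0:
        s = 1 if h > 0 else -1
        basis = np.array([[0, 1, 0], [0, 0, 1], [s, 0, 0]])
    else:
        p, q = _ext_gcd(k, l)
        g_kl = abs(gcd(k, l)) or 1
        c2 = np.array([0, l // g_kl, -k // g_kl])
        if cell_matrix is not None:
            # choose the shorter of the equivalent c1 candidates (ASE-style
            # metric reduction keeps the in-plane cell compact)
            a1, a2, a3 = cell_matrix
            k1 = np.dot(p * (k * a1 - h * a2) + q * (l * a1 - h * a3),
                        l * a2 - k * a3)
            k2 = np.dot(l * (k * a1 - h * a2) - k * (l * a1 - h * a3),
                        l * a2 - k * a3)
            if abs(k2) > _EPS:
                i = -int(round(k1 / k2))
                p, q = p + i * l, q - i * k
        c1 = np.array([p * k + q * l, -p * h, -q * h])
        a_, b_ = _ext_gcd(p * k + q * l, h)
        c3 = np.array([b_, a_ * p, a_ * q])
        basis = np.array([c1, c2, c3])
    det = int(round(np.linalg.det(basis)))
    if abs(det) != 1:
        raise GeometryError(f"no unimodular in-plane basis found for {hkl}")
    if det < 0:
        basis[1] = -basis[1]
    return basis


@dataclass
class SurfaceSlab:
    """Oriented, terminated (hkl) slab in a frame whose +X axis is the
    outward surface normal."""

    face: MillerFace
    molecules: list[Molecule]
    repeat: tuple[int, int, int]
    surface_x: float
    tile_origin: np.ndarray      # corner of the central reticular tile, at x = surface_x
    tile_v: np.ndarray           # in-plane tile edge vectors (slab frame, x ≈ 0)
    tile_w: np.ndarray
    termination_offset: float = 0.0
    rugosity: float | None = None

    @property
    def n_atoms(self) -> int:
        return sum(len(m.atoms) for m in self.molecules)

    @property
    def thickness(self) -> float:
        return self.repeat[2] * self.face.d_hkl

    def to_xyz(self) -> str:
        return write_xyz(self.molecules, comment=f"slab {self.face} repeat={self.repeat}")


def build_slab(crystal: CrystalStructure, hkl: tuple[int, int, int],
               repeat: tuple[int, int, int] = (3, 3, 2),
               termination_offset: float | None = None) -> SurfaceSlab:
    """Build the oriented W × L × H slab exposing (hkl).

    ``termination_offset`` is the fractional position (in units of d_hkl)
    of the cut plane within the stacking period; None selects the widest
    centroid gap automatically.  Raises a warning-level note via
    ``warnings`` when the slab is thinner than the largest molecule.
    """
    face = MillerFace.from_cell(crystal.cell, hkl)
    w_rep, l_rep, h_rep = repeat
    if min(repeat) < 1:
        raise GeometryError("repeat counts must be >= 1")

    basis = inplane_basis(hkl, crystal.cell.matrix)
    m = crystal.cell.matrix
    a1, a2, a3 = (basis @ m)  # Cartesian vectors of the re-based cell
    normal = np.cross(a1, a2)
    normal /= np.linalg.norm(normal)
    if np.dot(a3, normal) < 0:  # make c3 advance along the outward normal
        a3 = -a3
        basis = basis.copy()
        basis[2] = -basis[2]
    # one step of a3 along the normal is exactly d_hkl for a unimodular basis
    d_step = float(np.dot(a3, normal))
    if not math.isclose(d_step, face.d_hkl, rel_tol=1e-6):
        raise GeometryError("in-plane basis is inconsistent with d_hkl")

    # supercell spanned by W a1, L a2, H a3 from an origin shifted so the
    # termination cut falls in the chosen interplanar gap
    centroids = np.array([mol.centroid for mol in crystal.full_cell])
    phases = (centroids @ normal) / face.d_hkl % 1.0
    if termination_offset is None:
        cut = _widest_gap_cut(phases)
    else:
        cut = float(termination_offset) % 1.0

    sup = np.array([w_rep * a1, l_rep * a2, h_rep * a3])
    sup_inv = np.linalg.inv(sup)

    # integer translation range: bound the supercell box in original
    # fractional coordinates
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                       dtype=float) @ sup
    corners_frac = corners @ np.linalg.inv(m)
    lo = np.floor(corners_frac.min(axis=0)).astype(int) - 2
    hi = np.ceil(corners_frac.max(axis=0)).astype(int) + 2

    origin = cut * face.d_hkl * normal
    kept: list[Molecule] = []
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                shift = i * m[0] + j * m[1] + k * m[2]
                for mol, cen in zip(crystal.full_cell, centroids):
                    frac = (cen + shift - origin) @ sup_inv
                    if np.all(frac >= -_EPS) and np.all(frac < 1.0 - _EPS):
                        kept.append(mol.translated(shift - origin))
    if not kept:
        raise GeometryError(f"slab for {face} contains no molecules")

    # rotate: normal -> +X, a1 direction -> XY... (y axis along in-plane a1)
    x_axis = normal
    y_axis = a1 - np.dot(a1, normal) * normal
    y_axis /= np.linalg.norm(y_axis)
    z_axis = np.cross(x_axis, y_axis)
    rot = np.array([x_axis, y_axis, z_axis])  # rows: slab-frame axes

    molecules = [mol.transformed(rot) for mol in kept]
    molecules.sort(key=lambda mm: (round(mm.centroid[0], 6), round(mm.centroid[1], 6),
                                   round(mm.centroid[2], 6)))
    surface_x = max(float(a.position[0]) for mol in molecules for a in mol.atoms)

    tile_v = rot @ a1
    tile_w = rot @ a2
    tile_origin = rot @ ((w_rep // 2) * a1 + (l_rep // 2) * a2)
    tile_origin = np.array([surface_x, tile_origin[1], tile_origin[2]])

    largest = max(_molecule_extent(mol) for mol in crystal.full_cell)
    if h_rep * face.d_hkl < largest:
        import warnings
        warnings.warn(
            f"slab thickness {h_rep * face.d_hkl:.2f} Å is thinner than the "
            f"largest molecule ({largest:.2f} Å); consider a larger H",
            stacklevel=2)

    return SurfaceSlab(face, molecules, repeat, surface_x, tile_origin,
                       tile_v, tile_w, termination_offset=cut)


def _molecule_extent(mol: Molecule) -> float:
    c = mol.coords
    return float(np.linalg.norm(c.max(axis=0) - c.min(axis=0)))


def _widest_gap_cut(phases: np.ndarray) -> float:
    """Fractional cut position in the widest circular gap of the stacking
    phases (severs the fewest contacts)."""
    p = np.sort(np.unique(np.round(phases, 9)))
    if len(p) == 1:
        return float((p[0] + 0.5) % 1.0)
    gaps = np.diff(np.concatenate([p, [p[0] + 1.0]]))
    i = int(np.argmax(gaps))
    return float((p[i] + gaps[i] / 2.0) % 1.0)


def surface_rugosity(slab: SurfaceSlab, lateral_step: float = 0.25,
                     capture_radius: float = 1.0,
                     override: float | None = None) -> float:
    """Peak-to-valley surface height over one reticular area (Å).

    The topmost atomic height (x coordinate) is sampled on a lateral grid
    over the central reticular tile; at each grid point the height is the
    maximum x among atoms within ``capture_radius`` laterally.  Rugosity is
    max − min of the sampled heights.  ``override`` injects an externally
    determined value (e.g. from a reference workflow) unchanged.
    """
    if override is not None:
        slab.rugosity = float(override)
        return slab.rugosity
    coords = np.concatenate([mol.coords for mol in slab.molecules])
    lat = coords[:, 1:3]
    heights = coords[:, 0]
    nv = max(2, int(round(np.linalg.norm(slab.tile_v) / lateral_step)))
    nw = max(2, int(round(np.linalg.norm(slab.tile_w) / lateral_step)))
    sampled = []
    for i in range(nv):
        for j in range(nw):
            p = (slab.tile_origin + (i / nv) * slab.tile_v
                 + (j / nw) * slab.tile_w)[1:3]
            # small tolerance so columns of atoms that coincide laterally to
            # rounding are captured or excluded together at the boundary
            near = np.linalg.norm(lat - p, axis=1) <= capture_radius + 1e-9
            if near.any():
                sampled.append(float(heights[near].max()))
    if not sampled:
        raise GeometryError("no atoms sampled on the lateral grid; increase "
                            "capture_radius or refine the grid")
    slab.rugosity = float(max(sampled) - min(sampled))
    return slab.rugosity
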
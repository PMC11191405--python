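"""Dreiding-type rigid-body intermolecular energies.

Three channels are computed and accumulated separately:

* dispersive/repulsive van der Waals, 12-6 form
  ``E = D0 [ (R0/r)^12 - 2 (R0/r)^6 ]`` with geometric-mean combination
  rules for both ``R0`` and ``D0`` (minimum of exactly ``-D0`` at
  ``r = R0``);
* Coulombic, ``E = K q_i q_j / (eps r)`` with
  ``K = 332.0637 kcal Å mol^-1 e^-2`` (e²/(4πε₀Å) expressed in kcal/mol);
* hydrogen bonding, a 12-10 well over the donor–acceptor distance scaled
  by cos⁴ of the donor–H–acceptor angle,
  ``E = D_hb [ 5 (R_hb/R_DA)^12 - 6 (R_hb/R_DA)^10 ] cos^4(theta)``,
  evaluated per donor-H···acceptor triple and attributed to the
  H···acceptor pair.  The screening window (donor–acceptor distance
  ≤ 3.5 Å, angle ≥ 90°) and the well parameters are configurable since
  the published tables leave the hydrogen-bond variant open.

All energies are in kcal/mol; favorable interactions are negative.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .errors import NearSingularityError, ParameterError
from .structures import Atom, Molecule

#: Coulomb conversion constant e²/(4πε₀·Å) in kcal/mol
COULOMB_K = 332.0637

#: interatomic separations below this are treated as singular overlaps
MIN_SEPARATION = 0.1


@dataclass(frozen=True)
class VdwType:
    r0: float          # Å, position of the 12-6 minimum
    d0: float          # kcal/mol, well depth
    donor_hydrogen: bool = False
    acceptor: bool = False


@dataclass
class ForceFieldParams:
    """Nonbonded parameter set: per-type 12-6 constants plus the
    hydrogen-bond well, Coulomb constant and dielectric."""

    types: dict[str, VdwType]
    d_hb: float = 9.5            # kcal/mol
    r_hb: float = 2.75           # Å, donor–acceptor equilibrium distance
    hb_distance_cutoff: float = 3.5   # Å, donor–acceptor screening window
    hb_angle_min: float = 90.0   # degrees, minimum donor-H-acceptor angle
    coulomb_k: float = COULOMB_K
    dielectric: float = 1.0
    distance_dependent_dielectric: bool = False
    cutoff: float | None = None  # optional pair distance cutoff (Å); None = all pairs

    @classmethod
    def from_csv(cls, text: str, **kwargs) -> "ForceFieldParams":
        types = {}
        for row in csv.DictReader(io.StringIO(text)):
            types[row["ff_type"]] = VdwType(
                float(row["r0"]), float(row["d0"]),
                bool(int(row["donor_hydrogen"])), bool(int(row["acceptor"])))
        return cls(types=types, **kwargs)

    @classmethod
    def default(cls, **kwargs) -> "ForceFieldParams":
        """Bundled 12-6 Dreiding table (plus synthetic test types)."""
        text = resources.files("facetsolv.data").joinpath("dreiding_lj.csv").read_text()
        return cls.from_csv(text, **kwargs)

    def vdw(self, ff_type: str | None) -> VdwType:
        if ff_type is None or ff_type not in self.types:
            raise ParameterError(f"no parameters for force-field type {ff_type!r}")
        return self.types[ff_type]

    def with_overrides(self, **kwargs) -> "ForceFieldParams":
        return replace(self, **kwargs)


@dataclass
class EnergyComponents:
    """Decomposed interaction energy (kcal/mol)."""

    e_disp: float = 0.0
    e_hb: float = 0.0
    e_coul: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_disp + self.e_hb + self.e_coul

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(self.e_disp + other.e_disp,
                                self.e_hb + other.e_hb,
                                self.e_coul + other.e_coul)


# ---------------------------------------------------------------------------
# Pair- and triple-level terms
# ---------------------------------------------------------------------------


def pair_energy(atom_i: Atom, atom_j: Atom, r: float,
                params: ForceFieldParams) -> EnergyComponents:
    """12-6 van der Waals plus Coulomb energy of one interatomic pair.

    Hydrogen bonding is a three-body term (donor, H, acceptor) and is added
    by :func:`hbond_energy` at the molecule level, not here.
    """
    if r < MIN_SEPARATION:
        raise NearSingularityError(f"interatomic distance {r:.3f} Å below "
                                   f"{MIN_SEPARATION} Å")
    ti, tj = params.vdw(atom_i.ff_type), params.vdw(atom_j.ff_type)
    r0 = np.sqrt(ti.r0 * tj.r0)
    d0 = np.sqrt(ti.d0 * tj.d0)
    x6 = (r0 / r) ** 6
    e_disp = d0 * (x6 * x6 - 2.0 * x6)
    eps = params.dielectric * (r if params.distance_dependent_dielectric else 1.0)
    e_coul = params.coulomb_k * atom_i.charge * atom_j.charge / (eps * r)
    return EnergyComponents(e_disp=float(e_disp), e_coul=float(e_coul))


def hbond_energy(donor_pos: np.ndarray, h_pos: np.ndarray, acceptor_pos: np.ndarray,
                 params: ForceFieldParams) -> float:
    """12-10 hydrogen-bond well over the donor–acceptor distance, scaled by
    cos⁴(theta) with theta the donor–H–acceptor angle.  Returns 0 outside
    the screening window."""
    donor_pos = np.asarray(donor_pos, dtype=float)
    h_pos = np.asarray(h_pos, dtype=float)
    acceptor_pos = np.asarray(acceptor_pos, dtype=float)
    r_da = float(np.linalg.norm(acceptor_pos - donor_pos))
    if r_da > params.hb_distance_cutoff or r_da < MIN_SEPARATION:
        return 0.0
    v1 = donor_pos - h_pos
    v2 = acceptor_pos - h_pos
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cos_t = float(np.dot(v1, v2) / (n1 * n2))
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    if theta < params.hb_angle_min:
        return 0.0
    x = params.r_hb / r_da
    return float(params.d_hb * (5.0 * x ** 12 - 6.0 * x ** 10) * cos_t ** 4)


# ---------------------------------------------------------------------------
# Vectorized molecule-level kernel
# ---------------------------------------------------------------------------


@dataclass
class MolArrays:
    """Cached numpy views of a molecule for the vectorized kernel."""

    coords: np.ndarray
    r0: np.ndarray
    d0: np.ndarray
    q: np.ndarray
    donors: list[tuple[int, int]] = field(default_factory=list)  # (H index, heavy index)
    acceptors: list[int] = field(default_factory=list)

    @classmethod
    def from_molecule(cls, mol: Molecule, params: ForceFieldParams) -> "MolArrays":
        r0, d0 = [], []
        for a in mol.atoms:
            t = params.vdw(a.ff_type)
            r0.append(t.r0)
            d0.append(t.d0)
        donors, acceptors = [], []
        neighbor: dict[int, int] = {}
        for i, j in mol.bonds:
            neighbor.setdefault(i, j)
            neighbor.setdefault(j, i)
        for i, a in enumerate(mol.atoms):
            t = params.vdw(a.ff_type)
            is_donor_h = a.hb_role == "donor-H" or (a.hb_role == "none" and t.donor_hydrogen)
            is_acceptor = a.hb_role == "acceptor" or (a.hb_role == "none" and t.acceptor)
            if is_donor_h and i in neighbor:
                donors.append((i, neighbor[i]))
            if is_acceptor:
                acceptors.append(i)
        return cls(mol.coords, np.array(r0), np.array(d0),
                   np.array([a.charge for a in mol.atoms]), donors, acceptors)

    def with_coords(self, coords: np.ndarray) -> "MolArrays":
        return MolArrays(np.asarray(coords, dtype=float), self.r0, self.d0,
                         self.q, self.donors, self.acceptors)


def _pairwise(a: MolArrays, b: MolArrays, params: ForceFieldParams,
              strict_overlap: bool = True) -> EnergyComponents | None:
    """Vectorized disp+coul over all atom pairs of two molecules, plus the
    hydrogen-bond triples in both directions.  Returns None when an overlap
    is found and ``strict_overlap`` is False."""
    d = cdist(a.coords, b.coords)
    if (d < MIN_SEPARATION).any():
        if strict_overlap:
            raise NearSingularityError(
                f"atoms closer than {MIN_SEPARATION} Å between molecules")
        return None
    mask = np.ones_like(d, dtype=bool)
    if params.cutoff is not None:
        mask = d <= params.cutoff
    r0 = np.sqrt(np.outer(a.r0, b.r0))
    d0 = np.sqrt(np.outer(a.d0, b.d0))
    x6 = (r0 / d) ** 6
    e_disp = float((d0 * (x6 * x6 - 2.0 * x6))[mask].sum())
    eps = params.dielectric
    qq = np.outer(a.q, b.q)
    if params.distance_dependent_dielectric:
        e_coul = float((params.coulomb_k * qq / (eps * d * d))[mask].sum())
    else:
        e_coul = float((params.coulomb_k * qq / (eps * d))[mask].sum())
    e_hb = 0.0
    for h_i, heavy_i in a.donors:
        for acc_j in b.acceptors:
            e_hb += hbond_energy(a.coords[heavy_i], a.coords[h_i],
                                 b.coords[acc_j], params)
    for h_j, heavy_j in b.donors:
        for acc_i in a.acceptors:
            e_hb += hbond_energy(b.coords[heavy_j], b.coords[h_j],
                                 a.coords[acc_i], params)
    return EnergyComponents(e_disp=e_disp, e_hb=e_hb, e_coul=e_coul)


def molecule_pair_energy(mol_a: Molecule, mol_b: Molecule,
                         params: ForceFieldParams) -> tuple[EnergyComponents, float]:
    """Full atom-pair double sum between two molecules and their
    centroid–centroid distance R (Å)."""
    a = MolArrays.from_molecule(mol_a, params)
    b = MolArrays.from_molecule(mol_b, params)
    comp = _pairwise(a, b, params, strict_overlap=True)
    r = float(np.linalg.norm(mol_a.centroid - mol_b.centroid))
    return comp, r


def probe_slab_energy(probe: Molecule, slab, params: ForceFieldParams,
                      strict_overlap: bool = True) -> EnergyComponents | None:
    """Probe–slab interaction: sum of the probe's pair interactions with
    every slab molecule (intramolecular probe terms excluded).

    ``slab`` is any object with a ``molecules`` attribute (a
    :class:`~facetsolv.slab.SurfaceSlab` or a plain container).  Returns
    None when the pose overlaps slab atoms and ``strict_overlap`` is False.
    """
    a = MolArrays.from_molecule(probe, params)
    total = EnergyComponents()
    for mol in slab.molecules:
        b = MolArrays.from_molecule(mol, params)
        comp = _pairwise(a, b, params, strict_overlap=strict_overlap)
        if comp is None:
            return None
        total = total + comp
    return total


# ---------------------------------------------------------------------------
# Convenience: default typing and approximate partial charges
# ---------------------------------------------------------------------------

#: fallback element -> force-field type mapping (sp3-like defaults); curated
#: per-atom types from the structure file or sidecar always take precedence
DEFAULT_FF_TYPES = {
    "H": "H_", "C": "C_3", "N": "N_3", "O": "O_3", "F": "F_", "P": "P_3",
    "S": "S_3", "Cl": "Cl_", "Br": "Br_", "I": "I_", "Ar": "X_", "He": "X_",
}


def assign_default_ff_types(mol: Molecule) -> None:
    """Fill missing ``ff_type`` labels from the element-level defaults."""
    for a in mol.atoms:
        if a.ff_type is None:
            try:
                a.ff_type = DEFAULT_FF_TYPES[a.element]
            except KeyError:
                raise ParameterError(
                    f"no default force-field type for element {a.element}") from None

# element-level (a, b, c) electronegativity polynomials, Gasteiger-Marsili
_PEOE = {
    "H": (7.17, 6.24, -0.56),
    "C": (7.98, 9.18, 1.88),
    "N": (11.54, 10.82, 1.36),
    "O": (14.18, 12.92, 1.39),
    "F": (14.66, 13.85, 2.31),
    "Cl": (11.00, 9.69, 1.35),
    "Br": (10.08, 8.47, 1.16),
    "S": (10.14, 9.13, 1.38),
}
_CHI_H_PLUS = 20.02


def assign_peoe_charges(mol: Molecule, iterations: int = 6) -> None:
    """Iterative partial-equalization (Gasteiger-style) charges, in place.

    Element-level parameterization only — a labelled approximation for
    convenience; curated charges should be supplied through the CIF or a
    sidecar table for production runs.
    """
    for a in mol.atoms:
        if a.element not in _PEOE:
            raise ParameterError(f"no electronegativity parameters for {a.element}")
    n = len(mol.atoms)
    q = np.zeros(n)
    abc = [_PEOE[a.element] for a in mol.atoms]

    def chi(i: int, qi: float) -> float:
        a_, b_, c_ = abc[i]
        return a_ + b_ * qi + c_ * qi * qi

    def chi_plus(i: int) -> float:
        if mol.atoms[i].element == "H":
            return _CHI_H_PLUS
        a_, b_, c_ = abc[i]
        return a_ + b_ + c_

    for it in range(1, iterations + 1):
        damp = 0.5 ** it
        dq = np.zeros(n)
        for i, j in mol.bonds:
            ci, cj = chi(i, q[i]), chi(j, q[j])
            if ci == cj:
                continue
            if ci < cj:
                i, j, ci, cj = j, i, cj, ci
            transfer = (ci - cj) / chi_plus(j) * damp
            dq[i] -= transfer
            dq[j] += transfer
        q += dq
    for atom, qi in zip(mol.atoms, q):
        atom.charge = float(qi)
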
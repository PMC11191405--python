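"""Crystal and molecule containers, CIF input/output, and face geometry.

Molecular crystals are represented by a triclinic unit cell, an asymmetric
unit of rigid molecules, and the symmetry operators that expand it to the
full cell contents.  Faces are labelled by Miller indices (hkl); for each
face the interplanar spacing ``d_hkl`` and the reticular area
``S_hkl = V_cell / d_hkl`` (the projection of one unit cell onto the face)
are the geometric quantities the rest of the package consumes.

Units: lengths in Å, angles in degrees, partial charges in elementary
charges, molar masses in g/mol.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from math import gcd

import gemmi
import numpy as np

from .errors import GeometryError, ParseError, StructureError

# ---------------------------------------------------------------------------
# Bundled element data (IUPAC 2021 standard atomic weights, Cordero covalent
# radii).  Loaded once at import.
# ---------------------------------------------------------------------------


def _load_element_table() -> dict[str, tuple[float, float]]:
    text = resources.files("facetsolv.data").joinpath("elements.csv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for row in csv.DictReader(io.StringIO(text)):
        table[row["element"]] = (float(row["mass"]), float(row["covalent_radius"]))
    return table


ELEMENTS: dict[str, tuple[float, float]] = _load_element_table()

#: minimum allowed separation between distinct atoms in an expanded cell
COLLISION_DISTANCE = 0.5
#: atoms generated by different symmetry operators closer than this are the
#: same site (special position) and are merged
MERGE_DISTANCE = 0.3
#: bond perception: bonded iff r < BOND_FACTOR * (r_cov_i + r_cov_j)
BOND_FACTOR = 1.2


def atomic_mass(element: str) -> float:
    try:
        return ELEMENTS[element][0]
    except KeyError:
        raise StructureError(f"unknown element symbol {element!r}") from None


def covalent_radius(element: str) -> float:
    try:
        return ELEMENTS[element][1]
    except KeyError:
        raise StructureError(f"unknown element symbol {element!r}") from None


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom: element, Cartesian position (Å), partial charge (e),
    force-field type label and hydrogen-bond role."""

    element: str
    position: np.ndarray
    charge: float = 0.0
    ff_type: str | None = None
    hb_role: str = "none"  # "donor-H" | "acceptor" | "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.element not in ELEMENTS:
            raise StructureError(f"unknown element symbol {self.element!r}")
        if not math.isfinite(self.charge):
            raise StructureError("partial charge must be finite")
        if self.hb_role not in ("donor-H", "acceptor", "none"):
            raise StructureError(f"invalid hb_role {self.hb_role!r}")

    def copy(self) -> "Atom":
        return Atom(self.element, self.position.copy(), self.charge,
                    self.ff_type, self.hb_role)


@dataclass
class Molecule:
    """A rigid molecule: ordered atoms plus a bond list (index pairs)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    label: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def molar_mass(self) -> float:
        return float(sum(atomic_mass(a.element) for a in self.atoms))

    def is_connected(self) -> bool:
        n = len(self.atoms)
        if n <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        atoms = [a.copy() for a in self.atoms]
        for a, xyz in zip(atoms, np.asarray(coords, dtype=float)):
            a.position = np.array(xyz, dtype=float)
        return Molecule(atoms, list(self.bonds), self.label)

    def translated(self, vec: np.ndarray) -> "Molecule":
        return self.with_coords(self.coords + np.asarray(vec, dtype=float))

    def transformed(self, rot: np.ndarray, shift: np.ndarray | None = None) -> "Molecule":
        coords = self.coords @ np.asarray(rot, dtype=float).T
        if shift is not None:
            coords = coords + np.asarray(shift, dtype=float)
        return self.with_coords(coords)


@dataclass
class UnitCell:
    """Triclinic unit cell; ``matrix`` rows are the lattice vectors a, b, c."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        # standard crystallographic Cartesian frame: a along x, b in xy-plane
        v = math.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg))
        if v <= 0.0:
            raise GeometryError("cell angles are geometrically impossible")
        self.matrix = np.array([
            [self.a, 0.0, 0.0],
            [self.b * cg, self.b * sg, 0.0],
            [self.c * cb, self.c * (ca - cb * cg) / sg, self.c * v / sg],
        ])

    @property
    def volume(self) -> float:
        """Closed-form triclinic cell volume (Å³)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return self.a * self.b * self.c * math.sqrt(
            1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.matrix)


def interplanar_spacing(cell: UnitCell, hkl: tuple[int, int, int]) -> float:
    """d_hkl from the reciprocal metric: 1/d = |h b1 + k b2 + l b3|."""
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise GeometryError("Miller indices (0,0,0) do not define a plane")
    recip = np.linalg.inv(cell.matrix).T  # rows are reciprocal vectors
    g = h * recip[0] + k * recip[1] + l * recip[2]
    return 1.0 / float(np.linalg.norm(g))


def reticular_area(cell: UnitCell, hkl: tuple[int, int, int],
                   d_hkl: float | None = None) -> float:
    """S_hkl = V_cell / d_hkl: the projection of one unit cell onto (hkl)."""
    if d_hkl is None:
        d_hkl = interplanar_spacing(cell, hkl)
    return cell.volume / d_hkl


@dataclass
class MillerFace:
    """A crystal face (hkl) with its interplanar spacing and reticular area."""

    h: int
    k: int
    l: int
    d_hkl: float
    s_hkl: float

    @classmethod
    def from_cell(cls, cell: UnitCell, hkl: tuple[int, int, int]) -> "MillerFace":
        d = interplanar_spacing(cell, hkl)
        return cls(hkl[0], hkl[1], hkl[2], d, reticular_area(cell, hkl, d))

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)

    def __str__(self) -> str:
        return f"({self.h}{self.k}{self.l})"


@dataclass
class CrystalStructure:
    """Unit cell + asymmetric unit + symmetry operators + expanded contents."""

    cell: UnitCell
    asym_unit: list[Molecule]
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]]  # (rotation, translation), fractional
    full_cell: list[Molecule]
    name: str = ""

    @property
    def z(self) -> int:
        return len(self.full_cell)

    def face(self, hkl: tuple[int, int, int]) -> MillerFace:
        return MillerFace.from_cell(self.cell, hkl)


# ---------------------------------------------------------------------------
# Bond perception and molecule identification
# ---------------------------------------------------------------------------


def perceive_bonds(elements: list[str], coords: np.ndarray,
                   pbc_cell: UnitCell | None = None) -> list[tuple[int, int]]:
    """Distance-based bond perception: r < 1.2 × (sum of covalent radii).

    With ``pbc_cell`` the minimum-image distance is used so bonds across a
    cell boundary are found.
    """
    n = len(elements)
    radii = np.array([covalent_radius(e) for e in elements])
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _distance(coords[i], coords[j], pbc_cell)
            if d < BOND_FACTOR * (radii[i] + radii[j]):
                bonds.append((i, j))
    return bonds


def _distance(p: np.ndarray, q: np.ndarray, pbc_cell: UnitCell | None) -> float:
    if pbc_cell is None:
        return float(np.linalg.norm(p - q))
    df = pbc_cell.cart_to_frac(p - q)
    df -= np.round(df)
    return float(np.linalg.norm(pbc_cell.frac_to_cart(df)))


def _connected_components(n: int, bonds: list[tuple[int, int]]) -> list[list[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            for nb in sorted(adj[stack.pop()]):
                if nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


def _unwrap_component(comp: list[int], bonds: list[tuple[int, int]],
                      frac: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Shift each atom of a bonded component to the image nearest its bonded
    partner so the molecule is whole across cell boundaries."""
    idx = {a: i for i, a in enumerate(comp)}
    adj: dict[int, list[int]] = {a: [] for a in comp}
    for i, j in bonds:
        if i in idx and j in idx:
            adj[i].append(j)
            adj[j].append(i)
    out = frac[comp].copy()
    root = comp[0]
    seen = {root}
    stack = [root]
    while stack:
        cur = stack.pop()
        for nb in sorted(adj[cur]):
            if nb in seen:
                continue
            delta = out[idx[nb]] - out[idx[cur]]
            out[idx[nb]] -= np.round(delta)
            seen.add(nb)
            stack.append(nb)
    return cell.frac_to_cart(out)


# ---------------------------------------------------------------------------
# CIF input
# ---------------------------------------------------------------------------

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")


def _op_to_matrices(op: gemmi.Op) -> tuple[np.ndarray, np.ndarray]:
    rot = np.array(op.rot, dtype=float) / op.DEN
    tran = np.array(op.tran, dtype=float) / op.DEN
    return rot, tran


def parse_crystal(cif_text: str, name: str = "",
                  charge_table: str | None = None) -> CrystalStructure:
    """Read a crystal from CIF text and expand it to the full unit cell.

    Accepts fractional (``_atom_site_fract_*``) or Cartesian
    (``_atom_site_Cartn_*``) coordinate loops.  Partial charges and
    force-field types are taken from ``_atom_site_charge`` /
    ``_atom_site_ff_type`` columns when present, otherwise from an optional
    sidecar CSV (``index,charge,ff_type``), otherwise left unassigned.
    Bonds are inferred from covalent radii; molecules are kept whole across
    cell boundaries.
    """
    try:
        doc = gemmi.cif.read_string(cif_text)
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"could not read CIF: {exc}") from exc

    def cellval(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise ParseError(f"CIF missing cell item {tag}")
        return float(gemmi.cif.as_number(raw))

    cell = UnitCell(cellval("_cell_length_a"), cellval("_cell_length_b"),
                    cellval("_cell_length_c"), cellval("_cell_angle_alpha"),
                    cellval("_cell_angle_beta"), cellval("_cell_angle_gamma"))

    ops: list[gemmi.Op] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [gemmi.Op(gemmi.cif.as_string(s)) for s in col]
            break
    if not ops:
        sg_name = block.find_value("_symmetry_space_group_name_H-M") or \
            block.find_value("_space_group_name_H-M_alt")
        if sg_name:
            sg = gemmi.SpaceGroup(gemmi.cif.as_string(sg_name))
            ops = list(sg.operations())
        else:
            ops = [gemmi.Op("x,y,z")]

    labels_tag = ["_atom_site_label", "_atom_site_type_symbol",
                  "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"]
    table = block.find(labels_tag[:1] + [f"?{t}" for t in labels_tag[1:]])
    if len(table) == 0:
        raise ParseError("CIF has no _atom_site loop")

    elements, fracs, charges, ff_types = [], [], [], []
    charge_col = block.find_loop("_atom_site_charge")
    fftype_col = block.find_loop("_atom_site_ff_type")
    cartn = block.find(["_atom_site_label", "_atom_site_Cartn_x",
                        "_atom_site_Cartn_y", "_atom_site_Cartn_z"])
    use_cartn = table.column(2)[0] is None if len(table) else False

    def _element_from(label: str, symbol: str | None) -> str:
        if symbol:
            return symbol.strip()
        sym = "".join(ch for ch in label if ch.isalpha())[:2]
        if sym not in ELEMENTS:
            sym = sym[:1]
        return sym

    if use_cartn or (len(cartn) and not block.find_loop("_atom_site_fract_x")):
        for i, row in enumerate(cartn):
            sym_raw = None
            if block.find_loop("_atom_site_type_symbol"):
                sym_raw = gemmi.cif.as_string(block.find_loop("_atom_site_type_symbol")[i])
            elements.append(_element_from(gemmi.cif.as_string(row[0]), sym_raw))
            cart = [gemmi.cif.as_number(row[j]) for j in (1, 2, 3)]
            fracs.append(cell.cart_to_frac(np.array(cart)))
    else:
        if not block.find_loop("_atom_site_fract_x"):
            raise ParseError("CIF atom sites lack fractional and Cartesian coordinates")
        for row in table:
            label = gemmi.cif.as_string(row[0])
            sym = gemmi.cif.as_string(row[1]) if row.has(1) else None
            elements.append(_element_from(label, sym))
            fracs.append([gemmi.cif.as_number(row[j]) for j in (2, 3, 4)])

    n_sites = len(elements)
    charges = [float(gemmi.cif.as_number(v)) for v in charge_col] if len(charge_col) == n_sites \
        else [0.0] * n_sites
    ff_types = [gemmi.cif.as_string(v) for v in fftype_col] if len(fftype_col) == n_sites \
        else [None] * n_sites
    if charge_table is not None:
        charges, ff_types = _read_sidecar(charge_table, n_sites, charges, ff_types)

    fracs = np.array(fracs, dtype=float)

    # --- symmetry expansion, wrapping into [0,1), merging special positions
    exp_elem, exp_frac, exp_charge, exp_ff = [], [], [], []
    for rot, tran in (_op_to_matrices(op) for op in ops):
        new = (fracs @ rot.T + tran) % 1.0
        for i in range(n_sites):
            pos = new[i]
            dup = False
            for j, existing in enumerate(exp_frac):
                d = _distance(cell.frac_to_cart(pos), cell.frac_to_cart(np.asarray(existing)),
                              cell)
                if d < MERGE_DISTANCE and exp_elem[j] == elements[i]:
                    dup = True
                    break
                if d < COLLISION_DISTANCE:
                    raise StructureError(
                        f"atom-site collision after expansion: {elements[i]} at {pos} "
                        f"within {d:.2f} Å of {exp_elem[j]}")
            if not dup:
                exp_elem.append(elements[i])
                exp_frac.append(pos)
                exp_charge.append(charges[i])
                exp_ff.append(ff_types[i])

    exp_frac = np.array(exp_frac, dtype=float)
    cart = cell.frac_to_cart(exp_frac)
    bonds = perceive_bonds(exp_elem, cart, pbc_cell=cell)
    comps = _connected_components(len(exp_elem), bonds)

    full_cell = []
    for ci, comp in enumerate(comps):
        mol_cart = _unwrap_component(comp, bonds, exp_frac, cell)
        local = {a: i for i, a in enumerate(comp)}
        mol_bonds = [(local[i], local[j]) for i, j in bonds if i in local and j in local]
        atoms = [Atom(exp_elem[a], mol_cart[i], exp_charge[a], exp_ff[a])
                 for i, a in enumerate(comp)]
        full_cell.append(Molecule(atoms, mol_bonds, label=f"mol{ci}"))

    # asymmetric unit as molecules from the unexpanded site list
    asym_cart = cell.frac_to_cart(fracs)
    asym_bonds = perceive_bonds(elements, asym_cart, pbc_cell=cell)
    asym_unit = []
    for ci, comp in enumerate(_connected_components(n_sites, asym_bonds)):
        mol_cart = _unwrap_component(comp, asym_bonds, fracs, cell)
        local = {a: i for i, a in enumerate(comp)}
        mol_bonds = [(local[i], local[j]) for i, j in asym_bonds if i in local and j in local]
        atoms = [Atom(elements[a], mol_cart[i], charges[a], ff_types[a])
                 for i, a in enumerate(comp)]
        asym_unit.append(Molecule(atoms, mol_bonds, label=f"asym{ci}"))

    return CrystalStructure(cell, asym_unit,
                            [_op_to_matrices(op) for op in ops], full_cell, name=name)


def _read_sidecar(text: str, n_sites: int, charges: list[float],
                  ff_types: list[str | None]):
    """Sidecar CSV: columns index,charge,ff_type (0-based asymmetric-unit index)."""
    charges = list(charges)
    ff_types = list(ff_types)
    for row in csv.DictReader(io.StringIO(text)):
        i = int(row["index"])
        if not 0 <= i < n_sites:
            raise ParseError(f"sidecar index {i} outside atom-site range")
        charges[i] = float(row["charge"])
        if row.get("ff_type"):
            ff_types[i] = row["ff_type"]
    return charges, ff_types


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_p1_cif(crystal: CrystalStructure, name: str = "expanded") -> str:
    """Canonical P1 CIF of the expanded cell (6-decimal fractional coords),
    including charge and force-field-type columns."""
    c = crystal.cell
    lines = [
        f"data_{name or 'expanded'}",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "loop_",
        "_space_group_symop_operation_xyz",
        "x,y,z",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_charge",
        "_atom_site_ff_type",
    ]
    i = 0
    for mol in crystal.full_cell:
        for atom in mol.atoms:
            i += 1
            f = c.cart_to_frac(atom.position)
            lines.append(
                f"{atom.element}{i} {atom.element} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f} "
                f"{atom.charge:.6f} {atom.ff_type or '?'}")
    return "\n".join(lines) + "\n"


def write_xyz(molecules: list[Molecule], comment: str = "") -> str:
    """Plain XYZ text for one or more molecules."""
    rows = []
    n = 0
    for mol in molecules:
        for atom in mol.atoms:
            rows.append(f"{atom.element} {atom.position[0]:.6f} "
                        f"{atom.position[1]:.6f} {atom.position[2]:.6f}")
            n += 1
    return f"{n}\n{comment}\n" + "\n".join(rows) + "\n"


def read_xyz(text: str, label: str = "", charges: list[float] | None = None,
             ff_types: list[str] | None = None) -> Molecule:
    """Read a single molecule from XYZ text; bonds perceived from radii."""
    lines = text.strip().splitlines()
    try:
        n = int(lines[0].strip())
    except (IndexError, ValueError) as exc:
        raise ParseError("XYZ text must start with an atom count") from exc
    if len(lines) < n + 2:
        raise ParseError("XYZ text truncated")
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    coords = np.array(coords)
    atoms = [Atom(e, xyz,
                  charges[i] if charges else 0.0,
                  ff_types[i] if ff_types else None)
             for i, (e, xyz) in enumerate(zip(elements, coords))]
    return Molecule(atoms, perceive_bonds(elements, coords), label=label)


def reduced_miller(hkl: tuple[int, int, int]) -> tuple[int, int, int]:
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise GeometryError("Miller indices (0,0,0) do not define a plane")
    g = gcd(gcd(abs(h), abs(k)), abs(l))
    return (h // g, k // g, l // g)
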
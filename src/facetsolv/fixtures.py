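"""Synthetic toy crystals, probes, and independent brute-force oracles.

Everything here is generated programmatically so the full pipeline is
testable without any external structure download.  The fixture force-field
types use round-number parameters (``X_``: R0 = 3.0 Å, D0 = 0.1 kcal/mol,
etc., see the bundled table) so closed-form checks such as the 12-6
minimum at R0 are exact.  The brute-force oracles re-state the energy
model in plain nested Python loops, sharing no code with the vectorized
production kernel, and exist purely as an independent verification path.

Fixtures exercise code paths, not pharmacology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import OracleError, StructureError
from .forcefield import ForceFieldParams
from .gridscan import GridSpec, InteractionRecord, ProbePose, ScanResult
from .rankstats import RankCurve
from .slab import SurfaceSlab
from .structures import Atom, CrystalStructure, Molecule, UnitCell

VARIANTS = ("apolar", "polar-pair", "grooved")


@dataclass
class ToyCrystalSpec:
    """Recipe for a deterministic toy molecular crystal."""

    variant: str = "apolar"
    a: float = 6.0
    b: float = 6.0
    c: float = 6.0
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P1"  # "P1" | "P-1"
    seed: int | None = None
    jitter: float = 0.05  # Å, amplitude of seeded random perturbation


def _motif(spec: ToyCrystalSpec) -> list[Molecule]:
    """Small rigid molecules (1–6 atoms) with charges and ff types."""
    if spec.variant == "apolar":
        # homonuclear diatomic, pure dispersion
        atoms = [Atom("Ar", [0.0, 0.0, 0.0], 0.0, "X_"),
                 Atom("Ar", [1.2, 0.0, 0.0], 0.0, "X_")]
        return [Molecule(atoms, [(0, 1)], label="apolar")]
    if spec.variant == "polar-pair":
        # an O-H donor diatomic plus a lone acceptor atom
        donor = Molecule([
            Atom("O", [0.0, 0.0, 0.0], -0.40, "O_3", hb_role="acceptor"),
            Atom("H", [0.96, 0.0, 0.0], 0.40, "D_H", hb_role="donor-H"),
        ], [(0, 1)], label="donor")
        acceptor = Molecule([
            Atom("O", [0.5 * spec.a, 0.5 * spec.b, 0.5 * spec.c],
                 -0.20, "A_X", hb_role="acceptor"),
            Atom("He", [0.5 * spec.a + 1.1, 0.5 * spec.b, 0.5 * spec.c],
                 0.20, "X_"),
        ], [(0, 1)], label="acceptor")
        return [donor, acceptor]
    if spec.variant == "grooved":
        # two single-atom "molecules" at different heights: a grooved top
        # layer with a 1.5 Å peak-to-valley corrugation along c
        lo = Molecule([Atom("Ar", [0.15 * spec.a, 0.25 * spec.b, 0.25 * spec.c],
                            0.0, "X_")], label="valley")
        hi = Molecule([Atom("Ar", [0.15 * spec.a + 1.5, 0.75 * spec.b, 0.75 * spec.c],
                            0.0, "X_")], label="peak")
        return [lo, hi]
    raise StructureError(f"unknown toy variant {spec.variant!r}; "
                         f"choose from {VARIANTS}")


def make_toy_crystal(spec: ToyCrystalSpec) -> CrystalStructure:
    """Deterministic toy crystal; a given spec (incl. seed) always
    regenerates the identical structure."""
    cell = UnitCell(spec.a, spec.b, spec.c, spec.alpha, spec.beta, spec.gamma)
    motif = _motif(spec)
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        motif = [m.with_coords(m.coords + rng.normal(0.0, spec.jitter, m.coords.shape))
                 for m in motif]

    ops: list[tuple[np.ndarray, np.ndarray]] = [(np.eye(3), np.zeros(3))]
    full = [m.with_coords(m.coords) for m in motif]
    if spec.space_group == "P-1":
        ops.append((-np.eye(3), np.zeros(3)))
        shift = cell.frac_to_cart([0.5, 0.5, 0.5])
        for m in motif:
            inv = m.with_coords(-(m.coords) + 2 * shift)
            full.append(inv)
    elif spec.space_group != "P1":
        raise StructureError("toy crystals support P1 and P-1 only")

    # collision sanity over the expanded contents
    coords = np.concatenate([m.coords for m in full])
    n_mol_atoms = [len(m.atoms) for m in full]
    owner = np.repeat(np.arange(len(full)), n_mol_atoms)
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if owner[i] != owner[j] and np.linalg.norm(coords[i] - coords[j]) < 0.5:
                raise StructureError("overlapping motif in toy crystal spec")

    return CrystalStructure(cell, motif, ops, full, name=f"toy-{spec.variant}")


def toy_probe_single(ff_type: str = "X_", element: str = "Ar",
                     charge: float = 0.0) -> Molecule:
    return Molecule([Atom(element, [0.0, 0.0, 0.0], charge, ff_type)],
                    label="probe1")


def toy_probe_diatomic(separation: float = 1.2) -> Molecule:
    return Molecule([Atom("Ar", [0.0, 0.0, 0.0], 0.0, "X_"),
                     Atom("Ar", [separation, 0.0, 0.0], 0.0, "X_")],
                    [(0, 1)], label="probe2")


def toy_probe_polar() -> Molecule:
    """O-H donor probe for hydrogen-bond channel tests."""
    return Molecule([
        Atom("O", [0.0, 0.0, 0.0], -0.40, "O_3", hb_role="acceptor"),
        Atom("H", [0.96, 0.0, 0.0], 0.40, "D_H", hb_role="donor-H"),
    ], [(0, 1)], label="probeOH")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent code paths, plain Python)
# ---------------------------------------------------------------------------


def _oracle_pair_terms(ai: Atom, aj: Atom, pi, pj, params: ForceFieldParams):
    dx = pi[0] - pj[0]
    dy = pi[1] - pj[1]
    dz = pi[2] - pj[2]
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    ti = params.types[ai.ff_type]
    tj = params.types[aj.ff_type]
    r0 = math.sqrt(ti.r0 * tj.r0)
    d0 = math.sqrt(ti.d0 * tj.d0)
    s = (r0 / r) ** 6
    disp = d0 * (s * s - 2.0 * s)
    coul = params.coulomb_k * ai.charge * aj.charge / (params.dielectric * r)
    return r, disp, coul


def _oracle_hb(d_pos, h_pos, a_pos, params: ForceFieldParams) -> float:
    rda = math.dist(d_pos, a_pos)
    if rda > params.hb_distance_cutoff:
        return 0.0
    v1 = [d_pos[i] - h_pos[i] for i in range(3)]
    v2 = [a_pos[i] - h_pos[i] for i in range(3)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    cos_t = sum(v1[i] * v2[i] for i in range(3)) / (n1 * n2)
    cos_t = max(-1.0, min(1.0, cos_t))
    if math.degrees(math.acos(cos_t)) < params.hb_angle_min:
        return 0.0
    x = params.r_hb / rda
    return params.d_hb * (5.0 * x ** 12 - 6.0 * x ** 10) * cos_t ** 4


def _oracle_donors_acceptors(mol: Molecule, params: ForceFieldParams):
    neighbor = {}
    for i, j in mol.bonds:
        neighbor.setdefault(i, j)
        neighbor.setdefault(j, i)
    donors, acceptors = [], []
    for i, a in enumerate(mol.atoms):
        t = params.types[a.ff_type]
        if (a.hb_role == "donor-H" or (a.hb_role == "none" and t.donor_hydrogen)) \
                and i in neighbor:
            donors.append((i, neighbor[i]))
        if a.hb_role == "acceptor" or (a.hb_role == "none" and t.acceptor):
            acceptors.append(i)
    return donors, acceptors


def brute_force_pair_oracle(mol_a: Molecule, mol_b: Molecule,
                            params: ForceFieldParams) -> tuple[float, float, float]:
    """(E_disp, E_hb, E_coul) of a molecule pair by plain nested loops."""
    ca, cb = mol_a.coords.tolist(), mol_b.coords.tolist()
    disp = coul = 0.0
    for i, ai in enumerate(mol_a.atoms):
        for j, aj in enumerate(mol_b.atoms):
            _, d_, c_ = _oracle_pair_terms(ai, aj, ca[i], cb[j], params)
            disp += d_
            coul += c_
    hb = 0.0
    don_a, acc_a = _oracle_donors_acceptors(mol_a, params)
    don_b, acc_b = _oracle_donors_acceptors(mol_b, params)
    for h, heavy in don_a:
        for acc in acc_b:
            hb += _oracle_hb(ca[heavy], ca[h], cb[acc], params)
    for h, heavy in don_b:
        for acc in acc_a:
            hb += _oracle_hb(cb[heavy], cb[h], ca[acc], params)
    return disp, hb, coul


def _oracle_axes(mol: Molecule) -> np.ndarray:
    """Principal axes by direct eigendecomposition (deliberate duplication
    of the production conventions, written independently)."""
    c = mol.coords - mol.coords.mean(axis=0)
    vals, vecs = np.linalg.eigh(c.T @ c / max(1, len(c)))
    axes = vecs[:, np.argsort(vals)[::-1]].T
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i][j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def _oracle_rotation(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic x-y-z Euler rotation from explicit trigonometry."""
    a, b, g = (math.radians(x) for x in (alpha, beta, gamma))
    rx = np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)],
                   [0, math.sin(a), math.cos(a)]])
    ry = np.array([[math.cos(b), 0, math.sin(b)], [0, 1, 0],
                   [-math.sin(b), 0, math.cos(b)]])
    rz = np.array([[math.cos(g), -math.sin(g), 0],
                   [math.sin(g), math.cos(g), 0], [0, 0, 1]])
    return rx @ ry @ rz


def _oracle_poses(slab: SurfaceSlab, grid: GridSpec):
    """Independent enumeration of the pose grid (same conventions)."""
    nv = max(1, int(round(math.sqrt(sum(x * x for x in slab.tile_v)) / grid.lateral_step)))
    nw = max(1, int(round(math.sqrt(sum(x * x for x in slab.tile_w)) / grid.lateral_step)))
    angles = [grid.angle_step * t for t in range(int(360.0 / grid.angle_step)
                                                 if 360.0 % grid.angle_step == 0
                                                 else math.ceil(360.0 / grid.angle_step))]
    out = []
    for plane in range(1, grid.n_planes + 1):
        for i in range(nv):
            for j in range(nw):
                for a in angles:
                    for b in angles:
                        for g in angles:
                            out.append(ProbePose(plane, i / nv, j / nw,
                                                 (plane - 1) * grid.plane_spacing,
                                                 (a, b, g)))
    return out


def brute_force_scan_oracle(slab: SurfaceSlab, probe: Molecule,
                            grid: GridSpec, params: ForceFieldParams,
                            cutoff: float = -2.0) -> ScanResult:
    """Independent full grid scan (≤ 500 atom pairs per pose).

    Re-enumerates the pose grid with its own rotation/placement code and
    sums energies with the plain-loop pair oracle; shares no kernel code
    with the production scanner and exists only to cross-check
    :func:`facetsolv.gridscan.scan_surface`.
    """
    n_pairs = len(probe.atoms) * sum(len(m.atoms) for m in slab.molecules)
    if n_pairs > 500:
        raise OracleError(f"oracle size guard exceeded: {n_pairs} atom pairs per pose")
    axes = _oracle_axes(probe)
    local = (probe.coords - probe.centroid) @ axes.T
    records = []
    n_overlaps = 0
    poses = _oracle_poses(slab, grid)
    for pose in poses:
        rot = _oracle_rotation(*pose.euler)
        point = (slab.tile_origin + pose.v * slab.tile_v + pose.w * slab.tile_w
                 + np.array([pose.x_offset, 0.0, 0.0]))
        coords = (local @ rot.T) @ axes + point
        posed = probe.with_coords(coords)
        disp = hb = coul = 0.0
        overlap = False
        for mol in slab.molecules:
            for i, ai in enumerate(posed.atoms):
                for j, aj in enumerate(mol.atoms):
                    r, d_, c_ = _oracle_pair_terms(
                        ai, aj, posed.atoms[i].position, mol.atoms[j].position, params)
                    if r < 0.1:
                        overlap = True
                        break
                    disp += d_
                    coul += c_
                if overlap:
                    break
            if overlap:
                break
            d_p, a_p = _oracle_donors_acceptors(posed, params)
            d_s, a_s = _oracle_donors_acceptors(mol, params)
            for h, heavy in d_p:
                for acc in a_s:
                    hb += _oracle_hb(posed.atoms[heavy].position,
                                     posed.atoms[h].position,
                                     mol.atoms[acc].position, params)
            for h, heavy in d_s:
                for acc in a_p:
                    hb += _oracle_hb(mol.atoms[heavy].position,
                                     mol.atoms[h].position,
                                     posed.atoms[acc].position, params)
        if overlap:
            n_overlaps += 1
            continue
        total = disp + hb + coul
        if total <= cutoff:
            from .forcefield import EnergyComponents
            records.append(InteractionRecord(
                pose, EnergyComponents(e_disp=disp, e_hb=hb, e_coul=coul)))
    return ScanResult(str(slab.face), probe.label or "probe", cutoff, records,
                      grid, n_poses=len(poses), n_overlaps=n_overlaps)


def rugosity_oracle(slab: SurfaceSlab, step: float = 0.1,
                    capture_radius: float = 1.0) -> float:
    """Brute-force peak-to-valley height over the central tile at dense
    lateral sampling."""
    heights = []
    coords = [a.position for m in slab.molecules for a in m.atoms]
    nv = max(2, int(np.linalg.norm(slab.tile_v) / step))
    nw = max(2, int(np.linalg.norm(slab.tile_w) / step))
    for i in range(nv):
        for j in range(nw):
            p = slab.tile_origin + (i / nv) * slab.tile_v + (j / nw) * slab.tile_w
            best = None
            for xyz in coords:
                dy = xyz[1] - p[1]
                dz = xyz[2] - p[2]
                if math.sqrt(dy * dy + dz * dz) <= capture_radius + 1e-9:
                    if best is None or xyz[0] > best:
                        best = xyz[0]
            if best is not None:
                heights.append(best)
    return max(heights) - min(heights)


# ---------------------------------------------------------------------------
# Synthetic rank curves
# ---------------------------------------------------------------------------


def synthetic_rank_curve(breakpoint: int, slopes: tuple[float, float],
                         noise_sigma: float, n: int,
                         seed: int = 0, e0: float = -8.0) -> RankCurve:
    """Two-segment piecewise-linear rank curve with Gaussian noise.

    The head segment (ranks 1..breakpoint) rises with ``slopes[0]`` and the
    tail (breakpoint..n) with ``slopes[1]``; both slopes must be positive
    (energies weaken with rank).  A single-regime "all strong" curve (no
    asymptotic tail) is obtained with ``breakpoint >= n``.

    Monotonicity after noising is restored by a running maximum, which
    keeps each perturbation local and preserves the nominal segment
    slopes.  (A global re-sort would turn the near-flat tail into the
    order statistics of the noise, so the generated tail would no longer
    have slope ``slopes[1]``.)
    """
    if min(slopes) < 0:
        raise StructureError("rank-curve slopes must be non-negative")
    if breakpoint < 1:
        raise StructureError("breakpoint must be >= 1")
    x = np.arange(1, n + 1, dtype=float)
    bp = min(breakpoint, n)
    y = np.where(x <= bp, e0 + slopes[0] * (x - 1),
                 e0 + slopes[0] * (bp - 1) + slopes[1] * (x - bp))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = np.maximum.accumulate(y + rng.normal(0.0, noise_sigma, n))
    return RankCurve(y)
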
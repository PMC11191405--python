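"""Six-dimensional rigid-probe grid scan over a crystal surface.

The probe is placed with its centroid on each point of a lateral grid
spanning one central reticular area, on successive planes 1 Å apart moving
outward from the surface reference plane (plane 1 anchored at
``surface_x``), and rotated about its three principal axes in fixed angle
steps (default 30°, i.e. 12³ = 1728 orientations per translation point).
Every pose whose total interaction energy with the slab is at least as
favorable as the cutoff (default −2 kcal/mol) is recorded; the number of
recorded poses is the face's *interaction rank*.

The scan is exhaustive and deterministic: no randomness, fixed enumeration
order (plane, v, w, alpha, beta, gamma).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .forcefield import (EnergyComponents, ForceFieldParams, MIN_SEPARATION,
                         MolArrays, hbond_energy)
from .slab import SurfaceSlab
from .structures import Molecule, write_xyz

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = -2.0  # kcal/mol


@dataclass(frozen=True)
class GridSpec:
    """Scan grid: lateral step (Å-equivalent fractional subdivision of the
    reticular tile), number of 1 Å-spaced planes, and the Euler angle step."""

    lateral_step: float = 1.0
    n_planes: int = 8
    plane_spacing: float = 1.0
    angle_step: float = 30.0
    per_point_minimum: bool = False
    dedup_orientations: bool = False

    def angles(self) -> np.ndarray:
        if not 0.0 < self.angle_step <= 360.0:
            raise ConfigError("angle_step must be in (0, 360]")
        return np.arange(0.0, 360.0, self.angle_step)


@dataclass(frozen=True)
class ProbePose:
    """One probe placement: plane index (1-based), fractional in-plane
    coordinates, height above the surface plane, and intrinsic Euler angles
    (degrees) about the probe principal axes."""

    plane_index: int
    v: float
    w: float
    x_offset: float
    euler: tuple[float, float, float]


@dataclass
class InteractionRecord:
    pose: ProbePose
    energy: EnergyComponents


@dataclass
class ScanResult:
    face_id: str
    probe_id: str
    cutoff: float
    records: list[InteractionRecord]
    grid: GridSpec
    n_poses: int = 0
    n_overlaps: int = 0

    @property
    def interaction_rank(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "plane": r.pose.plane_index, "v": r.pose.v, "w": r.pose.w,
            "alpha": r.pose.euler[0], "beta": r.pose.euler[1],
            "gamma": r.pose.euler[2], "e_disp": r.energy.e_disp,
            "e_hb": r.energy.e_hb, "e_coul": r.energy.e_coul,
            "e_total": r.energy.e_total,
        } for r in self.records]
        return pd.DataFrame(rows, columns=["plane", "v", "w", "alpha", "beta",
                                           "gamma", "e_disp", "e_hb", "e_coul",
                                           "e_total"])

    def header_json(self) -> str:
        return json.dumps({
            "face": self.face_id, "probe": self.probe_id, "cutoff": self.cutoff,
            "lateral_step": self.grid.lateral_step, "n_planes": self.grid.n_planes,
            "plane_spacing": self.grid.plane_spacing,
            "angle_step": self.grid.angle_step,
            "interaction_rank": self.interaction_rank,
            "n_poses": self.n_poses, "n_overlaps": self.n_overlaps,
        }, indent=2)


def principal_axes(probe: Molecule) -> np.ndarray:
    """Orthonormal principal axes of the unit-weight gyration tensor of the
    atomic coordinates, rows ordered by descending eigenvalue (longest axis
    first), right-handed with deterministic sign fixing."""
    coords = probe.coords - probe.centroid
    gyr = coords.T @ coords / max(1, len(coords))
    vals, vecs = np.linalg.eigh(gyr)  # ascending
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order].T
    for i in range(2):  # sign: largest-magnitude component positive
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i][j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def generate_poses(slab: SurfaceSlab, probe: Molecule, grid: GridSpec) -> list[ProbePose]:
    """All (plane, lateral, orientation) combinations over one central
    reticular area, in deterministic order."""
    if grid.n_planes < 1:
        raise ConfigError("n_planes must be >= 1")
    nv = max(1, int(round(np.linalg.norm(slab.tile_v) / grid.lateral_step)))
    nw = max(1, int(round(np.linalg.norm(slab.tile_w) / grid.lateral_step)))
    angles = grid.angles()
    if len(angles) == 0:
        raise ConfigError("empty angle grid")
    poses = []
    for plane in range(1, grid.n_planes + 1):
        x_off = (plane - 1) * grid.plane_spacing
        for i in range(nv):
            for j in range(nw):
                for a in angles:
                    for b in angles:
                        for g in angles:
                            poses.append(ProbePose(plane, i / nv, j / nw,
                                                   x_off, (float(a), float(b), float(g))))
    return poses


def pose_coords(probe_local: np.ndarray, axes: np.ndarray, pose: ProbePose,
                slab: SurfaceSlab) -> np.ndarray:
    """Cartesian slab-frame coordinates of the probe in a given pose.

    ``probe_local`` are centroid-centered coordinates expressed in the
    probe principal frame (rows of ``axes``); the Euler rotation is applied
    in that frame and the result mapped back to the slab frame.
    """
    rot = Rotation.from_euler("XYZ", pose.euler, degrees=True).as_matrix()
    point = (slab.tile_origin + pose.v * slab.tile_v + pose.w * slab.tile_w
             + np.array([pose.x_offset, 0.0, 0.0]))
    return (probe_local @ rot.T) @ axes + point


def scan_surface(slab: SurfaceSlab, probe: Molecule, params: ForceFieldParams,
                 grid: GridSpec | None = None,
                 cutoff: float = DEFAULT_CUTOFF) -> ScanResult:
    """Exhaustive scan: one record per pose with E_total ≤ cutoff.

    Poses with atomic overlap (< 0.1 Å) are skipped and counted, never
    fatal.  With ``grid.per_point_minimum`` only the most favorable
    orientation at each translation point is eligible for recording.
    """
    grid = grid or GridSpec()
    axes = principal_axes(probe)
    probe_local = (probe.coords - probe.centroid) @ axes.T
    probe_arr = MolArrays.from_molecule(probe, params)

    if not slab.molecules:
        poses = generate_poses(slab, probe, grid)
        return ScanResult(str(slab.face), probe.label or "probe", cutoff, [],
                          grid, n_poses=len(poses))

    slab_arrays = [MolArrays.from_molecule(m, params) for m in slab.molecules]
    slab_coords = np.concatenate([a.coords for a in slab_arrays])
    slab_r0 = np.concatenate([a.r0 for a in slab_arrays])
    slab_d0 = np.concatenate([a.d0 for a in slab_arrays])
    slab_q = np.concatenate([a.q for a in slab_arrays])
    # hb participants with global indices into slab_coords
    slab_donors: list[tuple[int, int]] = []
    slab_acceptors: list[int] = []
    off = 0
    for arr in slab_arrays:
        slab_donors.extend((off + h, off + d) for h, d in arr.donors)
        slab_acceptors.extend(off + a for a in arr.acceptors)
        off += len(arr.coords)

    poses = generate_poses(slab, probe, grid)
    records: list[InteractionRecord] = []
    n_overlaps = 0
    point_best: dict[tuple[int, float, float], InteractionRecord] = {}

    for pose in poses:
        coords = pose_coords(probe_local, axes, pose, slab)
        d = cdist(coords, slab_coords)
        if (d < MIN_SEPARATION).any():
            n_overlaps += 1
            continue
        mask = slice(None) if params.cutoff is None else d <= params.cutoff
        r0 = np.sqrt(np.outer(probe_arr.r0, slab_r0))
        d0 = np.sqrt(np.outer(probe_arr.d0, slab_d0))
        x6 = (r0 / d) ** 6
        e_disp = float((d0 * (x6 * x6 - 2.0 * x6))[mask].sum())
        eps = params.dielectric
        qq = np.outer(probe_arr.q, slab_q)
        denom = d * d if params.distance_dependent_dielectric else d
        e_coul = float((params.coulomb_k * qq / (eps * denom))[mask].sum())
        e_hb = 0.0
        for h_i, heavy_i in probe_arr.donors:
            for acc in slab_acceptors:
                e_hb += hbond_energy(coords[heavy_i], coords[h_i],
                                     slab_coords[acc], params)
        for h_j, heavy_j in slab_donors:
            for acc_i in probe_arr.acceptors:
                e_hb += hbond_energy(slab_coords[heavy_j], slab_coords[h_j],
                                     coords[acc_i], params)
        comp = EnergyComponents(e_disp=e_disp, e_hb=e_hb, e_coul=e_coul)
        if comp.e_total > cutoff:
            continue
        rec = InteractionRecord(pose, comp)
        if grid.per_point_minimum:
            key = (pose.plane_index, pose.v, pose.w)
            best = point_best.get(key)
            if best is None or comp.e_total < best.energy.e_total:
                point_best[key] = rec
        else:
            records.append(rec)

    if grid.per_point_minimum:
        records = list(point_best.values())

    if n_overlaps:
        logger.info("scan %s/%s: skipped %d overlapping poses",
                    slab.face, probe.label, n_overlaps)
    return ScanResult(str(slab.face), probe.label or "probe", cutoff, records,
                      grid, n_poses=len(poses), n_overlaps=n_overlaps)


def export_poses(result: ScanResult, slab: SurfaceSlab, probe: Molecule,
                 k: int) -> list[str]:
    """XYZ documents (probe + slab) for the k lowest-energy recorded poses."""
    if not result.records:
        raise ConfigError("cannot export poses from an empty scan result")
    if k > len(result.records):
        import warnings
        warnings.warn(f"requested {k} poses but only {len(result.records)} "
                      "records; truncating", stacklevel=2)
        k = len(result.records)
    axes = principal_axes(probe)
    probe_local = (probe.coords - probe.centroid) @ axes.T
    best = sorted(result.records, key=lambda r: r.energy.e_total)[:k]
    docs = []
    for rec in best:
        coords = pose_coords(probe_local, axes, rec.pose, slab)
        posed = probe.with_coords(coords)
        docs.append(write_xyz([posed] + slab.molecules,
                              comment=f"E_total={rec.energy.e_total:.4f} kcal/mol"))
    return docs
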
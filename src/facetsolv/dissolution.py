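"""Binding-energy dissolution model with inequivalent wetting.

The solid-state binding energy of a face is the distance-weighted sum of
the pair interactions between a central reference molecule Mo and the
molecules lying toward the face,

    E_b(hkl) = sum_k E_MoMk / R_MoMk      (kcal/(mol·Å)),

including only pairs contributing at least −0.01 kcal/mol of stabilization.
Wetting enters through the energy differential

    E_d = E_s(solvent)/MW_solvent − E_s(solute)/MW_solute   (kcal/mol),

the molecular-weight-normalized difference between the solvent-probe and
solute-probe surface interaction energies of the face.  E_d modifies the
normalized binding energy into E_b,mod together with face geometry (cell
volume, reticular area, rugosity); the combination is configurable because
its published form is not recoverable from the tabulated values — the
default here is

    E_b,mod = −(E_b/MW_solute + E_d) · S_hkl · rugosity / V_cell,

and externally determined E_b,mod values can be injected verbatim.
Face-specific relative dissolution rates are ratios of modified binding
energies, R_rel,D(i, j) = E_b,mod(i) / E_b,mod(j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConvergenceError, GeometryError
from .forcefield import ForceFieldParams, molecule_pair_energy
from .structures import CrystalStructure, MillerFace

BINDING_THRESHOLD = -0.01  # kcal/mol: weakest stabilizing pair included


@dataclass
class BindingEnergyResult:
    """E_b of one face with the per-molecule contributions behind it."""

    face_id: str
    e_b: float  # kcal/(mol·Å)
    contributions: list[tuple[str, float, float]]  # (molecule id, E_MoMk, R_MoMk)
    threshold: float = BINDING_THRESHOLD

    def recompute(self) -> float:
        return float(sum(e / r for _, e, r in self.contributions))


def binding_energy(crystal: CrystalStructure, hkl: tuple[int, int, int],
                   params: ForceFieldParams,
                   threshold: float = BINDING_THRESHOLD,
                   max_shell: int = 5) -> BindingEnergyResult:
    """Distance-weighted lattice sum toward the face (hkl).

    The reference molecule is the full-cell molecule whose centroid is
    nearest the cell center.  Image molecules are enumerated in growing
    cubic shells of lattice translations; a molecule contributes when its
    centroid displacement from the reference has a positive component
    along the outward (hkl) normal and its pair energy is at least as
    stabilizing as ``threshold``.  Enumeration stops when the strongest
    pair energy in the outermost shell is weaker than |threshold|;
    exhausting ``max_shell`` first raises a convergence error carrying the
    residual.
    """
    face = MillerFace.from_cell(crystal.cell, hkl)
    cellm = crystal.cell.matrix
    recip = np.linalg.inv(cellm).T
    normal = hkl[0] * recip[0] + hkl[1] * recip[1] + hkl[2] * recip[2]
    normal = normal / np.linalg.norm(normal)

    center = crystal.cell.frac_to_cart(np.array([0.5, 0.5, 0.5]))
    ref_idx = int(np.argmin([np.linalg.norm(m.centroid - center)
                             for m in crystal.full_cell]))
    ref = crystal.full_cell[ref_idx]
    ref_cen = ref.centroid

    contributions: list[tuple[str, float, float]] = []
    converged = False
    residual = np.inf
    for shell in range(0, max_shell + 1):
        shell_max = 0.0
        for i in range(-shell, shell + 1):
            for j in range(-shell, shell + 1):
                for k in range(-shell, shell + 1):
                    if max(abs(i), abs(j), abs(k)) != shell:
                        continue
                    shift = i * cellm[0] + j * cellm[1] + k * cellm[2]
                    for mi, mol in enumerate(crystal.full_cell):
                        if shell == 0 and i == j == k == 0 and mi == ref_idx:
                            continue
                        other = mol.translated(shift)
                        disp = other.centroid - ref_cen
                        comp, r = molecule_pair_energy(ref, other, params)
                        e = comp.e_total
                        shell_max = max(shell_max, abs(e))
                        if np.dot(disp, normal) <= 1e-9:
                            continue
                        if e <= threshold:
                            contributions.append((f"{mi}@({i},{j},{k})", e, r))
        if shell > 0 and shell_max < abs(threshold):
            converged = True
            residual = shell_max
            break
    if not converged:
        raise ConvergenceError(
            f"binding-energy sum for {face} not converged within "
            f"{max_shell} shells (outer-shell max |E| = {shell_max:.4g})",
            residual=shell_max)

    e_b = float(sum(e / r for _, e, r in contributions))
    return BindingEnergyResult(str(face), e_b, contributions, threshold)


# ---------------------------------------------------------------------------
# Arithmetic of the wetting-modified model
# ---------------------------------------------------------------------------


def normalize_by_mw(energy: float, molar_mass: float) -> float:
    """Energy per unit molecular weight (g/mol divisor)."""
    if molar_mass <= 0:
        raise GeometryError("molar mass must be positive")
    return energy / molar_mass


def energy_differential(e_s_solvent_norm: float, e_s_solute_norm: float) -> float:
    """Solvent-minus-solute normalized surface interaction difference E_d."""
    return e_s_solvent_norm - e_s_solute_norm


CombineFn = Callable[[float, float, float, float, float], float]


def _default_combine(e_b_norm: float, e_d: float, v_cell: float,
                     s_hkl: float, rugosity: float) -> float:
    # additive solid-state + wetting term scaled by the dimensionless
    # exposed-roughness fraction of the cell
    return -(e_b_norm + e_d) * s_hkl * rugosity / v_cell


def modified_binding_energy(e_b_norm: float, e_d: float, v_cell: float,
                            s_hkl: float, rugosity: float,
                            combine: CombineFn | None = None) -> float:
    """Wetting- and geometry-modified binding energy E_b,mod
    (kcal/(mol·Å), positive by the tabulated sign convention)."""
    for name, val in (("v_cell", v_cell), ("s_hkl", s_hkl), ("rugosity", rugosity)):
        if val is None or not np.isfinite(val):
            raise GeometryError(f"geometric parameter {name} missing or non-finite")
    fn = combine or _default_combine
    return float(fn(e_b_norm, e_d, v_cell, s_hkl, rugosity))


def dissolution_ratio(e_i: float, e_j: float) -> float:
    """Relative dissolution rate of face i w.r.t. face j as the ratio of
    their (modified) binding energies."""
    if e_j == 0:
        raise GeometryError("zero denominator in dissolution ratio")
    return e_i / e_j


def percent_discrepancy(predicted: float, experimental: float) -> float:
    """100·|predicted − experimental| / experimental."""
    if experimental == 0:
        raise GeometryError("zero experimental value in discrepancy")
    return 100.0 * abs(predicted - experimental) / experimental


# ---------------------------------------------------------------------------
# Face-level model assembly (the "tables" arithmetic)
# ---------------------------------------------------------------------------


@dataclass
class FaceModelInput:
    """Everything the model needs about one face.

    Surface interaction energies are per-probe (kcal/mol); ``e_b`` is the
    solid-state binding energy (kcal/(mol·Å)); the geometric parameters
    feed the E_b,mod combination unless ``e_b_mod`` injects a value
    directly; ``experimental_rate`` is optional, for validation ratios.
    """

    face_id: str
    e_b: float
    e_s: dict[str, float]
    v_cell: float | None = None
    s_hkl: float | None = None
    rugosity: float | None = None
    e_b_mod: float | None = None
    experimental_rate: float | None = None


@dataclass
class DissolutionPrediction:
    """Per-face energies and per-pair predicted/experimental rate ratios."""

    faces: pd.DataFrame
    ratios: pd.DataFrame


def predict_dissolution(faces: list[FaceModelInput], solute: str,
                        solvent: str, molar_masses: dict[str, float],
                        ratio_pairs: list[tuple[str, str]] | None = None,
                        combine: CombineFn | None = None) -> DissolutionPrediction:
    """Assemble E_d, E_b,mod and relative dissolution rates for a face set.

    ``solute``/``solvent`` name the probes whose surface energies enter the
    energy differential; ``molar_masses`` maps probe names (and the solute)
    to g/mol.  ``ratio_pairs`` defaults to every face against the last one.
    """
    rows = []
    for f in faces:
        if solvent not in f.e_s or solute not in f.e_s:
            raise AnalysisError(
                f"face {f.face_id} lacks surface energies for {solvent!r}/{solute!r}")
        e_d = energy_differential(
            normalize_by_mw(f.e_s[solvent], molar_masses[solvent]),
            normalize_by_mw(f.e_s[solute], molar_masses[solute]))
        e_b_norm = normalize_by_mw(f.e_b, molar_masses[solute])
        if f.e_b_mod is not None:
            e_b_mod = f.e_b_mod
        else:
            e_b_mod = modified_binding_energy(e_b_norm, e_d, f.v_cell,
                                              f.s_hkl, f.rugosity, combine)
        rows.append({"face": f.face_id, "e_b": f.e_b, "e_b_norm": e_b_norm,
                     "e_d": e_d, "e_b_mod": e_b_mod,
                     "experimental_rate": f.experimental_rate})
    face_df = pd.DataFrame(rows).set_index("face")

    if ratio_pairs is None:
        last = faces[-1].face_id
        ratio_pairs = [(f.face_id, last) for f in faces[:-1]]
    ratio_rows = []
    for fi, fj in ratio_pairs:
        pred = dissolution_ratio(face_df.loc[fi, "e_b_mod"],
                                 face_df.loc[fj, "e_b_mod"])
        ri = face_df.loc[fi, "experimental_rate"]
        rj = face_df.loc[fj, "experimental_rate"]
        exp_ratio = (dissolution_ratio(ri, rj)
                     if ri is not None and rj is not None
                     and not (pd.isna(ri) or pd.isna(rj)) else None)
        disc = (percent_discrepancy(pred, exp_ratio)
                if exp_ratio is not None else None)
        ratio_rows.append({"pair": f"{fi}/{fj}", "predicted": pred,
                           "experimental": exp_ratio, "discrepancy_pct": disc})
    ratio_df = pd.DataFrame(ratio_rows,
                            columns=["pair", "predicted", "experimental",
                                     "discrepancy_pct"]).set_index("pair")
    return DissolutionPrediction(face_df, ratio_df)
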
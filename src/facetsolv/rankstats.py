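"""Rank-curve statistics for surface interaction energies.

Recorded interactions are sorted from strongest (most negative) to weakest
and plotted against their rank.  To average only the interactions that
matter for dissolution, a two-line construction selects a face- and
probe-specific rank: a least-squares line through the weak asymptotic tail
(final 5% of ranks) and the best-fitting line through the strong head of
the curve; the rank at their intersection bounds the averaging window.
The mean energy over that window is the surface interaction energy E_s.

Component percentages and plane-averaged landscapes are derived from the
same records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .gridscan import InteractionRecord, ScanResult


@dataclass
class LineFit:
    slope: float
    intercept: float

    def __call__(self, x):
        return self.slope * np.asarray(x) + self.intercept


@dataclass
class RankCurve:
    """Interaction energies sorted ascending (strongest first)."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)

    @property
    def rank(self) -> int:
        return len(self.energies)


@dataclass
class IntersectionResult:
    selected_rank: int
    head_fit: LineFit
    tail_fit: LineFit
    head_window: int
    fallback: bool = False


@dataclass
class SurfaceInteractionSummary:
    """E_s and its provenance for one (face, probe) pair."""

    face_id: str
    probe_id: str
    e_s: float
    selected_rank: int
    interaction_rank: int
    head_fit: LineFit
    tail_fit: LineFit
    component_pct: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "face": self.face_id, "probe": self.probe_id, "e_s": self.e_s,
            "selected_rank": self.selected_rank,
            "interaction_rank": self.interaction_rank,
            "head_fit": [self.head_fit.slope, self.head_fit.intercept],
            "tail_fit": [self.tail_fit.slope, self.tail_fit.intercept],
            "component_pct": self.component_pct,
        }


def rank_records(result: ScanResult) -> RankCurve:
    """Stable ascending sort of record energies (ties keep enumeration order)."""
    if not result.records:
        raise AnalysisError("cannot rank an empty scan result")
    e = np.array([r.energy.e_total for r in result.records])
    return RankCurve(e[np.argsort(e, kind="stable")])


def _prefix_r2(y: np.ndarray) -> np.ndarray:
    """R² of the least-squares line over each prefix [1..m] of (rank, y);
    entry m-1 holds the prefix of length m.  Perfect fits (zero residual
    variance) give R² = 1."""
    n = len(y)
    x = np.arange(1, n + 1, dtype=float)
    m = x  # prefix lengths
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, sxy, syy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = m * sxx - sx * sx
        slope = np.where(denom > 0, (m * sxy - sx * sy) / denom, 0.0)
        sst = syy - sy * sy / m
        sse = sst - slope * (sxy - sx * sy / m)
        r2 = np.where(sst > 1e-30, 1.0 - sse / np.maximum(sst, 1e-300), 1.0)
    return np.clip(r2, 0.0, 1.0)


def _lsq_line(x: np.ndarray, y: np.ndarray) -> LineFit:
    slope, intercept = np.polyfit(x, y, 1)
    return LineFit(float(slope), float(intercept))


def intersection_rank(curve: RankCurve,
                      tail_fraction: float = 0.05) -> IntersectionResult:
    """Two-line intersection selection of the averaging rank.

    The tail line is fitted to the final ``tail_fraction`` of ranks; the
    head line to the prefix [1..m] maximizing R² with m searched over
    [max(10, 1% of rank), 50% of rank].  The selected rank is the rounded
    rank coordinate of the line intersection, clamped to [1, rank].  When
    the lines are (near-)parallel or intersect outside the curve, the head
    window m is returned instead with a warning.
    """
    n = curve.rank
    if n < 20:
        raise AnalysisError(f"intersection-rank selection needs >= 20 records, got {n}")
    y = curve.energies
    x = np.arange(1, n + 1, dtype=float)

    n_tail = max(2, int(round(tail_fraction * n)))
    tail = _lsq_line(x[-n_tail:], y[-n_tail:])

    m_lo = max(10, int(np.ceil(0.01 * n)))
    m_hi = max(m_lo, n // 2)
    r2 = _prefix_r2(y)
    window = r2[m_lo - 1:m_hi]
    m = int(m_lo + np.argmax(window))
    head = _lsq_line(x[:m], y[:m])

    d_slope = head.slope - tail.slope
    if abs(d_slope) < 1e-12:
        warnings.warn("head and tail fits are parallel; falling back to the "
                      "head window", stacklevel=2)
        return IntersectionResult(m, head, tail, m, fallback=True)
    x_star = (tail.intercept - head.intercept) / d_slope
    if not 1.0 <= x_star <= n:
        warnings.warn(f"line intersection at rank {x_star:.1f} outside [1, {n}]; "
                      "falling back to the head window", stacklevel=2)
        return IntersectionResult(m, head, tail, m, fallback=True)
    return IntersectionResult(int(round(x_star)), head, tail, m)


def average_strongest(curve: RankCurve, selected_rank: int) -> float:
    """Arithmetic mean of the ``selected_rank`` strongest energies: E_s."""
    if not 1 <= selected_rank <= curve.rank:
        raise AnalysisError(f"selected_rank {selected_rank} outside [1, {curve.rank}]")
    return float(curve.energies[:selected_rank].mean())


def component_percentages(records: list[InteractionRecord]) -> dict[str, float]:
    """Percentage contribution of each channel over a record selection:
    100·ΣE_c/ΣE_total.  A channel opposing the total gives a negative
    percentage; the three always sum to 100."""
    if not records:
        raise AnalysisError("component percentages of an empty selection")
    s_disp = sum(r.energy.e_disp for r in records)
    s_hb = sum(r.energy.e_hb for r in records)
    s_coul = sum(r.energy.e_coul for r in records)
    s_tot = s_disp + s_hb + s_coul
    if s_tot == 0.0:
        raise AnalysisError("total energy sums to zero; percentages undefined")
    return {"dispersive": 100.0 * s_disp / s_tot,
            "hb": 100.0 * s_hb / s_tot,
            "coulombic": 100.0 * s_coul / s_tot}


def summarize(result: ScanResult, tail_fraction: float = 0.05,
              percentages_over_selection: bool = True) -> SurfaceInteractionSummary:
    """Full per-(face, probe) analysis: rank curve, intersection rank, E_s
    and component percentages (over the selected strongest records by
    default, over all records otherwise)."""
    curve = rank_records(result)
    inter = intersection_rank(curve, tail_fraction=tail_fraction)
    e_s = average_strongest(curve, inter.selected_rank)
    ordered = sorted(result.records, key=lambda r: r.energy.e_total)
    sel = ordered[:inter.selected_rank] if percentages_over_selection else ordered
    pct = component_percentages(sel)
    return SurfaceInteractionSummary(result.face_id, result.probe_id, e_s,
                                     inter.selected_rank, curve.rank,
                                     inter.head_fit, inter.tail_fit, pct)


def plane_profile(result: ScanResult) -> pd.DataFrame:
    """Per-plane mean of each energy component (the plane-averaged energy
    landscape).  Planes with no recorded interaction are absent."""
    df = result.to_dataframe()
    if df.empty:
        return pd.DataFrame(columns=["e_disp", "e_hb", "e_coul", "e_total"],
                            index=pd.Index([], name="plane"))
    return df.groupby("plane")[["e_disp", "e_hb", "e_coul", "e_total"]].mean()
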
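"""End-to-end orchestration: structure → slab → scan → analysis → model.

Two entry modes:

* ``full`` — crystal and probe structure files in, scans and summaries out,
  then the dissolution model on the computed surface energies;
* ``tables`` — pure arithmetic: printed/curated binding energies, surface
  interaction energies, geometry and experimental rates in, energy
  differentials, modified binding energies, rate ratios and discrepancies
  out.  No force-field code executes in tables mode, so model validation
  never depends on force-field reproduction.

Every run emits CSV/JSON artifacts plus a manifest (input checksums,
package version, effective configuration) sufficient to re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dissolution import DissolutionPrediction, FaceModelInput, predict_dissolution
from .errors import ConfigError
from .forcefield import ForceFieldParams, assign_default_ff_types
from .gridscan import DEFAULT_CUTOFF, GridSpec, scan_surface
from .rankstats import plane_profile, summarize
from .slab import build_slab, surface_rugosity
from .structures import parse_crystal, read_xyz

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (see the packaged examples in the docs)."""

    mode: str = "tables"                     # "tables" | "full"
    solute: str = ""
    solvent: str = ""
    molar_masses: dict[str, float] = field(default_factory=dict)
    faces: list[dict] = field(default_factory=list)
    ratio_pairs: list[tuple[str, str]] | None = None
    crystal: str | None = None               # path to CIF (full mode)
    probes: dict[str, str] = field(default_factory=dict)  # name -> structure path
    grid: GridSpec = field(default_factory=GridSpec)
    cutoff: float = DEFAULT_CUTOFF
    probe_cutoffs: dict[str, float] = field(default_factory=dict)
    repeat: tuple[int, int, int] = (3, 3, 2)
    termination_offset: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.grid, dict):
            self.grid = GridSpec(**self.grid)
        self.repeat = tuple(self.repeat)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        grid = GridSpec(**raw.pop("grid", {}))
        pairs = raw.pop("ratio_pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        repeat = tuple(raw.pop("repeat", (3, 3, 2)))
        cfg = cls(grid=grid, ratio_pairs=pairs, repeat=repeat, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("tables", "full"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.solute or not self.solvent:
            raise ConfigError("config must name solute and solvent probes")
        for name in (self.solute, self.solvent):
            if name not in self.molar_masses:
                raise ConfigError(f"molar mass missing for {name!r}")
        if not self.faces:
            raise ConfigError("config lists no faces")
        if self.mode == "full":
            if not self.crystal:
                raise ConfigError("full mode requires a crystal path")
            for name, path in {**{"crystal": self.crystal}, **self.probes}.items():
                if not Path(path).exists():
                    raise ConfigError(f"referenced file for {name!r} not found: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path,
                 params: ForceFieldParams | None = None) -> DissolutionPrediction:
    """Execute the configured workflow and write the report bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "facetsolv", "version": __version__,
                      "mode": config.mode, "inputs": {},
                      "config": _config_dict(config)}

    if config.mode == "full":
        prediction = _run_full(config, out, params or ForceFieldParams.default(),
                               manifest)
    else:
        prediction = _run_tables(config)

    prediction.faces.to_csv(out / "faces.csv")
    prediction.ratios.to_csv(out / "ratios.csv")
    report = {
        "faces": prediction.faces.reset_index().to_dict(orient="records"),
        "ratios": prediction.ratios.reset_index().to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return prediction


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["grid"] = dataclasses.asdict(config.grid)
    return d


def _face_inputs(config: RunConfig) -> list[FaceModelInput]:
    inputs = []
    for raw in config.faces:
        geom = raw.get("geometry", {})
        inputs.append(FaceModelInput(
            face_id=str(raw["face"]),
            e_b=float(raw["e_b"]),
            e_s={k: float(v) for k, v in raw.get("e_s", {}).items()},
            v_cell=geom.get("v_cell"), s_hkl=geom.get("s_hkl"),
            rugosity=geom.get("rugosity"),
            e_b_mod=raw.get("e_b_mod"),
            experimental_rate=raw.get("experimental_rate")))
    return inputs


def _run_tables(config: RunConfig) -> DissolutionPrediction:
    """Pure arithmetic from curated energies; no force-field code runs."""
    return predict_dissolution(_face_inputs(config), config.solute,
                               config.solvent, config.molar_masses,
                               config.ratio_pairs)


def _run_full(config: RunConfig, out: Path, params: ForceFieldParams,
              manifest: dict) -> DissolutionPrediction:
    crystal_path = Path(config.crystal)
    manifest["inputs"][str(crystal_path)] = _sha256(crystal_path)
    crystal = parse_crystal(crystal_path.read_text(), name=crystal_path.stem)

    probes = {}
    for name, path in config.probes.items():
        p = Path(path)
        manifest["inputs"][str(p)] = _sha256(p)
        if p.suffix.lower() == ".xyz":
            probes[name] = read_xyz(p.read_text(), label=name)
        else:
            mol = parse_crystal(p.read_text(), name=name).full_cell[0]
            mol.label = name
            probes[name] = mol
        assign_default_ff_types(probes[name])

    face_inputs = []
    for raw in config.faces:
        hkl = tuple(raw["miller"])
        slab = build_slab(crystal, hkl, repeat=config.repeat,
                          termination_offset=config.termination_offset)
        rug = surface_rugosity(slab, override=raw.get("geometry", {}).get("rugosity"))
        e_s = {k: float(v) for k, v in raw.get("e_s", {}).items()}
        for pname, probe in probes.items():
            if pname in e_s:
                continue  # curated override wins
            cutoff = config.probe_cutoffs.get(pname, config.cutoff)
            result = scan_surface(slab, probe, params, config.grid, cutoff=cutoff)
            tag = f"{''.join(map(str, hkl))}_{pname}"
            result.to_dataframe().to_csv(out / f"scan_{tag}.csv", index=False)
            (out / f"scan_{tag}.json").write_text(result.header_json())
            if result.records:
                if result.interaction_rank >= 20:
                    summary = summarize(result)
                    e_s[pname] = summary.e_s
                    (out / f"summary_{tag}.json").write_text(
                        json.dumps(summary.to_dict(), indent=2))
                else:
                    # too few records for the two-line selection: average all
                    e_s[pname] = float(np.mean(
                        [r.energy.e_total for r in result.records]))
                    logger.info("rank %d < 20 for %s on %s; E_s is the plain "
                                "mean of all records",
                                result.interaction_rank, pname, hkl)
                plane_profile(result).to_csv(out / f"planes_{tag}.csv")
            else:
                logger.warning("no interactions below cutoff for %s on %s",
                               pname, hkl)
        face_inputs.append(FaceModelInput(
            face_id=str(raw.get("face", hkl)),
            e_b=float(raw["e_b"]),
            e_s=e_s,
            v_cell=crystal.cell.volume,
            s_hkl=crystal.face(hkl).s_hkl,
            rugosity=rug,
            e_b_mod=raw.get("e_b_mod"),
            experimental_rate=raw.get("experimental_rate")))
    return predict_dissolution(face_inputs, config.solute, config.solvent,
                               config.molar_masses, config.ratio_pairs)
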
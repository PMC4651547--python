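"""End-to-end orchestration: structure → parameterize → surface → scan
→ minima → observables → reports.

A single validated config (YAML mapping or :class:`PipelineConfig`)
drives every stage; one top-level seed feeds the per-stage generators
through fixed offsets so each stage is independently reproducible, and
identical config + seed produces byte-identical outputs (no timestamps
in any report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import geometry, structure_io, synthetic
from .model import MolecularModel
from .scan import (
    EnergyLandscape,
    FieldSpec,
    Pose,
    ScanConfig,
    field_rerank,
    interaction_energy,
    place_above,
    rotate_model,
    scan_orientations,
    select_minima,
)
from .surface import SurfaceModel, SurfaceSpec, build_sam_surface

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]

_STRUCTURE_KEYS = {
    "path", "format", "synthetic", "parameterize", "charged_termini",
    "cofactor_charges", "cterm_sequence", "cterm_anchor",
}
_SURFACE_KEYS = {
    "nx", "ny", "thiol_spacing", "protonation_fraction",
    "headgroup_charge_protonated", "seed", "gold_layers",
}
_SCAN_KEYS = {
    "theta_step", "psi_step", "gap", "dielectric", "cutoff",
    "k_minima", "basin_separation",
}
_FIELD_KEYS = {"field_z", "pzc", "applied_potential", "weight"}
_TOP_KEYS = {"structure", "surface", "scan", "field", "outputs", "seed", "log_level"}
_OUTPUT_KEYS = {"directory", "formats"}
_SYNTH_KEYS = {"kind", "n_atoms", "radius", "cap_half_angle", "cap_charge",
               "q", "separation", "net_charge", "seed"}


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :func:`load_config`)."""

    structure: dict
    surface: SurfaceSpec
    scan: ScanConfig
    field: Optional[FieldSpec]
    output_dir: Path
    seed: int
    log_level: str
    raw: dict

    def checksum(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(source) -> PipelineConfig:
    """Parse and validate a pipeline config from a YAML file path or an
    already-parsed mapping. Unknown keys are rejected outright."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    _check_keys(data, _TOP_KEYS, "top level")

    structure = dict(data.get("structure") or {})
    _check_keys(structure, _STRUCTURE_KEYS, "structure:")
    if "synthetic" in structure:
        _check_keys(structure["synthetic"], _SYNTH_KEYS, "structure.synthetic:")
    if "path" not in structure and "synthetic" not in structure:
        raise ValueError("structure: needs either 'path' or 'synthetic'")

    seed = int(data.get("seed", 1))

    surf_raw = dict(data.get("surface") or {})
    _check_keys(surf_raw, _SURFACE_KEYS, "surface:")
    surf_raw.setdefault("seed", seed)
    surface = SurfaceSpec(**surf_raw)
    surface.validate()

    scan_raw = dict(data.get("scan") or {})
    _check_keys(scan_raw, _SCAN_KEYS, "scan:")
    if scan_raw.get("cutoff") in ("inf", "infinite", None):
        scan_raw.pop("cutoff", None)
    scan_cfg = ScanConfig(**scan_raw)
    scan_cfg.validate()

    field = None
    if data.get("field"):
        _check_keys(data["field"], _FIELD_KEYS, "field:")
        field = FieldSpec(**data["field"])
        field.validate()

    outputs = dict(data.get("outputs") or {})
    _check_keys(outputs, _OUTPUT_KEYS, "outputs:")
    out_dir = Path(outputs.get("directory", "samscan_out"))

    return PipelineConfig(
        structure=structure,
        surface=surface,
        scan=scan_cfg,
        field=field,
        output_dir=out_dir,
        seed=seed,
        log_level=str(data.get("log_level", "INFO")),
        raw=data,
    )


@dataclasses.dataclass
class RunReport:
    """Summary of one pipeline run: landscape statistics, the selected
    poses with their observables, warnings, and provenance."""

    landscape_summary: dict
    poses: list[dict]
    warnings: list[str]
    provenance: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=1, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def _build_structure(cfg: PipelineConfig) -> MolecularModel:
    sc = cfg.structure
    if "synthetic" in sc:
        syn = dict(sc["synthetic"])
        kind = syn.pop("kind")
        syn.setdefault("seed", cfg.seed + 1)
        if kind == "patchy_sphere":
            return synthetic.make_patchy_sphere(**syn)
        if kind == "dumbbell":
            syn.pop("seed", None)
            return synthetic.make_dumbbell(**syn)
        if kind == "random_blob":
            return synthetic.make_random_blob(**syn)
        raise ValueError(f"unknown synthetic structure kind {kind!r}")
    model = structure_io.read_structure(sc["path"], sc.get("format"))
    if sc.get("cterm_sequence"):
        anchor = sc.get("cterm_anchor")
        anchor = tuple(anchor) if isinstance(anchor, (list, tuple)) else anchor
        model = structure_io.append_cterm_helix(model, sc["cterm_sequence"], anchor)
    if sc.get("parameterize", True):
        model = structure_io.parameterize(
            model,
            charged_termini=sc.get("charged_termini", True),
            cofactor_charges=sc.get("cofactor_charges"),
        )
    return model


def _pose_observables(
    pose: Pose,
    protein: MolecularModel,
    surface: SurfaceModel,
    scan_cfg: ScanConfig,
) -> tuple[dict, MolecularModel]:
    posed = place_above(
        rotate_model(protein, pose.theta, pose.psi), surface, scan_cfg.gap
    )
    pose.translation = posed.center_of_geometry() - protein.center_of_geometry()
    dip = geometry.dipole_moment(posed)
    obs = {
        "dipole_debye": dip.magnitude,
        "dipole_angle_to_normal_deg": dip.angle_to_normal,
    }
    for label, key in (
        ("cofactor:NiFe", "nife_sam_distance_A"),
        ("cofactor:FeS", "fes_sam_distance_A"),
        ("cap", "cap_sam_distance_A"),
    ):
        if len(posed.select(label)):
            obs[key] = geometry.surface_distance(posed, label, surface, "sam_top")
    pose.observables = obs
    return obs, posed


def run_pipeline(config) -> RunReport:
    """Execute the full analysis described by *config* (path, mapping,
    or :class:`PipelineConfig`); writes the landscape (CSV + JSON), the
    selected poses (multi-MODEL PDB) and the run report (JSON) into the
    configured output directory, and returns the report."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    warnings: list[str] = []

    try:
        protein = _build_structure(cfg)
    except Exception as exc:
        raise RuntimeError(f"structure stage failed: {exc}") from exc
    report_param = getattr(protein, "param_report", None)
    if report_param and report_param["n_defaulted"]:
        warnings.append(
            f"{report_param['n_defaulted']} atoms parameterized from the "
            f"default entry"
        )
    if report_param and report_param["untreated_cofactors"]:
        warnings.append(
            "cofactors without charges: "
            + ", ".join(report_param["untreated_cofactors"])
        )

    try:
        surface = build_sam_surface(cfg.surface)
    except Exception as exc:
        raise RuntimeError(f"surface stage failed: {exc}") from exc

    span = np.ptp(protein.positions[:, :2], axis=0)
    if span[0] > surface.extent_x or span[1] > surface.extent_y:
        warnings.append("protein footprint overhangs the slab")

    try:
        landscape = scan_orientations(protein, surface, cfg.scan)
    except Exception as exc:
        raise RuntimeError(f"scan stage failed: {exc}") from exc

    if cfg.field is not None and cfg.field.weight > 0:
        dipoles = np.empty((len(landscape.theta_values),
                            len(landscape.psi_values), 3))
        for i, th in enumerate(landscape.theta_values):
            for j, ps in enumerate(landscape.psi_values):
                posed = place_above(
                    rotate_model(protein, th, ps), surface, cfg.scan.gap
                )
                dipoles[i, j] = geometry.dipole_moment(posed).vector
        landscape = field_rerank(landscape, dipoles, cfg.field)

    poses = select_minima(landscape, cfg.scan.k_minima, cfg.scan.basin_separation)
    if len(poses) < cfg.scan.k_minima:
        warnings.append("grid could not honor the requested basin separation")

    pose_rows = []
    posed_models = []
    for pose in poses:
        obs, posed = _pose_observables(pose, protein, surface, cfg.scan)
        posed_models.append(posed)
        pose_rows.append(
            {"theta_deg": pose.theta, "psi_deg": pose.psi,
             "energy_kcal_mol": pose.energy, **obs}
        )

    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    landscape.to_csv(cfg.output_dir / "landscape.csv")
    landscape.to_json(cfg.output_dir / "landscape.json")
    structure_io.write_structure(posed_models, cfg.output_dir / "poses.pdb", "PDB")

    report = RunReport(
        landscape_summary={
            "min_kcal_mol": float(landscape.energies.min()),
            "max_kcal_mol": float(landscape.energies.max()),
            "mean_kcal_mol": float(landscape.energies.mean()),
            "n_orientations": int(landscape.energies.size),
            "argmin": list(landscape.argmin()),
        },
        poses=pose_rows,
        warnings=warnings,
        provenance={
            "config_checksum": cfg.checksum(),
            "seed": cfg.seed,
            "surface_net_charge_e": surface.net_charge,
            "n_protonated_chains": int(len(surface.protonated_indices)),
            "n_chains": surface.n_chains,
            "protein_atoms": len(protein),
            "protein_net_charge_e": protein.net_charge,
            "config": cfg.raw,
        },
    )
    report.to_json(cfg.output_dir / "report.json")
    return report
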
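"""Scenario configuration and pipeline orchestration.

A single structured (YAML) configuration describes one study: the synthetic
capsule geometry, the regional material table, the load case (rotation
target in degrees, synovial pressure in kPa), the lesion subtypes, and the
analysis parameters.  ``run_pipeline`` solves the healthy capsule plus the
requested lesion scenarios, compares the strain fields region by region,
and (optionally) writes VTK results, a delimited report, and a run manifest
with a configuration hash so that runs are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ComparisonResult, compare_scenarios, region_strains
from .geometry import (
    CapsuleMesh,
    GeometryParams,
    external_rotation_axis,
    generate_capsule,
)
from .lesion import SUBTYPE_SECTORS, LesionSpec, apply_lesion
from .materials import region_materials
from .solver import (
    LoadCase,
    SolveState,
    Sphere,
    StrainField,
    default_schedule,
    solve_static,
    strain_field,
    total_strain_energy,
)
from .vtkio import write_field, write_mesh

__all__ = ["ScenarioConfig", "PipelineResult", "run_pipeline"]

_LESION_SUBTYPES = ("anterior", "posterior", "combined")


@dataclass
class ScenarioConfig:
    """Fully serializable description of one comparison study."""

    geometry: dict = field(default_factory=dict)
    material_table: dict | None = None  # None -> bundled regional constants
    rotation_target_deg: float = 30.0
    n_steps: int = 10
    pressure_kpa: float = 0.7
    contact_enabled: bool = False
    head_center: tuple = (0.0, 0.0, 10.0)
    head_radius: float = 20.0
    contact_stiffness: float = 10.0
    lesions: tuple = _LESION_SUBTYPES
    n_samples: int = 25
    seed: int = 0
    exclusion_hops: int = 2
    exclude_lesion_zone: bool = True
    solver_tol_rel: float = 1e-6

    def __post_init__(self) -> None:
        unknown = [s for s in self.lesions if s not in SUBTYPE_SECTORS or s == "none"]
        if unknown:
            raise ValueError(f"unknown lesion subtypes: {unknown}")
        self.lesions = tuple(self.lesions)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesions"] = list(self.lesions)
        d["head_center"] = list(self.head_center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    # -- derived model objects --------------------------------------------

    def geometry_params(self) -> GeometryParams:
        return GeometryParams(**self.geometry)

    def build_mesh(self) -> CapsuleMesh:
        return generate_capsule(self.geometry_params(), self.materials())

    def materials(self):
        return region_materials(self.material_table)

    def load_case(self) -> LoadCase:
        axis, center = external_rotation_axis(self.geometry_params())
        head = Sphere(self.head_center, self.head_radius) if self.contact_enabled else None
        return LoadCase(
            rotation_schedule=default_schedule(self.rotation_target_deg, self.n_steps),
            rotation_axis=axis,
            rotation_center=center,
            internal_pressure=self.pressure_kpa * 1e-3,  # kPa -> MPa
            humeral_head=head,
            contact_stiffness=self.contact_stiffness,
        )


@dataclass
class PipelineResult:
    mesh: CapsuleMesh
    states: dict[str, list[SolveState]]
    fields: dict[str, list[StrainField]]
    strain_energy: dict[str, float]
    comparisons: dict[str, list[ComparisonResult]]
    report: pd.DataFrame
    manifest: dict


def run_pipeline(config: ScenarioConfig, output_dir=None) -> PipelineResult:
    """Solve healthy + lesion scenarios and compare their strain fields.

    Scenario order and all sampling are deterministic for a fixed
    configuration.  When ``output_dir`` is given, writes ``mesh.vtk``, a
    final-step ``<scenario>.vtk`` per scenario, ``report.csv`` and
    ``manifest.json`` there (created if needed); partial outputs from
    earlier stages are preserved if a later stage fails.
    """
    mesh = config.build_mesh()
    materials = config.materials()
    base_case = config.load_case()
    handedness = config.geometry_params().handedness

    out = None
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mesh(out / "mesh.vtk", mesh)

    scenarios = ["healthy"] + list(config.lesions)
    states: dict[str, list[SolveState]] = {}
    fields: dict[str, list[StrainField]] = {}
    energy: dict[str, float] = {}
    released: dict[str, np.ndarray] = {}
    for name in scenarios:
        spec = LesionSpec("none" if name == "healthy" else name)
        case = apply_lesion(base_case, mesh, spec, handedness=handedness)
        released[name] = case.released_nodes
        try:
            st = solve_static(mesh, materials, case, tol_rel=config.solver_tol_rel)
        except Exception as exc:
            raise RuntimeError(f"solve stage failed for scenario {name!r}: {exc}") from exc
        states[name] = st
        fields[name] = [strain_field(mesh, s.displacements) for s in st]
        energy[name] = total_strain_energy(mesh, materials, st[-1].displacements)
        if out is not None:
            write_field(out / f"{name}.vtk", mesh, st[-1].displacements, fields[name][-1])

    comparisons: dict[str, list[ComparisonResult]] = {}
    report_rows = []
    for name in config.lesions:
        results, df = compare_scenarios(
            fields["healthy"],
            fields[name],
            mesh,
            n=config.n_samples,
            seed=config.seed,
            released_nodes=released[name] if config.exclude_lesion_zone else None,
            exclusion_hops=config.exclusion_hops,
        )
        comparisons[name] = results
        df.insert(0, "scenario", name)
        report_rows.append(df)
    report = (
        pd.concat(report_rows, ignore_index=True) if report_rows else pd.DataFrame()
    )

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "capsfem_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
        "scenarios": scenarios,
        "newton_iterations": {
            k: [s.n_iterations for s in v] for k, v in states.items()
        },
        "final_residuals": {k: v[-1].residual_norm for k, v in states.items()},
        "strain_energy_30deg": energy,
    }
    if out is not None:
        report.to_csv(out / "report.csv", index=False, float_format="%.10g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        mesh=mesh,
        states=states,
        fields=fields,
        strain_energy=energy,
        comparisons=comparisons,
        report=report,
        manifest=manifest,
    )
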
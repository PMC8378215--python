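"""Run configuration, deterministic tabular output and VTK field export.

Configurations use the catalogue units of the problem domain (mm, kPa,
uL/s); the library converts to SI at the boundary.  Every run can emit a
"resolved config" block (all defaults made explicit, plus seed and
package version) so that identical provenance implies identical output
for the deterministic solvers.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import units
from .core import DriveCondition, Material, NozzleGeometry, builtin_material
from .errors import ConfigError

__all__ = [
    "RunConfig",
    "MaterialConfig",
    "GeometryConfig",
    "DriveConfig",
    "CampaignConfig",
    "load_config",
    "write_summary",
    "summary_row",
    "SUMMARY_COLUMNS",
    "write_vtk",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Strict):
    name: str = "Alginate"
    density_kg_m3: Optional[float] = None
    consistency_pa_sn: Optional[float] = None
    power_law_index: Optional[float] = None

    def build(self) -> Material:
        custom = (self.density_kg_m3, self.consistency_pa_sn,
                  self.power_law_index)
        if all(v is None for v in custom):
            return builtin_material(self.name)
        if any(v is None for v in custom):
            raise ConfigError(
                "custom material needs density_kg_m3, consistency_pa_sn "
                "and power_law_index together"
            )
        return Material(self.name, self.density_kg_m3,
                        self.consistency_pa_sn, self.power_law_index)


class GeometryConfig(_Strict):
    shape: Literal["blunted", "conical"] = "blunted"
    r_small_mm: float = 0.2
    r_middle_mm: Optional[float] = None
    r_big_mm: float = 3.5
    l_lower_mm: float = 6.0
    l_upper_mm: float = 4.0

    def build(self) -> NozzleGeometry:
        return NozzleGeometry.from_mm(
            self.shape,
            r_small=self.r_small_mm,
            r_big=self.r_big_mm,
            l_lower=self.l_lower_mm,
            l_upper=self.l_upper_mm,
            r_middle=self.r_middle_mm,
        ).validate()


class DriveConfig(_Strict):
    mode: Literal["pressure", "flowrate"] = "pressure"
    delta_p_kpa: Optional[float] = None
    q_ul_s: Optional[float] = None

    @model_validator(mode="after")
    def _one_of(self):
        if self.mode == "pressure" and self.q_ul_s is not None:
            raise ValueError("pressure mode must not set q_ul_s")
        if self.mode == "flowrate" and self.delta_p_kpa is not None:
            raise ValueError("flowrate mode must not set delta_p_kpa")
        return self

    def build(self, mat: Material) -> DriveCondition:
        if self.mode == "pressure":
            dp = self.delta_p_kpa
            if dp is None:
                if mat.default_pressure is None:
                    raise ConfigError("no pressure given and material has "
                                      "no default")
                return DriveCondition.pressure(mat.default_pressure)
            return DriveCondition.pressure_kpa(dp)
        if self.q_ul_s is None:
            raise ConfigError("flowrate mode requires q_ul_s")
        return DriveCondition.flowrate_ul_s(self.q_ul_s)


class NumericsConfig(_Strict):
    solver: Literal["reduced", "fvm"] = "reduced"
    n_stations: int = 400
    dr_fine_mm: float = 0.005
    dz_fine_mm: float = 0.010
    tol: float = 1e-5
    max_outer: int = 120
    gamma_dot_min: float = 1e-3


class CampaignConfig(_Strict):
    n_designs: int = 200
    seed: int = 0
    shape: Literal["blunted", "conical"] = "blunted"
    ranges_mm: Optional[dict] = None


class RunConfig(_Strict):
    material: MaterialConfig = MaterialConfig()
    geometry: GeometryConfig = GeometryConfig()
    drive: DriveConfig = DriveConfig()
    numerics: NumericsConfig = NumericsConfig()
    campaign: CampaignConfig = CampaignConfig()
    output_dir: str = "."

    def resolved(self) -> dict:
        from . import __version__

        return {
            "version": __version__,
            "config": self.model_dump(),
        }


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON config; unknown keys are rejected."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


# ----------------------------------------------------------------------
# tabular output
# ----------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "case",
    "solver",
    "mss_kpa",
    "q_ul_s",
    "v_exit_m_s",
    "nu_exit_m2_s",
    "delta_p_kpa",
]


def summary_row(case: str, fs) -> dict:
    """Flatten a FlowSummary into the fixed summary-column convention."""
    return {
        "case": case,
        "solver": fs.solver,
        "mss_kpa": units.pa_to_kpa(fs.mss),
        "q_ul_s": units.m3_s_to_ul_s(fs.q),
        "v_exit_m_s": fs.v_exit_mean,
        "nu_exit_m2_s": fs.nu_exit,
        "delta_p_kpa": units.pa_to_kpa(fs.delta_p),
    }


def write_summary(rows, path) -> None:
    """CSV with fixed column order and 9-significant-digit floats.

    Deterministic formatting keeps diffs meaningful; an empty row list
    produces a header-only file.
    """
    df = pd.DataFrame(list(rows))
    if len(df) == 0:
        df = pd.DataFrame(columns=SUMMARY_COLUMNS)
    else:
        missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"rows missing summary columns: {missing}")
        extra = [c for c in df.columns if c not in SUMMARY_COLUMNS]
        df = df[SUMMARY_COLUMNS + sorted(extra)]
    df.to_csv(path, index=False, float_format="%.9g")


# ----------------------------------------------------------------------
# VTK export
# ----------------------------------------------------------------------

def write_vtk(field, path) -> None:
    """Export a 2D axisymmetric field as a legacy-ASCII VTK structured
    grid (r-z plane; cell-centered fields written as point data at cell
    centers)."""
    mesh = field.mesh
    Nr, Nz = mesh.Nr, mesh.Nz
    w_c = 0.5 * (field.w[:, :-1] + field.w[:, 1:])
    v_c = 0.5 * (field.v[:-1, :] + field.v[1:, :])
    fluid = mesh.fluid.astype(float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("nozzleflow axisymmetric field (r-z plane)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {Nz} {Nr} 1\n")
        fh.write(f"POINTS {Nr * Nz} float\n")
        for i in range(Nr):
            for j in range(Nz):
                fh.write(f"{mesh.zc[j]:.9g} {mesh.rc[i]:.9g} 0\n")
        fh.write(f"POINT_DATA {Nr * Nz}\n")
        scalars = {
            "pressure": field.p,
            "shear_rate": field.gamma_dot,
            "viscosity": field.eta,
            "shear_stress": field.tau,
            "fluid_mask": fluid,
        }
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(Nr * Nz, 1), fmt="%.9g")
        fh.write("VECTORS velocity float\n")
        vec = np.zeros((Nr * Nz, 3))
        vec[:, 0] = w_c.reshape(-1)
        vec[:, 1] = v_c.reshape(-1)
        np.savetxt(fh, vec, fmt="%.9g")
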
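"""Domain types: materials, nozzle geometry, drive conditions, flow summaries.

The rheological model throughout the package is the Ostwald-de Waele power
law,

    eta(gamma_dot) = K * gamma_dot**(n - 1),      tau = eta * gamma_dot,

with consistency coefficient ``K`` (Pa*s^n) and flow-behaviour index ``n``
(n = 1 Newtonian, n < 1 shear-thinning).  Nozzles come in two shapes: a
*blunted* (cylindrical) nozzle — a wide barrel with an abrupt 90-degree
contraction into a thin straight tube — and a *conical* (tapered) nozzle
whose lower section converges linearly from an intermediate radius
``R_middle`` down to the exit radius ``R_small``.

All quantities are SI internally; the ``from_mm``-style constructors accept
the mm/kPa/uL-per-s conventions used in supplier catalogues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import units
from .errors import (
    DriveError,
    GeometryConstraintError,
    GeometryError,
    UnknownMaterialError,
)

__all__ = [
    "Material",
    "NozzleGeometry",
    "DriveCondition",
    "FlowSummary",
    "builtin_material",
    "material_names",
    "radius_profile",
    "validate_geometry",
    "generalized_reynolds",
]


@dataclass(frozen=True)
class Material:
    """Power-law hydrogel.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Alginate"``.
    density : float
        Mass density rho, kg/m^3.
    consistency : float
        Consistency coefficient K, Pa*s^n.
    power_law_index : float
        Flow-behaviour index n (dimensionless); 0 < n <= 1.2.
    default_pressure : float, optional
        Typical printing pressure difference for this ink, Pa.
    """

    name: str
    density: float
    consistency: float
    power_law_index: float
    default_pressure: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not self.consistency > 0:
            raise ValueError(f"consistency K must be > 0, got {self.consistency}")
        if not 0 < self.power_law_index <= 1.2:
            raise ValueError(
                f"power-law index n must lie in (0, 1.2], got {self.power_law_index}"
            )

    def viscosity(self, gamma_dot):
        """Apparent viscosity eta = K * gamma_dot**(n-1), Pa*s."""
        return self.consistency * np.asarray(gamma_dot, dtype=float) ** (
            self.power_law_index - 1.0
        )

    def shear_stress(self, gamma_dot):
        """Shear stress tau = K * gamma_dot**n, Pa."""
        return self.consistency * np.asarray(gamma_dot, dtype=float) ** self.power_law_index


# Built-in hydrogel library: (density kg/m^3, K Pa*s^n, n, default pressure Pa).
_MATERIALS = {
    "PF127": (1000.0, 406.0, 0.127, units.kpa_to_pa(200.0)),
    "Alginate": (1000.0, 55.7, 0.335, units.kpa_to_pa(340.0)),
    "AlgGel": (1000.0, 13.3, 0.608, units.kpa_to_pa(80.0)),
}


def material_names() -> list[str]:
    return list(_MATERIALS)


def builtin_material(name: str) -> Material:
    """Look up a built-in hydrogel by name.

    Returns a :class:`Material` whose ``default_pressure`` carries the
    material's customary printing pressure (Pa).
    """
    try:
        rho, K, n, p = _MATERIALS[name]
    except KeyError:
        raise UnknownMaterialError(
            f"unknown material {name!r}; valid names: {sorted(_MATERIALS)}"
        ) from None
    return Material(name, rho, K, n, default_pressure=p)


@dataclass(frozen=True)
class NozzleGeometry:
    """Print-nozzle geometry (SI units, metres).

    ``shape`` is ``"blunted"`` or ``"conical"``.  The axial coordinate z runs
    from the inlet (z=0) to the outlet (z = l_upper + l_lower).  The blunted
    nozzle is a barrel of radius ``r_big`` over ``l_upper`` with an abrupt
    contraction to a straight tube of radius ``r_small`` over ``l_lower``.
    The conical nozzle tapers linearly r_big -> r_middle over the upper
    section, then r_middle -> r_small over the lower section.
    """

    shape: str
    r_small: float
    r_big: float
    l_lower: float
    l_upper: float
    r_middle: Optional[float] = None

    @classmethod
    def blunted(cls, r_small: float, r_big: float, l_lower: float, l_upper: float):
        return cls("blunted", r_small, r_big, l_lower, l_upper)

    @classmethod
    def conical(
        cls,
        r_small: float,
        r_middle: float,
        r_big: float,
        l_lower: float,
        l_upper: float,
    ):
        return cls("conical", r_small, r_big, l_lower, l_upper, r_middle)

    @classmethod
    def from_mm(
        cls,
        shape: str,
        r_small: float,
        r_big: float,
        l_lower: float,
        l_upper: float,
        r_middle: Optional[float] = None,
    ):
        """Construct from catalogue units (mm)."""
        return cls(
            shape,
            units.mm_to_m(r_small),
            units.mm_to_m(r_big),
            units.mm_to_m(l_lower),
            units.mm_to_m(l_upper),
            None if r_middle is None else units.mm_to_m(r_middle),
        )

    @property
    def length(self) -> float:
        return self.l_lower + self.l_upper

    def radius(self, z):
        return radius_profile(self, z)

    def validate(self) -> "NozzleGeometry":
        return validate_geometry(self)


def validate_geometry(geom: NozzleGeometry) -> NozzleGeometry:
    """Validate a geometry, returning it unchanged, or raise.

    Blunted nozzles require 0 < r_small < r_big; conical nozzles require the
    full ordering r_small < r_middle < r_big — designs with the entrance
    radius at or below the intermediate radius are rejected (the same
    exclusion applied when generating designs-of-experiments).
    """
    if geom.shape not in ("blunted", "conical"):
        raise GeometryError(f"unknown nozzle shape {geom.shape!r}")
    dims = {
        "r_small": geom.r_small,
        "r_big": geom.r_big,
        "l_lower": geom.l_lower,
        "l_upper": geom.l_upper,
    }
    if geom.shape == "conical":
        if geom.r_middle is None:
            raise GeometryError("conical geometry requires r_middle")
        dims["r_middle"] = geom.r_middle
    for k, v in dims.items():
        if not (np.isfinite(v) and v > 0):
            raise GeometryError(f"{k} must be finite and > 0, got {v}")
    if geom.shape == "blunted":
        if not geom.r_small < geom.r_big:
            raise GeometryConstraintError(
                f"blunted nozzle requires r_small < r_big "
                f"(got {geom.r_small} >= {geom.r_big})"
            )
        if geom.r_middle is not None:
            raise GeometryError("blunted geometry must not set r_middle")
    else:
        if not geom.r_small < geom.r_middle:
            raise GeometryConstraintError(
                f"conical nozzle requires r_small < r_middle "
                f"(got {geom.r_small} >= {geom.r_middle})"
            )
        if not geom.r_middle < geom.r_big:
            raise GeometryConstraintError(
                f"conical nozzle requires r_middle < r_big "
                f"(got {geom.r_middle} >= {geom.r_big})"
            )
    return geom


def radius_profile(geom: NozzleGeometry, z):
    """Wall radius R(z), z from inlet (0) to outlet (l_upper + l_lower).

    Blunted: R_big for z < l_upper, R_small from the contraction on (an
    abrupt step).  Conical: linear taper R_big -> R_middle over the upper
    section, then R_middle -> R_small over the lower section (continuous).
    """
    z = np.asarray(z, dtype=float)
    L = geom.length
    if np.any(z < -1e-15) or np.any(z > L * (1 + 1e-12)):
        raise GeometryError(f"z outside [0, {L}]")
    zc = np.clip(z, 0.0, L)
    if geom.shape == "blunted":
        out = np.where(zc < geom.l_upper, geom.r_big, geom.r_small)
    else:
        upper = geom.r_big + (geom.r_middle - geom.r_big) * np.minimum(
            zc / geom.l_upper, 1.0
        )
        frac = np.clip((zc - geom.l_upper) / geom.l_lower, 0.0, 1.0)
        lower = geom.r_middle + (geom.r_small - geom.r_middle) * frac
        out = np.where(zc < geom.l_upper, upper, lower)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DriveCondition:
    """Extrusion drive: constant pressure difference or constant flow rate.

    Exactly one of ``delta_p`` (Pa, inlet-to-outlet static pressure
    difference) or ``q_in`` (m^3/s, volumetric flow) is set.
    """

    mode: str
    delta_p: Optional[float] = None
    q_in: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode == "pressure":
            if self.delta_p is None or self.q_in is not None:
                raise DriveError("pressure mode requires delta_p only")
            if not self.delta_p > 0:
                raise DriveError(f"delta_p must be > 0, got {self.delta_p}")
        elif self.mode == "flowrate":
            if self.q_in is None or self.delta_p is not None:
                raise DriveError("flowrate mode requires q_in only")
            if not self.q_in > 0:
                raise DriveError(f"q_in must be > 0, got {self.q_in}")
        else:
            raise DriveError(f"unknown drive mode {self.mode!r}")

    @classmethod
    def pressure(cls, delta_p: float) -> "DriveCondition":
        return cls("pressure", delta_p=delta_p)

    @classmethod
    def pressure_kpa(cls, delta_p_kpa: float) -> "DriveCondition":
        return cls("pressure", delta_p=units.kpa_to_pa(delta_p_kpa))

    @classmethod
    def flowrate(cls, q: float) -> "DriveCondition":
        return cls("flowrate", q_in=q)

    @classmethod
    def flowrate_ul_s(cls, q_ul_s: float) -> "DriveCondition":
        return cls("flowrate", q_in=units.ul_s_to_m3_s(q_ul_s))


@dataclass
class FlowSummary:
    """Scalar outcome of one nozzle flow solution (SI units).

    Attributes
    ----------
    mss : float
        Maximum shear stress tau = eta*gamma_dot anywhere in the domain, Pa.
    q : float
        Volumetric flow rate, m^3/s.
    v_exit_mean : float
        Mean exit velocity Q / (pi R_small^2), m/s.
    nu_exit : float
        Representative kinematic viscosity at the outlet plane, m^2/s
        (apparent viscosity at the area-averaged outlet shear rate / rho).
    delta_p : float
        Applied (pressure drive) or required (flow drive) pressure
        difference, Pa.
    tau_wall : ndarray, shape (m, 2)
        Wall shear profile: columns (z, tau_w(z)).
    mss_location : tuple
        (z, r) of the maximum shear stress.
    solver : str
        Producing solver tag ("reduced" or "fvm").
    diagnostics : dict
        Solver-specific convergence metadata.
    """

    mss: float
    q: float
    v_exit_mean: float
    nu_exit: float
    delta_p: float
    tau_wall: np.ndarray
    mss_location: tuple
    solver: str = ""
    diagnostics: dict = field(default_factory=dict)


def generalized_reynolds(mat: Material, v_mean: float, diameter: float) -> float:
    """Metzner-Reed generalized Reynolds number for power-law pipe flow.

    Re_MR = rho V^(2-n) D^n / (8^(n-1) K ((3n+1)/(4n))^n); laminar below
    roughly 2000.
    """
    n, K = mat.power_law_index, mat.consistency
    return (
        mat.density
        * v_mean ** (2.0 - n)
        * diameter**n
        / (8.0 ** (n - 1.0) * K * ((3.0 * n + 1.0) / (4.0 * n)) ** n)
    )
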
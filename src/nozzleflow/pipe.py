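"""Closed-form power-law Poiseuille flow in a straight cylindrical tube.

For a fully developed power-law fluid driven by a pressure difference
``delta_p`` over a tube of radius R and length L:

    tau_w  = delta_p * R / (2 L)
    V_avg  = n/(3n+1) * (delta_p * R / (2 K L))**(1/n) * R
    Q      = pi R^2 V_avg
    u(r)   = (delta_p/(2 K L))**(1/n) * n/(n+1) * (R**((n+1)/n) - r**((n+1)/n))

These are exact for an infinitely long tube (no entrance or exit effects)
and serve both as the analytic oracle for the finite-volume solver and as
the classical single-tube estimate used when nozzle models are reduced to
the lower tube only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Material

__all__ = [
    "PipeSpec",
    "wall_shear",
    "mean_velocity",
    "flow_rate",
    "velocity_profile",
    "pressure_for_flow",
]


@dataclass(frozen=True)
class PipeSpec:
    """Straight tube: radius R and length L, metres."""

    R: float
    L: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")


def wall_shear(delta_p: float, pipe: PipeSpec) -> float:
    """Wall shear stress tau_w = delta_p * R / (2 L), Pa."""
    if delta_p < 0:
        raise ValueError(f"delta_p must be >= 0, got {delta_p}")
    return delta_p * pipe.R / (2.0 * pipe.L)


def mean_velocity(delta_p: float, pipe: PipeSpec, mat: Material) -> float:
    """Cross-section mean velocity V_avg, m/s."""
    n, K = mat.power_law_index, mat.consistency
    if n <= 0:
        raise ValueError("power-law index must be > 0")
    if delta_p < 0:
        raise ValueError(f"delta_p must be >= 0, got {delta_p}")
    if delta_p == 0:
        return 0.0
    return (
        n
        / (3.0 * n + 1.0)
        * (delta_p * pipe.R / (2.0 * K * pipe.L)) ** (1.0 / n)
        * pipe.R
    )


def flow_rate(pipe: PipeSpec, v_avg: float) -> float:
    """Volumetric flow rate Q = pi R^2 V_avg, m^3/s."""
    if v_avg < 0:
        raise ValueError(f"v_avg must be >= 0, got {v_avg}")
    return np.pi * pipe.R**2 * v_avg


def velocity_profile(r, delta_p: float, pipe: PipeSpec, mat: Material):
    """Fully developed axial velocity u(r), m/s; u(R) = 0 (no slip)."""
    n, K = mat.power_law_index, mat.consistency
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > pipe.R * (1 + 1e-12)):
        raise ValueError("r outside [0, R]")
    m = (n + 1.0) / n
    u = (
        (delta_p / (2.0 * K * pipe.L)) ** (1.0 / n)
        * n
        / (n + 1.0)
        * (pipe.R**m - np.minimum(r, pipe.R) ** m)
    )
    return u if u.ndim else float(u)


def pressure_for_flow(Q: float, pipe: PipeSpec, mat: Material) -> float:
    """Pressure difference producing flow Q; exact inverse of Eqs above.

    delta_p = (2 K L / R) * ((3n+1) Q / (n pi R^3))**n
    """
    if not Q > 0:
        raise ValueError(f"Q must be > 0, got {Q}")
    n, K = mat.power_law_index, mat.consistency
    return (
        2.0
        * K
        * pipe.L
        / pipe.R
        * ((3.0 * n + 1.0) * Q / (n * np.pi * pipe.R**3)) ** n
    )
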
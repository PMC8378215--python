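"""Quasi-1D (lubrication) nozzle solver with kinetic-energy correction.

The nozzle is discretized into axial stations; at each station the flow is
assumed locally fully developed, so the wall shear stress follows the
straight-tube power-law relation evaluated at the local radius,

    tau_w(z) = K * ((3n+1) Q / (n pi R(z)^3))**n,

and the viscous pressure gradient is dp/dz = 2 tau_w / R.  Because exit
velocities can reach tens of m/s, a mechanical-energy (kinetic) term is
added:

    delta_p = integral 2 tau_w / R dz  +  alpha(n) * rho/2 * (V_out^2 - V_in^2)

where alpha(n) is the kinetic-energy flux correction of the fully developed
power-law profile (alpha(1) = 2 for a parabola, -> 1 for plug flow).

The model deliberately contains no fitted entrance-loss coefficient and no
corner stress concentration: its maximum shear stress is the fully
developed wall value, a lower bound on what the 2D axisymmetric solver
reports near contraction corners and in developing-flow regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import DriveCondition, FlowSummary, Material, NozzleGeometry
from .errors import ConvergenceError

__all__ = ["ReducedOptions", "alpha_energy", "pressure_required", "solve"]


@dataclass(frozen=True)
class ReducedOptions:
    """Numerical options for the quasi-1D solver.

    n_stations : number of axial stations (midpoint rule), >= 10.
    alpha_mode : "fully_developed" uses alpha(n); "plug" uses alpha = 1.
    include_upper : include the upper (barrel/taper) section in the viscous
        integral; switching it off reduces the model to the lower tube.
    """

    n_stations: int = 400
    alpha_mode: str = "fully_developed"
    include_upper: bool = True

    def __post_init__(self) -> None:
        if self.n_stations < 10:
            raise ValueError("n_stations must be >= 10")
        if self.alpha_mode not in ("fully_developed", "plug"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")


def alpha_energy(n: float) -> float:
    """Kinetic-energy flux correction alpha(n) = <(u/V)^3> over the section.

    For the fully developed power-law profile u/V = c (1 - x**m) with
    x = r/R, m = (n+1)/n and c = (3n+1)/(n+1):

        alpha = 2 c^3 * (1/2 - 3/(m+2) + 3/(2m+2) - 1/(3m+2))

    alpha(1) = 2 (parabola); alpha -> 1 as n -> 0 (plug flow).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    m = (n + 1.0) / n
    c = (3.0 * n + 1.0) / (n + 1.0)
    integral = 0.5 - 3.0 / (m + 2.0) + 3.0 / (2.0 * m + 2.0) - 1.0 / (3.0 * m + 2.0)
    return 2.0 * c**3 * integral


def _stations(geom: NozzleGeometry, opts: ReducedOptions):
    z0 = 0.0 if opts.include_upper else geom.l_upper
    z_edges = np.linspace(z0, geom.length, opts.n_stations + 1)
    z_mid = 0.5 * (z_edges[:-1] + z_edges[1:])
    dz = np.diff(z_edges)
    R = np.asarray(geom.radius(z_mid), dtype=float)
    return z_mid, dz, R

def _wall_shear(Q: float, R, mat: Material):
    n = mat.power_law_index
    gw = (3.0 * n + 1.0) * Q / (n * np.pi * R**3)
    return mat.consistency * gw**n


def pressure_required(
    Q: float,
    geom: NozzleGeometry,
    mat: Material,
    opts: ReducedOptions = ReducedOptions(),
) -> float:
    """Pressure difference (Pa) needed to push flow Q through the nozzle."""
    if not Q > 0:
        raise ValueError(f"Q must be > 0, got {Q}")
    geom.validate()
    _, dz, R = _stations(geom, opts)
    tau = _wall_shear(Q, R, mat)
    dp_visc = float(np.sum(2.0 * tau / R * dz))
    alpha = 1.0 if opts.alpha_mode == "plug" else alpha_energy(mat.power_law_index)
    v_out = Q / (np.pi * geom.r_small**2)
    v_in = Q / (np.pi * float(geom.radius(0.0)) ** 2)
    dp_kin = alpha * 0.5 * mat.density * (v_out**2 - v_in**2)
    return dp_visc + dp_kin


def solve(
    geom: NozzleGeometry,
    mat: Material,
    drive: DriveCondition,
    opts: ReducedOptions = ReducedOptions(),
) -> FlowSummary:
    """Solve the quasi-1D nozzle flow for either drive mode.

    Flow-rate drive evaluates the pressure integral directly; pressure
    drive root-finds the unique Q with pressure_required(Q) = delta_p by
    bracketed bisection on log Q (the mapping is strictly increasing).
    """
    geom.validate()
    if drive.mode == "flowrate":
        Q = drive.q_in
        dp = pressure_required(Q, geom, mat, opts)
    else:
        dp = drive.delta_p
        Q = _invert_pressure(dp, geom, mat, opts)
    return _summary(Q, dp, geom, mat, opts)


def _invert_pressure(
    dp: float, geom: NozzleGeometry, mat: Material, opts: ReducedOptions
) -> float:
    # Initial guess: straight-tube solution for the lower tube alone
    # (overestimates Q -> good upper bracket seed).
    from . import pipe

    tube = pipe.PipeSpec(geom.r_small, geom.l_lower)
    q0 = pipe.flow_rate(tube, pipe.mean_velocity(dp, tube, mat))
    lo, hi = np.log(q0) - 2.0, np.log(q0) + 0.5

    def f(lq: float) -> float:
        return pressure_required(float(np.exp(lq)), geom, mat, opts) - dp

    n_expand = 0
    while f(hi) < 0:
        hi += 1.0
        n_expand += 1
        if n_expand > 200:
            raise ConvergenceError(
                f"bracket expansion failed: f({hi}) = {f(hi):.3e} still < 0"
            )
    while f(lo) > 0:
        lo -= 1.0
        n_expand += 1
        if n_expand > 200:
            raise ConvergenceError(
                f"bracket expansion failed: f({lo}) = {f(lo):.3e} still > 0"
            )
    try:
        lq = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails
        raise ConvergenceError(
            f"pressure inversion did not converge in bracket [{lo}, {hi}]: {exc}"
        ) from exc
    return float(np.exp(lq))


def _summary(
    Q: float, dp: float, geom: NozzleGeometry, mat: Material, opts: ReducedOptions
) -> FlowSummary:
    z_mid, dz, R = _stations(geom, opts)
    tau = _wall_shear(Q, R, mat)
    # Include the exact exit station (max tau for tapered lower sections).
    tau_exit = float(_wall_shear(Q, np.array([geom.r_small]), mat)[0])
    k = int(np.argmax(tau))
    if tau_exit >= tau[k]:
        mss, mss_z = tau_exit, geom.length
    else:
        mss, mss_z = float(tau[k]), float(z_mid[k])
    n = mat.power_law_index
    gw_exit = (3.0 * n + 1.0) * Q / (n * np.pi * geom.r_small**3)
    # Area-averaged shear rate of the fully developed profile:
    # gamma(r) = gamma_w (r/R)^(1/n)  =>  <gamma> = gamma_w * 2n/(2n+1).
    gbar = gw_exit * 2.0 * n / (2.0 * n + 1.0)
    nu_exit = float(mat.viscosity(gbar)) / mat.density
    return FlowSummary(
        mss=mss,
        q=Q,
        v_exit_mean=Q / (np.pi * geom.r_small**2),
        nu_exit=nu_exit,
        delta_p=dp,
        tau_wall=np.column_stack([z_mid, tau]),
        mss_location=(mss_z, float(geom.radius(min(mss_z, geom.length)))),
        solver="reduced",
        diagnostics={
            "n_stations": opts.n_stations,
            "alpha_mode": opts.alpha_mode,
            "include_upper": opts.include_upper,
        },
    )
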
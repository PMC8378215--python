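"""Constrained Latin-hypercube designs over nozzle geometry and campaigns.

The design space is the commercial print-nozzle catalogue box (mm):

    R_small 0.05-0.42, R_middle 1-3.5 (conical only), R_big 1.5-4.5,
    L_lower 4-20, L_upper 3-15.

Designs are one-value-per-bin stratified Latin hypercubes; a maximin
criterion is applied over random candidates.  Conical designs must satisfy
R_big > R_middle; violating rows are repaired by re-permuting the pairing
of the R_big column against the rest (never by redrawing values), which
preserves the one-dimensional stratification of every parameter exactly.
With the default ranges a feasible pairing always exists (sorting both
columns ascending pairs every R_big above its R_middle).

Campaigns evaluate every design with a nozzle solver (quasi-1D by
default) under a shared material and drive condition and collect the flow
summaries into a tidy response table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import reduced, units
from .core import DriveCondition, Material, NozzleGeometry
from .errors import CampaignError, NozzleFlowError

__all__ = [
    "TABLE_RANGES_MM",
    "parameter_names",
    "DesignTable",
    "lhs_design",
    "run_campaign",
    "summarize_campaign",
    "shear_thinning_sweep",
]

# catalogue ranges, mm
TABLE_RANGES_MM = {
    "r_small": (0.05, 0.42),
    "r_middle": (1.0, 3.5),
    "r_big": (1.5, 4.5),
    "l_lower": (4.0, 20.0),
    "l_upper": (3.0, 15.0),
}


def parameter_names(shape: str) -> list[str]:
    if shape == "conical":
        return ["r_small", "r_middle", "r_big", "l_lower", "l_upper"]
    if shape == "blunted":
        return ["r_small", "r_big", "l_lower", "l_upper"]
    raise ValueError(f"unknown shape {shape!r}")


@dataclass
class DesignTable:
    """A set of nozzle designs (parameter values in mm) plus provenance."""

    shape: str
    data: pd.DataFrame          # columns = parameter names, mm
    seed: int
    ranges_mm: dict = field(default_factory=lambda: dict(TABLE_RANGES_MM))

    @property
    def n_designs(self) -> int:
        return len(self.data)

    def geometries(self) -> list[NozzleGeometry]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                NozzleGeometry.from_mm(
                    self.shape,
                    r_small=row["r_small"],
                    r_big=row["r_big"],
                    l_lower=row["l_lower"],
                    l_upper=row["l_upper"],
                    r_middle=row.get("r_middle"),
                ).validate()
            )
        return out

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _lhs_matrix(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Plain stratified LHS in [0, 1)^d: one point per bin per column."""
    u = rng.random((n, d))
    out = np.empty((n, d))
    for j in range(d):
        perm = rng.permutation(n)
        out[:, j] = (perm + u[:, j]) / n
    return out


def _repair_conical(X01: np.ndarray, names: list[str], lo: np.ndarray,
                    hi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Re-permute the r_big column until every row has r_big > r_middle."""
    jb = names.index("r_big")
    jm = names.index("r_middle")
    vb = lo[jb] + (hi[jb] - lo[jb]) * X01[:, jb]
    vm = lo[jm] + (hi[jm] - lo[jm]) * X01[:, jm]
    n = len(vb)
    # feasibility: pair sorted r_big against sorted r_middle
    if not np.all(np.sort(vb) > np.sort(vm)):
        raise NozzleFlowError(
            "constraint r_big > r_middle unsatisfiable for these ranges"
        )
    order = np.arange(n)
    for _ in range(200):
        bad = np.flatnonzero(vb[order] <= vm)
        if len(bad) == 0:
            break
        # reshuffle the assignments of a random superset of the bad rows
        extra = rng.choice(np.setdiff1d(np.arange(n), bad),
                           size=min(len(bad) * 2, n - len(bad)),
                           replace=False) if n > len(bad) else []
        pool = np.concatenate([bad, np.asarray(extra, dtype=int)])
        order[pool] = order[rng.permutation(pool)]
    else:
        # deterministic fallback: sort-matching is always feasible, then
        # randomize with validity-preserving swaps
        order = np.argsort(vb)[np.argsort(np.argsort(vm))]
        for _ in range(10 * n):
            i, k = rng.integers(0, n, size=2)
            if vb[order[k]] > vm[i] and vb[order[i]] > vm[k]:
                order[[i, k]] = order[[k, i]]
    X = X01.copy()
    X[:, jb] = X01[order, jb]
    return X


def _maximin_score(X: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(X).min())


def lhs_design(
    n: int,
    seed: int,
    shape: str = "blunted",
    ranges_mm: Optional[dict] = None,
    n_candidates: int = 50,
) -> DesignTable:
    """Generate a constrained maximin Latin-hypercube design.

    ``n_candidates`` stratified designs are drawn and the one maximizing
    the minimum pairwise distance (in unit-box coordinates) is kept.
    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 designs")
    names = parameter_names(shape)
    ranges = dict(TABLE_RANGES_MM)
    if ranges_mm:
        ranges.update(ranges_mm)
    for k in names:
        lo_, hi_ = ranges[k]
        if not lo_ < hi_:
            raise ValueError(f"range for {k} must have low < high")
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for _ in range(max(1, n_candidates)):
        X01 = _lhs_matrix(n, len(names), rng)
        if shape == "conical":
            X01 = _repair_conical(X01, names, lo, hi, rng)
        score = _maximin_score(X01)
        if score > best_score:
            best, best_score = X01, score
    X = lo[None, :] + (hi[None, :] - lo[None, :]) * best
    df = pd.DataFrame(X, columns=names)
    table = DesignTable(shape=shape, data=df, seed=seed,
                        ranges_mm={k: ranges[k] for k in names})
    for g in table.geometries():  # raises if any row violates a constraint
        pass
    return table


def run_campaign(
    designs: DesignTable,
    mat: Material,
    drive: Optional[DriveCondition] = None,
    solver: str = "reduced",
    reduced_options: reduced.ReducedOptions = reduced.ReducedOptions(),
    fvm_mesh_options=None,
    fvm_numerics=None,
    max_failure_fraction: float = 0.05,
) -> pd.DataFrame:
    """Evaluate every design; returns the response table.

    Columns: design parameters (mm), then mss_kpa, q_ul_s, v_exit_m_s,
    nu_exit_m2_s, delta_p_kpa, solver, ok.  Solver failures are recorded
    (ok=False, NaN responses); more than ``max_failure_fraction`` failures
    aborts with :class:`CampaignError`.
    """
    if drive is None:
        if mat.default_pressure is None:
            raise ValueError("material has no default pressure; pass a drive")
        drive = DriveCondition.pressure(mat.default_pressure)
    if solver not in ("reduced", "fvm"):
        raise ValueError(f"unknown solver {solver!r}")
    rows = []
    failures = []
    for idx in range(designs.n_designs):
        rec = designs.data.iloc[idx].to_dict()
        try:
            geom = NozzleGeometry.from_mm(
                designs.shape,
                r_small=rec["r_small"],
                r_big=rec["r_big"],
                l_lower=rec["l_lower"],
                l_upper=rec["l_upper"],
                r_middle=rec.get("r_middle"),
            ).validate()
            if solver == "reduced":
                fs = reduced.solve(geom, mat, drive, reduced_options)
            else:
                from . import fvm as _fvm

                fs = _fvm.solve_nozzle(
                    geom,
                    mat,
                    drive,
                    mesh_options=fvm_mesh_options or _fvm.MeshOptions(),
                    num=fvm_numerics or _fvm.NumericsOptions(),
                )
            rec.update(
                mss_kpa=units.pa_to_kpa(fs.mss),
                q_ul_s=units.m3_s_to_ul_s(fs.q),
                v_exit_m_s=fs.v_exit_mean,
                nu_exit_m2_s=fs.nu_exit,
                delta_p_kpa=units.pa_to_kpa(fs.delta_p),
                ok=True,
            )
        except NozzleFlowError as exc:
            failures.append((idx, str(exc)))
            rec.update(mss_kpa=np.nan, q_ul_s=np.nan, v_exit_m_s=np.nan,
                       nu_exit_m2_s=np.nan, delta_p_kpa=np.nan, ok=False)
        rec["solver"] = solver
        rows.append(rec)
    resp = pd.DataFrame(rows)
    resp.attrs["material"] = mat.name
    resp.attrs["seed"] = designs.seed
    resp.attrs["failures"] = failures
    if len(failures) > max_failure_fraction * designs.n_designs:
        raise CampaignError(
            f"{len(failures)}/{designs.n_designs} designs failed: "
            f"{failures[:3]} ..."
        )
    return resp


def summarize_campaign(resp: pd.DataFrame) -> pd.DataFrame:
    """Distribution statistics (min/quartiles/median/max) per response."""
    if len(resp) == 0:
        raise ValueError("empty response table")
    cols = [c for c in ("mss_kpa", "q_ul_s", "nu_exit_m2_s", "v_exit_m_s",
                        "delta_p_kpa") if c in resp]
    ok = resp[resp.get("ok", True) == True]  # noqa: E712
    stats = ok[cols].describe(percentiles=[0.25, 0.5, 0.75])
    return stats.loc[["min", "25%", "50%", "75%", "max"]]


def shear_thinning_sweep(
    shape: str,
    n_values,
    sweep: str = "r_small",
    sweep_values_mm=None,
    mat_template: Optional[Material] = None,
    drive: Optional[DriveCondition] = None,
    base_mm: Optional[dict] = None,
    solver: str = "reduced",
) -> pd.DataFrame:
    """Sweep the maximum shear stress against one radius at several
    power-law indices, all other parameters fixed.

    Defaults mirror the canonical comparison: Alginate-like consistency,
    340 kPa drive, base geometry Rb=3.5 / Lu=4 / Ll=6 mm, with Rm=2.0 mm
    when sweeping R_small and Rs=0.2 mm when sweeping R_middle.
    """
    if sweep not in ("r_small", "r_middle"):
        raise ValueError("sweep must be 'r_small' or 'r_middle'")
    if sweep == "r_middle" and shape != "conical":
        raise ValueError("r_middle sweep requires the conical shape")
    base = {"r_big": 3.5, "l_lower": 6.0, "l_upper": 4.0}
    if shape == "conical":
        base["r_middle"] = 2.0
    base["r_small"] = 0.2
    if base_mm:
        base.update(base_mm)
    if sweep_values_mm is None:
        lo, hi = TABLE_RANGES_MM[sweep]
        sweep_values_mm = np.linspace(lo, hi, 12)
    template = mat_template or Material("sweep", 1000.0, 55.7, 0.335)
    drive = drive or DriveCondition.pressure_kpa(340.0)
    rows = []
    for n_ in n_values:
        if not 0 < n_ <= 1.2:
            raise ValueError(f"power-law index {n_} outside (0, 1.2]")
        mat = Material(f"{template.name}(n={n_})", template.density,
                       template.consistency, n_)
        for val in sweep_values_mm:
            params = dict(base)
            params[sweep] = float(val)
            geom = NozzleGeometry.from_mm(shape, **params)
            try:
                geom.validate()
            except NozzleFlowError:
                continue  # swept value incompatible with fixed parameters
            if solver == "reduced":
                fs = reduced.solve(geom, mat, drive)
            else:
                from . import fvm as _fvm

                fs = _fvm.solve_nozzle(geom, mat, drive)
            rows.append(
                {
                    "n": n_,
                    sweep + "_mm": float(val),
                    "mss_kpa": units.pa_to_kpa(fs.mss),
                    "q_ul_s": units.m3_s_to_ul_s(fs.q),
                }
            )
    return pd.DataFrame(rows)
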
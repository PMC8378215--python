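"""Gaussian-process surrogate and variance-based sensitivity analysis.

A stationary anisotropic (ARD) squared-exponential GP with a nugget is
fitted to campaign responses by maximizing the log marginal likelihood
(multi-start gradient optimization).  Inputs are scaled to [-1, 1] per
parameter over the design ranges and the response is standardized, so
main-effect plots read directly in "scaled response" units.

From the fitted surrogate:

* main effects -- Monte-Carlo averages of the predictive mean over all
  other inputs drawn uniformly, per parameter, with a 90% credible band;
* Sobol indices -- first-order S_j and total S_Tj estimated with the
  Saltelli pick-freeze scheme applied to the predictive mean under
  independent uniform inputs on the scaled box, with bootstrap spreads.

Usage follows the model/results pattern::

    model = GPSensitivity(X, y, param_names=names)
    res = model.fit(seed=0)
    res.summary()          # table of length-scales, S_j, S_Tj, ranking
    eff = res.main_effect("r_small")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "GPSensitivity",
    "GPSensitivityResults",
    "MainEffect",
    "SensitivityIndices",
]


@dataclass
class MainEffect:
    """Averaged effect of one parameter on the scaled response."""

    parameter: str
    grid: np.ndarray        # scaled coordinates in [-1, 1], sorted
    effect: np.ndarray      # centered scaled response
    ci90_low: np.ndarray
    ci90_high: np.ndarray
    n_mc: int
    seed: int

    def is_flat(self, threshold: float = 0.1) -> bool:
        """True when the effect span is below ``threshold`` scaled-response
        units (an inert parameter plots as a flat line at zero)."""
        return float(self.effect.max() - self.effect.min()) < threshold


@dataclass
class SensitivityIndices:
    """First-order and total Sobol indices with bootstrap spreads."""

    parameters: list
    s1: np.ndarray
    st: np.ndarray
    s1_boot: np.ndarray     # (n_boot, d)
    st_boot: np.ndarray
    n_base: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "S1": self.s1,
                "ST": self.st,
                "S1_sd": self.s1_boot.std(axis=0, ddof=1),
                "ST_sd": self.st_boot.std(axis=0, ddof=1),
            }
        )

    def rank(self, negligible_below: float = 0.05) -> pd.DataFrame:
        """Parameters ordered by decreasing total index.

        Ties are broken by declaration order (stable sort).  Parameters
        with S_T below ``negligible_below`` are flagged negligible.
        """
        df = self.to_frame()
        df["negligible"] = df["ST"] < negligible_below
        return df.sort_values("ST", ascending=False, kind="stable").reset_index(
            drop=True
        )


class GPSensitivity:
    """GP surrogate model of a scalar campaign response.

    Parameters
    ----------
    X : (n, d) array or DataFrame
        Design matrix in natural units (e.g. mm).
    y : (n,) array
        Response (e.g. maximum shear stress, kPa).
    param_names : sequence of str, optional
        Defaults to DataFrame columns or x0..x{d-1}.
    ranges : dict, optional
        Per-parameter (low, high) used for scaling to [-1, 1]; defaults
        to the observed min/max.
    """

    def __init__(self, X, y, param_names: Optional[Sequence[str]] = None,
                 ranges: Optional[dict] = None):
        if isinstance(X, pd.DataFrame):
            param_names = param_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        n, d = X.shape
        if len(y) != n:
            raise ValueError("X and y lengths differ")
        if n < 10:
            raise ValueError("need at least 10 rows to fit a surrogate")
        self.param_names = list(param_names) if param_names else [
            f"x{j}" for j in range(d)
        ]
        if ranges:
            lo = np.array([ranges[k][0] for k in self.param_names], float)
            hi = np.array([ranges[k][1] for k in self.param_names], float)
        else:
            lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        self._lo, self._span = lo, span
        Xs = self.scale(X)
        # collapse duplicated rows (averaging y) -- a GP with nugget still
        # dislikes exact duplicates during hyperparameter optimization
        key = np.round(Xs, 12)
        _, idx, inv = np.unique(key, axis=0, return_index=True,
                                return_inverse=True)
        if len(idx) < len(Xs):
            y_agg = np.zeros(len(idx))
            cnt = np.zeros(len(idx))
            np.add.at(y_agg, inv, y)
            np.add.at(cnt, inv, 1.0)
            Xs = key[np.sort(idx)]
            order = np.argsort(idx)
            y_agg, cnt = y_agg[order], cnt[order]
            y = y_agg / cnt
        self.Xs = Xs
        self.y = y
        self.y_mean = float(np.mean(y))
        ystd = float(np.std(y))
        self.y_std = ystd if ystd > 0 else 1.0
        self.degenerate = ystd == 0.0

    def scale(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return 2.0 * (X - self._lo[None, :]) / self._span[None, :] - 1.0

    def fit(self, seed: int = 0, n_restarts: int = 5) -> "GPSensitivityResults":
        """MAP hyperparameters by multi-start marginal-likelihood ascent."""
        ys = (self.y - self.y_mean) / self.y_std
        d = self.Xs.shape[1]
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(np.ones(d), (1e-2, 1e2))
            + WhiteKernel(1e-6, (1e-12, 1e-1))
        )
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=0 if self.degenerate else n_restarts,
            normalize_y=False,
            random_state=seed,
            alpha=1e-10,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # hyperparameters hitting their (wide) bounds on degenerate
            # synthetic responses is expected and benign
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(self.Xs, ys)
        return GPSensitivityResults(self, gpr, seed)


@dataclass
class GPSensitivityResults:
    """Fitted surrogate with prediction, main effects and Sobol indices."""

    model: GPSensitivity
    gpr: GaussianProcessRegressor
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    # -- prediction ----------------------------------------------------
    @property
    def length_scales(self) -> np.ndarray:
        return np.atleast_1d(self.gpr.kernel_.k1.k2.length_scale)

    @property
    def nugget(self) -> float:
        return float(self.gpr.kernel_.k2.noise_level)

    def predict(self, X, scaled_input: bool = False, scaled_output: bool = False):
        """Predictive mean, sd and 90% interval (mean +/- 1.645 sd).

        Inputs beyond [-1.05, 1.05] in scaled coordinates raise (mild
        extrapolation passes with a warning).
        """
        Xs = np.asarray(X, float) if scaled_input else self.model.scale(X)
        amax = np.max(np.abs(Xs)) if Xs.size else 0.0
        if amax > 1.5:
            raise ValueError(
                f"far extrapolation (|x_scaled| = {amax:.2f} > 1.5)"
            )
        if amax > 1.05:
            import warnings

            warnings.warn("extrapolating slightly beyond the design box",
                          stacklevel=2)
        mean_s, sd_s = self.gpr.predict(Xs, return_std=True)
        if scaled_output:
            mean, sd = mean_s, sd_s
        else:
            mean = mean_s * self.model.y_std + self.model.y_mean
            sd = sd_s * self.model.y_std
        return mean, sd, (mean - 1.645 * sd, mean + 1.645 * sd)

    def r2_holdout(self, test_fraction: float = 0.2, seed: int = 0) -> float:
        """Refit on a random split and score R^2 on the held-out part."""
        rng = np.random.default_rng(seed)
        n = len(self.model.y)
        idx = rng.permutation(n)
        n_test = max(1, int(test_fraction * n))
        test, train = idx[:n_test], idx[n_test:]
        sub = GPSensitivity(
            self.model.Xs[train], self.model.y[train],
            param_names=self.model.param_names,
            ranges={k: (-1.0, 1.0) for k in self.model.param_names},
        )
        res = sub.fit(seed=seed)
        pred, _, _ = res.predict(self.model.Xs[test], scaled_input=True)
        resid = self.model.y[test] - pred
        tot = self.model.y[test] - self.model.y[test].mean()
        return 1.0 - float(resid @ resid) / float(tot @ tot)

    # -- main effects --------------------------------------------------
    def main_effect(self, parameter, grid_size: int = 21, n_mc: int = 2000,
                    seed: Optional[int] = None) -> MainEffect:
        """Monte-Carlo main effect of one parameter on the scaled response.

        effect(x_j) = E[ m(x) | x_j ] under independent uniform inputs on
        [-1, 1]^d, centered to zero mean over the grid.  The 90% band is
        the averaged GP predictive band around the effect.
        """
        j = (self.model.param_names.index(parameter)
             if isinstance(parameter, str) else int(parameter))
        seed = self.seed if seed is None else seed
        if n_mc < 100:
            raise ValueError("n_mc too small for a stable effect estimate")
        rng = np.random.default_rng(seed + 1000 * j)
        d = self.model.Xs.shape[1]
        grid = np.linspace(-1.0, 1.0, grid_size)
        Z = rng.uniform(-1.0, 1.0, size=(n_mc, d))
        big = np.repeat(Z[None, :, :], grid_size, axis=0)
        big[:, :, j] = grid[:, None]
        mean_s, sd_s = self.gpr.predict(big.reshape(-1, d), return_std=True)
        mean_s = mean_s.reshape(grid_size, n_mc)
        sd_s = sd_s.reshape(grid_size, n_mc)
        eff = mean_s.mean(axis=1)
        eff_c = eff - eff.mean()
        band = 1.645 * sd_s.mean(axis=1)
        return MainEffect(
            parameter=self.model.param_names[j],
            grid=grid,
            effect=eff_c,
            ci90_low=eff_c - band,
            ci90_high=eff_c + band,
            n_mc=n_mc,
            seed=seed,
        )

    def main_effects(self, **kw) -> dict:
        return {p: self.main_effect(p, **kw) for p in self.model.param_names}

    # -- Sobol indices -------------------------------------------------
    def sobol_indices(self, n_base: int = 2048, seed: Optional[int] = None,
                      n_boot: int = 100) -> SensitivityIndices:
        """Saltelli pick-freeze estimates of S_j and S_Tj.

        Inputs are independent uniforms on the scaled box; the estimand is
        the variance decomposition of the GP predictive mean.  S_j uses
        the Saltelli (2010) estimator mean(f_B (f_ABj - f_A)) / V and
        S_Tj uses mean((f_A - f_ABj)^2) / (2 V).
        """
        if n_base < 256:
            raise ValueError("n_base too small for stable Sobol estimates")
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        d = self.model.Xs.shape[1]
        A = rng.uniform(-1.0, 1.0, size=(n_base, d))
        B = rng.uniform(-1.0, 1.0, size=(n_base, d))
        blocks = [A, B]
        for j in range(d):
            ABj = A.copy()
            ABj[:, j] = B[:, j]
            blocks.append(ABj)
        big = np.concatenate(blocks, axis=0)
        f = self.gpr.predict(big)
        fA = f[:n_base]
        fB = f[n_base : 2 * n_base]
        fAB = f[2 * n_base :].reshape(d, n_base)

        def estimate(idx):
            a, b_, ab = fA[idx], fB[idx], fAB[:, idx]
            var = np.var(np.concatenate([a, b_]), ddof=1)
            var = max(var, 1e-300)
            s1 = np.mean(b_[None, :] * (ab - a[None, :]), axis=1) / var
            st = 0.5 * np.mean((a[None, :] - ab) ** 2, axis=1) / var
            return s1, st

        s1, st = estimate(np.arange(n_base))
        s1_b = np.empty((n_boot, d))
        st_b = np.empty((n_boot, d))
        for k in range(n_boot):
            idx = rng.integers(0, n_base, size=n_base)
            s1_b[k], st_b[k] = estimate(idx)
        return SensitivityIndices(
            parameters=list(self.model.param_names),
            s1=s1, st=st, s1_boot=s1_b, st_boot=st_b,
            n_base=n_base, seed=seed,
        )

    def rank_parameters(self, negligible_below: float = 0.05,
                        **kw) -> pd.DataFrame:
        return self.sobol(**kw).rank(negligible_below)

    def sobol(self, **kw) -> SensitivityIndices:
        key = tuple(sorted(kw.items()))
        if key not in self._cache:
            self._cache[key] = self.sobol_indices(**kw)
        return self._cache[key]

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        sens = self.sobol()
        df = sens.rank()
        ls = self.length_scales
        lines = [
            "GP sensitivity analysis",
            f"  n = {len(self.model.y)} designs, "
            f"d = {len(self.model.param_names)} parameters",
            f"  kernel: {self.gpr.kernel_}",
            f"  nugget: {self.nugget:.3e}",
            "",
            "  parameter     length-scale      S1      ST  negligible",
        ]
        for _, row in df.iterrows():
            j = self.model.param_names.index(row.parameter)
            lines.append(
                f"  {row.parameter:<12}  {ls[j]:>11.3g}  {row.S1:>6.3f}"
                f"  {row.ST:>6.3f}  {'yes' if row.negligible else 'no':>10}"
            )
        return "\n".join(lines)

    def plot_panels(self, path=None, **effect_kw):
        """Main-effect curves with 90% bands plus an index box-plot."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        effs = self.main_effects(**effect_kw)
        sens = self.sobol()
        d = len(effs)
        fig, axes = plt.subplots(1, d + 1, figsize=(3 * (d + 1), 3))
        for ax, (name, eff) in zip(axes[:-1], effs.items()):
            ax.fill_between(eff.grid, eff.ci90_low, eff.ci90_high,
                            alpha=0.3, color="grey")
            ax.plot(eff.grid, eff.effect)
            ax.axhline(0.0, lw=0.5, color="k")
            ax.set_title(name)
            ax.set_xlabel("scaled input")
        axes[0].set_ylabel("scaled response")
        axes[-1].boxplot(sens.st_boot, tick_labels=sens.parameters)
        axes[-1].set_title("total Sobol index")
        axes[-1].tick_params(axis="x", rotation=45)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
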
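"""GP surrogate, main effects and Sobol indices on closed-form functions."""

import numpy as np
import pytest

from nozzleflow import doe
from nozzleflow.gp import GPSensitivity


def uniform_design(n, d, seed):
    return np.random.default_rng(seed).uniform(-1.0, 1.0, size=(n, d))


UNIT = {k: (-1.0, 1.0) for k in "abcd"}


@pytest.fixture(scope="module")
def linear_fit():
    """y = x1 + 2 x2 with two inert inputs."""
    X = uniform_design(120, 4, seed=0)
    y = X[:, 0] + 2 * X[:, 1]
    return GPSensitivity(X, y, param_names=list("abcd"), ranges=UNIT).fit(seed=0)


@pytest.fixture(scope="module")
def campaign_fit(campaign_blunted):
    designs, resp = campaign_blunted
    names = doe.parameter_names("blunted")
    return GPSensitivity(resp[names], resp["mss_kpa"],
                         ranges=designs.ranges_mm).fit(seed=0)


class TestFit:
    def test_constant_response(self):
        X = uniform_design(30, 2, seed=1)
        res = GPSensitivity(X, np.full(30, 3.5), param_names=["a", "b"],
                            ranges={"a": (-1, 1), "b": (-1, 1)}).fit()
        mean, _, _ = res.predict(uniform_design(5, 2, seed=2),
                                 scaled_input=True)
        assert mean == pytest.approx(np.full(5, 3.5), abs=1e-6)

    def test_ard_detects_inert_input(self):
        """y depends on x1 only: automatic relevance detection drives the
        inert input's length-scale far above the active one's."""
        X = uniform_design(60, 2, seed=3)
        y = np.sin(3 * X[:, 0])
        res = GPSensitivity(X, y, param_names=["a", "b"],
                            ranges={"a": (-1, 1), "b": (-1, 1)}).fit(seed=0)
        ls = res.length_scales
        assert ls[1] > 10 * ls[0]

    def test_interpolates_training_data(self, linear_fit):
        m = linear_fit.model
        pred, sd, _ = linear_fit.predict(m.Xs, scaled_input=True)
        # nugget-consistent reproduction (solver jitter floor ~1e-4 sd)
        nug_sd = m.y_std * (np.sqrt(linear_fit.nugget) + 1e-4)
        assert np.all(np.abs(pred - m.y) <= 2 * nug_sd)

    def test_duplicates_collapsed(self):
        X = np.vstack([uniform_design(20, 2, seed=4)] * 2)
        y = np.concatenate([np.ones(20), 3 * np.ones(20)])
        model = GPSensitivity(X, y, param_names=["a", "b"],
                              ranges={"a": (-1, 1), "b": (-1, 1)})
        assert len(model.y) == 20
        assert model.y == pytest.approx(np.full(20, 2.0))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            GPSensitivity(np.zeros((5, 2)), np.zeros(5))

    def test_campaign_holdout_r2(self, campaign_fit):
        """The response is smooth in geometry: held-out R^2 > 0.9."""
        assert campaign_fit.r2_holdout(0.2, seed=1) > 0.9


class TestPredict:
    def test_interval_symmetric_and_widens_offdata(self, linear_fit):
        x_in = np.array([[0.0, 0.0, 0.0, 0.0]])
        x_out = np.array([[1.04, 1.04, 1.04, 1.04]])
        m1, s1_, (lo1, hi1) = linear_fit.predict(x_in, scaled_input=True)
        m2, s2_, (lo2, hi2) = linear_fit.predict(x_out, scaled_input=True)
        assert hi1 - m1 == pytest.approx(m1 - lo1)
        assert s2_[0] > s1_[0]

    def test_far_extrapolation_rejected(self, linear_fit):
        with pytest.raises(ValueError):
            linear_fit.predict(np.array([[2.0, 0.0, 0.0, 0.0]]),
                               scaled_input=True)


class TestMainEffects:
    def test_additive_decomposition_recovered(self):
        """y = f1(x1) + f2(x2): effects match f1, f2 up to centering."""
        X = uniform_design(150, 3, seed=5)
        f1 = lambda x: x**2
        f2 = lambda x: np.sin(2 * x)
        y = f1(X[:, 0]) + f2(X[:, 1])
        res = GPSensitivity(X, y, param_names=["a", "b", "c"],
                            ranges={k: (-1, 1) for k in "abc"}).fit(seed=0)
        ystd = res.model.y_std
        ea = res.main_effect("a", n_mc=2000)
        ref = f1(ea.grid) - np.mean(f1(ea.grid))
        assert np.max(np.abs(ea.effect * ystd - ref)) < 0.08
        eb = res.main_effect("b", n_mc=2000)
        ref = f2(eb.grid) - np.mean(f2(eb.grid))
        assert np.max(np.abs(eb.effect * ystd - ref)) < 0.08

    def test_inert_parameter_flat(self, linear_fit):
        eff = linear_fit.main_effect("c")
        assert eff.is_flat()
        assert np.max(np.abs(eff.effect)) < 0.05

    def test_ci_brackets_effect(self, linear_fit):
        eff = linear_fit.main_effect("a")
        assert np.all(eff.ci90_low <= eff.effect)
        assert np.all(eff.effect <= eff.ci90_high)

    def test_campaign_effect_shapes(self, campaign_fit):
        """Entrance radius and upper length plot flat; exit radius and
        lower length do not."""
        effs = campaign_fit.main_effects()
        assert effs["r_big"].is_flat()
        assert effs["l_upper"].is_flat()
        assert not effs["r_small"].is_flat()
        assert not effs["l_lower"].is_flat()


class TestSobol:
    def test_linear_1_to_4_variance_split(self, linear_fit):
        s = linear_fit.sobol_indices(n_base=2048, seed=1)
        assert s.s1[0] == pytest.approx(0.2, abs=0.05)
        assert s.s1[1] == pytest.approx(0.8, abs=0.05)
        assert s.st[2] < 0.05 and s.st[3] < 0.05

    def test_pure_noise_finds_no_structure(self):
        """A pure-noise response carries no input-attributable variance:
        the surrogate's predictive-mean variance over the box is a small
        fraction of the data variance (normalized Sobol shares of a
        near-zero variance are not individually meaningful)."""
        rng = np.random.default_rng(8)
        X = uniform_design(80, 3, seed=8)
        y = rng.normal(size=80)
        res = GPSensitivity(X, y, param_names=["a", "b", "c"],
                            ranges={k: (-1, 1) for k in "abc"}).fit(seed=0)
        sample = rng.uniform(-1, 1, size=(4096, 3))
        mean, _, _ = res.predict(sample, scaled_input=True)
        assert np.var(mean) < 0.25 * np.var(y)

    def test_estimator_consistency_ishigami_like(self):
        """On y = sin(pi x1) + 7 sin(pi x2)^2 the estimates approach the
        analytic variance shares as the base sample grows."""
        X = uniform_design(250, 2, seed=9)
        a = 7.0
        y = np.sin(np.pi * X[:, 0]) + a * np.sin(np.pi * X[:, 1]) ** 2
        res = GPSensitivity(X, y, param_names=["a", "b"],
                            ranges={"a": (-1, 1), "b": (-1, 1)}).fit(seed=0)
        v1, v2 = 0.5, a**2 / 8.0
        exact = np.array([v1, v2]) / (v1 + v2)
        errs = []
        for nb in (1024, 4096):
            s = res.sobol_indices(n_base=nb, seed=3)
            errs.append(np.max(np.abs(s.s1 - exact)))
        assert errs[-1] < 0.05
        assert errs[-1] <= errs[0] + 0.01

    def test_campaign_classification(self, campaign_fit):
        """Entrance radius and upper length negligible; exit radius and
        lower length dominate."""
        rank = campaign_fit.sobol().rank(negligible_below=0.05)
        flags = dict(zip(rank.parameter, rank.negligible))
        assert flags["r_big"] and flags["l_upper"]
        assert not flags["r_small"] and not flags["l_lower"]
        top2 = set(rank.parameter.iloc[:2])
        assert top2 == {"r_small", "l_lower"}

    def test_single_active_parameter_ranked_first(self):
        X = uniform_design(60, 3, seed=10)
        y = X[:, 2] ** 3
        res = GPSensitivity(X, y, param_names=["a", "b", "c"],
                            ranges={k: (-1, 1) for k in "abc"}).fit(seed=0)
        rank = res.sobol(n_base=1024).rank()
        assert rank.parameter.iloc[0] == "c"
        assert rank.ST.iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_tie_break_declaration_order(self):
        s = __import__("nozzleflow.gp", fromlist=["SensitivityIndices"])
        si = s.SensitivityIndices(
            parameters=["p", "q", "r"],
            s1=np.array([0.0, 0.0, 0.9]),
            st=np.array([0.02, 0.02, 0.9]),
            s1_boot=np.zeros((3, 3)),
            st_boot=np.zeros((3, 3)),
            n_base=0, seed=0,
        )
        rank = si.rank()
        assert list(rank.parameter) == ["r", "p", "q"]

    def test_split_half_stability(self, campaign_blunted):
        """Two random halves of the campaign classify every parameter
        identically."""
        designs, resp = campaign_blunted
        names = doe.parameter_names("blunted")
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(resp))
        flags = []
        for half in (idx[:100], idx[100:]):
            sub = resp.iloc[half]
            res = GPSensitivity(sub[names], sub["mss_kpa"],
                                ranges=designs.ranges_mm).fit(seed=0)
            rank = res.sobol(n_base=1024).rank()
            flags.append(dict(zip(rank.parameter, rank.negligible)))
        assert flags[0] == flags[1]
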
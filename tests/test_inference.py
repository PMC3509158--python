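import numpy as np
import pandas as pd
import pytest

import fallowfun as ff
from _oracles import anova_sums_of_squares, ols_normal_equations
from fallowfun import inference
from fallowfun.errors import (
    CollinearityError,
    InsufficientSampleError,
    InvalidArgumentError,
)


class TestLinearModel:
    def test_hand_dataset(self):
        fit = inference.fit_linear_model([1, 2, 4], pd.DataFrame({"x": [1, 2, 3]}))
        assert fit.estimates["x"] == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-2 / 3)

    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        fit = inference.fit_linear_model(2 * x, pd.DataFrame({"x": x}))
        assert fit.estimates["x"] == pytest.approx(2.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_adjusted_r2(self):
        # with R^2 = 0, n=10, p=1: adjusted R^2 = 1 - (9/8) = -1/8
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize
        fit = inference.fit_linear_model(y, pd.DataFrame({"x": x}))
        assert fit.estimates["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(-1 / 8, abs=1e-9)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(18, 2)), columns=["a", "b"])
        fit = inference.fit_linear_model(rng.normal(size=18), X)
        assert fit.df_resid == 18 - 3
        assert fit.df_model == 2

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(8, 30))
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            fit = inference.fit_linear_model(y, pd.DataFrame(X, columns=["a", "b"]))
            beta = ols_normal_equations(y, X)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.estimates["a"] == pytest.approx(beta[1], abs=1e-8)
            assert fit.estimates["b"] == pytest.approx(beta[2], abs=1e-8)

    def test_errors(self):
        with pytest.raises(InsufficientSampleError):
            inference.fit_linear_model([1, 2], pd.DataFrame({"x": [1, 2]}))
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(CollinearityError):
            inference.fit_linear_model([1, 2, 3, 4, 5], X)


class TestFisherCI:
    @pytest.mark.parametrize(
        "r,n,lo,hi",
        [
            (0.854, 18, 0.64, 0.94),
            (0.751, 18, 0.44, 0.90),
            (0.446, 21, 0.02, 0.74),
            (-0.473, 18, -0.77, -0.01),
        ],
    )
    def test_printed_intervals(self, r, n, lo, hi):
        got_lo, got_hi = inference.fisher_ci(r, n)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_symmetric_about_zero(self):
        lo, hi = inference.fisher_ci(0.0, 20)
        assert lo == pytest.approx(-hi)

    def test_pearson_wrapper(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        res = inference.pearson_fisher_ci(x, x + rng.normal(size=25))
        assert res.ci_low <= res.r <= res.ci_high
        assert res.df == (1, 23)
        with pytest.raises(InvalidArgumentError):
            inference.pearson_fisher_ci(x, np.ones(25))


class TestAnova:
    def test_two_group_hand_value(self):
        F, df, P = inference.oneway_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(13.5)
        assert df == (1, 4)

    def test_identical_means(self):
        F, _, _ = inference.oneway_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=17)
        groups = np.array(["a"] * 5 + ["b"] * 8 + ["c"] * 4)
        F, _, _ = inference.oneway_anova(vals, groups)
        assert F == pytest.approx(anova_sums_of_squares(vals, groups), rel=1e-10)

    def test_single_group(self):
        with pytest.raises(InvalidArgumentError):
            inference.oneway_anova([1, 2, 3], ["a", "a", "a"])


def _model_data(n_grazed=24, n_improved=24, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_grazed + n_improved):
        ftype = "grazed" if i < n_grazed else "improved"
        rows.append(
            {
                "fallow_type": ftype,
                "grazing_class": rng.choice(["light", "moderate", "heavy"]) if ftype == "grazed" else "",
                "fd": rng.uniform(2, 12),
                "richness": rng.integers(2, 14),
                "soc": rng.uniform(0.008, 0.025),
                "grazing": rng.choice([0.095, 0.525, 0.825]) if ftype == "grazed" else np.nan,
                "prop_asin_05": rng.uniform(0, 1.5),
                "mpe": rng.normal(0, 30),
            }
        )
    return pd.DataFrame(rows)


class TestModelSuite:
    def test_enumeration(self):
        table = inference.run_model_suite(_model_data())
        counts = table.groupby(["fallow_type", "response"])["model"].nunique()
        assert (counts.loc["grazed"] == 8).all()
        assert (counts.loc["improved"] == 5).all()
        # bivariate models carry two coefficient rows
        rows = table.groupby(["fallow_type", "response"]).size()
        assert (rows.loc["grazed"] == 12).all()
        assert (rows.loc["improved"] == 7).all()

    def test_fd_effect_recovery(self):
        """A planted diversity effect is detected in the grazed model suite."""
        from fallowfun.multifunc import indicator_table

        cfg = ff.GeneratorConfig(seed=101, n_grazed=200, n_improved=3)
        prof = ff.generate_profiles(cfg)
        g = prof[prof.fallow_type == "grazed"]
        ind, _ = indicator_table(g, thresholds=(0.5,))
        frame = ind.merge(g[["plot_id", "fd"]], on="plot_id")
        fit = inference.fit_linear_model(frame["prop_asin_05"], frame[["fd"]])
        assert fit.estimates["fd"] > 0
        assert fit.p_values["fd"] < 0.05

    def test_grazing_subgroup(self):
        data = _model_data(seed=2)
        grazed = data[data.fallow_type == "grazed"]
        fit = inference.grazing_subgroup_fit(grazed, "mpe", group="moderate")
        n_mod = (grazed["grazing_class"] == "moderate").sum()
        assert fit.df_resid == n_mod - 2

    def test_grazing_subgroup_errors(self):
        data = _model_data(seed=3)
        grazed = data[data.fallow_type == "grazed"].copy()
        with pytest.raises(InsufficientSampleError):
            inference.grazing_subgroup_fit(grazed.iloc[:2], "mpe")
        mod = grazed[grazed.grazing_class == "moderate"].copy()
        mod["fd"] = 1.0
        with pytest.raises(InvalidArgumentError):
            inference.grazing_subgroup_fit(mod, "mpe")
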
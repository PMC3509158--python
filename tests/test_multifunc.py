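import math

import numpy as np
import pandas as pd
import pytest

from fallowfun import multifunc as mf
from fallowfun.errors import InsufficientSampleError, InvalidArgumentError, MissingDataError


class TestTransforms:
    def test_registry(self):
        assert mf.transform_function(0.0, "wood") == 0.0
        assert mf.transform_function(4.0, "forage") == 2.0
        assert mf.transform_function(9.0, "infiltration") == 3.0
        assert mf.transform_function(8.8, "cations") == pytest.approx(
            math.asin(math.sqrt(0.088))
        )

    def test_domain_errors(self):
        with pytest.raises(InvalidArgumentError):
            mf.transform_function(-1.0, "wood")
        with pytest.raises(InvalidArgumentError):
            mf.transform_function(101.0, "cations")
        with pytest.raises(InvalidArgumentError):
            mf.transform_function(1.0, "biomassx")

    @pytest.mark.parametrize("kind", mf.FUNCTIONS)
    def test_inverse_round_trip(self, kind):
        for v in (0.01, 0.5, 3.7, 42.0):
            if kind == "cations" and v > 99:
                continue
            t = mf.transform_function(v, kind)
            assert mf.inverse_transform(t, kind) == pytest.approx(v, rel=1e-12)


class TestTypeReference:
    def test_mean_of_top_three(self):
        ref = mf.type_reference([1, 2, 3, 4, 5])
        assert ref.maximum == pytest.approx(4.0)
        assert ref.mean == pytest.approx(3.0)

    def test_constant_sample(self):
        ref = mf.type_reference([7.0, 7.0, 7.0, 7.0])
        assert ref.maximum == ref.mean == 7.0

    def test_exactly_three(self):
        assert mf.type_reference([1.0, 2.0, 6.0]).maximum == pytest.approx(3.0)

    def test_too_few(self):
        with pytest.raises(InsufficientSampleError):
            mf.type_reference([1.0, 2.0])


def _ref(maxima, means=None):
    means = means or maxima
    return {
        f: mf.TypeReference(maximum=m, mean=mu)
        for f, m, mu in zip(mf.FUNCTIONS, maxima, means)
    }


class TestProportionAbove:
    def test_extremes(self):
        ref = _ref([2.0, 2.0, 4.0, 2.0])
        at_max = dict(zip(mf.FUNCTIONS, [2.0, 2.0, 4.0, 2.0]))
        assert mf.proportion_above(at_max, ref, 0.5)[0] == 1.0
        zeros = dict(zip(mf.FUNCTIONS, [0.0, 0.0, 0.0, 0.0]))
        assert mf.proportion_above(zeros, ref, 0.5)[0] == 0.0

    def test_three_of_four(self):
        ref = _ref([2.0, 2.0, 4.0, 2.0])
        x = dict(zip(mf.FUNCTIONS, [1.0, 2.0, 3.0, 0.4]))
        prop, asin = mf.proportion_above(x, ref, 0.5)
        assert prop == 0.75
        assert asin == pytest.approx(math.asin(math.sqrt(0.75)))

    def test_monotone_in_threshold_and_value(self):
        ref = _ref([2.0, 2.0, 4.0, 2.0])
        x = dict(zip(mf.FUNCTIONS, [1.3, 0.9, 2.6, 1.1]))
        props = [mf.proportion_above(x, ref, tau)[0] for tau in (0.25, 0.5, 0.75)]
        assert props == sorted(props, reverse=True)
        x2 = dict(x)
        x2["wood"] = x["wood"] + 1.0
        assert mf.proportion_above(x2, ref, 0.5)[0] >= mf.proportion_above(x, ref, 0.5)[0]

    def test_missing_value(self):
        ref = _ref([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(MissingDataError):
            mf.proportion_above({"wood": 1.0}, ref, 0.5)


class TestMeanPercentageExcess:
    def test_identity_at_means(self):
        ref = _ref([2.0] * 4, [1.0] * 4)
        x = dict(zip(mf.FUNCTIONS, [1.0] * 4))
        assert mf.mean_percentage_excess(x, ref) == 0.0

    def test_hand_value(self):
        ref = _ref([2.0] * 4, [1.0, 1.0, 1.0, 1.0])
        x = dict(zip(mf.FUNCTIONS, [2.0, 1.0, 1.0, 1.0]))
        assert mf.mean_percentage_excess(x, ref) == pytest.approx(25.0)

    def test_degenerate_mean(self):
        ref = _ref([1.0] * 4, [0.0, 1.0, 1.0, 1.0])
        with pytest.raises(InvalidArgumentError):
            mf.mean_percentage_excess(dict(zip(mf.FUNCTIONS, [1.0] * 4)), ref)

    def test_zero_mean_identity(self):
        """Averaging mpe over the plots that define the means gives exactly 0."""
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            {"plot_id": [f"p{i}" for i in range(12)], "fallow_type": "grazed"}
        )
        for f in mf.FUNCTIONS:
            frame[f] = rng.uniform(0.5, 5.0, 12)
        indicators, _ = mf.indicator_table(frame)
        assert abs(indicators["mpe"].mean()) < 1e-12


class TestJointness:
    def _frame(self, rows):
        df = pd.DataFrame(rows, columns=["plot_id", "fallow_type", *mf.FUNCTIONS])
        return df

    def test_all_plots_at_maxima(self):
        frame = self._frame(
            [(f"p{i}", "grazed", 2.0, 2.0, 2.0, 2.0) for i in range(4)]
        )
        refs = {"grazed": _ref([2.0] * 4)}
        for mode in ("half_max", "above_mean"):
            joint = mf.jointness(frame, refs, mode)
            assert (joint["incidence"] == 4).all()

    def test_half_max_toy(self):
        # pair (wood, forage): only the first plot clears both half-maxima
        refs = {"grazed": _ref([1.0, 1.0, 1.0, 1.0], [0.5] * 4)}
        frame = self._frame(
            [
                ("p1", "grazed", 1.0, 1.0, 1.0, 1.0),
                ("p2", "grazed", 0.6, 0.4, 1.0, 1.0),
                ("p3", "grazed", 0.2, 0.9, 1.0, 1.0),
            ]
        )
        joint = mf.jointness(frame, refs, "half_max")
        wf = joint[joint["pair"] == "wood-forage"]["incidence"].iloc[0]
        assert wf == 1

    def test_above_mean_toy(self):
        refs = {"grazed": _ref([2.0] * 4, [0.5] * 4)}
        frame = self._frame(
            [
                ("p1", "grazed", 0.9, 0.9, 0.9, 0.9),
                ("p2", "grazed", 0.1, 0.1, 0.9, 0.9),
            ]
        )
        joint = mf.jointness(frame, refs, "above_mean")
        assert joint[joint["pair"] == "wood-forage"]["incidence"].iloc[0] == 1

    def test_bounded_by_single_function_counts(self):
        rng = np.random.default_rng(9)
        frame = self._frame(
            [
                (f"p{i}", "grazed", *rng.uniform(0, 1, 4))
                for i in range(15)
            ]
        )
        refs = {"grazed": {f: mf.type_reference(frame[f]) for f in mf.FUNCTIONS}}
        joint = mf.jointness(frame, refs, "half_max")
        singles = {
            f: int((frame[f] >= 0.5 * refs["grazed"][f].maximum).sum())
            for f in mf.FUNCTIONS
        }
        for _, row in joint.iterrows():
            fa, fb = row["pair"].split("-")
            assert row["incidence"] <= min(singles[fa], singles[fb])

    def test_unknown_mode(self):
        with pytest.raises(InvalidArgumentError):
            mf.jointness(self._frame([("p", "grazed", 1, 1, 1, 1)]), {}, "median")


def test_top_plot_always_above_half_maximum():
    """The largest value exceeds half the top-3 mean for positive data."""
    rng = np.random.default_rng(4)
    for _ in range(30):
        vals = rng.uniform(0.01, 10.0, rng.integers(3, 25))
        ref = mf.type_reference(vals)
        assert vals.max() >= 0.5 * ref.maximum
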
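"""Saltelli designs and Sobol index estimators against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from lurpm.ensemble import ModelEnsemble
from lurpm.features import FeatureTable
from lurpm.sobol import (
    ParameterSpace,
    aggregate_over_ensemble,
    build_parameter_space,
    estimate_indices,
    round_categoricals,
    saltelli_sample,
    screen_features,
    total_evaluations,
)


def unit_space(D, lo=0.0, hi=1.0):
    names = [f"x{i}" for i in range(D)]
    bounds = np.tile([lo, hi], (D, 1)).astype(float)
    return ParameterSpace(names=names, bounds=bounds,
                          kinds={n: "continuous" for n in names})


def naive_indices(y, D, N):
    """Straight-from-the-formula re-implementation (python loops)."""
    f_a = [float(v) for v in y[:N]]
    f_b = [float(v) for v in y[N : 2 * N]]
    pooled = f_a + f_b
    mean = sum(pooled) / len(pooled)
    v = sum((p - mean) ** 2 for p in pooled) / len(pooled)
    fos, tos = [], []
    for i in range(D):
        f_ab = [float(w) for w in y[(2 + i) * N : (3 + i) * N]]
        s = sum(b * (ab - a) for a, b, ab in zip(f_a, f_b, f_ab)) / N / v
        t = sum((a - ab) ** 2 for a, ab in zip(f_a, f_ab)) / (2 * N * v)
        fos.append(s)
        tos.append(t)
    return np.array(fos), np.array(tos)


class TestDesign:
    def test_non_power_of_two_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="1024"):
            saltelli_sample(unit_space(2), N=1000)

    def test_row_count_formula(self):
        design = saltelli_sample(unit_space(1), N=8, seed=0)
        assert design.samples.shape == (24, 1)
        assert design.S == total_evaluations(8, 1) == 24

    def test_block_structure(self):
        D = 4
        design = saltelli_sample(unit_space(D), N=16, seed=1)
        s = design.samples
        A, B = s[:16], s[16:32]
        for i in range(D):
            ab = s[(2 + i) * 16 : (3 + i) * 16]
            assert np.array_equal(ab[:, i], B[:, i])
            others = [j for j in range(D) if j != i]
            assert np.array_equal(ab[:, others], A[:, others])

    def test_columns_uniform_over_bounds(self):
        space = unit_space(3, lo=-2.0, hi=6.0)
        design = saltelli_sample(space, N=512, seed=2)
        s = design.samples
        assert s.min() >= -2.0 and s.max() <= 6.0
        # mean of a U(-2, 6) column is 2 with SE = 8/sqrt(12 N_rows)
        se = 8.0 / math.sqrt(12.0 * len(s))
        assert np.all(np.abs(s.mean(axis=0) - 2.0) < 3 * se)

    def test_scrambling_seeded(self):
        a = saltelli_sample(unit_space(2), N=32, seed=9).samples
        b = saltelli_sample(unit_space(2), N=32, seed=9).samples
        assert np.array_equal(a, b)


class TestRoundCategoricals:
    def make(self, values, codes=(1, 2, 3, 4)):
        space = ParameterSpace(
            names=["k"], bounds=np.array([[1.0, 4.0]]),
            kinds={"k": "categorical"}, codes={"k": list(codes)},
        )
        from lurpm.sobol import SobolDesign
        design = SobolDesign(samples=np.asarray(values, float).reshape(-1, 1),
                             N=1, D=1, names=["k"])
        return round_categoricals(design, space).samples.ravel()

    def test_rounding_rules(self):
        assert list(self.make([2.4, 2.6, 2.5])) == [2.0, 3.0, 3.0]

    def test_clamped_to_nearest_valid_code(self):
        assert list(self.make([2.4, 6.9], codes=(1, 3))) == [3.0, 3.0]
        assert list(self.make([0.2], codes=(1, 3))) == [1.0]


class TestEstimateIndices:
    def test_constant_model_all_zero(self):
        with pytest.warns(UserWarning, match="variance"):
            fos, tos = estimate_indices(np.ones(5 * 8), D=3, N=8)
        assert np.all(fos == 0) and np.all(tos == 0)

    def test_additive_two_input_model(self):
        space = unit_space(2)
        design = saltelli_sample(space, N=1024, seed=3)
        y = design.samples[:, 0] + design.samples[:, 1]
        fos, tos = estimate_indices(y, D=2, N=1024)
        assert np.allclose(fos, 0.5, atol=0.05)
        assert np.allclose(tos, fos, atol=0.05)
        assert 0.9 <= fos.sum() <= 1.1

    def test_pure_interaction_has_total_order_excess(self):
        space = unit_space(2, lo=-1.0, hi=1.0)
        design = saltelli_sample(space, N=1024, seed=4)
        y = design.samples[:, 0] * design.samples[:, 1]
        fos, tos = estimate_indices(y, D=2, N=1024)
        assert np.all(tos - fos > 0.1)

    def test_matches_naive_reimplementation(self, rng):
        N, D = 64, 3
        y = rng.normal(size=N * (D + 2))
        fos, tos = estimate_indices(y, D=D, N=N)
        nfos, ntos = naive_indices(y, D, N)
        assert np.allclose(fos, nfos, atol=1e-10)
        assert np.allclose(tos, ntos, atol=1e-10)

    def test_ishigami_closed_form(self):
        a, b = 7.0, 0.1
        space = unit_space(3, lo=-math.pi, hi=math.pi)
        design = saltelli_sample(space, N=2048, seed=5)
        x = design.samples
        y = (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
             + b * x[:, 2] ** 4 * np.sin(x[:, 0]))
        fos, tos = estimate_indices(y, D=3, N=2048)
        # analytic variance decomposition
        v1 = 0.5 * (1 + b * math.pi**4 / 5) ** 2
        v2 = a**2 / 8
        v13 = 8 * b**2 * math.pi**8 / 225
        v = v1 + v2 + v13
        expect_fos = np.array([v1 / v, v2 / v, 0.0])
        expect_tos = np.array([(v1 + v13) / v, v2 / v, v13 / v])
        assert np.allclose(fos, expect_fos, atol=0.05)
        assert np.allclose(tos, expect_tos, atol=0.05)
        assert np.all(tos >= fos - 0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_indices(np.ones(10), D=2, N=4)


class _StubModel:
    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return self.fn(np.asarray(X, dtype=float))


def stub_ensemble(fns, names):
    return ModelEnsemble(
        seeds=list(range(len(fns))),
        models={i: _StubModel(f) for i, f in enumerate(fns)},
        feature_names=names,
    )


class TestAggregateOverEnsemble:
    def test_single_model_mean_equals_its_indices(self):
        space = unit_space(2)
        design = saltelli_sample(space, N=256, seed=6)
        fn = lambda X: X[:, 0] + 2 * X[:, 1]  # noqa: E731
        ens = stub_ensemble([fn], design.names)
        res = aggregate_over_ensemble(ens, design)
        fos, _ = estimate_indices(fn(design.samples), D=2, N=256)
        assert np.allclose(res.mean_fos.to_numpy(), fos)

    def test_duplicated_model_zero_spread(self):
        space = unit_space(2)
        design = saltelli_sample(space, N=128, seed=7)
        fn = lambda X: X[:, 0]  # noqa: E731
        res = aggregate_over_ensemble(stub_ensemble([fn, fn], design.names), design)
        assert np.allclose(res.spread_fos.to_numpy(), 0.0)
        assert np.allclose(res.spread_tos.to_numpy(), 0.0)

    def test_constant_features_filled_for_prediction(self):
        space = unit_space(1)
        design = saltelli_sample(space, N=32, seed=8)
        ens = stub_ensemble([lambda X: X[:, 0] + X[:, 1]], ["x0", "const"])
        res = aggregate_over_ensemble(ens, design, constants={"const": 5.0})
        assert np.isfinite(res.mean_fos.to_numpy()).all()


class TestParameterSpaceAndScreening:
    def make_table(self, rng):
        data = pd.DataFrame(
            {
                "a": rng.uniform(0, 10, 50),
                "b": np.full(50, 3.0),
                "k": rng.integers(1, 4, 50).astype(float),
            }
        )
        return FeatureTable(
            data=data,
            feature_names=["a", "b", "k"],
            codebook={"K": [1, 2, 3]},
            column_kind={"a": "continuous", "b": "continuous",
                         "k": "categorical"},
            column_layer={"a": "A", "b": "B", "k": "K"},
            target=None,
        )

    def test_observed_bounds_and_constant_dropped(self, rng):
        table = self.make_table(rng)
        with pytest.warns(UserWarning, match="constant"):
            space = build_parameter_space(table)
        assert space.names == ["a", "k"]
        assert space.D == 2
        assert space.dropped == ["b"]
        assert space.constant_values == {"b": 3.0}
        assert space.bounds[0, 0] == table.data["a"].min()

    def test_all_constant_rejected(self):
        data = pd.DataFrame({"a": np.ones(10)})
        table = FeatureTable(data=data, feature_names=["a"],
                             column_kind={"a": "continuous"},
                             column_layer={"a": "A"}, target=None)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                build_parameter_space(table)

    def test_screening_threshold_strict(self):
        from lurpm.sobol import SensitivityResult

        res = SensitivityResult(
            names=["A", "B", "C"],
            fos=np.array([[0.3, 0.005, 0.01]]),
            tos=np.array([[0.4, 0.01, 0.02]]),
        )
        sel = screen_features(res, threshold=0.01)
        assert sel.parsimonious == ["A"]  # 0.01 boundary excluded

    def test_streets_union(self):
        from lurpm.sobol import SensitivityResult

        res = SensitivityResult(
            names=["A", "street_StEP_cat_max_25"],
            fos=np.array([[0.3, 0.0]]),
            tos=np.array([[0.3, 0.0]]),
        )
        sel = screen_features(res)
        assert sel.streets == ["A", "street_StEP_cat_max_25"]
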
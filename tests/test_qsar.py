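"""Forward-selection QSAR training, VIF guard, and the frozen registry."""

import numpy as np
import pandas as pd
import pytest

from nanosorb import (
    GeneratorConfig,
    LinearModel,
    SplitSpec,
    adjusted_r2,
    evaluate_model,
    forward_select,
    gen_table_from_model,
    partition_dataset,
    vif,
)
from nanosorb.qsar import adjusted_r2_from_r2


class TestPartitionDataset:
    def test_extremes_forced_into_train_and_cover(self, rng):
        resp = pd.Series(rng.normal(3, 1, 100), index=[f"c{i}" for i in range(100)])
        train, validate = partition_dataset(resp, SplitSpec(ratio=0.8, seed=0))
        assert set(train) | set(validate) == set(resp.index)
        assert not set(train) & set(validate)
        assert resp.idxmin() in train and resp.idxmax() in train
        assert 70 <= len(train) <= 90

    def test_two_compounds_all_train_with_warning(self):
        resp = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            train, validate = partition_dataset(resp, SplitSpec())
        assert sorted(train) == ["a", "b"] and validate == []

    def test_same_seed_same_partition(self, rng):
        resp = pd.Series(rng.normal(size=50), index=range(50))
        p1 = partition_dataset(resp, SplitSpec(seed=42))
        p2 = partition_dataset(resp, SplitSpec(seed=42))
        assert sorted(p1[0]) == sorted(p2[0]) and sorted(p1[1]) == sorted(p2[1])


class TestVif:
    def test_orthogonal_columns_give_one(self):
        design = pd.DataFrame({"x": [1, -1, 1, -1], "y": [1, 1, -1, -1]}, dtype=float)
        assert vif(design, "x") == pytest.approx(1.0)
        assert vif(design, "y") == pytest.approx(1.0)

    def test_duplicated_column_is_infinite(self):
        design = pd.DataFrame({"x": [1.0, 2, 3, 4], "x2": [1.0, 2, 3, 4]})
        assert vif(design, "x") == np.inf

    def test_matches_regress_and_invert_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        X["c"] = 0.6 * X["a"] + rng.normal(scale=0.5, size=30)
        for col in X.columns:
            others = X.drop(columns=col)
            import statsmodels.api as sm

            fit = sm.OLS(X[col], sm.add_constant(others)).fit()
            assert vif(X, col) == pytest.approx(1.0 / (1.0 - fit.rsquared), rel=1e-8)


class TestForwardSelect:
    def test_recovers_generating_model_noise_free(self, frozen_models):
        model = frozen_models["AlOOH"]
        table, resp = gen_table_from_model(
            model, GeneratorConfig(n=200, seed=1), n_decoys=10
        )
        result = forward_select(table, resp)
        assert sorted(result.model.descriptor_names) == sorted(model.descriptor_names)
        fitted = dict(result.model.terms)
        for name, coef in model.terms:
            assert fitted[name] == pytest.approx(coef, abs=1e-8)
        assert result.model.intercept == pytest.approx(model.intercept, abs=1e-8)

    def test_constant_response_gives_intercept_only(self):
        table = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 4)),
                             columns=list("abcd"))
        result = forward_select(table, np.full(20, 2.5))
        assert result.model.terms == ()
        assert result.model.intercept == pytest.approx(2.5)

    def test_duplicate_best_column_blocked_by_vif(self, rng):
        x = rng.normal(size=60)
        table = pd.DataFrame({"x1": x, "x1copy": x, "z": rng.normal(size=60)})
        resp = 2.0 * x + 0.5 * table["z"].to_numpy()
        result = forward_select(table, resp, max_terms=3)
        names = result.model.descriptor_names
        assert not {"x1", "x1copy"} <= set(names)

    def test_selection_trace_r2_non_decreasing(self, frozen_models, rng):
        model = frozen_models["TiO2_NM105"]
        table, resp = gen_table_from_model(
            model, GeneratorConfig(n=150, seed=5, noise_sd=0.3), n_decoys=8
        )
        result = forward_select(table, resp)
        r2s = [s.r2 for s in result.trace]
        assert all(a <= b + 1e-12 for a, b in zip(r2s, r2s[1:]))
        assert all(s.max_vif <= 2.0 for s in result.trace)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3, 4, 5, 6, 7])
        assert adjusted_r2(y, y, p=2) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # R^2 = 0.5, n = 11, p = 4 -> 1 - 0.5 * 10/6
        assert adjusted_r2_from_r2(0.5, n=11, p=4) == pytest.approx(1 - 0.5 * 10 / 6)
        assert adjusted_r2_from_r2(0.5, n=11, p=4) == pytest.approx(0.16667, abs=1e-4)

    def test_collapses_to_r2_when_p_zero(self):
        assert adjusted_r2_from_r2(0.37, n=50, p=0) == pytest.approx(0.37)

    def test_zero_variance_observed_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2([1, 2, 3], [2, 2, 2], p=1)

    def test_adjusted_not_above_unadjusted(self, rng):
        for _ in range(5):
            r2 = rng.uniform(0, 1)
            assert adjusted_r2_from_r2(r2, n=30, p=5) <= r2 + 1e-12


class TestFrozenRegistry:
    def test_nineteen_models_each_with_five_terms(self, frozen_models):
        assert len(frozen_models) == 19
        assert all(len(m.terms) == 5 for m in frozen_models.values())
        assert all(np.isfinite(m.intercept) for m in frozen_models.values())

    def test_registry_covers_all_nanomaterial_classes(self, frozen_models):
        ids = set(frozen_models)
        assert "FullrC60" in ids
        assert sum(i.startswith(("MWNT", "sMWCNT")) for i in ids) == 5
        assert len(ids) - 6 == 13  # the remaining models are metal ENMs

    def test_evaluate_at_zero_vector_returns_intercept(self, frozen_models):
        cols = sorted({n for m in frozen_models.values() for n in m.descriptor_names})
        zeros = pd.DataFrame(0.0, index=["z"], columns=cols)
        for m in frozen_models.values():
            assert evaluate_model(m, zeros).iloc[0] == pytest.approx(m.intercept)

    def test_evaluate_matches_dot_product_oracle(self, frozen_models, rng):
        model = frozen_models["SiO2_Naked"]
        table = pd.DataFrame(
            rng.normal(size=(10, 5)), columns=model.descriptor_names
        )
        got = evaluate_model(model, table)
        want = model.intercept + table.to_numpy() @ np.array(
            [c for _, c in model.terms]
        )
        np.testing.assert_allclose(got.to_numpy(), want, atol=1e-12)

    def test_missing_descriptor_column_named(self, frozen_models):
        table = pd.DataFrame({"ALogP": [1.0]})
        with pytest.raises(KeyError, match="Fsp3"):
            evaluate_model(frozen_models["Ag50_Citrat"], table)

    def test_repeated_descriptor_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            LinearModel("x", 0.0, (("a", 1.0), ("a", 2.0)))
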
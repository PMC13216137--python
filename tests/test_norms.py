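"""Covariate analysis: clustered correlations, regression, residual extremes."""

import numpy as np
import pandas as pd
import pytest

from bwsnorm import norms_analysis as na


@pytest.fixture(scope="module")
def planted():
    preds, util = na.synthesize_predictor_table(2000, seed=3)
    return preds, util


class TestClusteredCorrelation:
    def test_block_structure_groups_pairs(self):
        rng = np.random.default_rng(1)
        n = 500
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "x1": a + 0.1 * rng.normal(size=n),
                "y1": b + 0.1 * rng.normal(size=n),
                "x2": a + 0.1 * rng.normal(size=n),
                "y2": b + 0.1 * rng.normal(size=n),
            }
        )
        out = na.clustered_correlation_matrix(df)
        order = out["order"]
        # the two correlated pairs must be adjacent in cluster order
        assert abs(order.index("x1") - order.index("x2")) == 1
        assert abs(order.index("y1") - order.index("y2")) == 1

    def test_identical_columns_adjacent_with_unit_r(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=100)
        out = na.clustered_correlation_matrix(df)
        assert out["pearson"].loc["a", "b"] == pytest.approx(1.0)
        assert abs(out["order"].index("a") - out["order"].index("b")) == 1

    def test_spearman_of_rank_transform_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=200)
        df = pd.DataFrame({"x": x, "rx": pd.Series(x).rank(), "z": rng.normal(size=200)})
        out = na.clustered_correlation_matrix(df)
        assert out["spearman"].loc["x", "rx"] == pytest.approx(1.0)

    def test_order_invariant_to_row_shuffle(self, planted):
        preds, _ = planted
        num = preds.drop(columns=["item_id", "item"])
        out1 = na.clustered_correlation_matrix(num)
        shuffled = num.sample(frac=1.0, random_state=9)
        out2 = na.clustered_correlation_matrix(shuffled)
        assert out1["order"] == out2["order"]

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50), "c": 1.0})
        out = na.clustered_correlation_matrix(df)
        assert out["dropped_constant"] == ["c"]
        assert "c" not in out["pearson"].columns


class TestRegression:
    def test_exact_linear_fit_recovers_coefficients(self):
        rng = np.random.default_rng(5)
        n = 300
        preds = pd.DataFrame(
            {
                "item_id": np.arange(1, n + 1),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
            }
        )
        y = 0.3 + 1.5 * preds["x1"] - 2.0 * preds["x2"]
        scores = pd.Series(y.to_numpy(), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        coefs = rep.coefficients.set_index("term")["coef"]
        assert coefs["const"] == pytest.approx(0.3, abs=1e-8)
        assert coefs["x1"] == pytest.approx(1.5, abs=1e-8)
        assert coefs["x2"] == pytest.approx(-2.0, abs=1e-8)

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(6)
        n = 10_000
        preds = pd.DataFrame({"item_id": np.arange(1, n + 1)})
        for j in range(5):
            preds[f"x{j}"] = rng.normal(size=n)
        scores = pd.Series(rng.normal(size=n), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds)
        assert rep.r_squared < 0.01

    def test_planted_coefficients_recovered_within_3se(self, planted):
        preds, util = planted
        rep = na.fit_utility_regression(util.rename("score"), preds.drop(columns=["item", "is_mwe", "prevalence"]))
        coefs = rep.coefficients.set_index("term")
        spec = na.DEFAULT_COVARIATE_SPEC["coefficients"]
        for term, beta in spec.items():
            row = coefs.loc[term]
            assert abs(row["coef"] - beta) < 3 * row["se"], term

    def test_residuals_sum_to_zero_with_intercept(self, planted):
        preds, util = planted
        rep = na.fit_utility_regression(util.rename("score"), preds.drop(columns=["item"]))
        assert abs(rep.residuals.sum()) < 1e-8

    def test_matrix_closed_form_equals_qr_route(self, planted):
        preds, util = planted
        cols = ["frequency_zipf", "aoa", "concreteness"]
        rep = na.fit_utility_regression(
            util.rename("score"), preds[["item_id"] + cols]
        )
        X = np.column_stack([np.ones(len(preds)), preds[cols].to_numpy()])
        y = util.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = rep.coefficients.set_index("term")["coef"]
        np.testing.assert_allclose(
            got[["const"] + cols].to_numpy(), beta, atol=1e-8
        )

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(7)
        n = 100
        preds = pd.DataFrame({"item_id": np.arange(1, n + 1), "x1": rng.normal(size=n)})
        preds["x2"] = 2.0 * preds["x1"]
        scores = pd.Series(rng.normal(size=n), index=preds["item_id"], name="score")
        with pytest.raises(ValueError, match="x1.*x2|x2.*x1"):
            na.fit_utility_regression(scores, preds)

    def test_part_of_speech_treatment_coding(self):
        rng = np.random.default_rng(8)
        n = 400
        preds = pd.DataFrame(
            {
                "item_id": np.arange(1, n + 1),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "part_of_speech": rng.choice(["noun", "noun", "verb", "adj"], size=n),
            }
        )
        scores = pd.Series(rng.normal(size=n), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds)
        terms = set(rep.coefficients["term"])
        # most frequent category (noun) is the reference: no pos_noun dummy
        assert "pos_noun" not in terms
        assert {"pos_verb", "pos_adj"} <= terms


class TestResidualExtremes:
    def test_planted_outlier_tops_positive_table(self):
        rng = np.random.default_rng(9)
        n = 200
        preds = pd.DataFrame(
            {
                "item_id": np.arange(1, n + 1),
                "item": [f"w{i}" for i in range(n)],
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
            }
        )
        y = 0.5 + 0.1 * preds["x1"] - 0.1 * preds["x2"]
        y.iloc[42] += 0.2  # perturb one item upward
        scores = pd.Series(y.to_numpy(), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds[["item_id", "x1", "x2"]])
        ext = na.residual_extremes(rep, items=preds, top_n=5)
        assert ext["positive"].iloc[0]["item_id"] == 43
        assert not ext["degenerate"]

    def test_table_shape_and_columns(self, planted):
        preds, util = planted
        rep = na.fit_utility_regression(util.rename("score"), preds.drop(columns=["item"]))
        ext = na.residual_extremes(rep, items=preds, top_n=20)
        for side in ("positive", "negative"):
            tbl = ext[side]
            assert len(tbl) == 20
            assert {"Word", "Utility", "Predicted Utility"} <= set(tbl.columns)

    def test_exact_fit_flagged_degenerate(self):
        rng = np.random.default_rng(10)
        n = 50
        preds = pd.DataFrame(
            {"item_id": np.arange(1, n + 1), "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
        )
        y = preds["x1"] + preds["x2"]
        scores = pd.Series(y.to_numpy(), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds)
        ext = na.residual_extremes(rep, top_n=5)
        assert ext["degenerate"]

    def test_top_n_truncated_with_warning(self, planted):
        preds, util = planted
        rep = na.fit_utility_regression(util.rename("score"), preds.drop(columns=["item"]))
        with pytest.warns(UserWarning, match="truncating"):
            ext = na.residual_extremes(rep, top_n=10_000)
        assert len(ext["positive"]) == rep.n


class TestSynthesizer:
    def test_determinism(self):
        a, ua = na.synthesize_predictor_table(100, seed=1)
        b, ub = na.synthesize_predictor_table(100, seed=1)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(ua, ub)

    def test_identity_covariance_near_zero_cross_correlation(self):
        spec = {
            "columns": ["a", "b", "c"],
            "correlation": np.eye(3).tolist(),
            "coefficients": {"a": 1.0, "b": 0.0, "c": 0.0},
            "noise_sd": 0.1,
        }
        n = 5000
        preds, _ = na.synthesize_predictor_table(n, covariance_spec=spec, seed=2)
        corr = preds[["a", "b", "c"]].corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 4 / np.sqrt(n)

    def test_non_psd_spec_rejected(self):
        spec = {
            "columns": ["a", "b", "c"],
            "correlation": [[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
            "coefficients": {"a": 1.0, "b": 0.0, "c": 0.0},
        }
        with pytest.raises(ValueError, match="positive semidefinite"):
            na.synthesize_predictor_table(100, covariance_spec=spec)

    def test_planted_concreteness_sign_recovered_across_replicates(self):
        # the planted negative concreteness effect should be recovered with
        # a negative fitted coefficient in (essentially) every replicate
        hits = 0
        for seed in range(100):
            preds, util = na.synthesize_predictor_table(400, seed=seed)
            rep = na.fit_utility_regression(
                util.rename("score"),
                preds.drop(columns=["item", "is_mwe", "prevalence"]),
            )
            coef = rep.coefficients.set_index("term").loc["concreteness", "coef"]
            hits += coef < 0
        assert hits >= 99

    def test_default_spec_is_psd_and_complete(self):
        spec = na.DEFAULT_COVARIATE_SPEC
        R = np.asarray(spec["correlation"])
        assert np.linalg.eigvalsh(R).min() > -1e-10
        assert set(spec["coefficients"]) == set(spec["columns"])


class TestPermutationImportance:
    def test_strong_predictor_ranks_first(self):
        rng = np.random.default_rng(11)
        n = 1000
        preds = pd.DataFrame(
            {
                "item_id": np.arange(1, n + 1),
                "strong": rng.normal(size=n),
                "weak": rng.normal(size=n),
            }
        )
        y = 2.0 * preds["strong"] + 0.1 * preds["weak"] + rng.normal(size=n)
        scores = pd.Series(y.to_numpy(), index=preds["item_id"], name="score")
        rep = na.fit_utility_regression(scores, preds)
        imp = na.permutation_importance(rep, preds, scores, n_repeats=5, seed=0)
        assert imp.iloc[0]["term"] == "strong"
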